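"""The four data-integration methods.

Given per-SNP GWAS summary statistics (z_i, p_i) and an independent
annotation statistic z_add,i per SNP, four ways of combining them:

* inverse-variance **meta-analysis** of z-statistics,
* **Fisher's method** on p-values (chi-square with 4 df),
* the **weighted p-value** approach: p_i / w_i with non-negative,
  mean-one weights w_i built from the annotation alone,
* **stratified FDR (sFDR)** control: SNPs split into annotation-defined
  strata, FDR run per stratum at a common level, and the implied
  group-specific weights applied to the p-values.

Meta-analysis and Fisher treat the two sources as exchangeable evidence;
the weighting approaches treat the GWAS as primary and the annotation as
prior information only, which is what makes them robust to uninformative
or misleading scores.

All p-values are floored at ``P_FLOOR`` before any logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr
from scipy.stats import chi2

from .exceptions import ValidationError

#: global flooring constant applied to p-values before logarithms/divisions
P_FLOOR = 1e-300


def _check_p(p, name: str = "p") -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise ValidationError(f"{name} must be non-empty")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValidationError(f"{name} values must lie in (0, 1]")
    return arr


# ---------------------------------------------------------------------------
# meta-analysis and Fisher's method


def meta_combine(z, z_add, v=None, v_add=None):
    """Inverse-variance meta-analysis of the GWAS z and the rescaled z_add.

    ``Z_meta = (sqrt(1/v)*z + sqrt(1/v_add)*z_add) / sqrt(1/v + 1/v_add)``.
    With equal unit variances (the default, appropriate when z_add is an
    inverse-normal-rescaled score) this is ``(z + z_add)/sqrt(2)``.

    Returns
    -------
    (Z_meta, p) : tuple of ndarray
        The combined statistic and its two-sided normal p-value.
    """
    z = np.asarray(z, dtype=float)
    z_add = np.asarray(z_add, dtype=float)
    if z.shape != z_add.shape:
        raise ValidationError("z and z_add must have equal length")
    v = np.ones_like(z) if v is None else np.asarray(v, dtype=float)
    v_add = np.ones_like(z) if v_add is None else np.asarray(v_add, dtype=float)
    if v.shape != z.shape or v_add.shape != z.shape:
        raise ValidationError("variance vectors must match z in length")
    if np.any(v <= 0) or np.any(v_add <= 0):
        raise ValidationError("variances must be strictly positive")
    prec, prec_add = 1.0 / v, 1.0 / v_add
    z_meta = (np.sqrt(prec) * z + np.sqrt(prec_add) * z_add) / np.sqrt(prec + prec_add)
    p = 2.0 * ndtr(-np.abs(z_meta))
    return z_meta, p


def fisher_combine(p, p_add):
    """Fisher's method: ``-2*(ln p + ln p_add)``, chi-square with 4 df.

    Returns
    -------
    (stat, p_combined) : tuple of ndarray
    """
    p = _check_p(p, "p")
    p_add = _check_p(p_add, "p_add")
    if p.shape != p_add.shape:
        raise ValidationError("p and p_add must have equal length")
    stat = -2.0 * (np.log(np.maximum(p, P_FLOOR)) + np.log(np.maximum(p_add, P_FLOOR)))
    return stat, chi2.sf(stat, df=4)


# ---------------------------------------------------------------------------
# weighted p-values


@dataclass(frozen=True)
class WeightVector:
    """Per-SNP non-negative weights with mean exactly one.

    Attributes
    ----------
    w : ndarray
        The weights; ``mean(w) == 1`` within 1e-8 by construction.
    beta : float
        Scheme parameter.
    scheme : str
        ``"cumulative"`` or ``"exponential"``.
    """

    w: np.ndarray
    beta: float
    scheme: str

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if np.any(w < 0):
            raise ValidationError("weights must be non-negative")
        if abs(w.mean() - 1.0) > 1e-8:
            raise ValidationError("weights must average to one")
        object.__setattr__(self, "w", w)


def make_weights(z_add, beta: float = 2.0, scheme: str = "cumulative") -> WeightVector:
    """Build a valid weight vector from annotation scores.

    cumulative : ``w_i = m * Phi(z_add_i - beta) / sum_j Phi(z_add_j - beta)``
    exponential: ``w_i = m * exp(beta*z_add_i) / sum_j exp(beta*z_add_j)``,
    computed with a max-shift for overflow safety.

    The cumulative scheme (default, beta=2) is the recommended choice:
    the exponential scheme is highly sensitive to large scores, and
    phred-scale meta-scores can reach 80.
    """
    s = np.asarray(z_add, dtype=float)
    if s.size == 0:
        raise ValidationError("scores must be non-empty")
    if not np.all(np.isfinite(s)):
        raise ValidationError("scores must be finite")
    if scheme == "cumulative":
        base = ndtr(s - beta)
    elif scheme == "exponential":
        base = np.exp(beta * (s - s.max()))
    else:
        raise ValidationError(f"unknown weighting scheme: {scheme!r}")
    total = base.sum()
    if total <= 0:
        raise ValidationError("degenerate weights: normalizer is zero")
    return WeightVector(w=s.size * base / total, beta=beta, scheme=scheme)


def apply_weights(p, w) -> np.ndarray:
    """Weighted p-values ``min(p_i/w_i, 1)``; a zero weight maps to 1."""
    p = _check_p(p)
    wv = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    if wv.shape != p.shape:
        raise ValidationError("weights must match p in length")
    out = np.ones_like(p)
    pos = wv > 0
    out[pos] = np.minimum(p[pos] / wv[pos], 1.0)
    return out


# ---------------------------------------------------------------------------
# stratified FDR


def estimate_pi0(p) -> float:
    """Conservative null-proportion estimate ``#{p > 0.5} / (0.5*m)``.

    Clamped into ``[1/(0.5*m), 1]`` so downstream q-values stay valid even
    when no (or all) p-values exceed one half.
    """
    p = _check_p(p)
    m = p.size
    pi0 = np.count_nonzero(p > 0.5) / (0.5 * m)
    return float(min(1.0, max(1.0 / (0.5 * m), pi0)))


def qvalues(p, pi0: float) -> np.ndarray:
    """Step-up q-values from p-values and a null-proportion estimate.

    With ordered p_(1) <= ... <= p_(m):
    ``q_(m) = pi0 * p_(m)`` and ``q_(i) = min(pi0*m*p_(i)/i, q_(i+1))``.
    Ties in p share the q of the last tied position; output is returned in
    the original SNP order.
    """
    p = _check_p(p)
    if not (0.0 < pi0 <= 1.0):
        raise ValidationError("pi0 must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    raw = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = q_sorted
    return out


def stratify_by_score(scores, k: int = 2, top_fraction: float = 0.05) -> np.ndarray:
    """Assign SNPs to k strata from their annotation scores alone.

    Group 1 is the ``ceil(top_fraction*m)`` SNPs with the highest scores
    (the presumed high-priority stratum).  For k > 2 the remaining SNPs
    are split into k-1 equal-count score quantiles (groups 2..k in
    decreasing score order).  Assignment never looks at the GWAS p-values.

    Returns a 1-based integer group label per SNP.
    """
    s = np.asarray(scores, dtype=float)
    m = s.size
    if m == 0:
        raise ValidationError("scores must be non-empty")
    if k < 2:
        raise ValidationError("k must be at least 2")
    if k > m:
        raise ValidationError(f"k={k} exceeds the number of SNPs m={m}")
    if not (0.0 < top_fraction < 1.0):
        raise ValidationError("top_fraction must lie in (0, 1)")
    n_top = int(np.ceil(top_fraction * m))
    order = np.argsort(-s, kind="stable")  # ties: first occurrence wins
    groups = np.empty(m, dtype=np.int64)
    groups[order[:n_top]] = 1
    rest = order[n_top:]
    for g, chunk in enumerate(np.array_split(rest, k - 1), start=2):
        groups[chunk] = g
    return groups


@dataclass(frozen=True)
class SfdrFit:
    """Fitted stratified-FDR state.

    Attributes
    ----------
    k : int
        Number of strata.
    gamma : float
        FDR level used to derive the weights.
    group_of : ndarray
        1-based stratum label per SNP.
    m_k, pi0_k, alpha_k, w_k : ndarray
        Per-group sizes, null-proportion estimates, maximum rejected
        p-value (0 if the group rejects nothing), and group weights.
    q : ndarray
        Per-SNP q-values (computed within the SNP's group).
    """

    k: int
    gamma: float
    group_of: np.ndarray
    m_k: np.ndarray
    pi0_k: np.ndarray
    alpha_k: np.ndarray
    w_k: np.ndarray
    q: np.ndarray = field(repr=False)

    @property
    def weights_per_snp(self) -> np.ndarray:
        return self.w_k[self.group_of - 1]


def sfdr_weights(p, groups, gamma: float = 0.05) -> SfdrFit:
    """Run per-stratum FDR control and derive the implied group weights.

    Within each stratum: estimate pi0, compute q-values, reject q < gamma,
    and record alpha_k, the largest GWAS p among the rejected SNPs (0 if
    none).  The group weight is ``w_k = m * alpha_k / sum_j alpha_j m_j``,
    which covers the one-group-rejects edge case (the rejecting group gets
    m/m_k, the other 0); if no group rejects, all weights are 1 and the
    analysis reduces to the unweighted case.
    """
    p = _check_p(p)
    groups = np.asarray(groups)
    if groups.shape != p.shape:
        raise ValidationError("groups must match p in length")
    if not (0.0 < gamma < 1.0):
        raise ValidationError("gamma must lie in (0, 1)")
    labels = np.unique(groups)
    k = labels.size
    # relabel to contiguous 1..k to make indexing safe
    group_of = np.searchsorted(labels, groups) + 1
    m = p.size
    m_k = np.empty(k, dtype=np.int64)
    pi0_k = np.empty(k)
    alpha_k = np.empty(k)
    q = np.empty(m)
    for j in range(k):
        mask = group_of == j + 1
        m_k[j] = np.count_nonzero(mask)
        pi0_k[j] = estimate_pi0(p[mask])
        qj = qvalues(p[mask], pi0_k[j])
        q[mask] = qj
        rejected = qj < gamma
        alpha_k[j] = p[mask][rejected].max() if np.any(rejected) else 0.0
    denom = float(np.sum(alpha_k * m_k))
    if denom > 0.0:
        w_k = m * alpha_k / denom
    else:
        w_k = np.ones(k)
    return SfdrFit(
        k=k, gamma=gamma, group_of=group_of,
        m_k=m_k, pi0_k=pi0_k, alpha_k=alpha_k, w_k=w_k, q=q,
    )


def sfdr_adjust(
    p,
    scores,
    k: int = 2,
    top_fraction: float = 0.05,
    gamma: float = 0.05,
) -> tuple[np.ndarray, SfdrFit]:
    """sFDR-weighted p-values ``min(p_i / w^(g(i)), 1)``.

    Stratifies by score, fits the group weights at level gamma, and
    divides each p by its group weight (a zero weight maps to 1).

    Returns
    -------
    (p_sfdr, fit) : tuple of ndarray and SfdrFit
    """
    groups = stratify_by_score(scores, k=k, top_fraction=top_fraction)
    fit = sfdr_weights(p, groups, gamma=gamma)
    return apply_weights(p, fit.weights_per_snp), fit
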