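"""Transforms of variant functional meta-scores.

Meta-scores such as CADD or Eigen summarise many genomic features into a
single per-variant deleteriousness score.  The raw scores have no common
scale, so every downstream use here is rank-based:

* ``phred_scale`` — the phred convention, ``-10*log10(rank/m)`` with rank 1
  the most deleterious variant; a phred of 10 marks the top 10%, 20 the
  top 1%.  Because rank/m is uniform on the grid {1/m, ..., 1}, the phred
  scores of m variants behave like a ``(10/ln 10)/2 * chi^2_2`` sample
  (~2.17 chi^2_2).
* ``rank_uniform_p`` — the same ranks mapped to pseudo p-values rank/m,
  suitable for Fisher-style combination (small p = deleterious).
* ``inverse_normal_rescale`` — inverse-normal transform of the ranks,
  producing a unit-normal-scale statistic for inverse-variance
  meta-analysis; the sign is copied from the GWAS z so the combination is
  a best case for meta-analysis.

Ties are resolved by stable competition: the first occurrence in input
order receives the better (more deleterious) rank.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .exceptions import ValidationError

#: phred = -10*log10(U) = (10/ln 10)/2 * (-2*ln U), and -2*ln U is chi^2_2,
#: so phred/PHRED_CHI2_SCALE is chi-square with 2 df for uniform ranks.
PHRED_CHI2_SCALE = (10.0 / np.log(10.0)) / 2.0


def _as_vector(raw, name: str = "raw") -> np.ndarray:
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if arr.size == 0:
        raise ValidationError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def descending_ranks(raw) -> np.ndarray:
    """Competition ranks with rank 1 = highest score.

    Ties are broken by input order (first occurrence gets the better rank),
    making every rank-based transform deterministic.
    """
    arr = _as_vector(raw)
    order = np.argsort(-arr, kind="stable")
    ranks = np.empty(arr.size, dtype=np.int64)
    ranks[order] = np.arange(1, arr.size + 1)
    return ranks


def phred_scale(raw) -> np.ndarray:
    """Phred-scale raw scores: ``-10*log10(rank/m)``, rank 1 = highest raw.

    The output is non-negative; the least deleterious variant maps to
    exactly 0.  Invariant under any strictly increasing transform of the
    raw scores.
    """
    ranks = descending_ranks(raw)
    return -10.0 * np.log10(ranks / ranks.size)


def rank_uniform_p(raw) -> np.ndarray:
    """Rank-based pseudo p-values ``rank/m`` with rank 1 = highest score.

    For distinct scores the values form the exact uniform grid
    {1/m, ..., 1}; the most deleterious variant gets the smallest p.
    """
    ranks = descending_ranks(raw)
    return ranks / ranks.size


def inverse_normal_rescale(raw, sign_source) -> np.ndarray:
    """Inverse-normal transform of score ranks, direction-aligned with z.

    The raw score is rescaled to the normal quantile
    ``v = Phi^-1((r - 0.5)/m)`` with ``r`` the ascending rank (highest
    score -> largest quantile; the half offset keeps the extremes finite)
    and returned as ``sign(z) * v``, so that an above-median score pushes
    the combined statistic away from zero in the direction of the GWAS z,
    while a below-median score (negative quantile) attenuates it.
    ``sign(0)`` is treated as +1.  The multiset of magnitudes |z_add|
    always equals the quantile-grid magnitudes.

    This direction-alignment is the best case for meta-analysis: a
    deleterious variant is never penalised for disagreeing in sign with
    the GWAS statistic.
    """
    arr = _as_vector(raw)
    z = np.asarray(sign_source, dtype=float)
    if z.shape != arr.shape:
        raise ValidationError(
            f"sign_source length {z.size} does not match raw length {arr.size}"
        )
    if not np.all(np.isfinite(z)):
        raise ValidationError("sign_source contains non-finite values")
    m = arr.size
    asc = m + 1 - descending_ranks(arr)  # rank m = highest score
    v = ndtri((asc - 0.5) / m)
    sign = np.where(z >= 0.0, 1.0, -1.0)
    return sign * v


def similarity(score_i, score_j):
    """Pairwise functional-similarity ``1 - |a - b|/(a + b)`` in [0, 1].

    Defined for non-negative scores with a positive sum; symmetric and
    scale-invariant.  A value of 1 means identical scores, values near 0
    mean one score dwarfs the other.
    """
    a = np.asarray(score_i, dtype=float)
    b = np.asarray(score_j, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValidationError("similarity requires non-negative scores")
    total = a + b
    if np.any(total == 0):
        raise ValidationError("similarity undefined when both scores are zero")
    out = 1.0 - np.abs(a - b) / total
    if isinstance(score_i, numbers.Number) and isinstance(score_j, numbers.Number):
        return float(out)
    return out


def permute_scores(track: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Jointly permute the score columns of an annotation track.

    One uniform-random permutation is applied to every score column
    (``raw``, ``phred``, and any derived transforms present), leaving the
    ``snp_id`` order untouched.  This breaks any score/position association
    while conserving the score multiset — the construction used to obtain
    uninformative annotations for robustness checks.
    """
    if len(track) == 0:
        raise ValidationError("cannot permute an empty annotation track")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(track))
    out = track.copy()
    score_cols = [c for c in track.columns if c != "snp_id"]
    for col in score_cols:
        out[col] = track[col].to_numpy()[perm]
    return out
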