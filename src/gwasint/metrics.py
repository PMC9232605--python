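"""Evaluation statistics for data-integration methods.

Four complementary views of method performance:

* family-wise error rate (FWER) across null replicates,
* Recall / Precision / FDR against a baseline set of findings,
* power under different rejection rules (Bonferroni, fixed-region top-k,
  fixed-FDR),
* rank-based relative efficiency (RE): 1 minus the ratio of the mean rank
  of the truly associated SNPs after integration to their mean baseline
  rank; positive means the method moved the truth up the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .integrate import estimate_pi0, qvalues
from .loci import LocusSet


@dataclass(frozen=True)
class EvalReport:
    """Recall/Precision bookkeeping against a baseline finding set.

    ``m1`` is the baseline significant count, ``P`` the post-integration
    count, ``TP`` the retained baseline findings.  By convention,
    ``P == 0`` gives precision 1 and FDR 0; recall is None when m1 == 0.
    """

    m1: int
    P: int
    TP: int

    @property
    def FP(self) -> int:
        return self.P - self.TP

    @property
    def new_discoveries(self) -> int:
        return self.FP

    @property
    def recall(self) -> float | None:
        return self.TP / self.m1 if self.m1 > 0 else None

    @property
    def precision(self) -> float:
        return self.TP / self.P if self.P > 0 else 1.0

    @property
    def fdr(self) -> float:
        return 1.0 - self.precision


def eval_counts(baseline_sig: set, post_sig: set, m1: int | None = None) -> EvalReport:
    """Compare post-integration findings with the baseline set (by id)."""
    baseline_sig, post_sig = set(baseline_sig), set(post_sig)
    if m1 is None:
        m1 = len(baseline_sig)
    elif m1 != len(baseline_sig):
        raise ValidationError("m1 must equal the baseline set size")
    tp = len(baseline_sig & post_sig)
    return EvalReport(m1=m1, P=len(post_sig), TP=tp)


def eval_loci(
    baseline: LocusSet,
    post: LocusSet,
    alpha: float = 5e-8,
) -> EvalReport:
    """Locus-level Recall/Precision with shared-member matching.

    Clumps are recomputed per p-vector, so locus identity is matched by
    overlap: a post-integration significant locus counts as a true
    positive when it shares its index SNP or at least one member with a
    baseline significant locus.  Recall divides the number of matched
    post loci by the baseline count; because the same LD backs both
    clumpings, a retained baseline signal yields exactly one matching
    post locus.
    """
    base_sig = baseline.significant(alpha)
    base_members: set[str] = set()
    for locus in base_sig:
        base_members.update(locus.members)
    post_sig = post.significant(alpha)
    post_members: set[str] = set()
    for locus in post_sig:
        post_members.update(locus.members)
    tp_post = sum(1 for l in post_sig if base_members.intersection(l.members))
    tp_base = sum(1 for l in base_sig if post_members.intersection(l.members))
    # the two counts coincide except when loci split/merge across clumpings;
    # the min keeps TP <= min(m1, P) in those edge cases
    return EvalReport(m1=len(base_sig), P=len(post_sig), TP=min(tp_post, tp_base))


@dataclass(frozen=True)
class FwerReport:
    """Empirical FWER over null replicates.

    ``counts`` holds the per-replicate rejection counts; ``at_least[j]``
    tabulates how many replicates had >= j rejections (j = 1, 2, 3).
    """

    counts: np.ndarray

    @property
    def replicates(self) -> int:
        return int(self.counts.size)

    @property
    def fwer(self) -> float:
        return float(np.mean(self.counts >= 1))

    @property
    def se(self) -> float:
        f = self.fwer
        return float(np.sqrt(f * (1.0 - f) / self.replicates))

    @property
    def at_least(self) -> dict[int, int]:
        return {j: int(np.count_nonzero(self.counts >= j)) for j in (1, 2, 3)}

    @property
    def max_count(self) -> int:
        return int(self.counts.max())


def empirical_fwer(rejections_per_replicate) -> FwerReport:
    """Wrap per-replicate rejection counts into an FwerReport."""
    counts = np.asarray(rejections_per_replicate, dtype=np.int64)
    if counts.size == 0:
        raise ValidationError("at least one replicate is required")
    if np.any(counts < 0):
        raise ValidationError("rejection counts must be non-negative")
    return FwerReport(counts=counts)


def power_at_rule(
    snp_ids,
    p_integrated,
    truth: set,
    rule: str = "bonferroni",
    alpha: float = 0.05,
    k: int = 100,
    gamma: float = 0.05,
) -> float:
    """Power = share of truly associated SNPs rejected under a rule.

    rule="bonferroni": reject p < alpha/m.
    rule="top_k":      reject the k smallest p (stable ties).
    rule="fdr":        reject q < gamma with q-values over the full vector.
    """
    ids = np.asarray(snp_ids)
    p = np.asarray(p_integrated, dtype=float)
    if ids.shape != p.shape:
        raise ValidationError("snp_ids and p_integrated must match in length")
    truth = set(truth)
    if not truth:
        raise ValidationError("truth set must be nonempty")
    m = p.size
    if rule == "bonferroni":
        rejected = ids[p < alpha / m]
    elif rule == "top_k":
        if k > m:
            raise ValidationError(f"k={k} exceeds m={m}")
        rejected = ids[np.argsort(p, kind="stable")[:k]]
    elif rule == "fdr":
        q = qvalues(p, estimate_pi0(p))
        rejected = ids[q < gamma]
    else:
        raise ValidationError(f"unknown rejection rule: {rule!r}")
    return len(truth.intersection(rejected)) / len(truth)


@dataclass(frozen=True)
class REResult:
    """Rank-based relative efficiency of a method against the baseline."""

    mean_rank_baseline: float
    mean_rank_method: float

    @property
    def re(self) -> float:
        return 1.0 - self.mean_rank_method / self.mean_rank_baseline


def ranks_from_p(p) -> np.ndarray:
    """Significance ranks (1 = smallest p); ties broken by input order."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(p.size, dtype=np.int64)
    ranks[order] = np.arange(1, p.size + 1)
    return ranks


def relative_efficiency(rank_baseline, rank_method) -> REResult:
    """RE = 1 - mean(rank_method)/mean(rank_baseline) over the truth SNPs.

    Zero means no change, positive means improvement, negative means the
    integration was counter-productive.
    """
    rb = np.asarray(rank_baseline, dtype=float)
    rm = np.asarray(rank_method, dtype=float)
    if rb.size == 0 or rb.shape != rm.shape:
        raise ValidationError("rank vectors must be nonempty and equal-length")
    if np.any(rb < 1) or np.any(rm < 1):
        raise ValidationError("ranks are 1-based")
    return REResult(
        mean_rank_baseline=float(rb.mean()),
        mean_rank_method=float(rm.mean()),
    )
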