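"""Synthetic inputs with the statistical structure the methods assume.

Generators for every input the pipeline needs:

* null GWAS z-scores (iid standard normal, two-sided p),
* annotation tracks whose phred scores follow ~2.17 * chi^2_2 by
  construction (rank transform of an arbitrary continuous raw score),
* block-exchangeable LD genomes and heritable traits with clustered
  significant loci,
* the eight annotation-informativeness scenarios (completely informative,
  partially informative, misleading, uninformative) used to probe method
  robustness.

All generators are deterministic given a seed; replicate r of a run uses
the derived seed sequence (seed, r) so replicates are independent but
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .annotation import phred_scale
from .exceptions import ValidationError
from .loci import LdTable


def replicate_rng(seed: int, *subkeys: int) -> np.random.Generator:
    """Generator for replicate/stream ``subkeys`` of a master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(subkeys)))


def two_sided_p(z: np.ndarray) -> np.ndarray:
    """Two-sided normal p-value, floored away from exact zero."""
    return np.maximum(2.0 * ndtr(-np.abs(z)), 1e-300)


def _snp_ids(m: int) -> np.ndarray:
    return np.array([f"snp{i:07d}" for i in range(1, m + 1)])


def simulate_null_gwas(m: int, seed: int, chrom: str = "1", spacing: int = 1000) -> pd.DataFrame:
    """GWAS summary statistics under the complete null.

    z iid N(0, 1) with two-sided p; SNPs laid out on one chromosome at
    ``spacing`` bp.  Marginally identical to regressing a random trait on
    real genotypes, but with independence in place of LD.
    """
    if m < 1:
        raise ValidationError("m must be at least 1")
    rng = replicate_rng(seed)
    z = rng.standard_normal(m)
    return pd.DataFrame(
        {
            "snp_id": _snp_ids(m),
            "chrom": chrom,
            "pos": np.arange(1, m + 1, dtype=np.int64) * spacing,
            "z": z,
            "p": two_sided_p(z),
        }
    )


def simulate_scores(m: int, seed: int) -> pd.DataFrame:
    """Annotation track with phred scores ~2.17 * chi^2_2 by construction.

    Raw scores are iid uniform (any continuous distribution gives the same
    phred values, which depend on ranks only).
    """
    if m < 1:
        raise ValidationError("m must be at least 1")
    rng = replicate_rng(seed)
    raw = rng.random(m)
    return pd.DataFrame({"snp_id": _snp_ids(m), "raw": raw, "phred": phred_scale(raw)})


def simulate_ld_blocks(
    n_blocks: int,
    block_size: int | tuple[int, int],
    within_r2: float = 0.8,
    bp_spacing: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, LdTable]:
    """Exchangeable LD-block genome skeleton.

    SNPs sit on one chromosome at ``bp_spacing`` intervals; every pair
    within a block has r^2 = ``within_r2``, pairs across blocks have 0.
    ``block_size`` may be an int or an inclusive (low, high) range sampled
    per block.  The skeleton carries ``within_r2`` in ``df.attrs`` for the
    trait simulator.
    """
    if not (0.0 <= within_r2 < 1.0):
        raise ValidationError("within_r2 must lie in [0, 1)")
    if n_blocks < 1:
        raise ValidationError("n_blocks must be at least 1")
    rng = replicate_rng(seed)
    if isinstance(block_size, tuple):
        lo, hi = block_size
        sizes = rng.integers(lo, hi + 1, size=n_blocks)
    else:
        sizes = np.full(n_blocks, int(block_size), dtype=np.int64)
    m = int(sizes.sum())
    block = np.repeat(np.arange(n_blocks), sizes)
    snp = _snp_ids(m)
    skeleton = pd.DataFrame(
        {
            "snp_id": snp,
            "chrom": "1",
            "pos": np.arange(1, m + 1, dtype=np.int64) * bp_spacing,
            "block": block,
        }
    )
    skeleton.attrs["within_r2"] = float(within_r2)
    ld = LdTable()
    if within_r2 > 0.0:
        start = 0
        for size in sizes:
            ids = snp[start : start + size]
            for a in range(size):
                for b in range(a + 1, size):
                    ld.set(ids[a], ids[b], within_r2)
            start += size
    return skeleton, ld


def simulate_heritable_gwas(
    skeleton: pd.DataFrame,
    n_causal_blocks: int,
    ncp: float,
    seed: int,
) -> pd.DataFrame:
    """Trait summary statistics on an LD-block genome.

    Causal blocks are chosen uniformly.  Within each block, z-statistics
    share a common factor so that corr(z_i, z_j) = r = sqrt(within_r2),
    the z-score correlation LD implies.  The first SNP of a causal block
    is the causal one with mean ``ncp``; its block mates inherit the
    attenuated mean r*ncp.  All other blocks are null (mean 0) but carry
    the same within-block correlation.
    """
    n_blocks = int(skeleton["block"].max()) + 1
    if n_causal_blocks > n_blocks:
        raise ValidationError("n_causal_blocks exceeds n_blocks")
    r = float(np.sqrt(skeleton.attrs.get("within_r2", 0.0)))
    rng = replicate_rng(seed)
    causal = set(rng.choice(n_blocks, size=n_causal_blocks, replace=False).tolist())
    block = skeleton["block"].to_numpy()
    m = len(skeleton)
    # shared factor per block + idiosyncratic noise -> corr r within block
    shared = rng.standard_normal(n_blocks)
    noise = rng.standard_normal(m)
    z = np.sqrt(r) * shared[block] + np.sqrt(1.0 - r) * noise
    mu = np.zeros(m)
    first_in_block = np.flatnonzero(np.diff(block, prepend=-1) != 0)
    for b in causal:
        members = np.flatnonzero(block == b)
        mu[members] = r * ncp
        mu[first_in_block[b]] = ncp
    z = z + mu
    out = skeleton.copy()
    out["z"] = z
    out["p"] = two_sided_p(z)
    out["causal_block"] = np.isin(block, list(causal))
    return out


# ---------------------------------------------------------------------------
# informativeness scenarios


@dataclass(frozen=True)
class Scenario:
    """One configuration of the annotation-informativeness study.

    ``m1`` SNPs are truly associated (GWAS z ~ N(mu1, 1)); ``m_add`` SNPs
    are score-enriched (z_add ~ N(mu_add, 1)), of which ``overlap``
    coincide with the truth.  Category I is completely informative,
    II partially informative, III misleading, IV uninformative noise.
    """

    scenario_id: int
    category: str
    m_add: int
    mu_add: float
    overlap: int
    m: int = 10_000
    m1: int = 100
    mu1: float = 3.0

    def __post_init__(self):
        if not (0 <= self.overlap <= min(self.m1, self.m_add)):
            raise ValidationError("overlap must lie in [0, min(m1, m_add)]")
        if self.m1 > self.m or self.m_add > self.m:
            raise ValidationError("m1 and m_add cannot exceed m")


def scenario_catalog() -> list[Scenario]:
    """The eight annotation scenarios, in their canonical order."""
    return [
        Scenario(1, "I completely informative", m_add=100, mu_add=3.0, overlap=100),
        Scenario(2, "II partially informative", m_add=100, mu_add=1.5, overlap=100),
        Scenario(3, "II partially informative", m_add=50, mu_add=3.0, overlap=50),
        Scenario(4, "II partially informative", m_add=50, mu_add=1.5, overlap=50),
        Scenario(5, "III misleading", m_add=100, mu_add=3.0, overlap=50),
        Scenario(6, "III misleading", m_add=100, mu_add=1.5, overlap=50),
        Scenario(7, "III misleading", m_add=100, mu_add=3.0, overlap=0),
        Scenario(8, "IV uninformative", m_add=0, mu_add=0.0, overlap=0),
    ]


def simulate_design3_pair(sc: Scenario, seed: int) -> tuple[pd.DataFrame, np.ndarray]:
    """One replicate of (GWAS summary statistics, annotation z_add).

    The first ``m1`` SNPs are the truth with z ~ N(mu1, 1); the remaining
    SNPs are null.  ``overlap`` of the truth SNPs plus ``m_add - overlap``
    null SNPs (chosen uniformly without replacement, redrawn per
    replicate) receive enriched z_add ~ N(mu_add, 1); everything else gets
    N(0, 1).  Returns the GWAS table and the z_add vector.
    """
    rng = replicate_rng(seed)
    m, m1 = sc.m, sc.m1
    z = rng.standard_normal(m)
    z[:m1] += sc.mu1
    z_add = rng.standard_normal(m)
    if sc.m_add > 0:
        truth_part = rng.choice(m1, size=sc.overlap, replace=False)
        null_part = m1 + rng.choice(m - m1, size=sc.m_add - sc.overlap, replace=False)
        enriched = np.concatenate([truth_part, null_part])
        z_add[enriched] += sc.mu_add
    gwas = pd.DataFrame(
        {
            "snp_id": _snp_ids(m),
            "chrom": "1",
            "pos": np.arange(1, m + 1, dtype=np.int64) * 1000,
            "z": z,
            "p": two_sided_p(z),
        }
    )
    return gwas, z_add


@dataclass(frozen=True)
class SyntheticTrait:
    """Tag describing a simulated trait's heritability class.

    The labels mirror the four heritability-confidence categories used for
    biobank traits (nonsig / nominal / z4 / z7); here they are tags only.
    """

    label: str
    n_causal_loci: int
    effect_z: float

    def __post_init__(self):
        if self.label not in {"nonsig", "nominal", "z4", "z7"}:
            raise ValidationError(f"unknown trait label {self.label!r}")
        if self.label == "nonsig" and self.n_causal_loci != 0:
            raise ValidationError("nonsig traits must have no causal loci")
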