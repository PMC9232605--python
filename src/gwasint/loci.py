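"""Greedy LD clumping into independent loci.

Mirrors the common clumping convention: repeatedly take the most
significant unassigned SNP as an index, and pull into its locus every
unassigned SNP on the same chromosome within the base-pair window that is
in LD with it (r^2 strictly above the threshold).  Every SNP ends up in
exactly one locus; a locus is called significant when its index SNP passes
the genome-wide threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError


class LdTable:
    """Sparse pairwise LD (r^2) lookup keyed by SNP-id pairs.

    Absent pairs are treated as r^2 = 0; self-pairs are 1 by definition.
    """

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        r2 = float(r2)
        if not (0.0 <= r2 <= 1.0):
            raise ValidationError(f"r2 for ({a}, {b}) outside [0, 1]: {r2}")
        if a == b:
            return  # self-pairs implicit
        self._r2[self._key(a, b)] = r2

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LdTable":
        """Build from a three-column table (snp_a, snp_b, r2)."""
        required = {"snp_a", "snp_b", "r2"}
        if not required.issubset(df.columns):
            raise ValidationError(f"LD table needs columns {sorted(required)}")
        out = cls()
        for a, b, r2 in zip(df["snp_a"], df["snp_b"], df["r2"]):
            out.set(str(a), str(b), r2)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


@dataclass(frozen=True)
class Locus:
    index_snp: str
    members: tuple[str, ...]
    index_p: float

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class LocusSet:
    loci: tuple[Locus, ...]

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def significant(self, alpha: float = 5e-8) -> tuple[Locus, ...]:
        return tuple(l for l in self.loci if l.index_p < alpha)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": np.arange(1, len(self.loci) + 1),
                "index_snp": [l.index_snp for l in self.loci],
                "n_members": [len(l) for l in self.loci],
                "index_p": [l.index_p for l in self.loci],
            }
        )


def greedy_clump(
    gwas: pd.DataFrame,
    ld: LdTable,
    window_bp: int = 1_000_000,
    r2_threshold: float = 0.1,
) -> LocusSet:
    """Partition SNPs into independent loci by greedy LD clumping.

    Parameters
    ----------
    gwas : DataFrame
        Needs columns ``snp_id``, ``chrom``, ``pos``, ``p``.
    ld : LdTable
        Pairwise r^2; absent pairs count as 0.
    window_bp : int
        Half-window around the index SNP, inclusive.
    r2_threshold : float
        A SNP joins a clump only when r^2 with the index is *strictly*
        greater than this (r^2 equal to the threshold does not join).

    Loci are formed in order of increasing p; ties in p are broken by
    (chrom, pos, snp_id) so the output is deterministic.
    """
    for col in ("snp_id", "chrom", "pos", "p"):
        if col not in gwas.columns:
            raise ValidationError(f"clumping requires column {col!r}")
    if gwas["p"].isna().any():
        raise ValidationError("clumping requires a p-value for every SNP")

    snp = gwas["snp_id"].to_numpy()
    chrom = gwas["chrom"].astype(str).to_numpy()
    pos = gwas["pos"].to_numpy(dtype=np.int64)
    p = gwas["p"].to_numpy(dtype=float)

    # per-chromosome position-sorted views for windowed neighbour lookup
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        order = idx[np.argsort(pos[idx], kind="stable")]
        by_chrom[c] = (pos[order], order)

    visit = sorted(range(len(snp)), key=lambda i: (p[i], chrom[i], pos[i], snp[i]))
    assigned = np.zeros(len(snp), dtype=bool)
    loci: list[Locus] = []
    for i in visit:
        if assigned[i]:
            continue
        assigned[i] = True
        members = [i]
        cpos, cidx = by_chrom[chrom[i]]
        lo = np.searchsorted(cpos, pos[i] - window_bp, side="left")
        hi = np.searchsorted(cpos, pos[i] + window_bp, side="right")
        for j in cidx[lo:hi]:
            if assigned[j]:
                continue
            if ld.get(snp[i], snp[j]) > r2_threshold:
                assigned[j] = True
                members.append(j)
        loci.append(
            Locus(
                index_snp=snp[i],
                members=tuple(snp[k] for k in sorted(members)),
                index_p=float(p[i]),
            )
        )
    return LocusSet(loci=tuple(loci))


def count_significant_loci(loci: LocusSet, alpha: float = 5e-8) -> int:
    """Number of loci whose index SNP has p below alpha."""
    return len(loci.significant(alpha))
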