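"""Reading, writing and aligning the tabular formats the pipeline touches.

Canonical dialect: tab-separated with a header row; gzip is accepted
transparently (by file extension).  Coordinates are 1-based and inclusive;
scores are per-SNP and strand-free.

A GWAS summary table carries columns ``snp_id, chrom, pos, z, p`` (z or p
may be absent, with p back-filled from z but never the reverse — the sign
of z is unknowable from p alone).  An annotation table carries
``snp_id, raw, phred`` (phred back-filled from raw when absent).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .annotation import phred_scale
from .exceptions import AlignmentError, ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: default column names of a summary-statistics TSV
SUMSTAT_COLUMNS = {"snp": "snp", "chrom": "chr", "pos": "pos", "z": "z", "p": "p", "se": "se"}
ANNOTATION_COLUMNS = {"snp": "snp", "raw": "raw_score", "phred": "phred"}


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Check the GwasSummary invariants, raising ValidationError on breach."""
    if df["snp_id"].duplicated().any():
        dup = df["snp_id"][df["snp_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate snp_id {dup!r} in summary statistics")
    if (df["pos"] <= 0).any():
        raise ValidationError("positions must be strictly positive (1-based)")
    if "p" in df and df["p"].notna().any():
        p = df["p"].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isnan(p) & ((p <= 0) | (p > 1)))
        if bad.size:
            raise ValidationError(
                f"p outside (0, 1] at row {bad[0]} (snp {df['snp_id'].iloc[bad[0]]!r})"
            )
    if "z" in df and "p" in df:
        both = df["z"].notna() & df["p"].notna()
        if both.any():
            z = df.loc[both, "z"].to_numpy(dtype=float)
            p = df.loc[both, "p"].to_numpy(dtype=float)
            if np.max(np.abs(p - 2.0 * ndtr(-np.abs(z)))) > 1e-6:
                raise ValidationError("p and z are inconsistent (|p - 2*Phi(-|z|)| > 1e-6)")
    return df


def read_sumstats(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a summary-statistics TSV into a validated GwasSummary table.

    ``column_map`` maps the logical names (snp, chrom, pos, z, p, se) to
    the file's column names.  If only z is present, p is filled as
    ``2*Phi(-|z|)``; if only p is present, z is left absent.
    """
    names = {**SUMSTAT_COLUMNS, **(column_map or {})}
    raw = _read_tsv(path)
    for logical in ("snp", "chrom", "pos"):
        if names[logical] not in raw.columns:
            raise ConfigurationError(
                f"missing mandatory column {names[logical]!r} (for {logical})"
            )
    if names["z"] not in raw.columns and names["p"] not in raw.columns:
        raise ConfigurationError("summary statistics need a z or a p column")
    out = pd.DataFrame(
        {
            "snp_id": raw[names["snp"]].astype(str),
            "chrom": raw[names["chrom"]].astype(str),
            "pos": raw[names["pos"]].astype(np.int64),
        }
    )
    out["z"] = raw[names["z"]].astype(float) if names["z"] in raw.columns else np.nan
    if names["p"] in raw.columns:
        out["p"] = raw[names["p"]].astype(float)
    else:
        out["p"] = 2.0 * ndtr(-np.abs(out["z"].to_numpy()))
    if names["se"] in raw.columns:
        out["se"] = raw[names["se"]].astype(float)
    return validate_sumstats(out)


def read_annotations(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read an annotation TSV into an AnnotationTrack table.

    At least one of the raw-score / phred columns must be present; a
    missing phred column is computed from the raw scores.
    """
    names = {**ANNOTATION_COLUMNS, **(column_map or {})}
    raw = _read_tsv(path)
    if names["snp"] not in raw.columns:
        raise ConfigurationError(f"missing mandatory column {names['snp']!r}")
    has_raw = names["raw"] in raw.columns
    has_phred = names["phred"] in raw.columns
    if not has_raw and not has_phred:
        raise ConfigurationError("annotation table needs a raw_score or phred column")
    out = pd.DataFrame({"snp_id": raw[names["snp"]].astype(str)})
    if out["snp_id"].duplicated().any():
        raise ValidationError("duplicate snp_id in annotation table")
    out["raw"] = raw[names["raw"]].astype(float) if has_raw else np.nan
    if has_phred:
        out["phred"] = raw[names["phred"]].astype(float)
        if (out["phred"] < 0).any():
            raise ValidationError("phred scores must be non-negative")
    else:
        out["phred"] = phred_scale(out["raw"].to_numpy())
    return out


def write_table(df: pd.DataFrame, path) -> None:
    """Write any pipeline table as TSV (12 significant digits)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def align_tracks(
    gwas: pd.DataFrame,
    annotations: pd.DataFrame,
    policy: str = "inner",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align a GWAS table and an annotation track by SNP id.

    ``inner`` keeps the intersection (logging the dropped counts) in the
    GWAS table's order; ``strict`` requires the two id sets to be equal.
    Aligning already-aligned tables is the identity.
    """
    if len(gwas) == 0 or len(annotations) == 0:
        raise ValidationError("cannot align empty tables")
    g_ids = set(gwas["snp_id"])
    a_ids = set(annotations["snp_id"])
    if policy == "strict":
        if g_ids != a_ids:
            raise AlignmentError(
                f"strict alignment failed: {len(g_ids - a_ids)} GWAS-only ids, "
                f"{len(a_ids - g_ids)} annotation-only ids"
            )
        shared = g_ids
    elif policy == "inner":
        shared = g_ids & a_ids
        if not shared:
            raise AlignmentError("no shared snp_id between the two tables")
        dropped_g, dropped_a = len(g_ids) - len(shared), len(a_ids) - len(shared)
        if dropped_g or dropped_a:
            logger.info(
                "align_tracks: dropped %d GWAS rows and %d annotation rows",
                dropped_g, dropped_a,
            )
    else:
        raise ConfigurationError(f"unknown alignment policy {policy!r}")
    g = gwas[gwas["snp_id"].isin(shared)].reset_index(drop=True)
    a = annotations.set_index("snp_id").loc[g["snp_id"]].reset_index()
    return g, a
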