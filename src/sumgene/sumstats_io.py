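"""Reading, validation and writing of summary statistics and gene files.

GWAS summary files have no single column-name standard, so the reader
takes a dialect mapping from canonical names to file columns (with the
common SNP/CHR/POS/A1/A2/BETA/SE/P/EAF/N defaults). Validation derives z
from beta/se and p from z when absent, folds the effect-allele frequency
to MAF = min(f, 1−f), and rejects records with non-finite z or se.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import SUMSTATS_COLUMNS, GeneRegion

logger = logging.getLogger(__name__)

DEFAULT_DIALECT = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "A1",
    "other_allele": "A2",
    "beta": "BETA",
    "se": "SE",
    "z": "Z",
    "p": "P",
    "eaf": "EAF",
    "n": "N",
    "mac": "MAC",
}


class SumstatsFormatError(ValueError):
    """Required columns missing or irreparably malformed input."""


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return special.erfc(np.abs(z) / np.sqrt(2.0))


def read_sumstats(
    path: str | Path, dialect: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a summary-statistics table.

    Requires either beta+se or z; p is derived from z when absent, z from
    beta/se. Row order is preserved; records with non-finite z or
    non-positive se are dropped with a logged count.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    raw = pd.read_csv(path, sep="\t", dtype={mapping["variant_id"]: str})
    cols = {canon: fc for canon, fc in mapping.items() if fc in raw.columns}

    required = ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise SumstatsFormatError(f"missing required columns: {missing}")
    has_beta_se = "beta" in cols and "se" in cols
    if not has_beta_se and "z" not in cols:
        raise SumstatsFormatError("need either beta+se or z column")
    if "eaf" not in cols and "maf" not in raw.columns:
        raise SumstatsFormatError("need an allele-frequency column")

    df = pd.DataFrame({"variant_id": raw[cols["variant_id"]].astype(str)})
    df["chrom"] = raw[cols["chrom"]].astype(str)
    df["pos"] = raw[cols["pos"]].astype(np.int64)
    df["effect_allele"] = raw[cols["effect_allele"]].astype(str).str.upper()
    df["other_allele"] = raw[cols["other_allele"]].astype(str).str.upper()

    if has_beta_se:
        df["beta"] = raw[cols["beta"]].astype(float)
        df["se"] = raw[cols["se"]].astype(float)
        if "z" in cols:
            df["z"] = raw[cols["z"]].astype(float)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                df["z"] = df["beta"] / df["se"]
    else:
        df["z"] = raw[cols["z"]].astype(float)
        df["beta"] = np.nan
        df["se"] = np.nan

    if "p" in cols:
        df["p"] = raw[cols["p"]].astype(float)
    else:
        df["p"] = _two_sided_p(df["z"].to_numpy())

    if "eaf" in cols:
        f = raw[cols["eaf"]].astype(float)
        df["maf"] = np.minimum(f, 1.0 - f)
    else:
        df["maf"] = raw["maf"].astype(float)

    df["n"] = raw[cols["n"]].astype(np.int64) if "n" in cols else 0
    df["mac"] = raw[cols["mac"]].astype(float) if "mac" in cols else np.nan

    ok = np.isfinite(df["z"].to_numpy())
    if has_beta_se:
        ok &= np.isfinite(df["se"].to_numpy()) & (df["se"].to_numpy() > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%d records rejected (non-finite z or invalid se)", n_bad)
        df = df[ok]
    bad_maf = ~((df["maf"] > 0) & (df["maf"] <= 0.5))
    if bad_maf.any():
        logger.warning("%d records rejected (MAF outside (0, 0.5])", int(bad_maf.sum()))
        df = df[~bad_maf]
    return df.reset_index(drop=True)[SUMSTATS_COLUMNS]


def write_sumstats(stats: pd.DataFrame, path: str | Path) -> None:
    """Write a validated table back out in the default dialect."""
    rename = {k: v for k, v in DEFAULT_DIALECT.items() if k != "eaf"}
    rename["maf"] = "EAF"
    out = stats.rename(columns=rename)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def filter_variants(
    stats: pd.DataFrame,
    min_mac: int = 5,
    max_maf: float = 1.0,
    min_maf: float = 0.0,
) -> pd.DataFrame:
    """Apply the MAC/MAF inclusion filters, logging removals per criterion.

    Keeps records with mac ≥ min_mac (where mac is present) and
    min_maf < maf < max_maf.
    """
    if min_mac < 0 or min_maf < 0:
        raise ValueError("thresholds must be non-negative")
    if not min_maf < max_maf:
        raise ValueError("min_maf must be < max_maf")
    mac = stats["mac"].to_numpy(dtype=float)
    maf = stats["maf"].to_numpy(dtype=float)
    keep_mac = np.isnan(mac) | (mac >= min_mac)
    keep_maf = (maf > min_maf) & (maf < max_maf)
    logger.info(
        "filter_variants: %d removed by MAC, %d by MAF",
        int((~keep_mac).sum()), int((~keep_maf).sum()),
    )
    out = stats[keep_mac & keep_maf].reset_index(drop=True)
    if out.empty:
        logger.warning("filter_variants: no records retained")
    return out


def read_gene_regions(
    path: str | Path, stats: pd.DataFrame | None = None
) -> list[GeneRegion]:
    """Read gene definitions: (gene_id, variant_id) pairs or BED-like ranges.

    Range rows (gene_id, chrom, start, end; 1-based inclusive) are
    resolved against the summary-statistics positions, which must then be
    provided. Variants listed by id but absent from the statistics are
    retained in the definition and flagged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    regions: list[GeneRegion] = []
    if {"gene_id", "variant_id"}.issubset(cols):
        for gid, grp in df.groupby("gene_id", sort=True):
            vids = grp["variant_id"].tolist()
            if len(set(vids)) != len(vids):
                raise SumstatsFormatError(f"duplicate variant within gene {gid}")
            flagged = []
            if stats is not None:
                known = set(stats["variant_id"])
                flagged = [v for v in vids if v not in known]
            regions.append(GeneRegion(str(gid), vids, flagged_missing=flagged))
    elif {"gene_id", "chrom", "start", "end"}.issubset(cols):
        if stats is None:
            raise ValueError("range-based gene definitions need summary statistics")
        for row in df.itertuples(index=False):
            sel = stats[
                (stats["chrom"] == str(row.chrom))
                & (stats["pos"] >= int(row.start))
                & (stats["pos"] <= int(row.end))
            ]
            regions.append(GeneRegion(str(row.gene_id), sel["variant_id"].tolist()))
    else:
        raise SumstatsFormatError(
            "gene file needs (gene_id, variant_id) or (gene_id, chrom, start, end)"
        )
    empty = [r.gene_id for r in regions if len(r) == 0]
    if empty:
        logger.warning("%d empty genes excluded: %s", len(empty), empty[:5])
    return [r for r in regions if len(r) > 0]


def read_annotation_probs(path: str | Path):
    """Read (variant_id, channel...) probability table."""
    from .containers import AnnotationProbs

    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    return AnnotationProbs(df.astype(float))


def write_results(results: list, path: str | Path) -> None:
    """One row per gene, sorted by (chrom, pos of first variant).

    Columns: gene id, per-method combined p, overall omnibus p, number of
    variants used, flags. P-values carry 10 significant digits so a
    round-trip is lossless well beyond 1e-6 relative.
    """
    if not results:
        raise ValueError("write_results requires a non-empty result list")
    rows = [res.to_row() for res in results]
    df = pd.DataFrame(rows)
    sort_cols = [c for c in ("chrom", "start_pos") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def p_z_consistent(p: np.ndarray, z: np.ndarray, rtol: float = 1e-4) -> np.ndarray:
    """Check p against the two-sided tail of z on the −log10 scale."""
    nl_p = -np.log10(np.maximum(np.asarray(p, dtype=float), 1e-300))
    ln_one_sided = special.log_ndtr(-np.abs(np.asarray(z, dtype=float)))
    nl_from_z = -(ln_one_sided + np.log(2.0)) / np.log(10.0)
    return np.isclose(nl_p, nl_from_z, rtol=rtol, atol=1e-6)


def z_magnitude_from_p(p: np.ndarray) -> np.ndarray:
    """|z| implied by a two-sided p (inverse of the normal tail)."""
    return stats.norm.isf(np.asarray(p, dtype=float) / 2.0)
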