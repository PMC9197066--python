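"""Per-gene LD (genotype-correlation) matrices.

The region tests need the Pearson correlation matrix R between genotype
dosages of the variants in each gene, computed from the analysis sample
itself or from an ancestry-matched reference panel. This module builds R
from a dosage panel (with the panel-quality filters on MAF and
imputation info), repairs numerically indefinite matrices to valid
correlation structure, stores matrices per gene, and aligns a gene's
summary statistics, probabilities and LD on one canonical variant order
(flipping z when the effect allele is swapped between the two sources).
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import AlignedGene, AnnotationProbs, GeneRegion, LDMatrix

logger = logging.getLogger(__name__)

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def build_ld(
    genotypes: np.ndarray,
    variant_ids: list[str],
    min_maf: float = 1e-5,
    min_info: float = 0.3,
    info: np.ndarray | None = None,
) -> LDMatrix:
    """Pearson correlations between dosage columns of a genotype panel.

    Variants failing the panel filters (MAF ≤ ``min_maf``, imputation
    info ≤ ``min_info`` when an info vector is given) and monomorphic
    variants are excluded.
    """
    geno = np.asarray(genotypes, dtype=float)
    if geno.ndim != 2 or geno.shape[0] < 2:
        raise ValueError("genotype panel must be n×m with n >= 2")
    n, m = geno.shape
    if len(variant_ids) != m:
        raise ValueError("variant id count does not match panel columns")
    freq = geno.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf > min_maf
    if info is not None:
        keep &= np.asarray(info, dtype=float) > min_info
    sd = geno.std(axis=0)
    mono = sd == 0
    if np.any(mono & keep):
        logger.warning("%d monomorphic variants excluded from LD", int(np.sum(mono & keep)))
    keep &= ~mono
    if not np.any(keep):
        raise ValueError("no variants left after LD panel filters")
    idx = np.flatnonzero(keep)
    r = np.corrcoef(geno[:, idx], rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    return LDMatrix([variant_ids[k] for k in idx], r, panel_n=n)


def repair_psd(ld: LDMatrix) -> LDMatrix:
    """Clip negative eigenvalues and rescale to unit diagonal.

    A no-op (same object) when the matrix is already PSD within 1e-10;
    otherwise the minimal eigenvalue-clipping repair, followed by
    rescaling back to a correlation matrix.
    """
    r = ld.r
    if not np.allclose(r, r.T, atol=0.0):
        raise ValueError("repair_psd requires a symmetric matrix")
    evals, evecs = np.linalg.eigh(r)
    if evals[0] >= -1e-10:
        return ld
    evals = np.clip(evals, 0.0, None)
    fixed = (evecs * evals) @ evecs.T
    d = np.sqrt(np.diag(fixed))
    d[d == 0] = 1.0
    fixed = fixed / np.outer(d, d)
    fixed = np.clip(0.5 * (fixed + fixed.T), -1.0, 1.0)
    np.fill_diagonal(fixed, 1.0)
    return LDMatrix(list(ld.variant_ids), fixed, ld.panel_n)


def align(
    stats: pd.DataFrame,
    region: GeneRegion,
    ld: LDMatrix,
    probs: AnnotationProbs | None = None,
    panel_alleles: pd.DataFrame | None = None,
    drop_ambiguous: bool = True,
) -> AlignedGene | None:
    """Intersect a gene's summary stats with its LD matrix on one order.

    The canonical order is the region's variant order restricted to the
    intersection. When ``panel_alleles`` (columns effect_allele /
    other_allele indexed by variant_id) is given, z-scores are negated
    for variants whose effect allele in the stats is the panel's other
    allele; strand-ambiguous pairs (A/T, C/G) are dropped by default;
    irreconcilable allele pairs are dropped with a count. Returns None
    (gene skipped) when the intersection is empty.
    """
    st = stats.set_index("variant_id", drop=False)
    in_ld = set(ld.variant_ids)
    ordered = [v for v in region.variant_ids if v in in_ld and v in st.index]
    if not ordered:
        logger.info("gene %s skipped: empty stats∩LD∩region", region.gene_id)
        return None

    flips: dict[str, float] = {}
    dropped_mismatch = 0
    if panel_alleles is not None:
        keep: list[str] = []
        for v in ordered:
            ea, oa = str(st.at[v, "effect_allele"]).upper(), str(st.at[v, "other_allele"]).upper()
            if drop_ambiguous and (ea, oa) in _AMBIGUOUS:
                continue
            pea = str(panel_alleles.at[v, "effect_allele"]).upper()
            poa = str(panel_alleles.at[v, "other_allele"]).upper()
            if (ea, oa) == (pea, poa):
                flips[v] = 1.0
                keep.append(v)
            elif (ea, oa) == (poa, pea):
                flips[v] = -1.0
                keep.append(v)
            else:
                dropped_mismatch += 1
        ordered = keep
    if dropped_mismatch:
        logger.warning("gene %s: %d variants dropped (allele mismatch)",
                       region.gene_id, dropped_mismatch)
    if not ordered:
        logger.info("gene %s skipped: no alignable variants", region.gene_id)
        return None

    ld_pos = {v: k for k, v in enumerate(ld.variant_ids)}
    idx = np.array([ld_pos[v] for v in ordered], dtype=int)
    sign = np.array([flips.get(v, 1.0) for v in ordered])
    sub = st.loc[ordered]
    pos = sub["pos"].to_numpy(dtype=float) if "pos" in sub else None
    return AlignedGene(
        gene_id=region.gene_id,
        variant_ids=ordered,
        z=sub["z"].to_numpy(dtype=float) * sign,
        maf=sub["maf"].to_numpy(dtype=float),
        ld=ld.subset(idx),
        pos=pos,
        probs=probs,
    )


# ---------------------------------------------------------------------------
# storage
# ---------------------------------------------------------------------------


class LDStore:
    """Per-gene LD container backed by one HDF5 file.

    Layout: one group per gene holding ``variant_ids`` (UTF-8 strings),
    scalar ``panel_n`` and the lower triangle of r as float32
    (``r_tril``). A gzip-text sidecar format is provided for
    interoperability (:func:`write_ld_text`/:func:`read_ld_text`).
    """

    def __init__(self, path: str | Path, mode: str = "r"):
        self.path = Path(path)
        self._h5 = h5py.File(self.path, mode)

    def close(self) -> None:
        self._h5.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._h5

    def genes(self) -> list[str]:
        return sorted(self._h5.keys())

    def put(self, gene_id: str, ld: LDMatrix) -> None:
        if gene_id in self._h5:
            del self._h5[gene_id]
        grp = self._h5.create_group(gene_id)
        grp.create_dataset(
            "variant_ids", data=np.array(ld.variant_ids, dtype=object),
            dtype=h5py.string_dtype("utf-8"),
        )
        grp.attrs["panel_n"] = int(ld.panel_n)
        grp.create_dataset(
            "r_tril", data=ld.r[np.tril_indices(ld.m)].astype(np.float32)
        )

    def get(self, gene_id: str) -> LDMatrix:
        grp = self._h5[gene_id]
        ids = [v.decode() if isinstance(v, bytes) else str(v)
               for v in grp["variant_ids"][()]]
        m = len(ids)
        r = np.zeros((m, m))
        r[np.tril_indices(m)] = grp["r_tril"][()].astype(float)
        r = r + np.tril(r, -1).T
        np.fill_diagonal(r, 1.0)
        return LDMatrix(ids, r, int(grp.attrs["panel_n"]))


def write_ld_text(ld: LDMatrix, path: str | Path) -> None:
    """Gzip-text per-gene format: header lines then the lower triangle."""
    with gzip.open(path, "wt") as fh:
        fh.write(f"#panel_n\t{ld.panel_n}\n")
        fh.write("#variants\t" + "\t".join(ld.variant_ids) + "\n")
        for a in range(ld.m):
            fh.write("\t".join(f"{ld.r[a, b]:.7g}" for b in range(a + 1)) + "\n")


def read_ld_text(path: str | Path) -> LDMatrix:
    with gzip.open(path, "rt") as fh:
        panel_n = int(fh.readline().strip().split("\t")[1])
        ids = fh.readline().strip().split("\t")[1:]
        m = len(ids)
        r = np.zeros((m, m))
        for a in range(m):
            row = [float(v) for v in fh.readline().split("\t")]
            r[a, : a + 1] = row
    r = r + np.tril(r, -1).T
    np.fill_diagonal(r, 1.0)
    return LDMatrix(ids, r, panel_n)


def read_ld_plain(path: str | Path, panel_n: int = 0) -> LDMatrix:
    """Plain-text square-matrix reader (header row + column of ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(v) for v in df.index]
    if list(df.columns) != ids:
        raise ValueError("square LD matrix must have matching row/column ids")
    return LDMatrix(ids, df.to_numpy(dtype=float), panel_n)
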