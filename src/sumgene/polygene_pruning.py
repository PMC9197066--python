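"""Polygene pruning: shield a gene from strong GWAS signals outside it.

A genome-wide-significant association just outside a gene can leak into
the gene-based statistic through LD, inflating it for reasons unrelated
to the gene itself. Pruning removes every within-gene variant whose
squared correlation with any such outside hit exceeds a threshold —
in effect an extreme 0/1 down-weighting by outside LD. The alternative
(conditional analysis on the outside hits) needs genotypes or a joint
model; pruning needs only cross-correlations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import AlignedGene, GeneRegion, PruneConfig

logger = logging.getLogger(__name__)


def find_outside_hits(
    stats: pd.DataFrame, region: GeneRegion, cfg: PruneConfig | None = None
) -> list[str]:
    """Genome-wide-significant variants flanking (but not inside) the gene.

    The search window is the span of the gene's variants extended by
    ``cfg.window_bp`` on each side, on the gene's chromosome.
    """
    cfg = cfg or PruneConfig()
    inside = set(region.variant_ids)
    members = stats[stats["variant_id"].isin(inside)]
    if members.empty:
        return []
    chrom = members["chrom"].iloc[0]
    lo = members["pos"].min() - cfg.window_bp
    hi = members["pos"].max() + cfg.window_bp
    cand = stats[
        (stats["chrom"] == chrom)
        & (stats["pos"] >= lo)
        & (stats["pos"] <= hi)
        & (~stats["variant_id"].isin(inside))
        & (stats["p"] < cfg.outside_p_threshold)
    ]
    return cand["variant_id"].tolist()


def prune_gene(
    g: AlignedGene,
    hits: list[str],
    cross_ld: pd.DataFrame,
    cfg: PruneConfig | None = None,
) -> AlignedGene | None:
    """Drop gene variants in strong LD with any outside hit.

    ``cross_ld`` holds correlations r (not r²) with gene variants as rows
    and hit ids as columns. Returns the re-aligned gene, the unchanged
    gene when there are no hits, or None when every variant is pruned.
    """
    cfg = cfg or PruneConfig()
    if not hits:
        return g
    missing = [h for h in hits if h not in cross_ld.columns]
    if missing:
        raise ValueError(f"cross-LD missing hits: {missing}")
    r = cross_ld.reindex(index=g.variant_ids, columns=hits).to_numpy(dtype=float)
    if np.any(np.isnan(r)):
        raise ValueError("cross-LD must cover all (gene variant, hit) pairs")
    max_r2 = np.max(r**2, axis=1)
    keep = np.flatnonzero(max_r2 < cfg.ld_r2_threshold)
    n_pruned = g.m - keep.size
    if keep.size == 0:
        logger.warning("gene %s: all variants pruned by outside LD", g.gene_id)
        return None
    if n_pruned == 0:
        return g
    out = g.subset(keep)
    out.flags.add("pruned")
    out.flags.add(f"pruned_n={n_pruned}")
    return out


def prune_table(
    g: AlignedGene, hits: list[str], cross_ld: pd.DataFrame,
    cfg: PruneConfig | None = None,
) -> pd.DataFrame:
    """Tab-separated pruning report: which variant fell to which hit."""
    cfg = cfg or PruneConfig()
    rows = []
    if hits:
        r = cross_ld.reindex(index=g.variant_ids, columns=hits).to_numpy(dtype=float)
        r2 = r**2
        for k, vid in enumerate(g.variant_ids):
            jmax = int(np.argmax(r2[k]))
            if r2[k, jmax] >= cfg.ld_r2_threshold:
                rows.append(
                    {"gene_id": g.gene_id, "variant_id": vid,
                     "max_r2": r2[k, jmax], "hit_id": hits[jmax]}
                )
    return pd.DataFrame(rows, columns=["gene_id", "variant_id", "max_r2", "hit_id"])
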