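"""The omnibus grid driver: methods × weighting functions × probabilities.

No single gene-based test is uniformly most powerful — which test wins
depends on the (unknown) genetic architecture of the gene. The omnibus
therefore evaluates each chosen method under every combination of
beta-MAF weighting function (index i ∈ [1, I]) and causal-probability
channel (index j ∈ [0, J]; j = 0 means no annotation), then combines the
resulting p-value lattice by a two-level Cauchy (ACAT) scheme: first
across the (i, j) cells within a method, then across methods.

The driver is organized as a model/results pair: :class:`GeneAssociation`
binds one aligned gene to a test configuration, its :meth:`fit` computes
the lattice and the combined p-values and returns a
:class:`GeneAssociationResults` with a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._acat import acat_combine, cauchy_sf  # noqa: F401  (re-exported)
from .containers import (
    ALL_METHODS,
    AlignedGene,
    AnnotationProbs,
    ApproxConfig,
    TestConfig,
    WeightGrid,
)
from .large_gene import approx_test
from .region_tests import (
    CollinearityError,
    DegenerateTestError,
    run_test,
)
from .weighting import ZeroWeightsError, beta_weights, effective_weights

logger = logging.getLogger(__name__)


@dataclass
class GeneResult:
    """P-value lattice and combined p-values for one gene."""

    gene_id: str
    p_lattice: dict[tuple[str, int, int], float]
    p_method: dict[str, float]
    p_overall: float | None
    m_used: int
    flags: set = field(default_factory=set)
    chrom: str | None = None
    start_pos: int | None = None

    def to_row(self) -> dict:
        row = {"gene_id": self.gene_id}
        if self.chrom is not None:
            row["chrom"] = self.chrom
        if self.start_pos is not None:
            row["start_pos"] = self.start_pos
        for method in ALL_METHODS:
            row[f"p_{method}"] = self.p_method.get(method, np.nan)
        row["p_overall"] = self.p_overall if self.p_overall is not None else np.nan
        row["m_used"] = self.m_used
        row["flags"] = ";".join(sorted(self.flags)) or "."
        return row


class GeneAssociation:
    """Gene-based omnibus association model for one aligned gene.

    Parameters
    ----------
    gene : aligned per-gene data (z, MAF, LD, positions, probabilities).
    methods : subset of {BT, SKAT, SKATO, ACATV, FLM, PCA}.
    weight_grid : beta-density parameter pairs (the i axis).
    test_config, approx_config : tuning knobs for the individual tests
        and the large-gene approximation routing.
    """

    def __init__(
        self,
        gene: AlignedGene,
        methods: tuple[str, ...] = ALL_METHODS,
        weight_grid: WeightGrid | None = None,
        test_config: TestConfig | None = None,
        approx_config: ApproxConfig | None = None,
    ):
        if not methods:
            raise ValueError("at least one method required")
        unknown = set(methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        self.gene = gene
        self.methods = tuple(methods)
        self.weight_grid = weight_grid or WeightGrid()
        self.test_config = test_config or TestConfig()
        self.approx_config = approx_config or ApproxConfig()

    @property
    def n_channels(self) -> int:
        return self.gene.probs.n_channels if self.gene.probs is not None else 0

    def _cell_p(self, method: str, w) -> float:
        g = self.gene
        cfg = self.approx_config
        if g.m > cfg.trigger_m and method in cfg.enabled_methods:
            return approx_test(g, w, method, cfg, self.test_config)
        return run_test(method, g, w, self.test_config)

    def fit(self) -> "GeneAssociationResults":
        """Compute the full p-value lattice and the two-level combination."""
        g = self.gene
        lattice: dict[tuple[str, int, int], float] = {}
        flags = set(g.flags)
        if g.m > self.approx_config.trigger_m and any(
            m in self.approx_config.enabled_methods for m in self.methods
        ):
            flags.add("approximated")
        for i, (a1, a2) in enumerate(self.weight_grid.specs, start=1):
            wb = beta_weights(g.maf, a1, a2)
            for j in range(self.n_channels + 1):
                probs_j = (
                    g.probs.channel(j, g.variant_ids) if j >= 1 else None
                )
                try:
                    w = effective_weights(wb, probs_j, i=i, j=j)
                except ZeroWeightsError:
                    logger.info("gene %s: cell (i=%d, j=%d) skipped, zero weights",
                                g.gene_id, i, j)
                    continue
                for method in self.methods:
                    try:
                        lattice[(method, i, j)] = self._cell_p(method, w)
                    except CollinearityError:
                        flags.add("flm_rejected")
                    except DegenerateTestError as exc:
                        logger.info("gene %s: %s cell (%d,%d) degenerate: %s",
                                    g.gene_id, method, i, j, exc)
        p_method: dict[str, float] = {}
        for method in self.methods:
            cells = [p for (mth, _, _), p in lattice.items() if mth == method]
            if cells:
                p_method[method] = acat_combine(cells)
        p_overall = acat_combine(list(p_method.values())) if p_method else None
        return GeneAssociationResults(
            model=self,
            result=GeneResult(
                gene_id=g.gene_id,
                p_lattice=lattice,
                p_method=p_method,
                p_overall=p_overall,
                m_used=g.m,
                flags=flags,
                chrom=None,
                start_pos=None,
            ),
        )


class GeneAssociationResults:
    """Fitted omnibus results for one gene."""

    def __init__(self, model: GeneAssociation, result: GeneResult):
        self.model = model
        self.result = result

    @property
    def p_overall(self) -> float | None:
        return self.result.p_overall

    @property
    def p_method(self) -> dict[str, float]:
        return self.result.p_method

    @property
    def p_lattice(self) -> dict[tuple[str, int, int], float]:
        return self.result.p_lattice

    def lattice_frame(self) -> pd.DataFrame:
        rows = [
            {"method": mth, "i": i, "j": j, "p": p}
            for (mth, i, j), p in sorted(self.result.p_lattice.items())
        ]
        return pd.DataFrame(rows, columns=["method", "i", "j", "p"])

    def summary(self) -> str:
        res = self.result
        lines = [
            "Gene-based omnibus association",
            "=" * 46,
            f"gene:            {res.gene_id}",
            f"variants used:   {res.m_used}",
            f"methods:         {', '.join(self.model.methods)}",
            f"weight grid (I): {self.model.weight_grid.I}",
            f"channels (J):    {self.model.n_channels}",
            f"flags:           {', '.join(sorted(res.flags)) or '-'}",
            "-" * 46,
        ]
        for method in self.model.methods:
            if method in res.p_method:
                lines.append(f"  {method:<6} combined p = {res.p_method[method]:.6g}")
            else:
                lines.append(f"  {method:<6} combined p = (no valid cells)")
        lines.append("-" * 46)
        if res.p_overall is not None:
            lines.append(f"  omnibus (ACAT) p = {res.p_overall:.6g}")
        else:
            lines.append("  omnibus (ACAT) p = (gene not testable)")
        return "\n".join(lines)


def run_gene(
    g: AlignedGene,
    methods: tuple[str, ...] = ALL_METHODS,
    wgrid: WeightGrid | None = None,
    probs: AnnotationProbs | None = None,
    cfg: TestConfig | None = None,
    approx_cfg: ApproxConfig | None = None,
) -> GeneResult:
    """Functional wrapper: fit the omnibus model for one gene."""
    if probs is not None:
        g.probs = probs
    model = GeneAssociation(g, methods, wgrid, cfg, approx_cfg)
    return model.fit().result


def run_analysis(
    stats: pd.DataFrame,
    regions,
    ld_getter,
    probs: AnnotationProbs | None = None,
    methods: tuple[str, ...] = ALL_METHODS,
    wgrid: WeightGrid | None = None,
    cfg: TestConfig | None = None,
    approx_cfg: ApproxConfig | None = None,
    panel_alleles: pd.DataFrame | None = None,
) -> list[GeneResult]:
    """Per-gene omnibus analysis over a list of gene regions.

    ``ld_getter`` maps gene_id → LDMatrix (an :class:`~sumgene.ld_reference.
    LDStore` works directly). Genes with no usable variants are skipped
    with a logged reason; failure is aggregate only if nothing runs.
    """
    from .ld_reference import align

    results: list[GeneResult] = []
    st = stats.set_index("variant_id", drop=False)
    for region in regions:
        try:
            ld = ld_getter.get(region.gene_id) if hasattr(ld_getter, "get") else ld_getter(region.gene_id)
        except KeyError:
            logger.info("gene %s skipped: no LD matrix", region.gene_id)
            continue
        if ld is None:
            logger.info("gene %s skipped: no LD matrix", region.gene_id)
            continue
        g = align(stats, region, ld, probs, panel_alleles)
        if g is None:
            continue
        res = run_gene(g, methods, wgrid, probs, cfg, approx_cfg)
        if not res.p_lattice:
            logger.info("gene %s skipped: zero valid grid cells", region.gene_id)
            continue
        first = g.variant_ids[0]
        if first in st.index:
            res.chrom = str(st.at[first, "chrom"])
            res.start_pos = int(st.at[first, "pos"])
        results.append(res)
    if not results:
        raise RuntimeError("no genes analyzable")
    return results
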