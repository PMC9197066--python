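"""Shared data containers.

The framework works from three per-gene ingredients: a vector of GWAS
z-scores, a matrix of genotype correlations (LD) from the same or a
reference panel, and optional per-variant probabilities of being causal.
These dataclasses keep those ingredients aligned on a single canonical
variant order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical column order for summary-statistics tables.
SUMSTATS_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "z", "p", "maf", "n", "mac",
]


@dataclass
class GeneRegion:
    """A gene's variant membership; ``variant_ids`` order is canonical."""

    gene_id: str
    variant_ids: list[str]
    flagged_missing: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError(f"duplicate variant ids in gene {self.gene_id}")

    def __len__(self) -> int:
        return len(self.variant_ids)


@dataclass
class AnnotationProbs:
    """Per-variant probabilities of being causal, one column per channel.

    Channel index j runs 1..J; j=0 is reserved for "no annotation"
    (unit probabilities) and is not stored.
    """

    table: pd.DataFrame  # index: variant_id, columns: channel names

    def __post_init__(self) -> None:
        vals = self.table.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("annotation probabilities must lie in [0, 1]")

    @property
    def channel_names(self) -> list[str]:
        return list(self.table.columns)

    @property
    def n_channels(self) -> int:
        return self.table.shape[1]

    def channel(self, j: int, variant_ids: list[str]) -> np.ndarray | None:
        """Probabilities for channel j (1-based) aligned to variant_ids.

        j=0 returns None (no annotation). Variants absent from the table
        get probability 1.0 (uninformative).
        """
        if j == 0:
            return None
        name = self.channel_names[j - 1]
        probs = self.table[name].reindex(variant_ids).fillna(1.0)
        return probs.to_numpy(dtype=float)


@dataclass
class LDMatrix:
    """Pearson genotype-correlation matrix for one gene."""

    variant_ids: list[str]
    r: np.ndarray
    panel_n: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError("LD matrix shape does not match variant count")

    @property
    def m(self) -> int:
        return len(self.variant_ids)

    def validate(self, check_psd: bool = False) -> None:
        if not np.allclose(self.r, self.r.T, atol=0.0):
            raise ValueError("LD matrix not symmetric")
        if not np.all(np.diag(self.r) == 1.0):
            raise ValueError("LD matrix diagonal not exactly 1")
        if np.abs(self.r).max() > 1.0 + 1e-12:
            raise ValueError("LD entries outside [-1, 1]")
        if check_psd:
            if np.linalg.eigvalsh(self.r)[0] < -1e-8:
                raise ValueError("LD matrix not PSD after repair")

    def subset(self, idx: np.ndarray) -> "LDMatrix":
        ids = [self.variant_ids[k] for k in np.atleast_1d(idx)]
        return LDMatrix(ids, self.r[np.ix_(idx, idx)], self.panel_n)


@dataclass
class AlignedGene:
    """One gene with z-scores, MAFs, positions, probabilities and LD aligned.

    Every vector and the matrix are indexed identically by ``variant_ids``.
    """

    gene_id: str
    variant_ids: list[str]
    z: np.ndarray
    maf: np.ndarray
    ld: LDMatrix
    pos: np.ndarray | None = None
    probs: AnnotationProbs | None = None
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        m = len(self.variant_ids)
        if m < 1:
            raise ValueError("aligned gene must contain at least one variant")
        if self.z.shape != (m,) or self.maf.shape != (m,):
            raise ValueError("misaligned vectors in AlignedGene")
        if self.ld.m != m:
            raise ValueError("misaligned LD matrix in AlignedGene")
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=float)
            if self.pos.shape != (m,):
                raise ValueError("misaligned positions in AlignedGene")

    @property
    def m(self) -> int:
        return len(self.variant_ids)

    def subset(self, idx) -> "AlignedGene":
        idx = np.atleast_1d(np.asarray(idx, dtype=int))
        return AlignedGene(
            gene_id=self.gene_id,
            variant_ids=[self.variant_ids[k] for k in idx],
            z=self.z[idx],
            maf=self.maf[idx],
            ld=self.ld.subset(idx),
            pos=None if self.pos is None else self.pos[idx],
            probs=self.probs,
            flags=set(self.flags),
        )


@dataclass
class WeightGrid:
    """The i-axis of the omnibus grid: beta-density parameter pairs."""

    specs: list[tuple[float, float]] = field(
        default_factory=lambda: [(1.0, 25.0), (1.0, 1.0)]
    )

    def __post_init__(self) -> None:
        if len(self.specs) < 1:
            raise ValueError("weight grid must contain at least one entry")
        for a1, a2 in self.specs:
            if a1 <= 0 or a2 <= 0:
                raise ValueError("beta parameters must be strictly positive")

    @property
    def I(self) -> int:  # noqa: E743 - grid-axis name
        return len(self.specs)


@dataclass
class EffectiveWeights:
    """Weight vector for one (i, j) grid cell."""

    w: np.ndarray
    i: int = 1
    j: int = 0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not np.all(np.isfinite(self.w)) or np.any(self.w < 0):
            raise ValueError("effective weights must be finite and >= 0")


@dataclass
class TestConfig:
    """Tuning knobs shared by the region tests."""

    __test__ = False  # not a pytest class despite the name

    rho_grid: tuple[float, ...] = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)
    n_basis: int = 25
    basis_kind: str = "bspline"  # or "fourier"
    pca_var_prop: float = 0.85
    acatv_maf_weighting: bool = True
    flm_max_cond: float = 1e8

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho_grid, dtype=float)
        if rho.min() < 0 or rho.max() > 1 or 0.0 not in rho or 1.0 not in rho:
            raise ValueError("rho_grid must lie in [0,1] and contain 0 and 1")
        if self.n_basis < 4:
            raise ValueError("n_basis must be >= 4")
        if not 0 < self.pca_var_prop <= 1:
            raise ValueError("pca_var_prop must be in (0, 1]")
        if self.basis_kind not in ("bspline", "fourier"):
            raise ValueError("basis_kind must be 'bspline' or 'fourier'")


@dataclass
class ApproxConfig:
    """Large-gene approximation settings.

    Genes with more than ``trigger_m`` variants route the expensive kernel
    tests through the weighted-p split approximation at ``threshold``.
    """

    threshold: float = 0.8
    trigger_m: int = 500
    enabled_methods: tuple[str, ...] = ("SKAT", "SKATO", "PCA", "FLM")

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if self.trigger_m < 1:
            raise ValueError("trigger_m must be >= 1")

    def expected_time_reduction(self, cost_exponent: float = 3.0) -> float:
        """Expected speed-up factor for a polynomial-cost test.

        With null p-values uniform, a threshold t retains a fraction t of
        the variants, so a test whose cost grows as m^k speeds up by
        1/t^k — about 2 for the default t = 0.8 and cubic-cost kernels.
        """
        return float(self.threshold**-cost_exponent)


@dataclass
class PruneConfig:
    """Polygene-pruning settings (see :mod:`sumgene.polygene_pruning`)."""

    outside_p_threshold: float = 5e-8
    ld_r2_threshold: float = 0.5
    window_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0 < self.ld_r2_threshold <= 1:
            raise ValueError("ld_r2_threshold must be in (0, 1]")
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")


ALL_METHODS = ("BT", "SKAT", "SKATO", "ACATV", "FLM", "PCA")
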