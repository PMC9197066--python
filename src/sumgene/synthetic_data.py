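"""Synthetic genotype, phenotype and summary-statistic generator.

Everything the framework consumes — summary statistics, per-gene LD
matrices, gene definitions, causal-probability annotations — can be
generated here with known ground truth, so no external download is ever
needed. Genotypes follow a latent-Gaussian threshold model: two haplotype
layers of an AR(1) latent field with correlation exp(−ld_decay·|a−b|)
between adjacent variant indices, thresholded at the normal quantile of
each variant's target MAF and summed to 0/1/2 dosages. This gives
Hardy–Weinberg genotypes with tunable LD and exact target frequencies in
expectation.

The module also hosts the individual-level oracle tests: each region
test recomputed from raw genotypes and phenotype by direct dense linear
algebra. On data where the LD panel *is* the analysis sample these must
agree with the summary-level tests — the analytical equivalence the
framework rests on, exercised numerically in the test suite.

GWAS z-scores are score-test z (null residual variance shared across
variants), the convention under which the equivalence is exact rather
than asymptotic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._acat import acat_combine
from .containers import AnnotationProbs, GeneRegion, LDMatrix
from .region_tests import (
    CollinearityError,
    DegenerateTestError,
    QuadForm,
    TestConfig,
    basis_matrix,
    p_from_z,
    pval_quadform,
    skato_from_parts,
)


@dataclass
class SimConfig:
    """Study conditions for one simulated gene."""

    n: int = 5000
    m: int = 50
    maf_range: tuple[float, float] = (0.005, 0.5)  # log-uniform MAF law
    ld_decay: float = 0.1
    causal_frac: float = 0.1
    effect_sd: float = 0.15
    trait: str = "quantitative"
    prevalence: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.m < 1:
            raise ValueError("need n >= 2 and m >= 1")
        if not 0 <= self.causal_frac <= 1:
            raise ValueError("causal_frac must be in [0, 1]")
        if self.effect_sd < 0 or self.ld_decay < 0:
            raise ValueError("rates must be non-negative")
        if self.trait not in ("quantitative", "binary"):
            raise ValueError("trait must be quantitative or binary")


def _sample_maf(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.maf_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.m))


def _ar1_normal(n: int, m: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """n×m standard-normal field with corr(col a, col b) = rho^|a−b|."""
    x = rng.standard_normal((n, m))
    if rho > 0 and m > 1:
        scale = np.sqrt(1.0 - rho**2)
        for k in range(1, m):
            x[:, k] = rho * x[:, k - 1] + scale * x[:, k]
    return x


def simulate_genotypes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, dict]:
    """Draw an n×m dosage matrix with AR(1)-decaying LD; returns truth."""
    rng = rng or np.random.default_rng(cfg.seed)
    maf = _sample_maf(cfg, rng)
    rho = np.exp(-cfg.ld_decay)
    thresh = stats.norm.ppf(maf)
    hap1 = _ar1_normal(cfg.n, cfg.m, rho, rng) < thresh
    hap2 = _ar1_normal(cfg.n, cfg.m, rho, rng) < thresh
    geno = (hap1.astype(np.int8) + hap2.astype(np.int8)).astype(float)
    truth = {"maf": maf, "latent_rho": rho}
    return geno, truth


def simulate_phenotype(
    genotypes: np.ndarray, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, dict]:
    """Additive phenotype on standardized genotypes plus unit-variance noise.

    A ``causal_frac`` share of variants receives effects β ~ N(0,
    effect_sd²) on the standardized-dosage scale. Binary traits are
    produced by thresholding the latent value at the target prevalence.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n, m = genotypes.shape
    n_causal = int(round(cfg.causal_frac * m))
    causal = rng.choice(m, size=n_causal, replace=False) if n_causal else np.array([], dtype=int)
    beta = rng.normal(0.0, cfg.effect_sd, size=n_causal)
    sd = genotypes.std(axis=0)
    sd[sd == 0] = 1.0
    g_std = (genotypes - genotypes.mean(axis=0)) / sd
    latent = g_std[:, causal] @ beta + rng.standard_normal(n)
    if cfg.trait == "binary":
        cut = np.quantile(latent, 1.0 - cfg.prevalence)
        y = (latent > cut).astype(float)
    else:
        y = latent
    return y, {"causal_idx": causal, "beta": beta}


def gwas(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    variant_ids: list[str] | None = None,
    chrom: str = "1",
    pos: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant association scan producing a summary-statistics table.

    Quantitative traits use the linear score test with the null residual
    variance; binary traits the intercept-only logistic score test.
    Monomorphic variants are dropped.
    """
    geno = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n, m = geno.shape
    if n <= 2:
        raise ValueError("need n > 2")
    if variant_ids is None:
        variant_ids = [f"v{k+1}" for k in range(m)]
    if pos is None:
        pos = 1 + np.arange(m, dtype=np.int64) * 100

    sd = geno.std(axis=0)
    poly = sd > 0
    yc = y - y.mean()
    gc = geno - geno.mean(axis=0)
    norms = np.sqrt(np.sum(gc**2, axis=0))
    norms[~poly] = 1.0
    u = gc.T @ yc
    binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary:
        ybar = y.mean()
        var_u = ybar * (1.0 - ybar) * norms**2
        z = u / np.sqrt(np.where(var_u > 0, var_u, 1.0))
    else:
        sigma0 = np.sqrt(yc @ yc / (n - 1))
        z = u / (sigma0 * norms)
    beta = u / norms**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(z != 0, np.abs(beta / z), np.nan)
    freq = geno.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    mac = np.minimum(geno.sum(axis=0), 2 * n - geno.sum(axis=0))

    df = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": chrom,
            "pos": np.asarray(pos, dtype=np.int64),
            "effect_allele": "A",
            "other_allele": "G",
            "beta": beta,
            "se": se,
            "z": z,
            "p": p_from_z(z),
            "maf": maf,
            "n": n,
            "mac": mac,
        }
    )
    return df[poly].reset_index(drop=True)


def simulate_probs(
    variant_ids: list[str],
    n_channels: int = 1,
    rng: np.random.Generator | None = None,
    causal_idx: np.ndarray | None = None,
    boost: float = 0.4,
) -> AnnotationProbs:
    """Causal-probability channels; causal variants optionally up-weighted."""
    rng = rng or np.random.default_rng(0)
    m = len(variant_ids)
    table = {}
    for c in range(n_channels):
        p = rng.uniform(0.05, 0.6, size=m)
        if causal_idx is not None and causal_idx.size:
            p[causal_idx] = np.clip(p[causal_idx] + boost, 0.0, 1.0)
        table[f"aPC{c+1}"] = p
    return AnnotationProbs(pd.DataFrame(table, index=variant_ids))


def ar1_ld_matrix(variant_ids: list[str], ld_decay: float, panel_n: int = 0) -> LDMatrix:
    """Analytic AR(1) correlation matrix exp(−ld_decay·|a−b|)."""
    from scipy.linalg import toeplitz

    m = len(variant_ids)
    first_row = np.exp(-ld_decay * np.arange(m, dtype=float))
    return LDMatrix(variant_ids, toeplitz(first_row), panel_n)


def simulate_gene_summary(
    m: int,
    rng: np.random.Generator,
    ld_decay: float = 0.1,
    causal_frac: float = 0.005,
    delta_sd: float = 3.5,
    null_prob: float = 0.5,
    maf_range: tuple[float, float] = (0.005, 0.5),
    gene_id: str = "gene",
):
    """Summary-level gene draw: z ~ N(Rδ, R) with analytic AR(1) LD.

    This skips individual-level data entirely — appropriate when the
    quantity under study (e.g. the large-gene approximation) is a
    deterministic function of (z, R, w). It emulates the gene-level
    landscape of a polygenic trait: a ``null_prob`` share of genes carry
    no causal variants, the rest get a mean shift Rδ at
    ``causal_frac``·m causal variants with per-variant non-centrality
    δ ~ N(0, delta_sd²), spreading genes from null to strong signal.
    """
    from .containers import AlignedGene

    rho = np.exp(-ld_decay)
    e = rng.standard_normal(m)
    z = np.empty(m)
    z[0] = e[0]
    scale = np.sqrt(1.0 - rho**2)
    for k in range(1, m):
        z[k] = rho * z[k - 1] + scale * e[k]
    ids = [f"{gene_id}_v{k+1}" for k in range(m)]
    ld = ar1_ld_matrix(ids, ld_decay)
    is_null = rng.uniform() < null_prob
    n_causal = 0 if is_null else max(1, int(round(causal_frac * m)))
    if n_causal:
        causal = rng.choice(m, size=n_causal, replace=False)
        delta = rng.normal(0.0, delta_sd, size=n_causal)
        z = z + ld.r[:, causal] @ delta
    maf = np.exp(rng.uniform(np.log(maf_range[0]), np.log(maf_range[1]), size=m))
    return AlignedGene(
        gene_id=gene_id, variant_ids=ids, z=z, maf=maf, ld=ld,
        pos=1.0 + 100.0 * np.arange(m),
    )


# ---------------------------------------------------------------------------
# individual-level oracle
# ---------------------------------------------------------------------------


def oracle_region_tests(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    w: np.ndarray,
    method: str,
    maf: np.ndarray | None = None,
    pos: np.ndarray | None = None,
    cfg: TestConfig | None = None,
) -> float:
    """Classical raw-genotype score test for one region method.

    Computed by direct dense linear algebra on the centered, standardized
    dosage matrix — no summary-level shortcut. Weights apply on the
    standardized-genotype scale (matching the summary-level convention).
    """
    cfg = cfg or TestConfig()
    geno = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n, m = geno.shape
    w = np.asarray(w, dtype=float)
    if w.shape != (m,):
        raise ValueError("weight length mismatch")
    wmax = w.max()
    if wmax <= 0:
        raise DegenerateTestError("all-zero weights")
    w = w / wmax

    yc = y - y.mean()
    gc = geno - geno.mean(axis=0)
    norms = np.sqrt(np.sum(gc**2, axis=0))
    if np.any(norms == 0):
        raise DegenerateTestError("monomorphic variant in oracle")
    g_std = gc / norms
    binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary:
        ybar = y.mean()
        sigma0 = np.sqrt(ybar * (1.0 - ybar))
    else:
        sigma0 = np.sqrt(yc @ yc / (n - 1))
    score = g_std.T @ yc / sigma0  # N(0, GᵀG) under the null

    if method == "BT":
        b = g_std @ w
        stat = float(b @ yc) ** 2 / (sigma0**2 * float(b @ b))
        return float(stats.chi2.sf(stat, df=1))
    if method == "SKAT":
        if m == 1:
            return oracle_region_tests(geno, y, w, "BT")
        q = float(np.sum((w * score) ** 2))
        x = g_std * w  # n×m; Φ = XᵀX
        lam = np.linalg.eigvalsh(x.T @ x)
        return pval_quadform(QuadForm(lam, q))
    if method == "SKATO":
        if m == 1:
            return oracle_region_tests(geno, y, w, "BT")
        s = w * score
        x = g_std * w
        return skato_from_parts(float(s @ s), float(s.sum()) ** 2, x.T @ x,
                                cfg.rho_grid)
    if method == "ACATV":
        pvals = np.maximum(np.atleast_1d(p_from_z(score)), 5e-324)
        if maf is None:
            freq = geno.mean(axis=0) / 2.0
            maf = np.minimum(freq, 1.0 - freq)
        omega = w**2 * maf * (1.0 - maf) if cfg.acatv_maf_weighting else w**2
        return acat_combine(pvals, omega)
    if method == "FLM":
        if m <= cfg.n_basis:
            raise CollinearityError("m <= K in oracle FLM")
        if pos is None:
            pos = np.arange(m, dtype=float)
        span = pos.max() - pos.min()
        x01 = (pos - pos.min()) / span if span > 0 else np.full(m, 0.5)
        b = basis_matrix(x01, cfg.n_basis, cfg.basis_kind)
        design = (g_std * w) @ b  # n×K
        u = design.T @ yc / sigma0
        sigma = design.T @ design
        eigs = np.linalg.eigvalsh(sigma)
        if eigs[0] <= 0 or eigs[-1] / eigs[0] > cfg.flm_max_cond:
            raise CollinearityError("ill-conditioned oracle FLM covariance")
        stat = float(u @ np.linalg.solve(sigma, u))
        return float(stats.chi2.sf(stat, df=cfg.n_basis))
    if method == "PCA":
        if m == 1:
            return oracle_region_tests(geno, y, w, "BT")
        x = g_std * w
        evals, evecs = np.linalg.eigh(x.T @ x)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        if evals[0] <= 0:
            raise DegenerateTestError("zero leading eigenvalue in oracle PCA")
        posv = np.clip(evals, 0.0, None)
        share = np.cumsum(posv) / posv.sum()
        k = int(np.searchsorted(share, cfg.pca_var_prop - 1e-12) + 1)
        k = min(k, int(np.sum(evals > evals[0] * 1e-10)))
        proj = evecs.T @ (w * score)
        stat = float(np.sum(proj[:k] ** 2 / evals[:k]))
        return float(stats.chi2.sf(stat, df=k))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# fixture-set assembly
# ---------------------------------------------------------------------------


@dataclass
class StudyFixture:
    """A complete simulated study: stats, regions, LD, probs, truth."""

    stats: pd.DataFrame
    regions: list[GeneRegion]
    ld: dict[str, LDMatrix]
    probs: AnnotationProbs | None
    truth: dict = field(default_factory=dict)

    def ld_getter(self):
        store = self.ld

        class _Getter:
            def get(self, gid):
                return store[gid]

        return _Getter()


def simulate_study(
    n_genes: int = 3,
    cfg: SimConfig | None = None,
    n_channels: int = 1,
    seed: int = 0,
) -> StudyFixture:
    """Simulate a multi-gene study with per-gene independent genotypes."""
    from .ld_reference import build_ld

    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    frames, regions, ld, truth = [], [], {}, {}
    prob_frames = []
    offset = 0
    for gidx in range(n_genes):
        geno, gt = simulate_genotypes(cfg, rng)
        y, pt = simulate_phenotype(geno, cfg, rng)
        vids = [f"g{gidx+1}_v{k+1}" for k in range(cfg.m)]
        pos = 1 + offset + np.arange(cfg.m, dtype=np.int64) * 100
        st = gwas(geno, y, variant_ids=vids, pos=pos)
        frames.append(st)
        used = st["variant_id"].tolist()
        regions.append(GeneRegion(f"gene{gidx+1}", used))
        keep = [k for k, v in enumerate(vids) if v in set(used)]
        ld[f"gene{gidx+1}"] = build_ld(geno[:, keep], used, min_maf=0.0)
        if n_channels:
            pr = simulate_probs(vids, n_channels, rng, pt["causal_idx"])
            prob_frames.append(pr.table)
        truth[f"gene{gidx+1}"] = {**gt, **pt}
        offset += cfg.m * 100 + 10_000
    probs = AnnotationProbs(pd.concat(prob_frames)) if prob_frames else None
    return StudyFixture(
        stats=pd.concat(frames, ignore_index=True),
        regions=regions, ld=ld, probs=probs, truth=truth,
    )
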