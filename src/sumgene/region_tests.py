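"""Gene-based region tests computed from summary statistics.

All six tests operate on the sufficient statistics (z, R, w): the vector
of per-variant GWAS z-scores, the genotype correlation (LD) matrix, and a
non-negative weight vector. Under the null hypothesis z ~ N(0, R), so
every test statistic is a quadratic form in Gaussian variables and its
p-value follows from the tail of a mixture of 1-df chi-square variables
(or a central chi-square for the fixed-df tests).

The tests:

* ``burden_test``   — (wᵀz)² / (wᵀRw), 1 df. Powerful for unidirectional
  effects.
* ``skat_test``     — Σ w_k² z_k², mixture of chi-squares with weights
  equal to the eigenvalues of W R W.
* ``skato_test``    — optimal convex combination Q_ρ = (1−ρ)Q_SKAT +
  ρQ_burden over a grid of ρ, with the one-dimensional integral giving
  the p-value of the minimum.
* ``acatv_test``    — Cauchy combination of the per-variant p-values.
* ``flm_test``      — effect sizes modelled as a smooth function of
  genomic position via a basis expansion; chi-square with K df.
* ``pca_test``      — chi-square on the leading principal components of
  the weighted LD structure.

Weights act on the standardized-genotype scale throughout, which is the
natural scale when z and R are the inputs.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import integrate, special, stats
from scipy.interpolate import BSpline

from ._acat import acat_combine
from .containers import AlignedGene, EffectiveWeights, TestConfig


class DegenerateTestError(ValueError):
    """The test statistic carries no information (e.g. zero variance)."""


class CollinearityError(ValueError):
    """FLM basis-projected covariance too ill-conditioned for a valid test."""


# ---------------------------------------------------------------------------
# p-value primitives
# ---------------------------------------------------------------------------

_LN10 = np.log(10.0)


def p_from_z(z) -> np.ndarray | float:
    """Two-sided normal p-value; erfc form stays accurate for |z| > 8."""
    return special.erfc(np.abs(z) / np.sqrt(2.0))


def neglog10_p_from_z(z) -> np.ndarray | float:
    """−log10 of the two-sided normal p, safe far beyond p = 1e-300."""
    ln_one_sided = special.log_ndtr(-np.abs(z))
    return -(ln_one_sided + np.log(2.0)) / _LN10


class QuadForm:
    """Eigenvalue spectrum and observed value of a chi-square mixture."""

    def __init__(self, lambdas, q_obs: float):
        lam = np.sort(np.asarray(lambdas, dtype=float))[::-1]
        if lam.size == 0 or not np.all(np.isfinite(lam)):
            raise ValueError("invalid eigenvalue spectrum")
        self.lambdas = lam
        self.q_obs = float(q_obs)


def _clean_lambdas(lam: np.ndarray) -> np.ndarray:
    """Drop numerically-zero eigenvalues (rank deficiency, PSD clipping)."""
    lam = np.asarray(lam, dtype=float)
    if lam.size == 0:
        return lam
    cutoff = max(lam.max(), 0.0) * 1e-10
    return lam[lam > cutoff]


def _imhof_sf(q: float, lam: np.ndarray) -> tuple[float, float]:
    """Imhof's numerical inversion of the mixture characteristic function.

    Returns (survival probability, integration error estimate).
    """

    def integrand(u):
        lu = lam * u
        theta = 0.5 * np.sum(np.arctan(lu)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p(lu * lu)))
        return np.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return 0.5 + val / np.pi, err


def _saddlepoint_sf(q: float, lam: np.ndarray) -> float:
    """Kuonen's saddlepoint (Lugannani–Rice) tail for Σ λ_k χ²_1."""
    mean = lam.sum()
    if q <= mean:  # saddlepoint at/left of the mean: not a tail problem
        return 1.0
    lmax = lam.max()
    hi = 1.0 / (2.0 * lmax)

    def kprime(t):
        return np.sum(lam / (1.0 - 2.0 * t * lam)) - q

    lo = 0.0
    # K'(t) is increasing on [0, 1/(2 λmax)); bisection is bullet-proof
    hi_eff = hi * (1.0 - 1e-12)
    for _ in range(200):
        mid = 0.5 * (lo + hi_eff)
        if kprime(mid) < 0:
            lo = mid
        else:
            hi_eff = mid
    t_hat = 0.5 * (lo + hi_eff)
    k = -0.5 * np.sum(np.log1p(-2.0 * t_hat * lam))
    k2 = 2.0 * np.sum(lam**2 / (1.0 - 2.0 * t_hat * lam) ** 2)
    w = np.sign(t_hat) * np.sqrt(max(2.0 * (t_hat * q - k), 0.0))
    v = t_hat * np.sqrt(k2)
    if w == 0.0 or v == 0.0:
        return 1.0
    zstat = w + np.log(v / w) / w
    return float(special.ndtr(-zstat))


def pval_quadform(qf: QuadForm) -> float:
    """Tail probability P(Σ λ_k χ²_{1,k} ≥ q).

    Exact numerical inversion (Imhof) with a saddlepoint fallback when the
    oscillatory integral loses accuracy (very small p, failed quadrature).
    """
    lam = _clean_lambdas(qf.lambdas)
    if lam.size == 0:
        raise DegenerateTestError("all eigenvalues are <= 0")
    q = qf.q_obs
    if q <= 0:
        return 1.0
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], df=1))
    if np.allclose(lam, lam[0], rtol=1e-12):
        return float(stats.chi2.sf(q / lam[0], df=lam.size))
    p, err = _imhof_sf(q, lam)
    bad = (not np.isfinite(p)) or p <= 1e-9 or p > 1.0 or err > max(1e-9, 0.01 * abs(p))
    if bad:
        p = _saddlepoint_sf(q, lam)
    return float(min(max(p, 5e-324), 1.0))


# ---------------------------------------------------------------------------
# the six tests
# ---------------------------------------------------------------------------


def _normalized_w(w: np.ndarray) -> np.ndarray:
    wmax = w.max()
    if wmax <= 0:
        raise DegenerateTestError("all weights are zero")
    return w / wmax


def burden_test(g: AlignedGene, w: EffectiveWeights) -> float:
    """Weighted burden score test, 1 df chi-square."""
    wn = _normalized_w(w.w)
    denom = float(wn @ g.ld.r @ wn)
    if denom <= 1e-12:
        raise DegenerateTestError("burden variance wᵀRw is numerically zero")
    q = float(wn @ g.z) ** 2 / denom
    return float(stats.chi2.sf(q, df=1))


def skat_test(g: AlignedGene, w: EffectiveWeights) -> float:
    """Variance-component (kernel) test with mixture-of-chi-square null."""
    wn = _normalized_w(w.w)
    if g.m == 1:
        return burden_test(g, w)
    q = float(np.sum(wn**2 * g.z**2))
    phi = (wn[:, None] * g.ld.r) * wn[None, :]
    lam = np.linalg.eigvalsh(phi)
    return pval_quadform(QuadForm(lam, q))


def _liu_qmin(lam: np.ndarray, tail_prob: float) -> float:
    """Quantile of a chi-square mixture by modified moment matching."""
    c1 = lam.sum()
    c2 = np.sum(lam**2)
    c3 = np.sum(lam**3)
    c4 = np.sum(lam**4)
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_x = df + delta
    sigma_x = np.sqrt(2.0 * (df + 2.0 * delta))
    mu_q = c1
    sigma_q = np.sqrt(2.0 * c2)
    q_tail = stats.ncx2.isf(tail_prob, df, delta) if delta > 0 else stats.chi2.isf(tail_prob, df)
    return float((q_tail - mu_x) / sigma_x * sigma_q + mu_q)


def _rho_lambdas(phi: np.ndarray, rho: float) -> np.ndarray:
    """Eigenvalues of M_ρ^{1/2} Φ M_ρ^{1/2} with M_ρ = (1−ρ)I + ρ11ᵀ."""
    m = phi.shape[0]
    ones = np.ones(m)
    a = np.sqrt(1.0 - rho)
    b = (np.sqrt(1.0 - rho + m * rho) - a) / m
    # M^{1/2} = aI + b 11ᵀ
    sqrt_m = a * np.eye(m) + b * np.outer(ones, ones)
    return np.linalg.eigvalsh(sqrt_m @ phi @ sqrt_m)


def skato_test(
    g: AlignedGene, w: EffectiveWeights, rho_grid=None
) -> float:
    """Optimal combination of burden and SKAT over a grid of mixing ρ."""
    if rho_grid is None:
        rho_grid = TestConfig().rho_grid
    rho_grid = np.asarray(rho_grid, dtype=float)
    if rho_grid.min() < 0 or rho_grid.max() > 1:
        raise ValueError("rho grid must lie in [0, 1]")
    wn = _normalized_w(w.w)
    if g.m == 1:
        return burden_test(g, w)
    if rho_grid.size == 1:
        rho = rho_grid[0]
        if rho == 1.0:
            return burden_test(g, w)
        if rho == 0.0:
            return skat_test(g, w)

    s = wn * g.z  # score vector, Cov = Φ under the null
    phi = (wn[:, None] * g.ld.r) * wn[None, :]
    q_skat = float(s @ s)
    q_burden = float(s.sum()) ** 2
    return skato_from_parts(q_skat, q_burden, phi, rho_grid)


def skato_from_parts(
    q_skat: float, q_burden: float, phi: np.ndarray, rho_grid
) -> float:
    """SKAT-O p-value from the two component statistics and score covariance.

    ``phi`` is the null covariance of the (weighted) score vector; for
    summary statistics this is W R W, for individual-level data
    W GᵀG W / σ̂² with centered standardized genotypes G.
    """
    rho_grid = np.asarray(rho_grid, dtype=float)
    m = phi.shape[0]
    # per-rho p-values
    p_each = np.empty(rho_grid.size)
    for idx, rho in enumerate(rho_grid):
        q_rho = (1.0 - rho) * q_skat + rho * q_burden
        if rho == 1.0:
            denom = float(phi.sum())
            if denom <= 0:
                raise DegenerateTestError("burden variance is zero")
            p_each[idx] = stats.chi2.sf(q_rho / denom, df=1)
        else:
            lam = _rho_lambdas(phi, rho)
            p_each[idx] = pval_quadform(QuadForm(lam, q_rho))
    t_min = float(p_each.min())
    if t_min >= 1.0:
        return 1.0

    # null decomposition Q_ρ ≈ (1−ρ)κ + τ(ρ)η, η ~ χ²₁
    phi1 = phi @ np.ones(m)
    ssum = float(phi1.sum())
    if ssum <= 0:
        raise DegenerateTestError("degenerate weighted LD structure")
    kernel = phi - np.outer(phi1, phi1) / ssum
    lam_k = _clean_lambdas(np.linalg.eigvalsh(kernel))
    if lam_k.size == 0:
        # burden direction exhausts the kernel (e.g. perfect LD)
        return float(min(t_min * rho_grid.size, 1.0))
    var_remain = 4.0 * float(phi1 @ kernel @ phi1) / ssum
    mu_q = lam_k.sum()
    var_q = 2.0 * np.sum(lam_k**2) + var_remain
    sd_ratio = np.sqrt(2.0 * np.sum(lam_k**2)) / np.sqrt(var_q)
    tau = rho_grid * ssum + (1.0 - rho_grid) * float(phi1 @ phi1) / ssum

    q_min = np.empty(rho_grid.size)
    for idx, rho in enumerate(rho_grid):
        lam = _rho_lambdas(phi, min(rho, 0.999))
        q_min[idx] = _liu_qmin(_clean_lambdas(lam), t_min)

    rho_cap = np.minimum(rho_grid, 0.999)

    def kappa_sf(u: float) -> float:
        u_adj = (u - mu_q) * sd_ratio + mu_q
        if u_adj <= 0:
            return 1.0
        return pval_quadform(QuadForm(lam_k, u_adj))

    # P(min_ρ p_ρ ≤ T) = E_{x~χ²₁}[ S_κ(g(x)) ] with the piecewise-linear
    # decreasing bound g(x) = min_ρ (q_min(ρ) − τ(ρ)x)/(1−ρ). S_κ is
    # evaluated at a modest number of nodes and interpolated on the log
    # scale; the expectation is then a dense vectorized quadrature.
    try:
        x_hi = 40.0
        x_grid = np.linspace(0.0, x_hi, 2001)
        g_vals = np.min(
            (q_min[:, None] - np.outer(tau, x_grid)) / (1.0 - rho_cap)[:, None],
            axis=0,
        )
        g_pos = np.clip(g_vals, 0.0, None)
        u_max = g_pos.max()
        if u_max <= 0:
            raise FloatingPointError("degenerate integration bound")
        nodes = np.linspace(0.0, u_max, 30)
        log_sf = np.array(
            [0.0 if u <= 0 else np.log(max(kappa_sf(float(u)), 5e-324))
             for u in nodes]
        )
        sf_interp = np.exp(np.interp(g_pos, nodes, log_sf))
        sf_interp[g_vals <= 0] = 1.0
        integrand = sf_interp * stats.chi2.pdf(x_grid, df=1)
        # χ²₁ density has an integrable x^{-1/2} singularity at 0: handle
        # the first cell analytically (S_κ is effectively constant there)
        dx = x_grid[1]
        head = sf_interp[0] * float(stats.chi2.cdf(dx, df=1))
        val = head + np.trapezoid(integrand[1:], x_grid[1:])
        p = float(val + stats.chi2.sf(x_hi, df=1))
        if not np.isfinite(p) or p <= 0:
            raise FloatingPointError("non-finite SKAT-O integral")
    except FloatingPointError:
        warnings.warn("SKAT-O integral failed; Bonferroni fallback over rho grid")
        p = t_min * rho_grid.size
    # the omnibus p can never beat the best single rho by more than the grid
    p = max(p, t_min)
    p = min(p, t_min * rho_grid.size, 1.0)
    return float(max(p, 5e-324))


def acatv_test(
    g: AlignedGene, w: EffectiveWeights, maf_weighting: bool = True
) -> float:
    """Cauchy combination of per-variant p-values (set-based ACAT).

    The Cauchy weights are w_k² · maf_k(1−maf_k) (the set-test convention,
    mirroring the variance of a standardized score) unless
    ``maf_weighting`` is disabled, in which case plain w_k² is used.
    """
    pvals = np.atleast_1d(p_from_z(g.z))
    if np.any(pvals <= 0):
        warnings.warn("per-variant p underflowed; clamped to minimum representable")
        pvals = np.maximum(pvals, 5e-324)
    if maf_weighting:
        omega = w.w**2 * g.maf * (1.0 - g.maf)
    else:
        omega = w.w**2
    if not np.any(omega > 0):
        raise DegenerateTestError("all ACAT-V weights are zero")
    return acat_combine(np.minimum(pvals, 1.0), omega)


def basis_matrix(x: np.ndarray, n_basis: int, kind: str = "bspline") -> np.ndarray:
    """Evaluate K basis functions at normalized positions x ∈ [0, 1]."""
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0 - 1e-12)
    if kind == "bspline":
        degree = 3
        n_interior = n_basis - degree - 1
        if n_interior < 0:
            raise ValueError("n_basis too small for cubic B-splines")
        knots = np.concatenate(
            [np.zeros(degree + 1), np.linspace(0, 1, n_interior + 2)[1:-1],
             np.ones(degree + 1)]
        )
        return BSpline.design_matrix(x, knots, degree).toarray()
    if kind == "fourier":
        cols = [np.ones_like(x)]
        harmonic = 1
        while len(cols) < n_basis:
            cols.append(np.sin(2.0 * np.pi * harmonic * x))
            if len(cols) < n_basis:
                cols.append(np.cos(2.0 * np.pi * harmonic * x))
            harmonic += 1
        return np.column_stack(cols)
    raise ValueError(f"unknown basis kind {kind!r}")


def flm_test(
    g: AlignedGene, w: EffectiveWeights, cfg: TestConfig | None = None
) -> float:
    """Functional linear model region test.

    The genetic-effect function is expanded over K basis functions placed
    on variant positions rescaled to [0,1]; the basis-projected score
    vector u = BᵀWz has null covariance Σ = BᵀWRWB, giving the K-df
    chi-square statistic uᵀΣ⁻¹u.
    """
    cfg = cfg or TestConfig()
    k = cfg.n_basis
    if g.m <= k:
        raise CollinearityError(f"m={g.m} <= K={k} basis functions")
    if g.pos is not None:
        pos = np.asarray(g.pos, dtype=float)
    else:
        pos = np.arange(g.m, dtype=float)
    span = pos.max() - pos.min()
    if span <= 0:
        raise CollinearityError("all variants share one position")
    x = (pos - pos.min()) / span
    b = basis_matrix(x, k, cfg.basis_kind)
    wn = _normalized_w(w.w)
    u = b.T @ (wn * g.z)
    phi = (wn[:, None] * g.ld.r) * wn[None, :]
    sigma = b.T @ phi @ b
    sigma = 0.5 * (sigma + sigma.T)
    eigs = np.linalg.eigvalsh(sigma)
    if eigs[0] <= 0 or eigs[-1] / eigs[0] > cfg.flm_max_cond:
        raise CollinearityError("basis-projected covariance is ill-conditioned")
    stat = float(u @ np.linalg.solve(sigma, u))
    return float(stats.chi2.sf(stat, df=k))


def pca_test(
    g: AlignedGene, w: EffectiveWeights, var_prop: float = 0.85
) -> float:
    """Chi-square test on leading principal components of W R W."""
    if not 0 < var_prop <= 1:
        raise ValueError("var_prop must be in (0, 1]")
    wn = _normalized_w(w.w)
    if g.m == 1:
        return burden_test(g, w)
    phi = (wn[:, None] * g.ld.r) * wn[None, :]
    evals, evecs = np.linalg.eigh(phi)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    if evals[0] <= 0:
        raise DegenerateTestError("zero leading eigenvalue in PCA test")
    pos = np.clip(evals, 0.0, None)
    share = np.cumsum(pos) / pos.sum()
    k = int(np.searchsorted(share, var_prop - 1e-12) + 1)
    k = min(k, int(np.sum(evals > evals[0] * 1e-10)))
    scores = evecs.T @ (wn * g.z)
    stat = float(np.sum(scores[:k] ** 2 / evals[:k]))
    return float(stats.chi2.sf(stat, df=k))


_METHOD_FUNCS = {
    "BT": lambda g, w, cfg: burden_test(g, w),
    "SKAT": lambda g, w, cfg: skat_test(g, w),
    "SKATO": lambda g, w, cfg: skato_test(g, w, cfg.rho_grid),
    "ACATV": lambda g, w, cfg: acatv_test(g, w, cfg.acatv_maf_weighting),
    "FLM": lambda g, w, cfg: flm_test(g, w, cfg),
    "PCA": lambda g, w, cfg: pca_test(g, w, cfg.pca_var_prop),
}


def run_test(method: str, g: AlignedGene, w: EffectiveWeights,
             cfg: TestConfig | None = None) -> float:
    """Dispatch a single region test by method name."""
    cfg = cfg or TestConfig()
    try:
        func = _METHOD_FUNCS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}") from None
    return func(g, w, cfg)
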