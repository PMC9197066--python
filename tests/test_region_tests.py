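"""The six region tests and the shared quadratic-form p-value engine."""

import numpy as np
import pytest
from scipy import stats

from sumgene.containers import AlignedGene, EffectiveWeights, LDMatrix
from sumgene.containers import TestConfig as RTConfig
from sumgene.region_tests import (
    CollinearityError,
    DegenerateTestError,
    QuadForm,
    acatv_test,
    basis_matrix,
    burden_test,
    flm_test,
    p_from_z,
    pca_test,
    pval_quadform,
    skat_test,
    skato_test,
)


def make_gene(z, maf=None, r=None, pos=None):
    z = np.asarray(z, dtype=float)
    m = z.size
    ids = [f"v{k+1}" for k in range(m)]
    if r is None:
        r = np.eye(m)
    if maf is None:
        maf = np.full(m, 0.05)
    return AlignedGene("g", ids, z, np.asarray(maf, float),
                       LDMatrix(ids, np.asarray(r, float), 0), pos=pos)


def ar1(m, decay=0.3):
    idx = np.arange(m)
    return np.exp(-decay * np.abs(idx[:, None] - idx[None, :]))


class TestPvalQuadform:
    def test_single_chi_square_tail(self):
        assert pval_quadform(QuadForm([1.0], 3.841)) == pytest.approx(0.05, abs=5e-5)

    def test_two_equal_lambdas_chi2_2(self):
        assert pval_quadform(QuadForm([1.0, 1.0], 5.991)) == pytest.approx(0.05, abs=5e-5)

    def test_mixture_matches_monte_carlo(self):
        # frozen MC oracle: 1e7 draws of 2χ²+χ²+0.5χ², P(.>=7)=0.119937, 3SE=3.1e-4
        p = pval_quadform(QuadForm([2.0, 1.0, 0.5], 7.0))
        assert abs(p - 0.119937) < 3.5e-4

    def test_deep_tail_matches_exact_chi_square(self):
        # scaled-chi2 shortcut bypassed by unequal lambdas; saddlepoint regime
        p = pval_quadform(QuadForm([1.0, 1.0 + 1e-9], 60.0))
        assert p == pytest.approx(stats.chi2.sf(60.0, 2), rel=1e-3)

    def test_scaled_chi_square_family(self):
        p = pval_quadform(QuadForm([2.5, 2.5, 2.5], 2.5 * 7.815))
        assert p == pytest.approx(stats.chi2.sf(7.815, 3), rel=1e-9)

    def test_degenerate_spectrum_raises(self):
        with pytest.raises(DegenerateTestError):
            pval_quadform(QuadForm([0.0, -1e-12], 1.0))

    def test_nonpositive_statistic_gives_p_one(self):
        assert pval_quadform(QuadForm([1.0, 2.0], 0.0)) == 1.0


class TestSingleVariantReduction:
    def test_all_tests_collapse_to_two_sided_normal_p(self):
        g = make_gene([2.0], maf=[0.1])
        w = EffectiveWeights(np.array([0.37]))  # scale must not matter
        expect = stats.chi2.sf(4.0, 1)
        assert burden_test(g, w) == pytest.approx(expect, rel=1e-10)
        assert skat_test(g, w) == pytest.approx(expect, rel=1e-10)
        assert skato_test(g, w) == pytest.approx(expect, rel=1e-10)
        assert pca_test(g, w) == pytest.approx(expect, rel=1e-10)
        assert acatv_test(g, w) == pytest.approx(expect, rel=1e-8)


class TestBurden:
    def test_identity_ld_equal_z_closed_form(self):
        # statistic (Σz)²/m = 16/4 = 4
        g = make_gene([1.0, 1.0, 1.0, 1.0])
        p = burden_test(g, EffectiveWeights(np.ones(4)))
        assert p == pytest.approx(stats.chi2.sf(4.0, 1), rel=1e-12)

    def test_degenerate_weight_direction(self):
        # R with perfect anticorrelation: w'Rw = 0 for equal weights
        r = np.array([[1.0, -1.0], [-1.0, 1.0]])
        g = make_gene([1.0, -1.0], r=r)
        with pytest.raises(DegenerateTestError):
            burden_test(g, EffectiveWeights(np.ones(2)))


class TestSkat:
    def test_identity_ld_spectrum_is_squared_weights(self):
        z = np.array([1.0, -2.0, 0.5])
        w = np.array([1.0, 0.5, 2.0])
        g = make_gene(z)
        p = skat_test(g, EffectiveWeights(w))
        wn = w / w.max()
        direct = pval_quadform(QuadForm(wn**2, float(np.sum(wn**2 * z**2))))
        assert p == pytest.approx(direct, rel=1e-12)


class TestSkatO:
    def test_rho_one_reduces_to_burden(self):
        g = make_gene([1.0, 0.3, -0.5, 1.2], r=ar1(4))
        w = EffectiveWeights(np.array([1.0, 2.0, 0.5, 1.0]))
        assert skato_test(g, w, [1.0]) == pytest.approx(burden_test(g, w), rel=1e-12)

    def test_rho_zero_reduces_to_skat(self):
        g = make_gene([1.0, 0.3, -0.5, 1.2], r=ar1(4))
        w = EffectiveWeights(np.array([1.0, 2.0, 0.5, 1.0]))
        assert skato_test(g, w, [0.0]) == pytest.approx(skat_test(g, w), rel=1e-12)

    def test_matches_min_p_monte_carlo(self):
        # frozen oracle: 4000 draws of z~N(0,R), empirical P(min-rho p <= T)
        # = 0.15325, 3 binomial SE = 0.0159
        r = ar1(8)
        z = np.array([1.5, -0.5, 2.0, 0.3, 1.0, -1.2, 0.8, 2.2])
        g = make_gene(z, r=r)
        p = skato_test(g, EffectiveWeights(np.ones(8)), (0.0, 0.25, 0.5, 1.0))
        assert abs(p - 0.15325) < 0.0159

    def test_bounded_by_best_component_and_bonferroni(self):
        rho_grid = (0.0, 0.25, 1.0)
        g = make_gene([2.5, 1.8, 2.2, 0.1, -0.4], r=ar1(5))
        w = EffectiveWeights(np.ones(5))
        p = skato_test(g, w, rho_grid)
        components = [skat_test(g, w), burden_test(g, w)]
        assert min(components) <= p <= min(components) * len(rho_grid) + 1e-12


class TestAcatV:
    def test_all_half_p_values_combine_to_half(self):
        z_half = stats.norm.isf(0.25)  # two-sided p = 0.5
        g = make_gene([z_half] * 4)
        p = acatv_test(g, EffectiveWeights(np.ones(4)))
        assert p == pytest.approx(0.5, abs=1e-10)

    def test_matches_direct_formula(self, rng):
        z = rng.standard_normal(10)
        maf = rng.uniform(0.01, 0.4, 10)
        w = rng.uniform(0.5, 2.0, 10)
        g = make_gene(z, maf=maf)
        p = acatv_test(g, EffectiveWeights(w))
        omega = w**2 * maf * (1 - maf)
        omega = omega / omega.sum()
        t = float(np.sum(omega * np.tan((0.5 - p_from_z(z)) * np.pi)))
        assert p == pytest.approx(0.5 - np.arctan(t) / np.pi, rel=1e-10)

    def test_without_maf_weighting(self):
        g = make_gene([1.0, -2.0], maf=[0.01, 0.4])
        p1 = acatv_test(g, EffectiveWeights(np.ones(2)), maf_weighting=False)
        pv = p_from_z(np.array([1.0, -2.0]))
        t = float(np.mean(np.tan((0.5 - pv) * np.pi)))
        assert p1 == pytest.approx(0.5 - np.arctan(t) / np.pi, rel=1e-10)


class TestFLM:
    def test_too_few_variants_rejected(self):
        g = make_gene(np.zeros(10))
        with pytest.raises(CollinearityError):
            flm_test(g, EffectiveWeights(np.ones(10)), RTConfig(n_basis=25))

    def test_basis_matrix_shapes_and_partition_of_unity(self):
        x = np.linspace(0, 1, 57)
        b = basis_matrix(x, 25, "bspline")
        assert b.shape == (57, 25)
        assert b.sum(axis=1) == pytest.approx(np.ones(57))  # B-splines sum to 1
        f = basis_matrix(x, 7, "fourier")
        assert f.shape == (57, 7)
        assert f[:, 0] == pytest.approx(np.ones(57))

    def test_null_chi_square_calibration(self, rng):
        # with z ~ N(0, R) the FLM statistic is exactly chi-square K
        m, k = 40, 10
        r = ar1(m, 0.2)
        chol = np.linalg.cholesky(r)
        cfg = RTConfig(n_basis=k)
        pvals = []
        for _ in range(400):
            g = make_gene(chol @ rng.standard_normal(m), r=r,
                          pos=np.arange(m, dtype=float))
            pvals.append(flm_test(g, EffectiveWeights(np.ones(m)), cfg))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_fourier_alternative_runs(self):
        m = 30
        g = make_gene(np.linspace(-1, 2, m), r=ar1(m), pos=np.arange(m, dtype=float))
        p = flm_test(g, EffectiveWeights(np.ones(m)),
                     RTConfig(n_basis=9, basis_kind="fourier"))
        assert 0 < p <= 1


class TestPCA:
    def test_full_variance_identity_ld_is_chi2_m(self):
        z = np.array([1.0, -1.5, 0.7, 2.0])
        g = make_gene(z)
        p = pca_test(g, EffectiveWeights(np.ones(4)), var_prop=1.0)
        assert p == pytest.approx(stats.chi2.sf(float(z @ z), 4), rel=1e-10)

    def test_component_count_respects_variance_share(self):
        # two perfectly correlated variants: one component carries all variance
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        g = make_gene([1.0, 1.0], r=r)
        p = pca_test(g, EffectiveWeights(np.ones(2)), var_prop=0.85)
        # single component: stat = (z1+z2)²/(2·2) · 2 = chi2_1 on burden direction
        expect = stats.chi2.sf((2.0 / np.sqrt(2)) ** 2 / 2.0, 1)
        assert p == pytest.approx(expect, rel=1e-10)


class TestScaleInvariance:
    @pytest.mark.parametrize("func", [burden_test, skat_test, skato_test, pca_test])
    def test_weight_scale_does_not_change_p(self, func, rng):
        m = 12
        g = make_gene(rng.standard_normal(m), maf=rng.uniform(0.01, 0.4, m),
                      r=ar1(m))
        w = rng.uniform(0.2, 3.0, m)
        p1 = func(g, EffectiveWeights(w))
        p2 = func(g, EffectiveWeights(173.0 * w))
        assert p1 == pytest.approx(p2, abs=1e-10)
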