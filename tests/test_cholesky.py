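"""Multivariate Cholesky ACE decomposition: recovery, invariances, derived stats."""

import numpy as np
import pytest

from twinace import (
    CholeskyParams,
    SimConfig,
    expected_covariances,
    fit_ace,
    fit_cholesky,
    genetic_correlation,
    moment_matched_cohort,
    restandardize,
    simulate_cohort,
)
from twinace.cholesky import independent_ci
from twinace.errors import ConfigError, DegenerateScaleError, UndefinedCorrelationError
from twinace.pipeline import fixture_components


def _block_free_params():
    """Two traits with no cross paths: joint fit must match marginal fits."""
    return CholeskyParams(
        lambda_a=np.diag([np.sqrt(0.5), np.sqrt(0.3)]),
        lambda_c=np.diag([np.sqrt(0.2), np.sqrt(0.3)]),
        lambda_e=np.diag([np.sqrt(0.3), np.sqrt(0.4)]),
        trait_names=("x", "y"),
    )


def _gfree_achievement_params():
    """Bivariate g -> achievement model whose independent components are
    exactly (.32, .21, .17): g components (.44, .23, .33), common contributions
    (.18, .09, .03)."""
    g = (0.44, 0.23, 0.33)
    common = (0.18, 0.09, 0.03)
    independent = (0.32, 0.21, 0.17)
    mats = []
    for gi, co, ind in zip(g, common, independent):
        mats.append(np.array([[np.sqrt(gi), 0.0], [np.sqrt(co), np.sqrt(ind)]]))
    return CholeskyParams(*mats, trait_names=("g", "ach"))


class TestFitCholesky:
    def test_moment_matched_path_recovery(self, bivariate_params):
        d = moment_matched_cohort(bivariate_params, 500, 700, seed=9)
        fit = fit_cholesky(d, ("g", "ach"))
        np.testing.assert_allclose(
            fit.params.lambda_a, bivariate_params.lambda_a, atol=1e-4
        )
        np.testing.assert_allclose(
            fit.params.lambda_c, bivariate_params.lambda_c, atol=1e-4
        )
        np.testing.assert_allclose(
            fit.params.lambda_e, bivariate_params.lambda_e, atol=1e-4
        )

    def test_zero_cross_paths_match_univariate_fit(self):
        p = _block_free_params()
        d = moment_matched_cohort(p, 600, 600, seed=10)
        fit = fit_cholesky(d, ("x", "y"))
        # off-diagonal standardized paths ~ 0
        for comp in ("A", "C", "E"):
            assert fit.standardized.loc["y", (comp, f"{comp}1")] == pytest.approx(0.0, abs=1e-5)
        uni = fit_ace(d, "y", ci=False)
        ind = fit.independent
        assert ind[0] == pytest.approx(uni.A, abs=1e-4)
        assert ind[1] == pytest.approx(uni.C, abs=1e-4)
        assert ind[2] == pytest.approx(uni.E, abs=1e-4)

    def test_recovers_printed_independent_components_at_large_n(self):
        p = _gfree_achievement_params()
        d = simulate_cohort(
            SimConfig(n_mz_pairs=30_000, n_dz_pairs=30_000, cholesky=p, seed=12)
        )
        fit = fit_cholesky(d, ("g", "ach"))
        ind = fit.independent
        assert ind[0] == pytest.approx(0.32, abs=0.03)
        assert ind[1] == pytest.approx(0.21, abs=0.03)
        assert ind[2] == pytest.approx(0.17, abs=0.03)

    def test_standardized_contributions_sum_to_one(self, bivariate_params):
        d = simulate_cohort(
            SimConfig(n_mz_pairs=2000, n_dz_pairs=3000, cholesky=bivariate_params,
                      missing_rate=0.15, seed=13)
        )
        fit = fit_cholesky(d, ("g", "ach"))
        np.testing.assert_allclose(fit.standardized.sum(axis=1), 1.0, atol=1e-6)

    def test_implied_covariance_psd_and_order_invariant(self, bivariate_params):
        d = simulate_cohort(
            SimConfig(n_mz_pairs=3000, n_dz_pairs=3000, cholesky=bivariate_params, seed=14)
        )
        fit_fwd = fit_cholesky(d, ("g", "ach"))
        fit_rev = fit_cholesky(d, ("ach", "g"))
        for fit in (fit_fwd, fit_rev):
            mz, dz = expected_covariances(fit.params)
            assert np.linalg.eigvalsh(mz).min() > -1e-10
            assert np.linalg.eigvalsh(dz).min() > -1e-10
        # permuting trait order permutes but does not change the implied covariance
        perm_total = fit_rev.params.total_covariance[np.ix_([1, 0], [1, 0])]
        np.testing.assert_allclose(fit_fwd.params.total_covariance, perm_total, atol=5e-4)

    def test_trivariate_marginalization(self):
        sa, sc, se, names = fixture_components()
        idx = [0, 2, 3]  # ach10_teacher, g, ach12_teacher
        sub = np.ix_(idx, idx)
        p3 = CholeskyParams.from_components(sa[sub], sc[sub], se[sub],
                                            ("ach10", "g", "ach12"))
        d = moment_matched_cohort(p3, 800, 800, seed=15)
        fit3 = fit_cholesky(d, ("ach10", "g", "ach12"))
        fit2 = fit_cholesky(d, ("ach10", "g"))
        np.testing.assert_allclose(
            fit3.params.total_covariance[:2, :2],
            fit2.params.total_covariance,
            atol=1e-3,
        )

    def test_usage_errors(self, small_cohort):
        with pytest.raises(ConfigError):
            fit_cholesky(small_cohort, ("ach",))
        with pytest.raises(ConfigError):
            fit_cholesky(small_cohort, ("ach", "nope"))


class TestRestandardize:
    @pytest.mark.parametrize(
        "independent, expected",
        [
            ((0.32, 0.21, 0.17), (0.46, 0.30, 0.24)),
            ((0.19, 0.03, 0.23), (0.42, 0.07, 0.51)),
            ((0.29, 0.12, 0.17), (0.50, 0.21, 0.29)),
            ((0.25, 0.11, 0.16), (0.48, 0.21, 0.31)),
            ((0.15, 0.04, 0.22), (0.37, 0.10, 0.54)),
        ],
    )
    def test_published_added_value_arithmetic(self, independent, expected):
        restd = restandardize(independent)
        assert sum(restd) == pytest.approx(1.0, abs=1e-12)
        for got, want in zip(restd, expected):
            assert round(got, 2) == pytest.approx(want, abs=0.005)

    def test_single_nonzero_component(self):
        assert restandardize((0.4, 0.0, 0.0)) == pytest.approx((1.0, 0.0, 0.0))

    def test_degenerate_zero_sum(self):
        with pytest.raises(DegenerateScaleError):
            restandardize((0.0, 0.0, 0.0))


class TestGeneticCorrelation:
    def test_identical_genetic_paths_give_unit_correlation(self):
        lam = np.array([[0.7, 0.0], [0.7, 0.0]])
        p = CholeskyParams(lam, np.zeros((2, 2)), np.diag([0.5, 0.5]), ("x", "y"))
        assert genetic_correlation(p, "x", "y") == pytest.approx(1.0)

    def test_zero_cross_path_gives_zero_correlation(self):
        p = _block_free_params()
        assert genetic_correlation(p, "x", "y") == 0.0

    def test_zero_genetic_variance_is_undefined(self):
        p = CholeskyParams(
            np.diag([0.7, 0.0]), np.zeros((2, 2)), np.diag([0.7, 1.0]), ("x", "y")
        )
        with pytest.raises(UndefinedCorrelationError):
            genetic_correlation(p, "x", "y")

    def test_matches_brute_force_latent_simulation(self, bivariate_params):
        rg = genetic_correlation(bivariate_params, "g", "ach")
        rng = np.random.default_rng(20)
        z = rng.standard_normal((100_000, 2))
        a = z @ bivariate_params.lambda_a.T  # latent additive genetic values
        emp = np.corrcoef(a[:, 0], a[:, 1])[0, 1]
        assert rg == pytest.approx(emp, abs=0.02)


class TestIndependentCI:
    def test_boundary_component_flagged_ns(self):
        # C entirely absent from the outcome-specific factor
        g = (0.44, 0.23, 0.33)
        common = (0.18, 0.09, 0.03)
        independent = (0.40, 0.0, 0.30)
        mats = []
        for gi, co, ind in zip(g, common, independent):
            mats.append(np.array([[np.sqrt(gi), 0.0], [np.sqrt(co), np.sqrt(ind)]]))
        le = mats[2].copy()
        le[1, 1] = max(le[1, 1], 0.1)
        p = CholeskyParams(mats[0], mats[1], le, trait_names=("g", "ach"))
        d = simulate_cohort(SimConfig(n_mz_pairs=3000, n_dz_pairs=3000, cholesky=p, seed=21))
        fit = fit_cholesky(d, ("g", "ach"))
        lo, hi = independent_ci(fit, "C")
        assert lo == 0.0
        assert hi < 0.15

    def test_interval_contains_estimate(self, bivariate_params):
        d = simulate_cohort(
            SimConfig(n_mz_pairs=2000, n_dz_pairs=2000, cholesky=bivariate_params, seed=22)
        )
        fit = fit_cholesky(d, ("g", "ach"))
        lo, hi = independent_ci(fit, "A")
        a_ind = fit.independent[0]
        assert lo <= a_ind <= hi
        assert hi - lo < 0.35
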