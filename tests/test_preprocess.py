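"""Standardization, age/sex regression, composites, residualization."""

import numpy as np
import pandas as pd
import pytest

from twinace import (
    CorrectionSpec,
    SimConfig,
    TwinDataset,
    correct_age_sex,
    make_composite,
    residualize,
    simulate_cohort,
    standardize,
)
from twinace.errors import ConfigError, DegenerateScaleError, RankDeficiencyError
from twinace.pipeline import fixture_components
from twinace.sim import CholeskyParams


def _tiny(values_t1, values_t2, trait="y"):
    n = len(values_t1)
    df = pd.DataFrame(
        {
            "family_id": [f"f{i}" for i in range(n)],
            "zygosity": ["MZ"] * n,
            "sex_t1": ["F"] * n,
            "sex_t2": ["F"] * n,
            "age": [11.0] * n,
            f"{trait}_t1": values_t1,
            f"{trait}_t2": values_t2,
        }
    )
    return TwinDataset(df, (trait,))


class TestStandardize:
    def test_hand_arithmetic_with_missing_preserved(self):
        # values {1,2,3} (pop SD over pooled obs) -> {-something..}; with the
        # population convention the z-scores of 1,2,3 are -1.22..., 0, 1.22...
        # but over the pooled {1,2,3,NaN} set of 3 observations mean=2, sd=sqrt(2/3)
        d = _tiny([1.0, 2.0], [3.0, np.nan])
        z = standardize(d, ["y"])
        x = z.pairs("y")
        sd = np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(
            x, [[(1 - 2) / sd, (3 - 2) / sd], [0.0, np.nan]], rtol=1e-12
        )

    def test_simple_three_value_case(self):
        # {1,2,3} with one missing: mean 2, population SD sqrt(2/3);
        # scaled values keep their ordering and mean 0 / SD 1 pooled
        d = _tiny([1.0, 3.0, np.nan], [2.0, np.nan, np.nan])
        z = standardize(d, ["y"]).pairs("y")
        obs = z[~np.isnan(z)]
        assert obs.mean() == pytest.approx(0.0, abs=1e-12)
        assert obs.std() == pytest.approx(1.0, rel=1e-12)

    def test_idempotent(self, small_cohort):
        once = standardize(small_cohort, ["ach"])
        twice = standardize(once, ["ach"])
        np.testing.assert_allclose(
            once.pairs("ach"), twice.pairs("ach"), atol=1e-12, equal_nan=True
        )

    def test_constant_trait_raises(self):
        d = _tiny([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(DegenerateScaleError):
            standardize(d, ["y"])


@pytest.fixture(scope="module")
def agesex_cohort(uni_params):
    return simulate_cohort(
        SimConfig(n_mz_pairs=2000, n_dz_pairs=2000, cholesky=uni_params,
                  sex_effect=0.3, age_effect=0.2, seed=21)
    )


class TestCorrectAgeSex:
    def test_residuals_orthogonal_to_sex_and_age(self, agesex_cohort):
        out = correct_age_sex(agesex_cohort, ["ach"])
        long = out.long(["ach"])
        sex = (long["sex"] == "M").astype(float)
        assert abs(np.corrcoef(long["ach"], sex)[0, 1]) < 1e-10
        assert abs(np.corrcoef(long["ach"], long["age"])[0, 1]) < 1e-10

    def test_group_means_equalized(self, agesex_cohort):
        out = correct_age_sex(agesex_cohort, ["ach"])
        long = out.long(["ach"])
        means = long.groupby("sex")["ach"].mean()
        assert means["M"] == pytest.approx(means["F"], abs=1e-10)

    def test_trait_unrelated_to_age_sex_left_nearly_unchanged(self, uni_params):
        d = simulate_cohort(
            SimConfig(n_mz_pairs=5000, n_dz_pairs=5000, cholesky=uni_params, seed=31)
        )
        before = standardize(d, ["ach"]).long(["ach"])["ach"]
        after = correct_age_sex(d, ["ach"]).long(["ach"])["ach"]
        assert np.corrcoef(before, after)[0, 1] > 0.999


class TestComposite:
    def test_identical_subscales_reduce_to_standardized_value(self):
        base = _tiny([1.0, 2.0, 4.0], [3.0, 1.0, 2.0])
        d = base
        for s in ("s1", "s2", "s3"):
            d = d.with_trait(s, base.pairs("y")[:, 0], base.pairs("y")[:, 1])
        out = make_composite(d, ["s1", "s2", "s3"], "comp")
        np.testing.assert_allclose(
            out.pairs("comp"), standardize(base, ["y"]).pairs("y"), atol=1e-12
        )

    def test_mean_of_available_subscales(self):
        d = _tiny([0.0, 1.0], [1.0, 0.0], trait="s1")
        d = d.with_trait("s2", [1.0, 0.0], [np.nan, 1.0])
        out = make_composite(d, ["s1", "s2"], "comp")
        # twin2 of pair 1 has subscales {1, missing} -> pre-standardized mean 1
        raw = np.array([[0.5, 1.0], [0.5, 0.5]])
        z = (raw - raw.mean()) / raw.std()
        np.testing.assert_allclose(out.pairs("comp"), z, atol=1e-12)

    def test_six_subscales_intercorrelation_049_pc1_share(self):
        # six indicators with pairwise correlation .49 have first-PC share
        # .49 + .51/6 ~ .575 at large n
        from twinace import SubscaleSpec

        p = CholeskyParams.univariate(0.5, 0.3, 0.2, trait="ach")
        cfg = SimConfig(
            n_mz_pairs=20_000, n_dz_pairs=0, cholesky=p, seed=8,
            subscale_spec={"ach": SubscaleSpec(n_subscales=6, reliability=0.49)},
        )
        d = simulate_cohort(cfg)
        subs = d.long([f"ach_sub{i}" for i in range(1, 7)]).iloc[:, -6:]
        corr = np.corrcoef(subs.to_numpy(), rowvar=False)
        off = corr[~np.eye(6, dtype=bool)]
        assert off.mean() == pytest.approx(0.49, abs=0.02)
        share = np.linalg.eigvalsh(corr)[-1] / 6
        assert share == pytest.approx(0.58, abs=0.02)

    def test_empty_subscale_list_raises(self, small_cohort):
        with pytest.raises(ConfigError):
            make_composite(small_cohort, [], "comp")


@pytest.fixture(scope="module")
def cohort():
    sa, sc, se, names = fixture_components()
    params = CholeskyParams.from_components(sa, sc, se, names)
    d = simulate_cohort(
        SimConfig(n_mz_pairs=3000, n_dz_pairs=3000, cholesky=params,
                  missing_rate=0.05, seed=77)
    )
    return standardize(d, names)


class TestResidualize:
    def test_correlation_with_g_removed(self, cohort):
        long0 = cohort.long(["g", "ach12_test"]).dropna()
        before = np.corrcoef(long0["g"], long0["ach12_test"])[0, 1]
        assert before == pytest.approx(0.69, abs=0.03)
        out = residualize(cohort, CorrectionSpec("ach12_test", ("g",), "gfree"))
        long = out.long(["g", "gfree"]).dropna()
        assert abs(np.corrcoef(long["g"], long["gfree"])[0, 1]) < 1e-10

    def test_double_correction_orthogonal_to_both(self, cohort):
        spec = CorrectionSpec("ach12_teacher", ("ach10_teacher", "g"), "bothfree")
        out = residualize(cohort, spec)
        long = out.long(["bothfree", "ach10_teacher", "g"]).dropna()
        for cov in ("ach10_teacher", "g"):
            assert abs(np.corrcoef(long["bothfree"], long[cov])[0, 1]) < 1e-10

    def test_missing_covariate_propagates(self, cohort):
        out = residualize(cohort, CorrectionSpec("ach12_test", ("g",), "gfree"))
        g = out.pairs("g")
        gf = out.pairs("gfree")
        assert np.all(np.isnan(gf[np.isnan(g)]))

    def test_outcome_equal_to_covariate_raises(self, cohort):
        d = cohort.with_trait("g_copy", cohort.pairs("g")[:, 0], cohort.pairs("g")[:, 1])
        with pytest.raises(DegenerateScaleError, match="fully explained"):
            residualize(d, CorrectionSpec("g_copy", ("g",), "nothing"))

    def test_collinear_covariates_raise(self, cohort):
        d = cohort.with_trait("g2", 2 * cohort.pairs("g")[:, 0], 2 * cohort.pairs("g")[:, 1])
        with pytest.raises(RankDeficiencyError):
            residualize(d, CorrectionSpec("ach12_test", ("g", "g2"), "x"))

    def test_independent_covariate_leaves_trait_unchanged(self, uni_params):
        d = simulate_cohort(
            SimConfig(n_mz_pairs=5000, n_dz_pairs=5000, cholesky=uni_params, seed=13)
        )
        rng = np.random.default_rng(0)
        d = d.with_trait("noise", rng.standard_normal(d.n_pairs), rng.standard_normal(d.n_pairs))
        d = standardize(d, ["ach", "noise"])
        out = residualize(d, CorrectionSpec("ach", ("noise",), "resid"))
        long = out.long(["ach", "resid"]).dropna()
        assert np.corrcoef(long["ach"], long["resid"])[0, 1] > 0.999

    def test_pipeline_idempotent_on_own_output(self, cohort):
        once = correct_age_sex(standardize(cohort, ["ach12_test"]), ["ach12_test"])
        twice = correct_age_sex(standardize(once, ["ach12_test"]), ["ach12_test"])
        np.testing.assert_allclose(
            once.pairs("ach12_test"), twice.pairs("ach12_test"), atol=1e-8, equal_nan=True
        )

    def test_spec_validation(self):
        with pytest.raises(ConfigError):
            CorrectionSpec("y", ("y",), "bad")
        with pytest.raises(ConfigError):
            CorrectionSpec("y", (), "bad")
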