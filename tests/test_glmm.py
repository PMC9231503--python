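"""Mixed-model engine: scaling, GLM limits, oracle agreement, recovery,
likelihood-ratio tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import grouprhp as g
from grouprhp.errors import FitError, ScalingError
from grouprhp.glmm import (
    ModelSpec,
    _Binomial,
    _Design,
    drop1_lr,
    fit_glmm,
    fit_lmm,
    fit_poisson_olre,
    laplace_loglik,
    scale_predictors,
)


class TestScaling:
    def test_unit_variance_example(self):
        df = pd.DataFrame(dict(x=[1.0, 2.0, 3.0]))
        out, rec = scale_predictors(df, ["x"])
        np.testing.assert_allclose(out["x"], [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_column(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(dict(x=rng.normal(size=100)))
        once, _ = scale_predictors(df, ["x"])
        twice, _ = scale_predictors(once, ["x"])
        np.testing.assert_allclose(once["x"], twice["x"], atol=1e-12)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(dict(x=rng.normal(5, 3, 50)))
        out, rec = scale_predictors(df, ["x"])
        back = rec.inverse(out)
        np.testing.assert_allclose(back["x"], df["x"], atol=1e-12)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame(dict(rel_n_all=[2.0, 2.0, 2.0]))
        with pytest.raises(ScalingError, match="rel_n_all"):
            scale_predictors(df, ["rel_n_all"])


def _sim_binomial(rng, n=400, beta=(0.0, 1.0), n_groups=8, sigma=0.0):
    x = rng.normal(size=n)
    f = rng.integers(0, n_groups, n)
    r = (f + 1 + rng.integers(0, n_groups - 1, n)) % n_groups
    a = rng.normal(0, sigma, n_groups)
    eta = beta[0] + beta[1] * x + a[f] - a[r]
    return pd.DataFrame(
        dict(x=x, y=(rng.random(n) < expit(eta)).astype(int),
             fg=[f"G{i}" for i in f], rg=[f"G{i}" for i in r])
    )


class TestBinomialGlmm:
    def test_sigma_zero_matches_plain_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        d = _sim_binomial(rng, n=2500, sigma=0.0)
        spec = ModelSpec("y", ("x",), ("fg", "rg"), "binomial")
        fit = fit_glmm(spec, d)
        glm = sm.GLM(d["y"], sm.add_constant(d["x"]),
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta.to_numpy(), glm.params.to_numpy(),
                                   atol=1e-3)

    def test_laplace_at_zero_variance_equals_glm_loglik(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        d = _sim_binomial(rng, n=300, sigma=0.0)
        spec = ModelSpec("y", ("x",), ("fg", "rg"), "binomial")
        des = _Design(spec, d)
        fam = _Binomial(des.y, des.m)
        glm = sm.GLM(d["y"], sm.add_constant(d["x"]),
                     family=sm.families.Binomial()).fit()
        beta = glm.params.to_numpy()
        ll, _ = laplace_loglik(des, fam, beta, np.array([1e-12, 1e-12]))
        assert ll == pytest.approx(glm.llf, abs=1e-6)

    def test_mirrored_data_give_zero_intercept(self):
        rng = np.random.default_rng(4)
        d = _sim_binomial(rng, n=300, beta=(0.6, 0.8), sigma=0.3)
        mirror = d.copy()
        mirror["x"] = -d["x"]
        mirror["y"] = 1 - d["y"]
        mirror["fg"] = d["fg"] + "m"
        mirror["rg"] = d["rg"] + "m"
        both = pd.concat([d, mirror], ignore_index=True)
        fit = fit_glmm(ModelSpec("y", ("x",), ("fg", "rg"), "binomial"), both)
        assert abs(fit.beta["(Intercept)"]) < 1e-6

    def test_relabel_swap_likelihood_invariant_at_matched_params(self):
        rng = np.random.default_rng(5)
        d = _sim_binomial(rng, n=250, beta=(0.0, 0.9), sigma=0.4)
        swapped = d.copy()
        swapped["x"] = -d["x"]
        swapped["y"] = 1 - d["y"]
        swapped["fg"], swapped["rg"] = d["rg"], d["fg"]
        spec = ModelSpec("y", ("x",), ("fg", "rg"), "binomial")
        beta = np.array([0.0, 0.7])
        lls = []
        for frame, s2 in ((d, (0.2, 0.3)), (swapped, (0.3, 0.2))):
            des = _Design(spec, frame)
            fam = _Binomial(des.y, des.m)
            lls.append(laplace_loglik(des, fam, beta, np.array(s2))[0])
        assert lls[0] == pytest.approx(lls[1], abs=1e-8)

    def test_estimates_invariant_to_affine_raw_predictors(self):
        rng = np.random.default_rng(6)
        d = _sim_binomial(rng, n=300, sigma=0.3)
        d2 = d.copy()
        d2["x"] = 3.0 * d["x"] - 5.0
        spec = ModelSpec("y", ("x",), ("fg", "rg"), "binomial")
        fits = []
        for frame in (d, d2):
            scaled, _ = scale_predictors(frame, ["x"])
            fits.append(fit_glmm(spec, scaled, compute_se=False))
        np.testing.assert_allclose(fits[0].beta, fits[1].beta, atol=1e-6)

    def test_paired_difference_random_term(self):
        # the (focal, rival) paired term gives one shared ability per group
        rng = np.random.default_rng(7)
        d = _sim_binomial(rng, n=600, beta=(0.0, 1.0), n_groups=10, sigma=0.8)
        spec = ModelSpec("y", ("x",), (("fg", "rg"),), "binomial")
        fit = fit_glmm(spec, d)
        assert fit.converged
        name = "fg-rg"
        assert name in fit.random_variances
        assert fit.random_variances[name] > 0.1  # real signal present
        assert len(fit.ranef_modes[name]) == 10

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(8)
        d = _sim_binomial(rng, n=100)
        d["x2"] = d["x"]
        with pytest.raises(FitError):
            fit_glmm(ModelSpec("y", ("x", "x2"), ("fg",), "binomial"), d)


class TestGaussianLmm:
    def _sim(self, rng, n_id=60, reps=4, gap=147.0, sd_id=50.0, sd_e=80.0):
        ids = np.repeat(np.arange(n_id), reps)
        sex = np.repeat((rng.random(n_id) < 0.5).astype(float), reps)
        u = np.repeat(rng.normal(0, sd_id, n_id), reps)
        y = 1300 + gap * sex + u + rng.normal(0, sd_e, len(ids))
        return pd.DataFrame(dict(individual_id=ids, sex_male=sex, weight_g=y))

    spec = ModelSpec("weight_g", ("sex_male",), ("individual_id",), "gaussian")

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(9)
        d = self._sim(rng)
        fit = fit_lmm(self.spec, d)
        ref = smf.mixedlm("weight_g ~ sex_male", d, groups=d["individual_id"]).fit(
            reml=False
        )
        np.testing.assert_allclose(
            fit.beta.to_numpy(), ref.params.iloc[:2].to_numpy(), atol=1e-4
        )
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)
        assert fit.random_variances["individual_id"] == pytest.approx(
            ref.cov_re.iloc[0, 0], rel=1e-3
        )

    def test_reml_matches_statsmodels(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(10)
        d = self._sim(rng)
        fit = fit_lmm(self.spec, d, reml=True)
        ref = smf.mixedlm("weight_g ~ sex_male", d, groups=d["individual_id"]).fit(
            reml=True
        )
        assert fit.random_variances["individual_id"] == pytest.approx(
            ref.cov_re.iloc[0, 0], rel=1e-3
        )
        assert fit.residual_variance == pytest.approx(ref.scale, rel=1e-3)

    def test_zero_between_individual_variance_boundary(self):
        rng = np.random.default_rng(11)
        d = self._sim(rng, sd_id=0.0)
        fit = fit_lmm(self.spec, d)
        assert fit.random_variances["individual_id"] < 1e-3 * fit.residual_variance

    def test_sex_gap_recovered(self):
        rng = np.random.default_rng(12)
        d = self._sim(rng, n_id=250, reps=8, gap=147.0)
        fit = fit_lmm(self.spec, d)
        assert abs(fit.beta["sex_male"] - 147.0) < 3 * fit.se["sex_male"]

    def test_duplicating_rows_leaves_point_estimates(self):
        rng = np.random.default_rng(13)
        d = self._sim(rng, n_id=40)
        doubled = pd.concat([d, d], ignore_index=True)
        f1 = fit_lmm(self.spec, d, compute_se=False)
        f2 = fit_lmm(self.spec, doubled, compute_se=False)
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-8)


class TestPoissonOlre:
    spec = ModelSpec("y", ("x",), (), "poisson", olre=True)

    def _sim(self, rng, n=300, slope=0.8, olre_sd=0.5):
        x = rng.normal(size=n)
        eta = 1.0 + slope * x + rng.normal(0, olre_sd, n)
        return pd.DataFrame(dict(x=x, y=rng.poisson(np.exp(eta))))

    def test_equidispersed_counts_have_tiny_olre_variance(self):
        rng = np.random.default_rng(14)
        d = self._sim(rng, n=800, olre_sd=0.0)
        fit = fit_poisson_olre(self.spec, d)
        assert fit.random_variances["_olre"] < 0.05

    def test_overdispersion_and_slope_recovered(self):
        rng = np.random.default_rng(15)
        sds, slopes = [], []
        for _ in range(20):
            fit = fit_poisson_olre(self.spec, self._sim(rng), compute_se=False)
            sds.append(np.sqrt(fit.random_variances["_olre"]))
            slopes.append(fit.beta["x"])
        assert abs(np.median(sds) - 0.5) < 0.1
        assert abs(np.median(slopes) - 0.8) < 0.1


class TestDrop1:
    def test_chisq_is_twice_loglik_difference(self):
        rng = np.random.default_rng(16)
        d = _sim_binomial(rng, n=300, beta=(0.0, 0.7), sigma=0.3)
        spec = ModelSpec("y", ("x",), ("fg", "rg"), "binomial")
        full = fit_glmm(spec, d)
        reduced = fit_glmm(spec.drop("x"), d)
        lr = drop1_lr(full, "x", d)
        assert lr.chisq == pytest.approx(2 * (full.loglik - reduced.loglik), abs=1e-6)
        assert lr.df == 1 and 0 <= lr.p <= 1

    def test_null_term_p_values_are_uniform(self):
        rng = np.random.default_rng(17)
        ps = []
        spec = ModelSpec("y", ("x",), ("fg",), "binomial")
        for _ in range(120):
            d = _sim_binomial(rng, n=120, beta=(0.0, 0.0), sigma=0.3)
            try:
                ps.append(drop1_lr(fit_glmm(spec, d, compute_se=False), "x", d).p)
            except FitError:
                continue
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_unknown_term_rejected(self):
        rng = np.random.default_rng(18)
        d = _sim_binomial(rng, n=100)
        fit = fit_glmm(ModelSpec("y", ("x",), ("fg",), "binomial"), d)
        with pytest.raises(ValueError):
            drop1_lr(fit, "nope", d)
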