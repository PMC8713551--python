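import math

import numpy as np
import pandas as pd
import pytest

from searchbench.glmm import SeparationError
from searchbench.models import (EXP1_PREDICTORS, EXP2_PREDICTORS,
                                LOGIT_RESIDUAL_VAR, build_instance_table,
                                build_selection_table, build_trial_table,
                                delta_r2_by_predictor,
                                fit_false_positive_model, fit_instance_model,
                                fit_trial_model, predict_selection_probability,
                                pseudo_r2, vif)


@pytest.fixture(scope="module")
def exp2_instance_table(exp2_scored):
    _, sc = exp2_scored
    return build_instance_table(sc)


class TestTableBuilders:
    def test_instance_table_shape_and_outcome(self, exp2_scored):
        _, sc = exp2_scored
        it = build_instance_table(sc)
        truth = sc[sc["role"].isin(["TP", "FN"])]
        assert len(it) == len(truth)
        assert set(it["selected"].unique()) <= {0, 1}
        assert it["selected"].sum() == (truth["role"] == "TP").sum()
        assert np.allclose(it["log_area"], np.log(it["area"].astype(float)))

    def test_instance_table_excludes_false_positives(self, exp2_scored):
        _, sc = exp2_scored
        it = build_instance_table(sc)
        assert it["instance_id"].notna().all()

    def test_selection_table_outcome(self, exp2_scored):
        _, sc = exp2_scored
        st = build_selection_table(sc)
        clicks = sc[sc["role"].isin(["TP", "FP"])]
        assert len(st) == len(clicks)
        assert st["false_positive"].sum() == (clicks["role"] == "FP").sum()

    def test_trial_table_averages(self, exp2_scored):
        _, sc = exp2_scored
        tt = build_trial_table(sc)
        assert len(tt) == sc["trial_id"].nunique()
        assert tt["tp_rate"].between(0, 1).all()
        assert tt["pct_color_match"].between(0, 1).all()
        one = sc[sc["trial_id"] == tt.index[0]]
        assert tt.loc[tt.index[0], "n_targets"] == one["n_targets"].iloc[0]


class TestPredict:
    def test_all_zero_coefficients_give_half(self):
        p = predict_selection_probability({}, area=100, distance=10,
                                          n_targets=2)
        assert p == 0.5

    def test_reported_coefficients_reproduce_headline_probability(self):
        coefs = {"intercept": -5.88, "log_area": 0.92,
                 "dist_center": -0.001, "n_targets": -0.05}
        p = predict_selection_probability(coefs, area=10_000, distance=299,
                                          n_targets=1)
        eta = -5.88 + 0.92 * math.log(10_000) - 0.001 * 299 - 0.05 * 1
        assert p == pytest.approx(1 / (1 + math.exp(-eta)))
        assert p > 0.90

    def test_monotone_in_area_when_coefficient_positive(self):
        coefs = {"intercept": -5.88, "log_area": 0.92}
        ps = [predict_selection_probability(coefs, area=a, distance=0,
                                            n_targets=0)
              for a in (100, 1000, 10_000, 100_000)]
        assert ps == sorted(ps)

    def test_missing_required_extra_rejected(self):
        coefs = {"intercept": 0.0, "clarity": 0.5}
        with pytest.raises(ValueError, match="clarity"):
            predict_selection_probability(coefs, area=100, distance=0,
                                          n_targets=1)

    def test_extras_enter_linear_predictor(self):
        coefs = {"clarity": 1.0, "color_match": 2.0}
        p = predict_selection_probability(coefs, area=100, distance=0,
                                          n_targets=0, clarity=1.0,
                                          color_match=1.0)
        assert p == pytest.approx(1 / (1 + math.exp(-3.0)))


class TestPseudoR2:
    class _FakeFit:
        def __init__(self, s2f, vc):
            self.fixed_lp_var = s2f
            self.vc = vc

    def test_zero_fixed_variance_gives_zero_marginal(self):
        from searchbench.glmm import MixedModelFit
        fit = MixedModelFit(params=pd.Series({"Intercept": 0.0}),
                            bse=pd.Series({"Intercept": 1.0}),
                            vc={"worker": 1.0, "trial": 0.0}, loglik=0.0,
                            converged=True, n_obs=10, fixed_lp_var=0.0)
        r2m, r2c = pseudo_r2(fit)
        assert r2m == 0.0
        assert r2c == pytest.approx(1.0 / (1.0 + LOGIT_RESIDUAL_VAR))

    def test_unit_variances_closed_form(self):
        from searchbench.glmm import MixedModelFit
        fit = MixedModelFit(params=pd.Series({"Intercept": 0.0}),
                            bse=pd.Series({"Intercept": 1.0}),
                            vc={"worker": 0.5, "trial": 0.5}, loglik=0.0,
                            converged=True, n_obs=10, fixed_lp_var=1.0)
        r2m, r2c = pseudo_r2(fit)
        assert r2m == pytest.approx(1.0 / (2.0 + math.pi ** 2 / 3))
        assert r2c == pytest.approx(2.0 / (2.0 + math.pi ** 2 / 3))
        assert r2m <= r2c


class TestVif:
    def test_closed_form_from_pairwise_correlation(self, rng):
        n = 5000
        r_target = 0.6
        x = rng.normal(size=n)
        y = r_target * x + math.sqrt(1 - r_target ** 2) * rng.normal(size=n)
        out = vif(pd.DataFrame({"x": x, "y": y}))
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert out["x"] == pytest.approx(1.0 / (1.0 - r2))
        assert out["y"] == pytest.approx(1.0 / (1.0 - r2))

    def test_duplicate_column_is_infinite(self, rng):
        x = rng.normal(size=50)
        out = vif(pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)}))
        assert math.isinf(out["a"]) and math.isinf(out["b"])
        assert out["c"] < 1.5

    def test_affine_rescaling_invariant(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        X["b"] += 0.7 * X["a"]
        scaled = X * [10.0, 0.01, 3.0] + [5.0, -2.0, 0.0]
        pd.testing.assert_series_equal(vif(X), vif(scaled), atol=1e-9)

    def test_single_column_rejected(self, rng):
        with pytest.raises(ValueError):
            vif(pd.DataFrame({"a": rng.normal(size=10)}))


class TestTrialModel:
    def _table(self, rng, n=40):
        df = pd.DataFrame({
            "mean_clarity": rng.uniform(1, 5, n),
            "pct_color_match": rng.uniform(0, 1, n),
            "n_targets": rng.integers(1, 20, n).astype(float),
        }, index=[f"t{i}" for i in range(n)])
        df["tp_rate"] = (0.2 + 0.1 * df["mean_clarity"]
                         + 0.05 * df["pct_color_match"]
                         - 0.004 * df["n_targets"])
        return df

    def test_recovers_exact_linear_relationship(self, rng):
        tt = self._table(rng)
        fit = fit_trial_model(tt, predictors=("mean_clarity",
                                              "pct_color_match", "n_targets"))
        assert fit.r2 == pytest.approx(1.0)
        assert fit.params["Intercept"] == pytest.approx(0.2, abs=1e-8)
        assert fit.params["mean_clarity"] == pytest.approx(0.1, abs=1e-8)
        assert fit.params["n_targets"] == pytest.approx(-0.004, abs=1e-10)

    def test_rank_deficiency_names_collinear_pair(self, rng):
        tt = self._table(rng)
        tt["pct_color_match"] = 2.0 * tt["mean_clarity"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_trial_model(tt, predictors=("mean_clarity",
                                            "pct_color_match", "n_targets"))

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError, match="complete trials"):
            fit_trial_model(self._table(rng, n=4),
                            predictors=("mean_clarity", "pct_color_match",
                                        "n_targets"))

    def test_on_simulated_cohort(self, exp2_scored):
        _, sc = exp2_scored
        tt = build_trial_table(sc)
        fit = fit_trial_model(tt, predictors=("mean_clarity",
                                              "pct_color_match", "n_targets"))
        assert 0.0 <= fit.r2 <= 1.0
        assert fit.n_obs == len(tt)


class TestMixedModelsOnCohort:
    def test_instance_model_signs_match_generator(self, exp2_instance_table):
        fit = fit_instance_model(exp2_instance_table, EXP2_PREDICTORS)
        assert fit.converged
        assert fit.params["log_area"] > 0
        assert fit.params["clarity"] > 0
        assert fit.params["color_match"] > 0
        assert fit.n_obs == len(exp2_instance_table)

    def test_pseudo_r2_ordering(self, exp2_instance_table):
        fit = fit_instance_model(exp2_instance_table, EXP1_PREDICTORS)
        r2m, r2c = pseudo_r2(fit)
        assert 0.0 < r2m <= r2c < 1.0

    def test_delta_r2_dominated_by_log_area(self, exp2_instance_table):
        d = delta_r2_by_predictor(exp2_instance_table, EXP1_PREDICTORS)
        assert set(d.index) == set(EXP1_PREDICTORS)
        assert (d["delta_r2_marginal"] >= 0).all()
        assert d["delta_r2_marginal"].idxmax() == "log_area"

    def test_false_positive_model_fits_on_cohort(self, exp2_scored):
        _, sc = exp2_scored
        st = build_selection_table(sc)
        fit = fit_false_positive_model(st)
        assert fit.converged
        # FP placement rate falls with n_targets in the generator
        assert fit.params["n_targets"] < 0

    def test_false_positive_model_one_sided_outcome_rejected(self, exp2_scored):
        _, sc = exp2_scored
        st = build_selection_table(sc)
        st = st[st["false_positive"] == 0]
        with pytest.raises(SeparationError):
            fit_false_positive_model(st)
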