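"""Missingness model, weight stabilisation/truncation and IPW-GEE."""

import numpy as np
import pandas as pd
import pytest

import proimpute as pi
from proimpute.design import ModelSpec, Term
from proimpute.ipw import MissingnessModel, WeightModelSpec, default_weight_spec

INTERCEPT_ONLY = ModelSpec((), response="r_obs", random_intercept=False, name="intercept")


def _with_missing_pattern(trial, frac=0.4, seed=0):
    rng = np.random.default_rng(seed)
    out = trial.copy()
    non_base = out.rows["cycle"] > 1
    drop = rng.random(len(out.rows)) < frac
    out.rows.loc[drop & non_base, "qol"] = np.nan
    out.rows["r_obs"] = out.rows["qol"].notna().astype(int)
    return out


class TestMissingnessModel:
    def test_intercept_only_recovers_observed_fraction(self, complete_trial):
        data = _with_missing_pattern(complete_trial)
        p = pi.fit_missingness_model(data, INTERCEPT_ONLY)
        np.testing.assert_allclose(p, data.rows["r_obs"].mean(), atol=1e-8)

    def test_all_observed_is_degenerate(self, complete_trial):
        with pytest.raises(ValueError, match="degenerate"):
            pi.fit_missingness_model(complete_trial, INTERCEPT_ONLY)

    def test_logistic_parameter_recovery(self):
        # simulate a logistic observation model on the trial covariates
        cfg = pi.SimConfig(n_patients=800, seed=5)
        trial = pi.simulate_trial(cfg)
        rng = np.random.default_rng(6)
        s = np.minimum(trial.rows["s"].to_numpy(), 8.0)
        logit = 0.8 - 0.25 * s
        r = rng.random(len(s)) < 1.0 / (1.0 + np.exp(-logit))
        data = trial.copy()
        data.rows.loc[~r, "qol"] = np.nan
        data.rows["r_obs"] = data.rows["qol"].notna().astype(int)
        # model r on min(s, 8) via a precomputed column
        data.rows["s_capped"] = s
        spec = WeightModelSpec(ModelSpec((Term("s_capped"),), response="r_obs",
                                         random_intercept=False, name="lin"))
        res = MissingnessModel(data, spec).fit()
        est = dict(zip(res.builder.columns_, res.params))
        se = dict(zip(res.builder.columns_, res.bse))
        assert abs(est["intercept"] - 0.8) < 3 * se["intercept"]
        assert abs(est["s_capped"] - (-0.25)) < 3 * se["s_capped"]

    def test_weight_spec_guards(self):
        with pytest.raises(ValueError, match="r_obs"):
            WeightModelSpec(ModelSpec((), response="qol", random_intercept=False))
        with pytest.raises(ValueError, match="outcome"):
            WeightModelSpec(ModelSpec((Term("qol"),), response="r_obs", random_intercept=False))
        with pytest.raises(ValueError, match="random effects"):
            WeightModelSpec(ModelSpec((), response="r_obs", random_intercept=True))

    def test_default_weight_spec_mirrors_imputation_terms(self):
        spec = default_weight_spec("model3")
        assert spec.response == "r_obs" and not spec.random_intercept
        assert {t.var for t in spec.terms} >= {"s", "t_pd", "t_td", "cycle"}


class TestStabilizeTruncate:
    def test_marginal_model_gives_unit_weights(self, complete_trial):
        data = _with_missing_pattern(complete_trial)
        marg = data.rows.groupby("cycle")["r_obs"].mean()
        p = marg.reindex(data.rows["cycle"]).to_numpy()
        p = np.clip(p, 1e-9, 1 - 1e-9)
        ws = pi.stabilize_truncate(data, p, bounds=(0.0, 1.0))
        np.testing.assert_allclose(ws.weights, 1.0, atol=1e-6)

    def test_absolute_cap(self, complete_trial):
        data = _with_missing_pattern(complete_trial)
        # extreme probability on one row -> raw weight far above the cap
        marg = data.rows.groupby("cycle")["r_obs"].mean()
        p = np.clip(marg.reindex(data.rows["cycle"]).to_numpy(), 1e-9, 1 - 1e-9)
        p[5] = p[5] / 20.0  # raw weight 20 on this row
        ws = pi.stabilize_truncate(data, p, bounds=(0.0, 1.0), absolute_bounds=(0.0, 10.0))
        assert ws.weights[5] == 10.0 and ws.truncated[5]
        others = np.delete(ws.weights, 5)
        np.testing.assert_allclose(others, 1.0, atol=1e-6)

    def test_mean_weight_near_one_before_truncation(self, observed_trial):
        fitted = MissingnessModel(observed_trial, "model3").fit()
        ws = fitted.weight_set(bounds=(0.0, 1.0))
        mean_w = ws.observed_weights(observed_trial).mean()
        assert abs(mean_w - 1.0) < 0.05

    def test_percentile_truncation_flags_rows(self, observed_trial):
        fitted = MissingnessModel(observed_trial, "model3").fit()
        ws = fitted.weight_set(bounds=(0.05, 0.95))
        assert ws.truncated.any()
        lo, hi = np.quantile(ws.weights, [0.0, 1.0])
        assert hi <= np.quantile(fitted.weight_set(bounds=(0.0, 1.0)).weights, 0.951)

    def test_invalid_probabilities_rejected(self, observed_trial):
        with pytest.raises(ValueError, match="strictly in"):
            pi.stabilize_truncate(observed_trial, np.ones(observed_trial.n_rows))


class TestIpwGee:
    def test_unit_weights_reduce_to_available_case(self, observed_trial):
        ws = pi.WeightSet(
            p_obs=np.full(observed_trial.n_rows, 0.5),
            weights=np.ones(observed_trial.n_rows),
            truncation_bounds=(0.0, 1.0),
            truncated=np.zeros(observed_trial.n_rows, dtype=bool),
        )
        res = pi.ipw_gee_estimate(observed_trial, ws)
        ac = observed_trial.rows.groupby("cycle")["qol"].mean()
        got = res.cycle_means.table.set_index("cycle")["estimate"]
        np.testing.assert_allclose(got.to_numpy(), ac.to_numpy())

    def test_empty_cycle_flagged_not_fatal(self, complete_trial):
        data = complete_trial.copy()
        late = data.rows["cycle"] == data.schedule.max_cycle
        data.rows.loc[late, "qol"] = np.nan
        data.rows["r_obs"] = data.rows["qol"].notna().astype(int)
        ws = pi.WeightSet(
            p_obs=np.full(data.n_rows, 0.5), weights=np.ones(data.n_rows),
            truncation_bounds=(0.0, 1.0), truncated=np.zeros(data.n_rows, dtype=bool),
        )
        res = pi.ipw_gee_estimate(data, ws)
        row = res.cycle_means.table.set_index("cycle").loc[data.schedule.max_cycle]
        assert np.isnan(row["estimate"]) and row["n_used"] == 0

    def test_result_carries_survival_and_provenance(self, observed_trial):
        fitted = MissingnessModel(observed_trial, "model3").fit()
        res = pi.ipw_gee_estimate(observed_trial, fitted.weight_set())
        assert res.survival is not None
        assert res.provenance["method"] == "ipw_gee"
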