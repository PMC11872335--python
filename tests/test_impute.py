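"""Imputation engines: fitting, predictive draws, multiple imputation."""

import numpy as np
import pytest

import proimpute as pi
from proimpute.design import DesignBuilder, ModelSpec, Term, default_model_spec
from proimpute.impute import _pmm_match, default_m


def _known_lmm_trial(n=250, seed=9):
    """Trial whose scores follow a known linear mixed model (no ICE effects)."""
    cfg = pi.SimConfig(
        n_patients=n,
        schedule=pi.Schedule(tuple(range(1, 9))),
        survival_rate=0.02,
        admin_censor_time=8.0,
        trajectory=pi.TrajectoryModel(
            baseline_mean=70.0, slope_per_cycle=-0.5, death_decline_points=0.0,
            post_pd_drop=0.0, random_intercept_sd=5.0, residual_sd=6.0,
        ),
        clip_scores=False,
        seed=seed,
    )
    return pi.simulate_trial(cfg)


LINEAR_SPEC = ModelSpec((Term("cycle"),), name="linear")


class TestModelSpecs:
    def test_model3_contains_ice_terms(self):
        spec = default_model_spec("model3")
        labels = [t.label() for t in spec.terms]
        assert "rcs(s):death_ind" in labels
        assert "e_pd_now:pd_ind" in labels
        assert spec.random_intercept

    def test_naive_has_no_ice_information(self):
        spec = default_model_spec("naive")
        vars_ = {t.var for t in spec.terms}
        assert vars_.isdisjoint({"s", "t_pd", "t_td", "e_pd_now", "e_td_now", "death_ind"})

    def test_model2_uses_bsplines_with_random_intercept(self):
        spec = default_model_spec("model2")
        assert any(t.transform == "bspline" for t in spec.terms)
        assert spec.random_intercept

    def test_model45_is_fixed_effects_only(self):
        assert not default_model_spec("model45").random_intercept

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="unknown model variant"):
            default_model_spec("model9")


class TestFit:
    def test_parameter_recovery_known_model(self):
        complete = _known_lmm_trial()
        observed = pi.apply_missingness(
            complete, pi.MissingnessConfig(mechanism="MCAR", base_logit=-1.0), seed=10
        )
        fitted = pi.fit_imputation_model(observed, LINEAR_SPEC, "lmm_normal")
        est = dict(zip(fitted.builder.columns_, fitted.params))
        se = dict(zip(fitted.builder.columns_, np.sqrt(np.diag(fitted.cov_params))))
        assert abs(est["intercept"] - 70.5) < 3 * se["intercept"]
        assert abs(est["cycle"] - (-0.5)) < 3 * se["cycle"]
        assert abs(np.sqrt(fitted.sigma2) - 6.0) < 0.5
        assert abs(np.sqrt(fitted.tau2) - 5.0) < 1.0

    def test_constant_outcome(self):
        cfg = pi.SimConfig(
            n_patients=40, schedule=pi.Schedule(tuple(range(1, 6))),
            survival_rate=0.0, admin_censor_time=5.0,
            trajectory=pi.TrajectoryModel(baseline_mean=65.0, slope_per_cycle=0.0,
                                          death_decline_points=0.0, post_pd_drop=0.0,
                                          random_intercept_sd=0.0, residual_sd=0.0),
            seed=1,
        )
        data = pi.simulate_trial(cfg)
        fitted = pi.fit_imputation_model(data, LINEAR_SPEC, "lmm_normal")
        assert fitted.sigma2 < 1e-6
        est = dict(zip(fitted.builder.columns_, fitted.params))
        assert abs(est["intercept"] - 65.0) < 1e-3

    def test_duplicate_column_rejected(self, observed_trial):
        spec = ModelSpec((Term("age"), Term("age")), name="dup")
        with pytest.raises(ValueError, match="duplicate main-effect columns.*age"):
            pi.fit_imputation_model(observed_trial, spec, "lmm_normal")

    def test_expected_interaction_alias_is_pruned_not_fatal(self, observed_trial):
        # e_pd_now:pd_ind duplicates e_pd_now by construction (the indicator
        # only switches on for observed events); it must be dropped, logged
        fitted = pi.fit_imputation_model(observed_trial, "model3", "lmm_normal")
        assert "e_pd_now:pd_ind" in fitted.diagnostics["dropped_columns"]

    def test_rcs_to_bspline_fallback_on_ill_conditioning(self, observed_trial):
        with pytest.warns(UserWarning, match="fallback"):
            fitted = pi.fit_imputation_model(
                observed_trial, "model3", "lmm_normal", condition_threshold=10.0
            )
        assert "[bspline]" in fitted.spec.name

    def test_naive_engine_refuses_ice_spec(self, observed_trial):
        with pytest.raises(ValueError, match="ICE-free"):
            pi.ImputationModel(observed_trial, spec="model3", engine="naive_lmm")


class TestNormalDraws:
    def test_zero_missing_is_identity(self, complete_trial):
        fitted = pi.fit_imputation_model(complete_trial, LINEAR_SPEC, "lmm_normal")
        out = fitted.draw(np.random.default_rng(0))
        assert out.rows["qol"].equals(complete_trial.rows["qol"])

    def test_degenerate_draw_is_deterministic_predictor(self, observed_trial):
        fitted = pi.fit_imputation_model(observed_trial, LINEAR_SPEC, "lmm_normal")
        # force all uncertainty to zero: draw must equal BLUP + fixed predictor
        fitted.cov_params = np.zeros_like(fitted.cov_params)
        fitted.sigma2 = 0.0
        fitted.cond_var[:] = 0.0
        fitted.tau2 = 0.0
        a = fitted.draw(np.random.default_rng(1))
        b = fitted.draw(np.random.default_rng(2))
        assert np.allclose(a.rows["qol"], b.rows["qol"])

    def test_draw_variance_decomposition(self):
        complete = _known_lmm_trial(n=60, seed=17)
        rows = complete.rows.copy()
        # blank a single mid-study cell of a patient with several observations
        counts = rows.groupby("patient_id").size()
        pid = counts[counts >= 5].index[0]
        idx = rows.index[(rows["patient_id"] == pid)][2]
        observed = complete.copy()
        observed.rows.loc[idx, "qol"] = np.nan
        observed.rows["r_obs"] = observed.rows["qol"].notna().astype(int)
        fitted = pi.fit_imputation_model(observed, LINEAR_SPEC, "lmm_normal")
        rng = np.random.default_rng(3)
        draws = np.array([fitted.draw(rng).rows.loc[idx, "qol"] for _ in range(400)])
        x = fitted.X_all[list(observed.rows.index).index(idx)]
        n_i = (observed.rows["patient_id"] == pid).sum() - 1  # observed rows of the donor patient
        v_i = 1.0 / (1.0 / fitted.tau2 + n_i / fitted.sigma2)
        theoretical = float(x @ fitted.cov_params @ x + v_i + fitted.sigma2)
        assert draws.var(ddof=1) >= fitted.sigma2 * 0.85  # >= residual variance
        assert abs(draws.var(ddof=1) - theoretical) < 0.35 * theoretical


class TestPmm:
    def test_nearest_donor_matching(self):
        out = _pmm_match(
            np.array([55.0]), np.array([50.0, 54.0, 70.0]),
            np.array([48.0, 53.0, 71.0]), k_donors=1, rng=np.random.default_rng(0),
        )
        assert out[0] == 53.0

    def test_constant_observed_values(self, observed_trial):
        data = observed_trial.copy()
        data.rows.loc[data.rows["r_obs"] == 1, "qol"] = 72.0
        fitted = pi.fit_imputation_model(data, LINEAR_SPEC, "lmm_pmm")
        out = fitted.draw(np.random.default_rng(0))
        assert (out.rows["qol"] == 72.0).all()

    def test_support_subset_of_observed(self, observed_trial):
        fitted = pi.fit_imputation_model(observed_trial, "model2", "lmm_pmm")
        observed_support = set(observed_trial.rows["qol"].dropna())
        mis = observed_trial.rows["qol"].isna()
        rng = np.random.default_rng(4)
        for _ in range(20):
            drawn = set(fitted.draw(rng).rows.loc[mis, "qol"])
            assert drawn <= observed_support


class TestClusteredBootstrap:
    def test_zero_missing_is_identity(self, complete_trial):
        fitted = pi.fit_imputation_model(complete_trial, "model45", "boot_gam_normal")
        out = fitted.draw(np.random.default_rng(0))
        assert out.rows["qol"].equals(complete_trial.rows["qol"])

    def test_noise_free_trend_predicted_exactly(self):
        cfg = pi.SimConfig(
            n_patients=30, schedule=pi.Schedule(tuple(range(1, 7))),
            survival_rate=0.0, admin_censor_time=6.0,
            trajectory=pi.TrajectoryModel(baseline_mean=80.0, slope_per_cycle=-2.0,
                                          death_decline_points=0.0, post_pd_drop=0.0,
                                          random_intercept_sd=0.0, residual_sd=0.0),
            seed=2,
        )
        data = pi.simulate_trial(cfg)
        data.rows.loc[data.rows.index[10], "qol"] = np.nan
        data.rows["r_obs"] = data.rows["qol"].notna().astype(int)
        out = pi.draw_imputation_boot_gam(data, LINEAR_SPEC, np.random.default_rng(0), "normal")
        j = data.rows.loc[data.rows.index[10], "cycle"]
        assert abs(out.rows.loc[data.rows.index[10], "qol"] - (80.0 - 2.0 * (j - 1))) < 1e-6

    def test_between_imputation_variance_positive(self, observed_trial):
        fitted = pi.fit_imputation_model(observed_trial, "model45", "boot_gam_normal")
        idx = observed_trial.rows.index[observed_trial.rows["qol"].isna()][0]
        rng = np.random.default_rng(5)
        draws = [fitted.draw(rng).rows.loc[idx, "qol"] for _ in range(30)]
        assert np.var(draws) > 0

    def test_pmm_variant_bounded_by_observed_support(self, observed_trial):
        fitted = pi.fit_imputation_model(observed_trial, "model45", "boot_gam_pmm")
        out = fitted.draw(np.random.default_rng(6))
        mis = observed_trial.rows["qol"].isna()
        assert set(out.rows.loc[mis, "qol"]) <= set(observed_trial.rows["qol"].dropna())


class TestMultipleImputation:
    def test_default_m_rule(self):
        assert default_m(0.405) == 40  # 40.5% missing -> 40 imputations
        assert default_m(0.02) == 5    # never fewer than the floor
        assert default_m(0.17) == 17

    def test_determinism_and_observed_preservation(self, observed_trial):
        r1 = pi.multiply_impute(observed_trial, "model3", "lmm_normal", m=3, seed=7)
        r2 = pi.multiply_impute(observed_trial, "model3", "lmm_normal", m=3, seed=7)
        for a, b in zip(r1.datasets, r2.datasets):
            assert a.rows["qol"].equals(b.rows["qol"])  # bit-identical replay
        r1.check_against(observed_trial)
        obs_mask = observed_trial.rows["qol"].notna()
        for d in r1.datasets:
            assert d.rows.loc[obs_mask, "qol"].equals(observed_trial.rows.loc[obs_mask, "qol"])
            assert d.rows["qol"].notna().all()

    def test_m_floor(self, observed_trial):
        with pytest.raises(ValueError, match="M >= 2"):
            pi.fit_imputation_model(observed_trial, "model3", "lmm_normal").impute(m=1)

    def test_no_rows_added_ever(self, observed_trial):
        # the structural "never impute after death" guarantee
        res = pi.multiply_impute(observed_trial, "naive", "naive_lmm", m=2, seed=8)
        for d in res.datasets:
            assert len(d.rows) == len(observed_trial.rows)
            assert d.rows[["patient_id", "cycle"]].equals(
                observed_trial.rows[["patient_id", "cycle"]]
            )
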