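"""While-alive means, Rubin pooling, Kaplan-Meier and estimand transforms."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from hypothesis import given
from hypothesis import strategies as st
from lifelines import KaplanMeierFitter
from statsmodels.genmod.cov_struct import Independence

import proimpute as pi


def _tiny_completed():
    pats = [pi.PatientRecord(i, 0, 5.0, 0, 5.0, 1, 5.0) for i in (1, 2, 3)]
    data = pi.build_long_format(pats, pi.Schedule((1, 2)))
    data.rows["qol"] = [50.0, 50.0, 60.0, 60.0, 70.0, 70.0][: len(data.rows)]
    data.rows["r_obs"] = 1
    return data


class TestWhileAliveMeans:
    def test_mean_and_sandwich_se_closed_form(self):
        data = _tiny_completed()
        cm = pi.while_alive_means(data)
        row = cm.table[cm.table["cycle"] == 1].iloc[0]
        assert row["estimate"] == 60.0
        # per-cycle sandwich: sqrt(sum r^2)/n = sqrt(100+0+100)/3
        np.testing.assert_allclose(row["se"], np.sqrt(200.0) / 3.0)

    def test_weighted_mean(self):
        data = _tiny_completed()
        w = np.array([1.0, 1, 1, 1, 2.0, 2])
        cm = pi.while_alive_means(data, weights=w)
        assert cm.table[cm.table["cycle"] == 1]["estimate"].iloc[0] == 62.5

    def test_equals_independence_gee(self, complete_trial):
        """Independence GEE with categorical cycle = per-cycle sample means."""
        cm = pi.while_alive_means(complete_trial)
        df = complete_trial.rows
        gee = smf.gee("qol ~ C(cycle) - 1", groups="patient_id", data=df,
                      cov_struct=Independence()).fit()
        order = [int(name.split("[")[1].rstrip("]").lstrip("T.")) for name in gee.params.index]
        got = pd.Series(gee.params.values, index=order).sort_index()
        want = cm.table.set_index("cycle")["estimate"]
        np.testing.assert_allclose(got.values, want.values, atol=1e-10)
        got_se = pd.Series(gee.bse.values, index=order).sort_index()
        np.testing.assert_allclose(got_se.values, cm.table.set_index("cycle")["se"].values, atol=1e-8)

    def test_missing_outcomes_require_weights(self, observed_trial):
        with pytest.raises(ValueError, match="missing outcomes"):
            pi.while_alive_means(observed_trial)


class TestRubinPooling:
    def test_closed_form_toy(self):
        cms = [
            pi.CycleMeans(pd.DataFrame({"cycle": [1], "estimate": [e], "se": [2.0],
                                        "n_alive": [10], "n_used": [10]}))
            for e in (60.0, 62.0, 64.0)
        ]
        pooled = pi.pool_rubin(cms).table.iloc[0]
        assert pooled["estimate"] == 62.0
        assert pooled["within_var"] == 4.0
        assert pooled["between_var"] == 4.0
        np.testing.assert_allclose(pooled["total_var"], 28.0 / 3.0)
        np.testing.assert_allclose(pooled["se"], np.sqrt(28.0 / 3.0))

    def test_identical_imputations_collapse_to_normal_ci(self):
        cms = [
            pi.CycleMeans(pd.DataFrame({"cycle": [1], "estimate": [60.0], "se": [2.0],
                                        "n_alive": [10], "n_used": [10]}))
            for _ in range(3)
        ]
        row = pi.pool_rubin(cms).table.iloc[0]
        assert row["between_var"] == 0.0 and np.isinf(row["df"])
        np.testing.assert_allclose(row["ci_low"], 60.0 - 1.959963984540054 * 2.0)

    def test_mismatched_grids_rejected(self):
        a = pi.CycleMeans(pd.DataFrame({"cycle": [1], "estimate": [60.0], "se": [1.0],
                                        "n_alive": [5], "n_used": [5]}))
        b = pi.CycleMeans(pd.DataFrame({"cycle": [2], "estimate": [60.0], "se": [1.0],
                                        "n_alive": [5], "n_used": [5]}))
        with pytest.raises(ValueError, match="mismatched cycle grids"):
            pi.pool_rubin([a, b])

    @given(
        ests=st.lists(st.floats(-100, 100), min_size=2, max_size=8),
        ses=st.lists(st.floats(0.01, 50), min_size=8, max_size=8),
    )
    def test_total_variance_dominates_within(self, ests, ses):
        cms = [
            pi.CycleMeans(pd.DataFrame({"cycle": [1], "estimate": [e], "se": [s],
                                        "n_alive": [5], "n_used": [5]}))
            for e, s in zip(ests, ses)
        ]
        row = pi.pool_rubin(cms).table.iloc[0]
        assert row["total_var"] >= row["within_var"] - 1e-12
        assert row["between_var"] >= 0
        assert row["ci_low"] <= row["estimate"] <= row["ci_high"]


class TestKaplanMeier:
    def test_hand_product_limit(self):
        pats = pd.DataFrame({"surv_time": [2, 3, 4, 5], "death_ind": [1, 0, 1, 0]})
        surv = pi.km_survival(pats, cycle_grid=(1, 2, 3, 4, 5)).table.set_index("cycle")
        assert surv.loc[1, "survival"] == 1.0
        np.testing.assert_allclose(surv.loc[2, "survival"], 0.75)
        np.testing.assert_allclose(surv.loc[4, "survival"], 0.375)
        # Greenwood at t=2: S^2 * d/(n(n-d)) = 0.75^2 * 1/(4*3)
        np.testing.assert_allclose(surv.loc[2, "se"], np.sqrt(0.75**2 / 12.0))

    def test_no_events_flat_curve(self):
        pats = pd.DataFrame({"surv_time": [5, 6, 7], "death_ind": [0, 0, 0]})
        surv = pi.km_survival(pats, cycle_grid=(1, 3, 5)).table
        assert (surv["survival"] == 1.0).all() and (surv["se"] == 0.0).all()

    def test_agrees_with_lifelines(self, complete_trial):
        pats = complete_trial.patients
        grid = complete_trial.schedule.cycles
        mine = pi.km_survival(pats, grid).table.set_index("cycle")["survival"]
        kmf = KaplanMeierFitter().fit(pats["surv_time"], pats["death_ind"])
        theirs = kmf.survival_function_at_times(list(grid)).to_numpy()
        np.testing.assert_allclose(mine.to_numpy(), theirs, atol=1e-8)


class TestEstimandTransforms:
    def test_composite_adds_zero_rows_after_death(self):
        pats = [pi.PatientRecord(1, 1, 3.0, 0, 3.0, 1, 3.0)]
        data = pi.build_long_format(pats, pi.Schedule((1, 2, 3, 4, 5)))
        data.rows["qol"], data.rows["r_obs"] = 55.0, 1
        out = pi.composite_transform(data, horizon=5)
        added = out.rows[out.rows["cycle"] > 3]
        assert list(added["cycle"]) == [4, 5]
        assert (added["qol"] == 0.0).all()

    def test_composite_noop_without_deaths(self):
        data = _tiny_completed()
        out = pi.composite_transform(data)
        assert out.rows.equals(data.rows)

    def test_composite_horizon_validation(self, complete_trial):
        with pytest.raises(ValueError, match="horizon"):
            pi.composite_transform(complete_trial, horizon=5)

    def test_composite_mean_below_while_alive_mean(self, complete_trial):
        comp = pi.composite_transform(complete_trial)
        wa = pi.while_alive_means(complete_trial).table.set_index("cycle")["estimate"]
        cm = comp.rows.groupby("cycle")["qol"].mean()
        assert (cm <= wa + 1e-9).all()
        # brute-force identity: composite mean = while-alive mean * share alive
        n_tot = comp.rows.groupby("cycle").size()
        n_alive = complete_trial.rows.groupby("cycle").size()
        np.testing.assert_allclose(cm, wa * n_alive / n_tot)

    def test_while_on_treatment_subset(self, toy_patients):
        data = pi.build_long_format(toy_patients, pi.Schedule(tuple(range(1, 21))))
        out = pi.while_on_treatment_subset(data)
        td = data.patients.set_index("patient_id")["td_time"]
        expected = sum(
            len([j for j in data.schedule.cycles if j <= min(td[p.patient_id], p.surv_time)])
            for p in toy_patients
        )
        assert len(out.rows) == expected
        a_rows = out.rows[out.rows["patient_id"] == "a"]
        assert list(a_rows["cycle"]) == [1, 2, 3, 4, 5, 6]  # TD at cycle 6

    def test_while_on_treatment_keeps_all_when_td_late(self):
        pats = [pi.PatientRecord(1, 0, 5.0, 0, 5.0, 1, 5.0)]
        data = pi.build_long_format(pats, pi.Schedule((1, 2, 3)))
        assert len(pi.while_on_treatment_subset(data).rows) == 3

    def test_dichotomize(self):
        data = _tiny_completed()
        out = pi.dichotomize(data, threshold=60.0)
        assert set(out.rows["qol"]) <= {0.0, 1.0}
        assert out.rows.loc[data.rows["qol"] >= 60, "qol"].eq(1.0).all()
        all_ones = pi.dichotomize(data, threshold=0.0)
        assert (all_ones.rows["qol"] == 1.0).all()

    def test_pooled_proportion_is_mean_of_proportions(self, observed_trial):
        res = pi.multiply_impute(observed_trial, "naive", "naive_lmm", m=3, seed=3)
        per = [pi.while_alive_means(pi.dichotomize(d, 60.0)) for d in res.datasets]
        pooled = pi.pool_rubin(per).table
        manual = np.mean([cm.table["estimate"].to_numpy() for cm in per], axis=0)
        np.testing.assert_allclose(pooled["estimate"].to_numpy(), manual)


class TestEstimandResult:
    def test_while_alive_requires_survival_curve(self):
        cm = pi.while_alive_means(_tiny_completed())
        with pytest.raises(ValueError, match="survival"):
            pi.EstimandResult(estimand="while_alive", cycle_means=cm, survival=None)

    def test_summary_renders(self, complete_trial):
        cm = pi.while_alive_means(complete_trial)
        surv = pi.km_survival(complete_trial.patients, complete_trial.schedule)
        res = pi.EstimandResult("while_alive", cm, surv, {"engine": "none"})
        text = res.summary()
        assert "while_alive" in text and "km_surv" in res.table().columns
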