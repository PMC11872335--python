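"""Replicate simulation studies: parameter recovery, bias ordering, IPW behaviour.

These are the package's own validation experiments, run on the bundled
synthetic-trial generator.  They are used by the test suite and by the
acceptance script; trial sizes (500 patients, cycles 1-20, 25 replicates,
M = 15 imputations) are chosen so the whole study runs in a few minutes on
one CPU while leaving Monte-Carlo error well below the effects being
measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .encoding import Schedule
from .estimands import pool_rubin, while_alive_means
from .impute import ImputationModel
from .ipw import MissingnessModel, ipw_gee_estimate
from .simulate import MissingnessConfig, SimConfig, apply_missingness, simulate_trial, true_while_alive_mean

__all__ = ["StudyConfig", "ReplicateStudy", "run_replicate_study", "run_ipw_instability_study"]

RECOVERY_SCHEDULE = Schedule(tuple(range(1, 11)) + (12, 14, 16, 18, 20))


@dataclass(frozen=True)
class StudyConfig:
    """Settings of one replicate study."""

    n_replicates: int = 25
    n_patients: int = 500
    m: int = 15
    mechanism: str = "MAR_ICE"
    schedule: Schedule = field(default_factory=lambda: RECOVERY_SCHEDULE)
    seed: int = 2026
    with_ipw: bool = True
    min_survivors: int = 30

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_patients=self.n_patients,
            schedule=self.schedule,
            missingness=MissingnessConfig(mechanism=self.mechanism),
            admin_censor_time=float(self.schedule.max_cycle) + 2.0,
        )


@dataclass
class ReplicateStudy:
    """Stacked per-replicate, per-cycle estimates plus the truth curve."""

    config: StudyConfig
    truth: pd.DataFrame          # cycle, truth, mc_se, n_alive
    estimates: pd.DataFrame      # replicate, cycle, method, estimate, se, ci_low, ci_high, n_alive

    # -- summaries ---------------------------------------------------------
    def mean_curve(self, method: str) -> pd.DataFrame:
        e = self.estimates[self.estimates["method"] == method]
        g = e.groupby("cycle")["estimate"].agg(["mean", "std", "count"]).reset_index()
        g["mc_se"] = g["std"] / np.sqrt(g["count"])
        return g.merge(self.truth[["cycle", "truth"]], on="cycle")

    def bias(self, method: str, reliable_only: bool = True) -> pd.DataFrame:
        """Replicate-averaged bias per cycle (optionally only well-populated cycles)."""
        g = self.mean_curve(method)
        g["bias"] = g["mean"] - g["truth"]
        if reliable_only:
            g = g[self._reliable_cycles(g["cycle"])]
        return g[["cycle", "bias", "mc_se"]].reset_index(drop=True)

    def _reliable_cycles(self, cycles: pd.Series) -> np.ndarray:
        e = self.estimates
        n_alive = e.groupby("cycle")["n_alive"].mean()
        ok = n_alive[n_alive >= self.config.min_survivors].index
        return cycles.isin(ok).to_numpy()

    def max_abs_bias(self, method: str) -> float:
        return float(self.bias(method)["bias"].abs().max())

    def ci_coverage(self, method: str) -> float:
        """Fraction of (replicate, reliable cycle) CIs containing the truth."""
        e = self.estimates[self.estimates["method"] == method].merge(
            self.truth[["cycle", "truth"]], on="cycle"
        )
        e = e[self._reliable_cycles(e["cycle"])]
        hit = (e["ci_low"] <= e["truth"]) & (e["truth"] <= e["ci_high"])
        return float(hit.mean())

    def paired_difference(self, method_a: str, method_b: str, cycles=None) -> pd.DataFrame:
        """Replicate-paired difference a - b per cycle, with its MC standard error."""
        a = self.estimates[self.estimates["method"] == method_a]
        b = self.estimates[self.estimates["method"] == method_b]
        m = a.merge(b, on=["replicate", "cycle"], suffixes=("_a", "_b"))
        if cycles is not None:
            m = m[m["cycle"].isin(list(cycles))]
        m["diff"] = m["estimate_a"] - m["estimate_b"]
        g = m.groupby("cycle")["diff"].agg(["mean", "std", "count"]).reset_index()
        g["mc_se"] = g["std"] / np.sqrt(g["count"])
        return g

    def late_cycles(self, k: int = 3) -> list[int]:
        cyc = sorted(self.truth["cycle"].unique())
        return cyc[-k:]

    def empirical_se(self, method: str) -> pd.DataFrame:
        e = self.estimates[self.estimates["method"] == method]
        return e.groupby("cycle")["estimate"].std().reset_index(name="emp_se")


def _pooled_rows(study_rep: int, pooled, method: str) -> pd.DataFrame:
    t = pooled.table
    return pd.DataFrame(
        {
            "replicate": study_rep, "cycle": t["cycle"], "method": method,
            "estimate": t["estimate"], "se": t["se"],
            "ci_low": t["ci_low"], "ci_high": t["ci_high"], "n_alive": t["n_alive"],
        }
    )


def _cycle_rows(study_rep: int, cm, method: str) -> pd.DataFrame:
    t = cm.table
    z = 1.959963984540054
    return pd.DataFrame(
        {
            "replicate": study_rep, "cycle": t["cycle"], "method": method,
            "estimate": t["estimate"], "se": t["se"],
            "ci_low": t["estimate"] - z * t["se"], "ci_high": t["estimate"] + z * t["se"],
            "n_alive": t["n_alive"],
        }
    )


def run_replicate_study(config: StudyConfig | None = None, seed: int | None = None) -> ReplicateStudy:
    """Simulate -> impute (ICE-aware and naive) -> estimate, over replicates.

    Methods recorded per replicate: ``available_case``, ``model3`` (pooled
    ICE-aware mixed-model MI), ``naive`` (pooled ICE-free mixed-model MI)
    and, when ``config.with_ipw``, ``ipw`` (stabilised/truncated weights).
    """
    config = config or StudyConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    base = config.sim_config()
    truth = true_while_alive_mean(base, n_large=30000, seed=config.seed + 900001)
    frames = []
    for rep in range(config.n_replicates):
        rep_seed = config.seed + 1000 * (rep + 1)
        complete = simulate_trial(base, seed=rep_seed)
        observed = apply_missingness(complete, base.missingness, seed=rep_seed + 1)

        frames.append(_cycle_rows(rep, while_alive_means_available(observed), "available_case"))

        for method, engine, spec in (("model3", "lmm_normal", "model3"),
                                     ("naive", "naive_lmm", "naive")):
            fitted = ImputationModel(observed, spec=spec, engine=engine).fit()
            imp = fitted.impute(m=config.m, seed=rep_seed + 7)
            pooled = pool_rubin([while_alive_means(d) for d in imp.datasets])
            frames.append(_pooled_rows(rep, pooled, method))

        if config.with_ipw:
            w = MissingnessModel(observed, "model3").fit().weight_set()
            res = ipw_gee_estimate(observed, w)
            frames.append(_cycle_rows(rep, res.cycle_means, "ipw"))
    estimates = pd.concat(frames, ignore_index=True)
    return ReplicateStudy(config=config, truth=truth, estimates=estimates)


def while_alive_means_available(observed):
    """Available-case per-cycle means: unit weights on the observed rows."""
    return while_alive_means(observed, weights=np.ones(observed.n_rows))


def run_ipw_instability_study(n_replicates: int = 12, n_patients: int = 400,
                              seed: int = 515, m: int = 5) -> dict:
    """Push late-cycle observation probabilities below 0.1 and compare spread.

    Early progression and discontinuation plus a strong post-TD missingness
    effect leave almost no observed rows at late cycles; the replicate
    spread (empirical SE) of the IPW estimator is compared with the pooled
    MI estimator at those cycles and at well-observed early cycles.
    """
    schedule = Schedule(tuple(range(1, 13)))
    sim = SimConfig(
        n_patients=n_patients,
        schedule=schedule,
        pd_rate=0.30,
        td_lag_mean=1.0,
        admin_censor_time=float(schedule.max_cycle) + 2.0,
        missingness=MissingnessConfig(mechanism="MAR_ICE", base_logit=-1.5, coef_post_td=6.0),
    )
    ipw_est, mi_est, obs_frac = [], [], []
    for rep in range(n_replicates):
        rep_seed = seed + 1000 * (rep + 1)
        complete = simulate_trial(sim, seed=rep_seed)
        observed = apply_missingness(complete, sim.missingness, seed=rep_seed + 1)
        obs_frac.append(observed.rows.groupby("cycle")["r_obs"].mean())
        w = MissingnessModel(observed, "model3").fit().weight_set()
        ipw_est.append(ipw_gee_estimate(observed, w).cycle_means.table.set_index("cycle")["estimate"])
        fitted = ImputationModel(observed, spec="model3", engine="lmm_normal").fit()
        imp = fitted.impute(m=m, seed=rep_seed + 7)
        pooled = pool_rubin([while_alive_means(d) for d in imp.datasets])
        mi_est.append(pooled.table.set_index("cycle")["estimate"])
    obs_frac = pd.concat(obs_frac, axis=1).mean(axis=1)
    ipw_sd = pd.concat(ipw_est, axis=1).std(axis=1)
    mi_sd = pd.concat(mi_est, axis=1).std(axis=1)
    low = obs_frac[obs_frac < 0.1].index
    early = obs_frac[obs_frac > 0.5].index
    return {
        "observation_fraction": obs_frac,
        "ipw_empirical_se": ipw_sd,
        "mi_empirical_se": mi_sd,
        "low_prob_cycles": list(low),
        "early_cycles": list(early),
        "ipw_mi_se_ratio_low": float((ipw_sd[low] / mi_sd[low]).mean()) if len(low) else np.nan,
    }
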