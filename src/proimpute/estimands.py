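"""Estimand-aligned summaries of completed or weighted trial data.

The primary estimand is *while-alive*: the mean PRO at each scheduled
cycle among the patients still alive at that cycle, reported together with
the Kaplan-Meier survival probability up to that cycle.  Because visit
rows exist exactly for the cycles a patient is alive, an independence GEE
with cycle as a categorical covariate reduces to per-cycle (weighted)
sample means with a patient-clustered sandwich variance — which is how
:func:`while_alive_means` computes it, in closed form.

Per-imputation cycle means are combined with Rubin's rules
(:func:`pool_rubin`): total variance = within + (1 + 1/M) x between, with
the classical large-sample degrees of freedom.

Alternative estimands are supported as dataset transforms applied to each
completed copy before summarising: a composite endpoint that carries the
value 0 after death (:func:`composite_transform`), a while-on-treatment
restriction (:func:`while_on_treatment_subset`), and responder
dichotomisation (:func:`dichotomize`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import LongTrialData, Schedule

__all__ = [
    "CycleMeans",
    "PooledEstimate",
    "SurvivalCurve",
    "EstimandResult",
    "while_alive_means",
    "pool_rubin",
    "km_survival",
    "composite_transform",
    "while_on_treatment_subset",
    "dichotomize",
]


@dataclass
class CycleMeans:
    """Per-cycle estimates: mean, cluster-robust SE, counts."""

    table: pd.DataFrame  # columns: cycle, estimate, se, n_alive, n_used

    def __post_init__(self) -> None:
        need = {"cycle", "estimate", "se", "n_alive", "n_used"}
        if not need <= set(self.table.columns):
            raise ValueError(f"CycleMeans table must have columns {sorted(need)}")

    @property
    def cycles(self) -> np.ndarray:
        return self.table["cycle"].to_numpy()


@dataclass
class PooledEstimate:
    """Rubin-pooled per-cycle estimates with 95% CI."""

    table: pd.DataFrame  # cycle, estimate, within_var, between_var, total_var, se, df, ci_low, ci_high
    m: int = 0


@dataclass
class SurvivalCurve:
    """Kaplan-Meier survival at scheduled cycles with Greenwood SE."""

    table: pd.DataFrame  # cycle, survival, se, n_risk


@dataclass
class EstimandResult:
    """A labelled estimand summary plus provenance.

    While-alive results always carry the companion survival curve; the
    summary among the living is interpretable only next to the probability
    of being alive to report it.
    """

    estimand: str
    cycle_means: CycleMeans | PooledEstimate
    survival: SurvivalCurve | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.estimand == "while_alive" and self.survival is None:
            raise ValueError("a while-alive result must carry its survival curve")

    def table(self) -> pd.DataFrame:
        t = self.cycle_means.table.copy()
        if self.survival is not None:
            t = t.merge(
                self.survival.table.rename(columns={"se": "km_se", "survival": "km_surv"}),
                on="cycle", how="left",
            )
        return t

    def summary(self) -> str:
        t = self.table()
        lines = [f"Estimand: {self.estimand}"]
        if self.provenance:
            lines.append("provenance: " + ", ".join(f"{k}={v}" for k, v in self.provenance.items()))
        with pd.option_context("display.width", 120, "display.max_rows", 200):
            lines.append(t.round(4).to_string(index=False))
        return "\n".join(lines)


def while_alive_means(data: LongTrialData, weights: np.ndarray | pd.Series | None = None,
                      response: str = "qol") -> CycleMeans:
    """Per-cycle (weighted) mean among the alive, with sandwich SE.

    With complete data and no weights this equals the arithmetic per-cycle
    sample mean; the standard error is the independence-GEE cluster-robust
    (patient-clustered) sandwich, which for one row per patient per cycle
    is ``sqrt(sum w^2 r^2) / sum w``.  When ``weights`` are supplied only
    observed rows are used (inverse-probability weighting); otherwise the
    data must be complete.
    """
    rows = data.rows
    y = rows[response].to_numpy(dtype=float)
    if weights is None:
        if np.isnan(y).any():
            raise ValueError("data contain missing outcomes; impute first or supply weights")
        w = np.ones(len(rows))
        used = np.ones(len(rows), dtype=bool)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(rows),):
            raise ValueError("weights must align with data rows")
        used = ~np.isnan(y)
        if np.any(w[used] <= 0):
            raise ValueError("weights must be positive on observed rows")
    recs = []
    for cycle, idx in rows.groupby("cycle").indices.items():
        idx = np.asarray(idx)
        n_alive = idx.size
        sel = idx[used[idx]]
        if sel.size == 0:
            recs.append((cycle, np.nan, np.nan, n_alive, 0))
            continue
        wj, yj = w[sel], y[sel]
        sw = wj.sum()
        est = float(np.sum(wj * yj) / sw)
        r = yj - est
        se = float(np.sqrt(np.sum((wj * r) ** 2)) / sw)
        recs.append((cycle, est, se, n_alive, sel.size))
    table = pd.DataFrame(recs, columns=["cycle", "estimate", "se", "n_alive", "n_used"])
    return CycleMeans(table.sort_values("cycle").reset_index(drop=True))


def pool_rubin(per_imputation: list[CycleMeans], ci_level: float = 0.95) -> PooledEstimate:
    """Combine M per-imputation cycle means with Rubin's rules.

    Per cycle: Qbar = mean of estimates, W = mean within-imputation
    variance, B = between-imputation variance (ddof=1),
    T = W + (1 + 1/M) B, SE = sqrt(T), large-sample
    df = (M - 1) (1 + W / ((1 + 1/M) B))^2; when B = 0 a normal interval
    is used (df = inf).
    """
    m = len(per_imputation)
    if m < 2:
        raise ValueError("Rubin pooling needs M >= 2")
    grids = [tuple(cm.cycles) for cm in per_imputation]
    if len(set(grids)) != 1:
        raise ValueError("per-imputation results have mismatched cycle grids")
    est = np.vstack([cm.table["estimate"].to_numpy() for cm in per_imputation])
    var = np.vstack([cm.table["se"].to_numpy() ** 2 for cm in per_imputation])
    qbar = est.mean(axis=0)
    w = var.mean(axis=0)
    b = est.var(axis=0, ddof=1)
    t = w + (1.0 + 1.0 / m) * b
    se = np.sqrt(t)
    with np.errstate(divide="ignore"):
        df = np.where(b > 0, (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * np.where(b > 0, b, 1.0))) ** 2, np.inf)
    alpha = 1.0 - ci_level
    crit = np.where(np.isfinite(df), stats.t.ppf(1 - alpha / 2, np.clip(df, 1e-6, None)),
                    stats.norm.ppf(1 - alpha / 2))
    table = pd.DataFrame(
        {
            "cycle": per_imputation[0].cycles,
            "estimate": qbar,
            "within_var": w,
            "between_var": b,
            "total_var": t,
            "se": se,
            "df": df,
            "ci_low": qbar - crit * se,
            "ci_high": qbar + crit * se,
            "n_alive": per_imputation[0].table["n_alive"].to_numpy(),
        }
    )
    return PooledEstimate(table, m=m)


def km_survival(patients: pd.DataFrame, cycle_grid=None) -> SurvivalCurve:
    """Kaplan-Meier product-limit survival evaluated at scheduled cycles.

    ``patients`` needs columns ``surv_time`` and ``death_ind``.  Greenwood's
    formula gives the variance: ``S(t)^2 * sum d / (n (n - d))`` over event
    times up to ``t``.  Ties between deaths and censorings at the same time
    are resolved deaths-first (the standard convention).
    """
    time = patients["surv_time"].to_numpy(dtype=float)
    event = patients["death_ind"].to_numpy(dtype=int)
    if cycle_grid is None:
        cycle_grid = Schedule().cycles
    elif isinstance(cycle_grid, Schedule):
        cycle_grid = cycle_grid.cycles
    grid = np.asarray(list(cycle_grid), dtype=float)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    n = len(time)
    s_cur, gw_sum = 1.0, 0.0
    # unique death times with counts; at-risk just before each death time
    death_times = np.unique(time[event == 1])
    at_risk = n - np.searchsorted(time, death_times, side="left")
    deaths = np.array([np.sum((time == t) & (event == 1)) for t in death_times])
    steps_s = []
    for t, r, d in zip(death_times, at_risk, deaths):
        s_cur *= (r - d) / r
        if r - d > 0:
            gw_sum += d / (r * (r - d))
            steps_s.append((t, s_cur, s_cur**2 * gw_sum))
        else:
            steps_s.append((t, 0.0, 0.0))
    if steps_s:
        step_t = np.array([s[0] for s in steps_s])
        step_v = np.array([s[1] for s in steps_s])
        step_var = np.array([s[2] for s in steps_s])
        pos = np.searchsorted(step_t, grid, side="right") - 1
        s_grid = np.where(pos >= 0, step_v[np.maximum(pos, 0)], 1.0)
        var_grid = np.where(pos >= 0, step_var[np.maximum(pos, 0)], 0.0)
    else:
        s_grid = np.ones_like(grid)
        var_grid = np.zeros_like(grid)
    n_risk = np.array([np.sum(time >= g) for g in grid])
    table = pd.DataFrame(
        {"cycle": grid.astype(int) if np.allclose(grid, np.round(grid)) else grid,
         "survival": s_grid, "se": np.sqrt(var_grid), "n_risk": n_risk}
    )
    return SurvivalCurve(table)


def composite_transform(completed: LongTrialData, horizon: int | None = None) -> LongTrialData:
    """Composite endpoint for death: carry the value 0 after death.

    Extends each deceased patient's rows with outcome 0 at every scheduled
    cycle after death up to ``horizon`` (default: last scheduled cycle).
    Alive/censored patients are unchanged, so downstream per-cycle means
    run over all patients known to be in follow-up, not only the living.
    """
    sched = completed.schedule
    if horizon is None:
        horizon = sched.max_cycle
    if horizon < sched.max_cycle:
        raise ValueError(
            f"horizon {horizon} is before the last scheduled cycle {sched.max_cycle}"
        )
    if completed.rows["qol"].isna().any():
        raise ValueError("composite transform expects completed data")
    out = completed.copy()
    extra = []
    dead = out.patients[out.patients["death_ind"] == 1]
    for rec in dead.itertuples(index=False):
        for j in sched.cycles:
            if rec.surv_time < j <= horizon:
                extra.append(
                    {
                        "patient_id": rec.patient_id, "cycle": j, "qol": 0.0, "r_obs": 1,
                        "s": 0.0, "t_pd": completed.caps["pd"], "t_td": completed.caps["td"],
                        "e_pd_now": int(rec.pd_ind), "e_td_now": int(rec.td_ind),
                    }
                )
    if extra:
        out.rows = pd.concat([out.rows, pd.DataFrame(extra)], ignore_index=True)
        out.rows = out.rows.sort_values(["patient_id", "cycle"], kind="stable").reset_index(drop=True)
    return out


def while_on_treatment_subset(completed: LongTrialData) -> LongTrialData:
    """Keep only rows at or before each patient's treatment discontinuation."""
    out = completed.copy()
    td = out.patients.set_index("patient_id")["td_time"]
    keep = out.rows["cycle"].to_numpy() <= td.reindex(out.rows["patient_id"]).to_numpy()
    out.rows = out.rows[keep].reset_index(drop=True)
    return out


def dichotomize(completed: LongTrialData, threshold: float) -> LongTrialData:
    """Responder transform: outcome 1 iff the score is >= ``threshold``.

    Apply per completed copy, then pool the per-cycle proportions with
    Rubin's rules as usual.
    """
    if completed.rows["qol"].isna().any():
        raise ValueError("dichotomize expects completed data")
    out = completed.copy()
    out.rows["qol"] = (out.rows["qol"].to_numpy(dtype=float) >= threshold).astype(float)
    return out
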