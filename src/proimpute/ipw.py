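"""Inverse-probability-of-missingness weighting for while-alive means.

Instead of filling in missing scores, the observed rows are reweighted by
the inverse of their estimated probability of being observed, and the same
independence GEE is run on the incomplete data.  The observation model is
a flexible logistic regression of the observedness flag on the same
covariate vocabulary as the imputation models — splines of cycle and of
the ICE timescales, event indicators and baseline covariates — but never
the outcome itself.  Weights are stabilised by the marginal per-cycle
observation fraction (so they average ~1) and truncated at configurable
percentiles to tame the tail.

Death is handled structurally, not by weighting: the model is fitted on
alive rows only (rows after death do not exist), so the weighted means
remain while-alive summaries.  When cycle-specific observation
probabilities approach zero, a handful of rows carry enormous weights and
the estimates become unstable — multiple imputation is the robust
alternative in that regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import DesignBuilder, ModelSpec, default_model_spec
from .encoding import LongTrialData
from .estimands import CycleMeans, EstimandResult, km_survival, while_alive_means

__all__ = [
    "WeightModelSpec",
    "WeightSet",
    "MissingnessModel",
    "default_weight_spec",
    "fit_missingness_model",
    "stabilize_truncate",
    "ipw_gee_estimate",
]


def default_weight_spec(variant: str = "model3") -> ModelSpec:
    """Observation model terms: the fixed part of an imputation variant."""
    spec = default_model_spec(variant)
    return replace(spec, response="r_obs", random_intercept=False,
                   name=f"weights[{variant}]")


@dataclass(frozen=True)
class WeightModelSpec:
    """Thin wrapper asserting a valid missingness-model specification."""

    spec: ModelSpec

    def __post_init__(self) -> None:
        if self.spec.response != "r_obs":
            raise ValueError("weight model response must be the observedness flag 'r_obs'")
        if any(t.var == "qol" or t.by == "qol" for t in self.spec.terms):
            raise ValueError("the outcome may not predict its own missingness weights")
        if self.spec.random_intercept:
            raise ValueError("weight models are marginal: no random effects")


@dataclass
class WeightSet:
    """Per-row observation probabilities and stabilized/truncated weights."""

    p_obs: np.ndarray
    weights: np.ndarray
    truncation_bounds: tuple[float, float]
    truncated: np.ndarray
    spec_name: str = ""
    absolute_bounds: tuple[float, float] | None = None

    def observed_weights(self, data: LongTrialData) -> np.ndarray:
        return self.weights[data.rows["r_obs"].to_numpy() == 1]


class MissingnessModel:
    """Logistic observation model for planned-but-possibly-missed PROs."""

    def __init__(self, data: LongTrialData, spec: ModelSpec | WeightModelSpec | str = "model3"):
        if isinstance(spec, str):
            spec = default_weight_spec(spec)
        if isinstance(spec, ModelSpec):
            spec = WeightModelSpec(spec)
        self.data = data
        self.spec = spec.spec

    def fit(self) -> "MissingnessModelResults":
        frame = self.data.frame()
        r = frame["r_obs"].to_numpy(dtype=float)
        if r.min() == r.max():
            raise ValueError(
                "degenerate observation model: all rows are "
                + ("observed" if r.min() == 1 else "missing")
                + "; weighting is unnecessary/impossible"
            )
        builder = DesignBuilder(self.spec).fit(frame)
        X = builder.transform(frame)
        try:
            res = sm.GLM(r, X, family=sm.families.Binomial()).fit()
        except Exception as err:  # includes perfect separation
            raise RuntimeError(
                "observation model failed to fit (possibly complete separation); "
                f"consider simplifying the weight model terms: {err}"
            ) from err
        p = np.asarray(res.predict(X), dtype=float)
        if np.any(p <= 0) or np.any(p >= 1):
            p = np.clip(p, 1e-12, 1 - 1e-12)
        return MissingnessModelResults(self, builder, res, p)


@dataclass
class MissingnessModelResults:
    model: MissingnessModel
    builder: DesignBuilder
    glm_results: object
    p_obs: np.ndarray

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self.glm_results.params)

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self.glm_results.bse)

    def weight_set(self, bounds: tuple[float, float] = (0.01, 0.99)) -> WeightSet:
        return stabilize_truncate(self.model.data, self.p_obs, bounds=bounds,
                                  spec_name=self.model.spec.name)

    def summary(self) -> str:
        lines = ["Missingness (observation) model", "=" * 31]
        for name, est, se in zip(self.builder.columns_, self.params, self.bse):
            lines.append(f"  {name:<28s} {est:10.4f}  (se {se:.4f})")
        return "\n".join(lines)


def fit_missingness_model(observed: LongTrialData,
                          spec: ModelSpec | WeightModelSpec | str = "model3") -> np.ndarray:
    """Fitted per-row probability of a planned measurement being observed."""
    return MissingnessModel(observed, spec).fit().p_obs


def stabilize_truncate(data: LongTrialData, p_obs: np.ndarray,
                       bounds: tuple[float, float] = (0.01, 0.99),
                       spec_name: str = "",
                       absolute_bounds: tuple[float, float] | None = None) -> WeightSet:
    """Stabilise by the marginal per-cycle observation fraction, then truncate.

    ``w = p_marginal(cycle) / p_obs``; before truncation the mean weight
    over observed rows is ~1 by construction.  ``bounds`` are percentiles
    of the observed-row weight distribution (set to ``(0, 1)`` to disable);
    ``absolute_bounds``, when given, additionally clip the weights to fixed
    values.
    """
    p_obs = np.asarray(p_obs, dtype=float)
    rows = data.rows
    if p_obs.shape != (len(rows),):
        raise ValueError("p_obs must align with data rows")
    if np.any(p_obs <= 0) or np.any(p_obs >= 1):
        raise ValueError("observation probabilities must lie strictly in (0, 1)")
    marg = rows.groupby("cycle")["r_obs"].mean()
    num = marg.reindex(rows["cycle"]).to_numpy(dtype=float)
    w = num / p_obs
    obs = rows["r_obs"].to_numpy() == 1
    lo, hi = bounds
    if not 0 <= lo < hi <= 1:
        raise ValueError("truncation bounds must satisfy 0 <= low < high <= 1")
    w_lo, w_hi = np.quantile(w[obs], [lo, hi]) if obs.any() else (0.0, np.inf)
    truncated = (w < w_lo) | (w > w_hi)
    w = np.clip(w, w_lo, w_hi)
    if absolute_bounds is not None:
        truncated |= (w < absolute_bounds[0]) | (w > absolute_bounds[1])
        w = np.clip(w, absolute_bounds[0], absolute_bounds[1])
    return WeightSet(p_obs=p_obs, weights=w, truncation_bounds=(float(lo), float(hi)),
                     truncated=truncated, spec_name=spec_name,
                     absolute_bounds=absolute_bounds)


def ipw_gee_estimate(observed: LongTrialData, weights: WeightSet) -> EstimandResult:
    """Weighted while-alive means on the incomplete data (independence GEE).

    With all weights equal to 1 this reduces exactly to the available-case
    per-cycle means.  Cycles with zero observed rows are flagged with NaN
    estimates, never raised.
    """
    cm = while_alive_means(observed, weights=weights.weights)
    surv = km_survival(observed.patients, observed.schedule)
    return EstimandResult(
        estimand="while_alive",
        cycle_means=cm,
        survival=surv,
        provenance={
            "method": "ipw_gee",
            "weight_model": weights.spec_name,
            "truncation": weights.truncation_bounds,
            "n_truncated": int(weights.truncated[observed.rows["r_obs"].to_numpy() == 1].sum()),
        },
    )
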