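"""Multiple imputation of missing PRO scores using ICE-timescale covariates.

Because visit rows exist only while a patient is alive, no value is ever
created after death: imputation fills cells of the existing row set and
never adds rows.  Quality of life is the only incomplete variable, so no
chained-equations iteration is needed — a single conditional model for the
outcome is fitted to the observed rows and missing cells are drawn from
(an approximation of) its predictive distribution.

Engines
-------
``lmm_normal``
    Random-patient-intercept linear mixed model (REML); missing cells are
    drawn as coefficient draw + conditional random-intercept draw +
    residual noise.
``lmm_pmm``
    Same mixed model, but predictive mean matching: each missing cell
    copies the observed value of one of the ``k_donors`` rows whose
    (coefficient-perturbed) linear predictor is closest, so imputed values
    always lie in the observed support.
``boot_gam_normal`` / ``boot_gam_pmm``
    Fixed-effects additive (spline) model refitted on a clustered
    bootstrap of patients for every imputation — the resample accounts for
    the multilevel structure instead of a random effect; draws are normal
    residual draws or PMM against the original observed rows.
``naive_lmm``
    ``lmm_normal`` with the ICE-free specification (random intercept,
    spline of cycle, baseline covariates).  Kept as a benchmark of what is
    lost by ignoring intercurrent events.

Coefficient uncertainty is propagated through draws from the estimated
asymptotic covariance; variance-component uncertainty is not (a known,
documented understatement of between-imputation variance shared by common
approximation tools).  Normal draws are not clipped to the 0-100 scale by
default, since clipping biases means; PMM is the bounded alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .design import DesignBuilder, ModelSpec, default_model_spec
from .encoding import LongTrialData

__all__ = [
    "ENGINES",
    "ImputationModel",
    "ImputationModelResults",
    "ImputationResult",
    "default_m",
    "fit_imputation_model",
    "draw_imputation_lmm_normal",
    "draw_imputation_lmm_pmm",
    "draw_imputation_boot_gam",
    "multiply_impute",
]

ENGINES = ("lmm_normal", "lmm_pmm", "boot_gam_normal", "boot_gam_pmm", "naive_lmm")
_LMM_ENGINES = ("lmm_normal", "lmm_pmm", "naive_lmm")

_DEFAULT_SPEC_FOR_ENGINE = {
    "lmm_normal": "model3",
    "lmm_pmm": "model2",
    "boot_gam_normal": "model45",
    "boot_gam_pmm": "model45",
    "naive_lmm": "naive",
}


def default_m(missing_fraction: float, floor: int = 5) -> int:
    """Default number of imputations: the percentage of missing cells.

    Rule of thumb: as many imputations as the percentage of missing values
    (40.5% missing -> M = 40), never fewer than ``floor``.
    """
    return max(floor, int(round(100.0 * missing_fraction)))


def _mvn_draw(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Multivariate normal draw robust to a numerically singular covariance."""
    cov = np.asarray(cov, dtype=float)
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh((cov + cov.T) / 2.0)
        L = V * np.sqrt(np.clip(w, 0.0, None))
    return np.asarray(mean) + L @ rng.standard_normal(len(mean))


def _pmm_match(eta_mis: np.ndarray, eta_obs: np.ndarray, y_obs: np.ndarray,
               k_donors: int, rng: np.random.Generator) -> np.ndarray:
    """For each missing predictor value, copy one of the k nearest donors."""
    n_obs = eta_obs.size
    if n_obs < k_donors:
        raise ValueError(f"predictive mean matching needs >= {k_donors} observed rows, have {n_obs}")
    out = np.empty(eta_mis.size)
    chunk = 1024
    for start in range(0, eta_mis.size, chunk):
        block = eta_mis[start : start + chunk]
        d = np.abs(block[:, None] - eta_obs[None, :])
        if k_donors >= n_obs:
            nearest = np.tile(np.arange(n_obs), (block.size, 1))
        else:
            nearest = np.argpartition(d, k_donors - 1, axis=1)[:, :k_donors]
        pick = nearest[np.arange(block.size), rng.integers(0, nearest.shape[1], block.size)]
        out[start : start + chunk] = y_obs[pick]
    return out


class ImputationModel:
    """Imputation model bound to an observed (incomplete) trial dataset.

    Parameters
    ----------
    data:
        Observed :class:`~proimpute.encoding.LongTrialData` (missing PRO
        cells allowed, missing rows are structural and never imputed).
    spec:
        A :class:`~proimpute.design.ModelSpec` or the name of a bundled
        variant (``model2``/``model3``/``model45``/``naive``); defaults to
        the engine's canonical companion.
    engine:
        One of :data:`ENGINES`.
    """

    def __init__(self, data: LongTrialData, spec: ModelSpec | str | None = None,
                 engine: str = "lmm_normal", k_donors: int = 5,
                 clip_to_scale: bool = False, condition_threshold: float = 1e8,
                 max_boot_retries: int = 10):
        if engine not in ENGINES:
            raise ValueError(f"unknown engine {engine!r}; expected one of {ENGINES}")
        if spec is None:
            spec = _DEFAULT_SPEC_FOR_ENGINE[engine]
        if isinstance(spec, str):
            spec = default_model_spec(spec)
        if engine == "naive_lmm" and any(
            t.var in ("s", "t_pd", "t_td", "e_pd_now", "e_td_now", "death_ind") for t in spec.terms
        ):
            raise ValueError("naive_lmm is the ICE-free benchmark; its spec must not contain ICE terms")
        self.data = data
        self.spec = spec
        self.engine = engine
        self.k_donors = int(k_donors)
        self.clip_to_scale = bool(clip_to_scale)
        self.condition_threshold = float(condition_threshold)
        self.max_boot_retries = int(max_boot_retries)

    # -----------------------------------------------------------------
    def _build_design(self, spec: ModelSpec, obs: pd.DataFrame):
        builder = DesignBuilder(spec).fit(obs)
        if builder.duplicate_main_columns_:
            pairs = ", ".join(f"{a} == {b}" for a, b in builder.duplicate_main_columns_)
            raise ValueError(f"unresolvable rank deficiency: duplicate main-effect columns ({pairs})")
        return builder

    def _fit_mixed(self, spec: ModelSpec, frame: pd.DataFrame, obs_mask: np.ndarray):
        """REML random-intercept fit with the documented fallback ladder."""
        obs = frame[obs_mask]
        attempts: list[str] = []
        tried: list[ModelSpec] = [spec]
        if any(t.transform == "rcs" for t in spec.terms):
            tried.append(spec.with_spline_kind("bspline"))
        # progressively drop interactions from the last viable spec
        cur = tried[-1]
        while (nxt := cur.drop_interaction()) is not None:
            tried.append(nxt)
            cur = nxt
        last_err: Exception | None = None
        for i, sp in enumerate(tried):
            try:
                builder = self._build_design(sp, obs)
            except ValueError:
                if i == 0:
                    raise
                continue
            if i == 0 and builder.condition_number_ > self.condition_threshold and len(tried) > 1:
                attempts.append(
                    f"condition number {builder.condition_number_:.3g} above threshold; "
                    "switching restricted cubic splines to B-splines"
                )
                continue
            X = builder.transform(obs)
            y = obs[spec.response].to_numpy(dtype=float)
            groups = obs["patient_id"].to_numpy()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    res = MixedLM(y, X, groups=groups).fit(reml=True)
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
                attempts.append(f"{sp.name}: fit failed ({err})")
                continue
            if not res.converged:
                attempts.append(f"{sp.name}: REML did not converge")
                last_err = RuntimeError("REML did not converge")
                continue
            if attempts:
                warnings.warn(
                    "imputation model fallback applied: " + "; ".join(attempts), stacklevel=3
                )
            return sp, builder, res, attempts
        raise RuntimeError(
            f"imputation model could not be fitted: {attempts or last_err}"
        ) from last_err

    def fit(self) -> "ImputationModelResults":
        frame = self.data.frame()
        obs_mask = frame[self.spec.response].notna().to_numpy()
        if not obs_mask.any():
            raise ValueError("no observed outcome values to fit on")

        y_obs_all = frame.loc[obs_mask, self.spec.response].to_numpy(dtype=float)
        if self.engine in _LMM_ENGINES and np.var(y_obs_all) < 1e-12:
            # degenerate but legal: constant outcome, REML has nothing to do
            spec_used = self.spec
            builder = self._build_design(spec_used, frame[obs_mask])
            X = builder.transform(frame[obs_mask])
            params, *_ = np.linalg.lstsq(X, y_obs_all, rcond=None)
            cov = np.zeros((len(params), len(params)))
            sigma2, tau2 = 0.0, 0.0
            obs_pids = frame.loc[obs_mask, "patient_id"].unique()
            blups = pd.Series(0.0, index=obs_pids)
            cond_var = pd.Series(0.0, index=obs_pids)
            attempts, converged = [], True
        elif self.engine in _LMM_ENGINES:
            spec_used, builder, res, attempts = self._fit_mixed(self.spec, frame, obs_mask)
            k = len(res.fe_params)
            params = np.asarray(res.fe_params, dtype=float)
            cov = np.asarray(res.cov_params())[:k, :k]
            sigma2 = float(res.scale)
            tau2 = float(np.asarray(res.cov_re)[0, 0])
            blups = pd.Series(
                {g: float(np.asarray(v)[0]) for g, v in res.random_effects.items()}, dtype=float
            )
            n_obs_per_pat = frame.loc[obs_mask].groupby("patient_id").size()
            cond_var = 1.0 / (1.0 / max(tau2, 1e-12) + n_obs_per_pat / max(sigma2, 1e-12))
            converged = bool(res.converged)
        else:
            spec_used = self.spec
            obs = frame[obs_mask]
            builder = self._build_design(spec_used, obs)
            X = builder.transform(obs)
            y = obs[spec_used.response].to_numpy(dtype=float)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            dof = max(len(y) - X.shape[1], 1)
            params = beta
            cov = np.zeros((len(beta), len(beta)))
            sigma2 = float(resid @ resid / dof)
            tau2 = 0.0
            blups = pd.Series(dtype=float)
            cond_var = pd.Series(dtype=float)
            attempts = []
            converged = True

        X_all = builder.transform(frame)
        diagnostics = {
            "engine": self.engine,
            "spec": spec_used.name,
            "n_rows": int(len(frame)),
            "n_observed": int(obs_mask.sum()),
            "n_missing": int((~obs_mask).sum()),
            "converged": converged,
            "condition_number": builder.condition_number_,
            "dropped_columns": list(builder.dropped_),
            "fallbacks": list(attempts),
            "n_patients_without_observed": int(
                self.data.n_patients - frame.loc[obs_mask, "patient_id"].nunique()
            ),
        }
        return ImputationModelResults(
            model=self, spec=spec_used, builder=builder, params=params, cov_params=cov,
            sigma2=sigma2, tau2=tau2, blups=blups, cond_var=pd.Series(cond_var),
            frame=frame, obs_mask=obs_mask, X_all=X_all, diagnostics=diagnostics,
        )


@dataclass
class ImputationModelResults:
    """Fitted imputation model: estimates, uncertainties and draw methods."""

    model: ImputationModel
    spec: ModelSpec
    builder: DesignBuilder
    params: np.ndarray
    cov_params: np.ndarray
    sigma2: float
    tau2: float
    blups: pd.Series
    cond_var: pd.Series
    frame: pd.DataFrame
    obs_mask: np.ndarray
    X_all: np.ndarray
    diagnostics: dict

    @property
    def engine(self) -> str:
        return self.model.engine

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics["converged"])

    # -- helpers ----------------------------------------------------------
    def _require_converged(self) -> None:
        if not self.converged:
            raise RuntimeError("imputation model did not converge; draws refuse to run")

    def _patient_intercepts(self, rng: np.random.Generator | None) -> pd.Series:
        """Random-intercept value per patient: BLUP (+ uncertainty draw).

        Patients with no observed outcome get a draw from the marginal
        intercept distribution (or its mean 0 when ``rng`` is None).
        """
        pats = self.model.data.patients["patient_id"]
        b = self.blups.reindex(pats)
        v = self.cond_var.reindex(pats)
        marginal = b.isna()
        b = b.fillna(0.0)
        v = v.fillna(self.tau2)
        if rng is not None:
            b = b + rng.normal(0.0, 1.0, len(b)) * np.sqrt(np.clip(v.to_numpy(), 0.0, None))
        return pd.Series(b.to_numpy(), index=pats.to_numpy())

    def _finalize(self, imputed: np.ndarray) -> LongTrialData:
        out = self.model.data.copy()
        qol = out.rows["qol"].to_numpy(dtype=float).copy()
        if self.model.clip_to_scale:
            imputed = np.clip(imputed, 0.0, 100.0)
        qol[~self.obs_mask] = imputed
        out.rows["qol"] = qol
        return out

    # -- draw methods ------------------------------------------------------
    def draw(self, rng: np.random.Generator) -> LongTrialData:
        """One completed dataset (observed cells untouched)."""
        self._require_converged()
        if not (~self.obs_mask).any():
            return self.model.data.copy()
        engine = self.engine
        if engine in ("lmm_normal", "naive_lmm"):
            return self._draw_lmm_normal(rng)
        if engine == "lmm_pmm":
            return self._draw_lmm_pmm(rng)
        if engine == "boot_gam_normal":
            return self._draw_boot_gam(rng, matching="normal")
        if engine == "boot_gam_pmm":
            return self._draw_boot_gam(rng, matching="pmm")
        raise ValueError(f"unknown engine {engine!r}")

    def _draw_lmm_normal(self, rng: np.random.Generator) -> LongTrialData:
        beta = _mvn_draw(rng, self.params, self.cov_params)
        b = self._patient_intercepts(rng)
        mis = ~self.obs_mask
        pid_mis = self.frame.loc[mis, "patient_id"].to_numpy()
        mu = self.X_all[mis] @ beta + b.reindex(pid_mis).to_numpy()
        y = mu + rng.normal(0.0, np.sqrt(max(self.sigma2, 0.0)), mis.sum())
        return self._finalize(y)

    def _draw_lmm_pmm(self, rng: np.random.Generator) -> LongTrialData:
        beta = _mvn_draw(rng, self.params, self.cov_params)
        b = self._patient_intercepts(rng=None)  # BLUP part of the predictor, no extra noise
        eta = self.X_all @ beta + b.reindex(self.frame["patient_id"].to_numpy()).to_numpy()
        mis = ~self.obs_mask
        y_obs = self.frame.loc[self.obs_mask, self.spec.response].to_numpy(dtype=float)
        y = _pmm_match(eta[mis], eta[self.obs_mask], y_obs, self.model.k_donors, rng)
        return self._finalize(y)

    def _draw_boot_gam(self, rng: np.random.Generator, matching: str) -> LongTrialData:
        data = self.model.data
        frame, X_all = self.frame, self.X_all
        pids = data.patients["patient_id"].to_numpy()
        if len(pids) < 2:
            raise ValueError("clustered bootstrap needs at least 2 patients")
        row_idx = frame.groupby("patient_id", sort=False).indices
        obs_idx_set = np.nonzero(self.obs_mask)[0]
        obs_lookup = np.zeros(len(frame), dtype=bool)
        obs_lookup[obs_idx_set] = True
        for attempt in range(self.model.max_boot_retries):
            sampled = rng.choice(pids, size=len(pids), replace=True)
            take = np.concatenate([row_idx.get(p, np.empty(0, dtype=int)) for p in sampled])
            take = take[obs_lookup[take]]
            if take.size > X_all.shape[1]:
                break
        else:
            raise RuntimeError("clustered bootstrap produced all-missing samples 10 times in a row")
        Xb, yb = X_all[take], frame[self.spec.response].to_numpy(dtype=float)[take]
        beta, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
        resid = yb - Xb @ beta
        sigma = float(np.sqrt(resid @ resid / max(len(yb) - Xb.shape[1], 1)))
        mis = ~self.obs_mask
        mu = X_all[mis] @ beta
        if matching == "normal":
            y = mu + rng.normal(0.0, sigma, mis.sum())
        else:
            eta_obs = X_all[self.obs_mask] @ beta
            y_obs = frame.loc[self.obs_mask, self.spec.response].to_numpy(dtype=float)
            y = _pmm_match(mu, eta_obs, y_obs, self.model.k_donors, rng)
        return self._finalize(y)

    # -- multiple imputation ----------------------------------------------
    def impute(self, m: int | None = None, seed: int | None = None) -> "ImputationResult":
        """Draw ``m`` completed datasets (default: % missing, floor 5)."""
        miss_frac = float((~self.obs_mask).mean())
        if m is None:
            m = default_m(miss_frac)
        if m < 2:
            raise ValueError("multiple imputation needs M >= 2")
        seeds = [[0 if seed is None else int(seed), i] for i in range(m)]
        datasets = [self.draw(np.random.default_rng(s)) for s in seeds]
        return ImputationResult(
            datasets=datasets, engine=self.engine, spec=self.spec, m=m, seeds=seeds,
            diagnostics=dict(self.diagnostics),
        )

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            "Imputation model results",
            "========================",
            f"engine: {self.engine}   spec: {self.spec.name}   converged: {self.converged}",
            f"rows: {d['n_rows']} ({d['n_observed']} observed, {d['n_missing']} missing)",
            f"residual sd: {np.sqrt(max(self.sigma2, 0)):.3f}   "
            f"random-intercept sd: {np.sqrt(max(self.tau2, 0)):.3f}",
            f"design condition number: {d['condition_number']:.3g}",
        ]
        if d["dropped_columns"]:
            lines.append(f"columns dropped for rank: {d['dropped_columns']}")
        if d["fallbacks"]:
            lines.append(f"fallbacks: {d['fallbacks']}")
        if self.builder.columns_ is not None and len(self.params) == len(self.builder.columns_):
            lines.append("coefficients:")
            se = np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))
            for name, est, s in zip(self.builder.columns_, self.params, se):
                lines.append(f"  {name:<28s} {est:10.4f}  (se {s:.4f})")
        return "\n".join(lines)


@dataclass
class ImputationResult:
    """M completed copies of a trial plus full provenance."""

    datasets: list[LongTrialData]
    engine: str
    spec: ModelSpec
    m: int
    seeds: list
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.m < 2 or len(self.datasets) != self.m:
            raise ValueError("ImputationResult needs M >= 2 completed datasets")

    def check_against(self, observed: LongTrialData) -> None:
        """Raise if any structural invariant is violated w.r.t. the input."""
        base = observed.rows
        obs_mask = base["qol"].notna().to_numpy()
        for i, d in enumerate(self.datasets):
            if len(d.rows) != len(base) or not (
                d.rows[["patient_id", "cycle"]].to_numpy() == base[["patient_id", "cycle"]].to_numpy()
            ).all():
                raise AssertionError(f"imputation {i}: row set differs from input")
            same = d.rows.loc[obs_mask, "qol"].to_numpy() == base.loc[obs_mask, "qol"].to_numpy()
            if not same.all():
                raise AssertionError(f"imputation {i}: observed cells modified")
            if d.rows["qol"].isna().any():
                raise AssertionError(f"imputation {i}: missing cells remain")


# ---------------------------------------------------------------------------
# functional facade


def fit_imputation_model(observed: LongTrialData, spec: ModelSpec | str | None = None,
                         engine: str = "lmm_normal", **kwargs) -> ImputationModelResults:
    """Fit an imputation model (see :class:`ImputationModel`)."""
    return ImputationModel(observed, spec=spec, engine=engine, **kwargs).fit()


def draw_imputation_lmm_normal(fitted: ImputationModelResults, rng: np.random.Generator) -> LongTrialData:
    if fitted.engine not in ("lmm_normal", "naive_lmm"):
        raise ValueError("fitted model is not a normal-draw mixed model")
    return fitted.draw(rng)


def draw_imputation_lmm_pmm(fitted: ImputationModelResults, rng: np.random.Generator,
                            k_donors: int | None = None) -> LongTrialData:
    if fitted.engine != "lmm_pmm":
        raise ValueError("fitted model is not a mixed-model PMM engine")
    if k_donors is not None:
        fitted.model.k_donors = int(k_donors)
    return fitted.draw(rng)


def draw_imputation_boot_gam(observed: LongTrialData, spec: ModelSpec | str | None,
                             rng: np.random.Generator, matching: str = "normal") -> LongTrialData:
    if matching not in ("normal", "pmm"):
        raise ValueError("matching must be 'normal' or 'pmm'")
    engine = "boot_gam_normal" if matching == "normal" else "boot_gam_pmm"
    return ImputationModel(observed, spec=spec, engine=engine).fit().draw(rng)


def multiply_impute(observed: LongTrialData, spec: ModelSpec | str | None = None,
                    engine: str = "lmm_normal", m: int | None = None,
                    seed: int | None = None, **kwargs) -> ImputationResult:
    """Fit + draw M completed datasets; deterministic given ``seed``."""
    fitted = ImputationModel(observed, spec=spec, engine=engine, **kwargs).fit()
    result = fitted.impute(m=m, seed=seed)
    result.check_against(observed)
    return result
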