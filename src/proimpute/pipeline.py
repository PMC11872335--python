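"""End-to-end run configuration and orchestration with a reproducibility manifest.

A single :class:`RunConfig` (YAML-serialisable) drives simulate -> impute
-> estimate; every stochastic stage derives its stream from the mandatory
seed, and the manifest written next to the results is sufficient to replay
the run exactly.  Identical configs produce byte-identical result JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .encoding import LongTrialData, Schedule
from .estimands import (
    EstimandResult,
    composite_transform,
    dichotomize,
    km_survival,
    pool_rubin,
    while_alive_means,
    while_on_treatment_subset,
)
from .impute import multiply_impute
from .io import read_long_csv, write_long_csv
from .ipw import MissingnessModel, ipw_gee_estimate
from .simulate import MissingnessConfig, SimConfig, TrajectoryModel, apply_missingness, simulate_trial

__all__ = ["RunConfig", "run_pipeline", "estimate_from_imputations", "load_run_config"]

ESTIMANDS = ("while_alive", "composite", "while_on_treatment")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.  ``seed`` is mandatory."""

    seed: int
    input_csv: str | None = None          # mutually exclusive with simulate=True
    simulate: bool = True
    n_patients: int = 500
    max_cycle: int = 40
    engine: str = "lmm_normal"
    model: str = "model3"
    m: int | None = None                  # None -> percentage-of-missing rule
    estimand: str = "while_alive"
    dichotomize_threshold: float | None = None
    truncation: tuple[float, float] = (0.01, 0.99)
    use_ipw: bool = False
    missingness: str = "MAR_ICE"
    out_dir: str = "proimpute_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["truncation"] = list(self.truncation)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "truncation" in d:
            d["truncation"] = tuple(d["truncation"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _schedule_for(max_cycle: int) -> Schedule:
    cycles = tuple(j for j in Schedule().cycles if j <= max_cycle)
    return Schedule(cycles)


def _result_payload(result: EstimandResult) -> dict:
    table = result.table()
    recs = json.loads(table.to_json(orient="records", double_precision=10))
    return {"estimand": result.estimand, "provenance": result.provenance, "per_cycle": recs}


def estimate_from_imputations(datasets: list[LongTrialData], estimand: str = "while_alive",
                              dichotomize_threshold: float | None = None,
                              provenance: dict | None = None) -> EstimandResult:
    """Transform each completed copy per the estimand, summarise, pool."""
    if estimand not in ESTIMANDS:
        raise ValueError(f"unknown estimand {estimand!r}; expected one of {ESTIMANDS}")
    per = []
    for d in datasets:
        if estimand == "composite":
            d = composite_transform(d)
        elif estimand == "while_on_treatment":
            d = while_on_treatment_subset(d)
        if dichotomize_threshold is not None:
            d = dichotomize(d, dichotomize_threshold)
        per.append(while_alive_means(d))
    pooled = pool_rubin(per)
    surv = km_survival(datasets[0].patients, datasets[0].schedule) if estimand == "while_alive" else None
    return EstimandResult(estimand=estimand, cycle_means=pooled, survival=surv,
                          provenance=provenance or {})


def run_pipeline(config: RunConfig, write: bool = True) -> tuple[EstimandResult, dict]:
    """Execute the configured stages; return the result and the manifest."""
    out_dir = Path(config.out_dir)
    manifest: dict = {
        "proimpute_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": [],
    }
    try:
        if config.simulate:
            sim = SimConfig(
                n_patients=config.n_patients,
                schedule=_schedule_for(config.max_cycle),
                missingness=MissingnessConfig(mechanism=config.missingness),
                seed=config.seed,
            )
            complete = simulate_trial(sim)
            observed = apply_missingness(complete, sim.missingness, seed=config.seed + 1)
            manifest["stages"].append(
                {"stage": "simulate", "n_patients": sim.n_patients,
                 "missing_fraction": round(observed.missing_fraction(), 6)}
            )
        else:
            if not config.input_csv:
                raise ValueError("config must set input_csv when simulate is false")
            observed = read_long_csv(config.input_csv)
            manifest["stages"].append(
                {"stage": "read", "input": str(config.input_csv),
                 "n_patients": observed.n_patients, "n_rows": observed.n_rows}
            )

        if config.use_ipw:
            fitted = MissingnessModel(observed, config.model).fit()
            ws = fitted.weight_set(bounds=config.truncation)
            result = ipw_gee_estimate(observed, ws)
            manifest["stages"].append(
                {"stage": "ipw", "weight_model": config.model,
                 "truncation": list(config.truncation),
                 "n_truncated": result.provenance["n_truncated"]}
            )
        else:
            imp = multiply_impute(observed, spec=config.model, engine=config.engine,
                                  m=config.m, seed=config.seed + 2)
            manifest["stages"].append(
                {"stage": "impute", "engine": imp.engine, "m": imp.m,
                 "seeds": imp.seeds, "diagnostics": _jsonable(imp.diagnostics)}
            )
            result = estimate_from_imputations(
                imp.datasets, estimand=config.estimand,
                dichotomize_threshold=config.dichotomize_threshold,
                provenance={"engine": imp.engine, "m": imp.m,
                            "model": config.model, "config_hash": config.config_hash()},
            )
            manifest["stages"].append({"stage": "estimate", "estimand": config.estimand})
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {len(manifest['stages'])}: {err}"
        ) from err

    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "result.json", "w") as fh:
            json.dump(_result_payload(result), fh, indent=2, sort_keys=True)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
        if config.simulate:
            write_long_csv(observed, out_dir / "observed.csv")
    return result, manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
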