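"""CSV reading/writing for the long-format trial dialect.

One row per patient x scheduled cycle while alive.  Mandatory columns:
``patient_id, cycle, qol, age, sex, ecog, death_ind, surv_time_cycles,
pd_ind, pd_time_cycles, td_ind, td_time_cycles``; the derived timescale
columns (``s, t_pd, t_td, e_pd_now, e_td_now``) are written on export and
recomputed/validated on import.  Missing PRO scores are empty fields.
UTF-8, header row mandatory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import (
    DEFAULT_CAPS,
    PATIENT_COLUMNS,
    ROW_COLUMNS,
    LongTrialData,
    Schedule,
    validate_long_data,
)

__all__ = ["read_long_csv", "write_long_csv", "CSV_COLUMNS"]

_TIME_RENAME = {"surv_time": "surv_time_cycles", "pd_time": "pd_time_cycles", "td_time": "td_time_cycles"}
_TIME_RENAME_BACK = {v: k for k, v in _TIME_RENAME.items()}

CSV_COLUMNS = [
    "patient_id", "cycle", "qol", "age", "sex", "ecog",
    "death_ind", "surv_time_cycles", "pd_ind", "pd_time_cycles",
    "td_ind", "td_time_cycles", "s", "t_pd", "t_td", "e_pd_now", "e_td_now", "r_obs",
]

_MANDATORY = [c for c in CSV_COLUMNS if c not in ("s", "t_pd", "t_td", "e_pd_now", "e_td_now", "r_obs")]


def write_long_csv(data: LongTrialData, path) -> None:
    """Write the flat long-format CSV (missing scores as empty fields)."""
    flat = data.frame().rename(columns=_TIME_RENAME)
    flat = flat[CSV_COLUMNS]
    flat.to_csv(path, index=False, float_format="%.10g")


def read_long_csv(path, schedule: Schedule | None = None, validate: bool = True,
                  caps: dict | None = None) -> LongTrialData:
    """Read the long-format dialect and (by default) validate every invariant.

    The derived timescale columns are recomputed from the survival/ICE
    columns; if the schedule is not given it is inferred as the sorted set
    of cycles present in the file.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing mandatory column(s) {missing}")
    if not pd.api.types.is_numeric_dtype(df["qol"]):
        bad = df.loc[pd.to_numeric(df["qol"], errors="coerce").isna() & df["qol"].notna(), "qol"]
        raise ValueError(f"{path.name}: non-numeric qol values, e.g. {bad.head(3).tolist()}")
    dup = df.duplicated(subset=["patient_id", "cycle"])
    if dup.any():
        pairs = df.loc[dup, ["patient_id", "cycle"]].head(5).to_records(index=False).tolist()
        raise ValueError(f"{path.name}: duplicate (patient_id, cycle) rows, e.g. {pairs}")
    df = df.rename(columns=_TIME_RENAME_BACK)
    caps = dict(caps) if caps is not None else dict(DEFAULT_CAPS)

    patients = (
        df[PATIENT_COLUMNS].drop_duplicates(subset="patient_id").reset_index(drop=True)
    )
    conflicting = df.groupby("patient_id")[
        [c for c in PATIENT_COLUMNS if c != "patient_id"]
    ].nunique()
    if (conflicting > 1).any().any():
        bad = conflicting[(conflicting > 1).any(axis=1)].index.tolist()[:5]
        raise ValueError(f"{path.name}: inconsistent patient-level values for {bad}")

    rows = df[["patient_id", "cycle", "qol"]].copy()
    if "r_obs" in df.columns:
        # preserved observedness flags (imputed cells keep r_obs = 0)
        rows["r_obs"] = df["r_obs"].astype(int)
    else:
        rows["r_obs"] = rows["qol"].notna().astype(int)
    surv = patients.set_index("patient_id")["surv_time"].reindex(rows["patient_id"]).to_numpy()
    pd_t = patients.set_index("patient_id")["pd_time"].reindex(rows["patient_id"]).to_numpy()
    td_t = patients.set_index("patient_id")["td_time"].reindex(rows["patient_id"]).to_numpy()
    pd_i = patients.set_index("patient_id")["pd_ind"].reindex(rows["patient_id"]).to_numpy()
    td_i = patients.set_index("patient_id")["td_ind"].reindex(rows["patient_id"]).to_numpy()
    cyc = rows["cycle"].to_numpy(dtype=float)
    rows["s"] = surv - cyc
    rows["t_pd"] = np.maximum(pd_t - cyc, caps["pd"])
    rows["t_td"] = np.maximum(td_t - cyc, caps["td"])
    rows["e_pd_now"] = ((pd_i == 1) & (cyc >= pd_t)).astype(int)
    rows["e_td_now"] = ((td_i == 1) & (cyc >= td_t)).astype(int)

    if schedule is None:
        schedule = Schedule(tuple(sorted(rows["cycle"].unique())))
    data = LongTrialData(rows[ROW_COLUMNS], patients, schedule, caps)
    if validate:
        violations = validate_long_data(data)
        if violations:
            msgs = "\n".join(str(v) for v in violations[:20])
            raise ValueError(
                f"{path.name}: {len(violations)} validation violation(s):\n{msgs}"
            )
    return data
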