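"""Long-format trial data with intercurrent-event (ICE) timescale covariates.

Longitudinal patient-reported outcomes (PROs) in oncology trials are
interrupted by intercurrent events: death (terminal), disease progression
(PD) and treatment discontinuation (TD).  This module builds the long-format
data structure in which each patient contributes one row per scheduled
measurement cycle *while alive*, and each row carries the patient's position
on several timescales at once:

* ``s`` — time until death or survival censoring, in cycles (nonnegative;
  rows after death/censoring do not exist);
* ``t_pd``, ``t_td`` — time-distance to the non-terminal ICE, positive
  before the event, 0 at the event, and capped below after the event
  (default caps: 0 for TD because PRO collection stops at discontinuation,
  -3 for PD because data become sparse a few cycles after progression);
* ``e_pd_now``, ``e_td_now`` — whether the ICE has been observed by the
  current cycle (a censoring time never switches the indicator on).

All times are expressed in cycle units (1 cycle = 3 weeks by default);
convert days/months upstream.  Event times may be non-integer and are used
as-is; scheduled cycles are integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Schedule",
    "PatientRecord",
    "LongTrialData",
    "Violation",
    "DEFAULT_CYCLES",
    "ICE_KINDS",
    "compute_time_to_death",
    "compute_time_to_ice",
    "event_by_time_indicator",
    "build_long_format",
    "validate_long_data",
]

#: Tri-weekly cycles 1..10, then alternate cycles (every 6 weeks) to 40.
DEFAULT_CYCLES: tuple[int, ...] = tuple(range(1, 11)) + tuple(range(12, 41, 2))

#: Supported non-terminal ICE kinds and their default post-event caps for
#: the time-distance variable (data-driven choices, configurable).
ICE_KINDS = ("pd", "td")
DEFAULT_CAPS: dict[str, float] = {"pd": -3.0, "td": 0.0}

ROW_COLUMNS = [
    "patient_id",
    "cycle",
    "qol",
    "r_obs",
    "s",
    "t_pd",
    "t_td",
    "e_pd_now",
    "e_td_now",
]

PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "ecog",
    "death_ind",
    "surv_time",
    "pd_ind",
    "pd_time",
    "td_ind",
    "td_time",
]


@dataclass(frozen=True)
class Schedule:
    """Scheduled measurement cycles (strictly increasing positive integers)."""

    cycles: tuple[int, ...] = DEFAULT_CYCLES
    cycle_length_weeks: float = 3.0

    def __post_init__(self) -> None:
        cyc = tuple(int(c) for c in self.cycles)
        object.__setattr__(self, "cycles", cyc)
        arr = np.asarray(cyc)
        if arr.size == 0:
            raise ValueError("schedule must contain at least one cycle")
        if arr[0] <= 0 or np.any(np.diff(arr) <= 0):
            raise ValueError("schedule cycles must be strictly increasing positive integers")

    def cycles_until(self, t: float) -> list[int]:
        """Scheduled cycles at or before time ``t`` (cycles)."""
        return [j for j in self.cycles if j <= t]

    @property
    def max_cycle(self) -> int:
        return self.cycles[-1]


@dataclass
class PatientRecord:
    """Per-patient survival and ICE times plus baseline covariates.

    Times are in cycle units.  ``surv_time`` is a death time when
    ``death_ind == 1`` and a censoring time otherwise; ``pd_time`` /
    ``td_time`` follow the same convention via ``pd_ind`` / ``td_ind``.
    """

    patient_id: object
    death_ind: int
    surv_time: float
    pd_ind: int
    pd_time: float
    td_ind: int
    td_time: float
    age: float = 60.0
    sex: str = "F"
    ecog: int = 0

    def problems(self) -> list[str]:
        out = []
        if not self.surv_time > 0:
            out.append(f"patient {self.patient_id}: surv_time must be > 0")
        for kind, t in (("pd", self.pd_time), ("td", self.td_time)):
            if not t > 0:
                out.append(f"patient {self.patient_id}: {kind}_time must be > 0")
            if t > self.surv_time + 1e-12:
                out.append(
                    f"patient {self.patient_id}: {kind}_time {t} exceeds surv_time "
                    f"{self.surv_time} (no ICE after death/censoring)"
                )
        for name, ind in (("death_ind", self.death_ind), ("pd_ind", self.pd_ind), ("td_ind", self.td_ind)):
            if ind not in (0, 1):
                out.append(f"patient {self.patient_id}: {name} must be 0 or 1")
        return out


def compute_time_to_death(surv_time: float, cycle: float) -> float:
    """Time from cycle ``j`` until death/censoring, ``s = S_i - j`` (>= 0)."""
    if cycle > surv_time:
        raise ValueError(
            f"row beyond survival time: cycle {cycle} > surv_time {surv_time}"
        )
    return float(surv_time) - float(cycle)


def compute_time_to_ice(ice_time: float, cycle: float, ice_kind: str, cap: float | None = None) -> float:
    """Capped time-distance to a non-terminal ICE at cycle ``j``.

    The raw distance ``T_k - j`` is positive before the event, 0 at the
    event, and is held constant at ``cap`` once it would fall below it
    (default 0 for TD, -3 for PD).
    """
    if ice_kind not in ICE_KINDS:
        raise ValueError(f"unknown ice_kind {ice_kind!r}; expected one of {ICE_KINDS}")
    if not ice_time > 0:
        raise ValueError("ice_time must be positive")
    if cap is None:
        cap = DEFAULT_CAPS[ice_kind]
    return max(float(ice_time) - float(cycle), cap)


def event_by_time_indicator(event_ind: int, ice_time: float, cycle: float) -> int:
    """1 iff the ICE was observed (not censored) and occurred by cycle ``j``.

    The event cycle itself counts as post-event (``j >= T_k``).
    """
    return int(bool(event_ind) and cycle >= ice_time)


class LongTrialData:
    """Long-format trial dataset: visit rows, patient table and schedule.

    ``rows`` has one record per (patient, scheduled cycle <= survival time)
    with the PRO value ``qol`` (NaN when missing), the observedness flag
    ``r_obs`` and the derived ICE-timescale covariates.  ``patients`` holds
    the time-constant survival/ICE information and baseline covariates.
    """

    def __init__(self, rows: pd.DataFrame, patients: pd.DataFrame, schedule: Schedule,
                 caps: Mapping[str, float] | None = None):
        self.rows = rows.reset_index(drop=True)
        self.patients = patients.reset_index(drop=True)
        self.schedule = schedule
        self.caps = dict(caps) if caps is not None else dict(DEFAULT_CAPS)
        missing = [c for c in ROW_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"rows missing mandatory columns: {missing}")
        missing = [c for c in PATIENT_COLUMNS if c not in self.patients.columns]
        if missing:
            raise ValueError(f"patients missing mandatory columns: {missing}")

    # -- basic properties -------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def missing_fraction(self) -> float:
        """Fraction of visit rows with a missing PRO value."""
        if self.n_rows == 0:
            return 0.0
        return float(self.rows["qol"].isna().mean())

    def frame(self) -> pd.DataFrame:
        """Rows merged with the patient table (one flat analysis frame)."""
        return self.rows.merge(self.patients, on="patient_id", how="left", validate="m:1")

    def copy(self) -> "LongTrialData":
        return LongTrialData(self.rows.copy(), self.patients.copy(), self.schedule, self.caps)

    def with_qol(self, qol: np.ndarray | pd.Series) -> "LongTrialData":
        """Return a copy whose ``qol`` column is replaced (row order preserved)."""
        out = self.copy()
        out.rows["qol"] = np.asarray(qol, dtype=float)
        return out

    def equals(self, other: "LongTrialData") -> bool:
        return (
            self.rows.equals(other.rows)
            and self.patients.equals(other.patients)
            and self.schedule == other.schedule
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<LongTrialData: {self.n_patients} patients, {self.n_rows} rows, "
            f"{100 * self.missing_fraction():.1f}% missing PRO>"
        )


def _patients_frame(patients: Iterable[PatientRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(patients, pd.DataFrame):
        df = patients.copy()
    else:
        recs = list(patients)
        problems = [p for r in recs for p in r.problems()]
        if problems:
            raise ValueError("invalid patient records:\n" + "\n".join(problems))
        df = pd.DataFrame([vars(r) for r in recs], columns=PATIENT_COLUMNS)
    if df.empty:
        df = pd.DataFrame(columns=PATIENT_COLUMNS)
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id values: {dup}")
    return df[PATIENT_COLUMNS]


def _expand_rows(patients: pd.DataFrame, schedule: Schedule,
                 caps: Mapping[str, float]) -> pd.DataFrame:
    """Vectorised construction of one row per (patient, cycle <= surv_time)."""
    cycles = np.asarray(schedule.cycles, dtype=float)
    surv = patients["surv_time"].to_numpy(dtype=float)
    alive = cycles[None, :] <= surv[:, None]
    i_idx, j_idx = np.nonzero(alive)
    pid = patients["patient_id"].to_numpy()[i_idx]
    cyc = cycles[j_idx]
    s = surv[i_idx] - cyc
    pd_time = patients["pd_time"].to_numpy(dtype=float)[i_idx]
    td_time = patients["td_time"].to_numpy(dtype=float)[i_idx]
    pd_ind = patients["pd_ind"].to_numpy(dtype=int)[i_idx]
    td_ind = patients["td_ind"].to_numpy(dtype=int)[i_idx]
    t_pd = np.maximum(pd_time - cyc, caps["pd"])
    t_td = np.maximum(td_time - cyc, caps["td"])
    e_pd = ((pd_ind == 1) & (cyc >= pd_time)).astype(int)
    e_td = ((td_ind == 1) & (cyc >= td_time)).astype(int)
    return pd.DataFrame(
        {
            "patient_id": pid,
            "cycle": cyc.astype(int),
            "qol": np.nan,
            "r_obs": 0,
            "s": s,
            "t_pd": t_pd,
            "t_td": t_td,
            "e_pd_now": e_pd,
            "e_td_now": e_td,
        }
    )


def build_long_format(
    patients: Iterable[PatientRecord] | pd.DataFrame,
    schedule: Schedule | None = None,
    observed_pro: Mapping[tuple, float] | None = None,
    caps: Mapping[str, float] | None = None,
) -> LongTrialData:
    """Build a :class:`LongTrialData` from patient records and observed PROs.

    ``observed_pro`` maps ``(patient_id, cycle)`` to a PRO score; every key
    must refer to a scheduled cycle at or before the patient's survival /
    censoring time.  Cycles without a supplied score are missing
    (``qol = NaN``, ``r_obs = 0``).
    """
    schedule = schedule or Schedule()
    caps = dict(caps) if caps is not None else dict(DEFAULT_CAPS)
    pat = _patients_frame(patients)
    rows = _expand_rows(pat, schedule, caps)
    if observed_pro:
        surv = dict(zip(pat["patient_id"], pat["surv_time"]))
        sched = set(schedule.cycles)
        for (pid, j), val in observed_pro.items():
            if pid not in surv:
                raise ValueError(f"observed PRO for unknown patient {pid!r}")
            if j not in sched:
                raise ValueError(f"patient {pid!r}: cycle {j} is not a scheduled cycle")
            if j > surv[pid]:
                raise ValueError(
                    f"measurement after death/censoring: patient {pid!r} cycle {j} "
                    f"> surv_time {surv[pid]}"
                )
        keys = pd.MultiIndex.from_frame(rows[["patient_id", "cycle"]])
        obs = pd.Series(dict(observed_pro))
        obs.index = pd.MultiIndex.from_tuples(obs.index)
        aligned = obs.reindex(keys)
        rows["qol"] = aligned.to_numpy(dtype=float)
        rows["r_obs"] = rows["qol"].notna().astype(int)
    return LongTrialData(rows, pat, schedule, caps)


@dataclass(frozen=True)
class Violation:
    """A single invariant violation found by :func:`validate_long_data`."""

    patient_id: object
    cycle: object
    rule: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] patient {self.patient_id} cycle {self.cycle}: {self.detail}"


def validate_long_data(data: LongTrialData, qol_range: tuple[float, float] | None = (0.0, 100.0)) -> list[Violation]:
    """Check every structural invariant; return violations (never raises).

    Rules checked per row: existence only while alive, ``s = S - j >= 0``,
    time-distance caps, event-by-now indicator consistency, observedness
    flag consistency, PRO range (when ``qol_range`` is given).  Per patient:
    ICE times positive and at or before the survival time, and every
    scheduled cycle up to the survival time present exactly once.
    """
    out: list[Violation] = []
    pat = data.patients.set_index("patient_id")
    rows = data.rows
    # referential integrity
    unknown = set(rows["patient_id"]) - set(pat.index)
    for pid in sorted(unknown, key=str):
        out.append(Violation(pid, None, "referential_integrity", "row for unknown patient"))
    for rec in pat.reset_index().itertuples(index=False):
        for msg in PatientRecord(
            rec.patient_id, rec.death_ind, rec.surv_time, rec.pd_ind, rec.pd_time,
            rec.td_ind, rec.td_time, rec.age, rec.sex, rec.ecog,
        ).problems():
            out.append(Violation(rec.patient_id, None, "patient_invariant", msg))
    known = rows[rows["patient_id"].isin(pat.index)]
    merged = known.merge(pat.reset_index(), on="patient_id", how="left")
    sched = set(data.schedule.cycles)
    for r in merged.itertuples(index=False):
        pid, j = r.patient_id, r.cycle
        if j not in sched:
            out.append(Violation(pid, j, "unscheduled_cycle", f"cycle {j} not in schedule"))
        if j > r.surv_time:
            out.append(Violation(pid, j, "row_after_death", f"cycle {j} > surv_time {r.surv_time}"))
        elif abs(r.s - (r.surv_time - j)) > 1e-9 or r.s < -1e-9:
            out.append(Violation(pid, j, "s_mismatch", f"s={r.s}, expected {r.surv_time - j}"))
        exp_tpd = max(r.pd_time - j, data.caps["pd"])
        exp_ttd = max(r.td_time - j, data.caps["td"])
        if abs(r.t_pd - exp_tpd) > 1e-9:
            out.append(Violation(pid, j, "t_pd_mismatch", f"t_pd={r.t_pd}, expected {exp_tpd}"))
        if abs(r.t_td - exp_ttd) > 1e-9:
            out.append(Violation(pid, j, "t_td_mismatch", f"t_td={r.t_td}, expected {exp_ttd}"))
        if int(r.e_pd_now) != event_by_time_indicator(r.pd_ind, r.pd_time, j):
            out.append(Violation(pid, j, "e_pd_now_mismatch", f"e_pd_now={r.e_pd_now}"))
        if int(r.e_td_now) != event_by_time_indicator(r.td_ind, r.td_time, j):
            out.append(Violation(pid, j, "e_td_now_mismatch", f"e_td_now={r.e_td_now}"))
        qol_missing = r.qol != r.qol  # NaN check
        # r_obs flags *observedness*: an observed row must carry a value; a
        # row with a value but r_obs = 0 is an imputed cell and is legal
        if int(r.r_obs) == 1 and qol_missing:
            out.append(Violation(pid, j, "r_obs_mismatch", f"r_obs=1 but qol missing"))
        if (
            qol_range is not None and int(r.r_obs) == 1 and not qol_missing
            and not (qol_range[0] <= r.qol <= qol_range[1])
        ):
            out.append(Violation(pid, j, "qol_out_of_range", f"qol={r.qol}"))
    # completeness / duplicates
    dup = rows.duplicated(subset=["patient_id", "cycle"], keep=False)
    for r in rows[dup].drop_duplicates(subset=["patient_id", "cycle"]).itertuples(index=False):
        out.append(Violation(r.patient_id, r.cycle, "duplicate_row", "duplicate (patient, cycle)"))
    counts = rows.groupby("patient_id")["cycle"].apply(set)
    for pid, rec in pat.iterrows():
        expected = set(data.schedule.cycles_until(rec["surv_time"]))
        have = counts.get(pid, set())
        for j in sorted(expected - set(have)):
            out.append(Violation(pid, j, "missing_row", f"scheduled cycle {j} absent"))
    return out
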