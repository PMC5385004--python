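"""Patient/cohort data model and delimited-text I/O.

A cohort is one row per patient: demographics, labs, the vancomycin regimen
and (when available) the measured trough.  The column layout is explicit — a
:class:`ColumnSchema` maps canonical field names to file headers, and units
are fixed by the schema (cm, kg, mg/dL, μg/mL, hours).  Nothing is sniffed
or auto-converted; silent unit conversion is the classic failure mode of TDM
tooling.

Irregular dosing histories can be supplied through a long-format companion
table of events (patient_id, start_h, dose_mg, duration_h); otherwise the
regimen is the inline maintenance schedule (dose_mg, infusion_h, interval_h,
n_doses).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DoseRegimen",
    "PatientRecord",
    "Cohort",
    "ColumnSchema",
    "SchemaError",
    "CohortValidationError",
    "Exclusion",
    "load_cohort",
    "write_cohort",
    "filter_eligible",
]


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class CohortValidationError(ValueError):
    """One or more rows violate field-level invariants; carries row numbers."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


@dataclass(frozen=True)
class DoseRegimen:
    """Vancomycin infusion schedule.

    ``events`` is the realized history as (start_h, dose_mg, duration_h)
    tuples; ``maintenance`` is the (dose_mg, duration_h, interval_h) cycle
    used for steady-state projection.  For a regular schedule the events are
    just the first ``n`` maintenance cycles.
    """

    events: tuple[tuple[float, float, float], ...]
    maintenance: tuple[float, float, float]  # (dose_mg, duration_h, interval_h)
    irregular_flag: bool = False

    def __post_init__(self):
        dose, dur, tau = self.maintenance
        if dur <= 0:
            raise ValueError("infusion duration must be positive")
        if tau < dur:
            raise ValueError("dosing interval must be >= infusion duration")
        if dose < 0:
            raise ValueError("dose must be non-negative")
        last = -float("inf")
        for start, d, du in self.events:
            if du <= 0:
                raise ValueError("event duration must be positive")
            if start < last:
                raise ValueError("event starts must be non-decreasing")
            last = start

    @classmethod
    def regular(cls, dose_mg: float, duration_h: float, interval_h: float,
                n_doses: int) -> "DoseRegimen":
        events = tuple((i * interval_h, dose_mg, duration_h) for i in range(int(n_doses)))
        return cls(events=events, maintenance=(dose_mg, duration_h, interval_h))

    @property
    def daily_dose(self) -> float:
        dose, _, tau = self.maintenance
        return dose * 24.0 / tau


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str                     # "female" | "male"
    age: float                   # years
    height: float | None         # cm
    weight: float                # kg
    scr: float                   # mg/dL at initial dose planning
    bun: float | None            # mg/dL
    regimen: DoseRegimen
    scr_at_trough: float | None = None
    alb: float | None = None     # g/dL
    other_labs: Mapping[str, float] = field(default_factory=dict)
    measured_trough: float | None = None  # μg/mL
    trough_day: float | None = None       # days from first dose
    dialysis_flag: bool = False
    outpatient_flag: bool = False

    def __post_init__(self):
        problems = []
        if self.sex not in ("female", "male"):
            problems.append(f"sex must be female/male, got {self.sex!r}")
        if not self.age > 0:
            problems.append("age must be positive")
        if not self.weight > 0:
            problems.append("weight must be positive")
        if not self.scr > 0:
            problems.append("scr must be positive")
        if self.measured_trough is not None and self.measured_trough < 0:
            problems.append("measured_trough must be >= 0")
        if self.trough_day is not None and not (1 <= self.trough_day <= 30):
            problems.append("trough_day must lie in [1, 30]")
        if problems:
            raise CohortValidationError([f"patient {self.patient_id}: {p}" for p in problems])


@dataclass(frozen=True)
class Cohort:
    records: tuple[PatientRecord, ...]
    provenance: str = "unspecified"

    def __post_init__(self):
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError([f"duplicate patient_id values: {dupes}"])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


# ---------------------------------------------------------------------------
# Schema


#: Canonical column names and whether each is required in the cohort file.
_REQUIRED = ("id", "sex", "age", "weight", "scr", "bun",
             "dose_mg", "infusion_h", "interval_h")
_OPTIONAL = ("height", "scr_at_trough", "alb", "n_doses",
             "measured_trough", "trough_day", "dialysis", "outpatient")


@dataclass(frozen=True)
class ColumnSchema:
    """Maps canonical field names to the file's column headers.

    Any file column not claimed by the mapping is read into
    ``PatientRecord.other_labs`` as a free-form numeric lab value.
    """

    columns: Mapping[str, str] = field(
        default_factory=lambda: {name: name for name in _REQUIRED + _OPTIONAL})
    sex_aliases: Mapping[str, str] = field(default_factory=lambda: {
        "f": "female", "female": "female", "w": "female",
        "m": "male", "male": "male"})
    true_tokens: tuple[str, ...] = ("1", "true", "yes", "y")

    def header(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    def parse_sex(self, token) -> str:
        key = str(token).strip().lower()
        if key not in self.sex_aliases:
            raise ValueError(f"unrecognised sex token {token!r}")
        return self.sex_aliases[key]

    def parse_flag(self, token) -> bool:
        if token is None or (isinstance(token, float) and pd.isna(token)):
            return False
        return str(token).strip().lower() in self.true_tokens


def _opt_float(row, col, rownum, problems) -> float | None:
    if col not in row or pd.isna(row[col]) or row[col] == "":
        return None
    try:
        return float(row[col])
    except (TypeError, ValueError):
        problems.append(f"row {rownum}: non-numeric value {row[col]!r} in column {col!r}")
        return None


def load_cohort(path: str | Path, schema: ColumnSchema | None = None,
                sep: str | None = None,
                events_path: str | Path | None = None) -> Cohort:
    """Read a delimited cohort file into a typed :class:`Cohort`.

    ``sep=None`` accepts comma- or tab-delimited input (chosen per file by
    the csv sniffer over those two candidates only — headers are never
    sniffed).  ``events_path`` optionally supplies irregular dose histories
    in long format; patients present there get their events replaced and
    ``irregular_flag`` set.

    Raises :class:`SchemaError` for a missing required column and
    :class:`CohortValidationError` listing row numbers for unparseable rows.
    """
    schema = schema or ColumnSchema()
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     dtype=str, keep_default_na=True)
    missing = [c for c in _REQUIRED if schema.header(c) not in df.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s) {[schema.header(c) for c in missing]} in {path.name}")

    events_by_id: dict[str, list[tuple[float, float, float]]] = {}
    if events_path is not None:
        ev = pd.read_csv(events_path, sep=sep, engine="python" if sep is None else "c")
        for need in ("patient_id", "start_h", "dose_mg", "duration_h"):
            if need not in ev.columns:
                raise SchemaError(f"events file missing column {need!r}")
        for pid, grp in ev.groupby("patient_id"):
            grp = grp.sort_values("start_h")
            events_by_id[str(pid)] = [
                (float(r.start_h), float(r.dose_mg), float(r.duration_h))
                for r in grp.itertuples()]

    claimed = {schema.header(c) for c in _REQUIRED + _OPTIONAL}
    lab_cols = [c for c in df.columns if c not in claimed]

    records: list[PatientRecord] = []
    problems: list[str] = []
    for idx, raw in df.iterrows():
        rownum = idx + 2  # 1-based with header line
        row = {k: raw[k] for k in df.columns}
        get = lambda c: row.get(schema.header(c))

        def req_float(c):
            v = get(c)
            try:
                return float(v)
            except (TypeError, ValueError):
                problems.append(f"row {rownum}: non-numeric value {v!r} in column {schema.header(c)!r}")
                return None

        try:
            sex = schema.parse_sex(get("sex"))
        except ValueError as e:
            problems.append(f"row {rownum}: {e}")
            continue
        age, weight, scr = req_float("age"), req_float("weight"), req_float("scr")
        dose, dur, tau = req_float("dose_mg"), req_float("infusion_h"), req_float("interval_h")
        bun = _opt_float(row, schema.header("bun"), rownum, problems)
        if None in (age, weight, scr, dose, dur, tau):
            continue
        n_doses = _opt_float(row, schema.header("n_doses"), rownum, problems)
        trough_day = _opt_float(row, schema.header("trough_day"), rownum, problems)
        if n_doses is None:
            # Enough doses to span the observation window (or 10 days as a default)
            horizon_h = 24.0 * (trough_day if trough_day is not None else 10.0)
            n_doses = max(1, int(horizon_h // tau) + 1)
        pid = str(get("id"))
        if pid in events_by_id:
            regimen = DoseRegimen(events=tuple(events_by_id[pid]),
                                  maintenance=(dose, dur, tau), irregular_flag=True)
        else:
            regimen = DoseRegimen.regular(dose, dur, tau, int(n_doses))
        labs = {}
        for c in lab_cols:
            v = _opt_float(row, c, rownum, [])
            if v is not None:
                labs[c] = v
        try:
            records.append(PatientRecord(
                patient_id=pid, sex=sex, age=age,
                height=_opt_float(row, schema.header("height"), rownum, problems),
                weight=weight, scr=scr, bun=bun, regimen=regimen,
                scr_at_trough=_opt_float(row, schema.header("scr_at_trough"), rownum, problems),
                alb=_opt_float(row, schema.header("alb"), rownum, problems),
                other_labs=labs,
                measured_trough=_opt_float(row, schema.header("measured_trough"), rownum, problems),
                trough_day=trough_day,
                dialysis_flag=schema.parse_flag(get("dialysis")),
                outpatient_flag=schema.parse_flag(get("outpatient")),
            ))
        except CohortValidationError as e:
            problems.extend(f"row {rownum}: {p}" for p in e.problems)
    if problems:
        raise CohortValidationError(problems)
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    return Cohort(records=tuple(records), provenance=f"{path} @ {stamp}")


def write_cohort(cohort: Cohort, path: str | Path, schema: ColumnSchema | None = None,
                 sep: str = ",") -> None:
    """Write a cohort back to delimited text (inverse of :func:`load_cohort`).

    Floats are written with full repr so that load→write→load round-trips
    finite decimal inputs bit-identically.
    """
    schema = schema or ColumnSchema()
    rows = []
    for r in cohort:
        dose, dur, tau = r.regimen.maintenance
        row = {
            schema.header("id"): r.patient_id,
            schema.header("sex"): r.sex,
            schema.header("age"): r.age,
            schema.header("height"): r.height,
            schema.header("weight"): r.weight,
            schema.header("scr"): r.scr,
            schema.header("scr_at_trough"): r.scr_at_trough,
            schema.header("bun"): r.bun,
            schema.header("alb"): r.alb,
            schema.header("dose_mg"): dose,
            schema.header("infusion_h"): dur,
            schema.header("interval_h"): tau,
            schema.header("n_doses"): len(r.regimen.events),
            schema.header("measured_trough"): r.measured_trough,
            schema.header("trough_day"): r.trough_day,
            schema.header("dialysis"): int(r.dialysis_flag),
            schema.header("outpatient"): int(r.outpatient_flag),
        }
        row.update(r.other_labs)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class Exclusion:
    patient_id: str
    reason: str


def filter_eligible(cohort: Cohort, trough_window: tuple[float, float] = (3.0, 5.0),
                    ) -> tuple[Cohort, list[Exclusion]]:
    """Apply the study eligibility filter.

    Keeps inpatients aged >= 18, not on hemodialysis, with a measured trough
    sampled within ``trough_window`` days of the first dose.  Every excluded
    record is logged with its (first) reason; input size is conserved:
    ``len(kept) + len(exclusions) == len(cohort)``.
    """
    kept, excluded = [], []
    lo, hi = trough_window
    for r in cohort:
        if r.dialysis_flag:
            excluded.append(Exclusion(r.patient_id, "receiving hemodialysis"))
        elif r.outpatient_flag:
            excluded.append(Exclusion(r.patient_id, "outpatient"))
        elif r.age < 18:
            excluded.append(Exclusion(r.patient_id, "under 18"))
        elif r.measured_trough is None:
            excluded.append(Exclusion(r.patient_id, "no measured trough"))
        elif r.trough_day is None or not (lo <= r.trough_day <= hi):
            excluded.append(Exclusion(
                r.patient_id, f"trough sampled outside day {lo:g}-{hi:g} window"))
        else:
            kept.append(r)
    return Cohort(records=tuple(kept), provenance=cohort.provenance), excluded
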