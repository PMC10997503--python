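"""Patient-level data model, CSV readers/writers, and endpoint derivation.

One row per patient: presenting covariates (age, WBC, day-8 and day-29
MRD, genetics flags, CNS status), the first-event record (type and time
from end of induction, EOI), and optional death follow-up used only for
overall survival. Times are in years from EOI; MRD is stored on the
fraction scale (0.01% == 1e-4).

Endpoints:

* RFS — relapse-free survival: relapse or death in remission are events;
  a second malignant neoplasm (SMN) censors at its time.
* DFS — disease-free survival: relapse, death in remission, or SMN.
* OS — overall survival: death from any cause, using the optional
  ``death_flag``/``death_time_years`` columns when present so that deaths
  after relapse are captured.

Patients with induction death or induction failure never enter the
RFS/DFS cohorts (they failed to reach EOI remission).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import pandas as pd

from .errors import SchemaError, CohortExclusionError

CNS_CODES = ("CNS1", "CNS2", "CNS3")
NCI_CODES = ("SR", "HR")
EVENT_TYPES = (
    "none",
    "relapse",
    "remission_death",
    "smn",
    "induction_death",
    "induction_failure",
)
ENDPOINTS = ("RFS", "DFS", "OS")
COHORT_LABELS = ("training", "testing")

#: Documented CSV column order.
CSV_COLUMNS = (
    "id",
    "age_years",
    "wbc",
    "d8_mrd",
    "d29_mrd",
    "frg",
    "urg",
    "cns",
    "nci_risk",
    "event_type",
    "time_from_eoi_years",
    "death_flag",
    "death_time_years",
    "cohort_label",
)


@dataclass
class PatientRecord:
    """One subject's raw covariates, first event, and follow-up."""

    id: str
    age_years: float
    wbc: float
    d8_mrd: float | None
    d29_mrd: float | None
    frg: bool
    urg: bool
    cns: str
    nci_risk: str | None
    event_type: str
    time_from_eoi_years: float
    death_flag: int | None = None
    death_time_years: float | None = None
    cohort_label: str | None = None

    def __post_init__(self):
        if self.frg and self.urg:
            raise SchemaError(f"record {self.id}: frg and urg cannot both be true")
        if self.cns not in CNS_CODES:
            raise SchemaError(f"record {self.id}: unknown CNS code {self.cns!r}")
        if self.event_type not in EVENT_TYPES:
            raise SchemaError(f"record {self.id}: unknown event type {self.event_type!r}")
        if self.nci_risk is not None and self.nci_risk not in NCI_CODES:
            raise SchemaError(f"record {self.id}: unknown NCI risk {self.nci_risk!r}")
        if self.cohort_label is not None and self.cohort_label not in COHORT_LABELS:
            raise SchemaError(f"record {self.id}: unknown cohort label {self.cohort_label!r}")
        if self.time_from_eoi_years < 0 or math.isnan(self.time_from_eoi_years):
            raise SchemaError(f"record {self.id}: negative or NaN follow-up time")
        if not self.age_years > 0:
            raise SchemaError(f"record {self.id}: age must be > 0")
        if not self.wbc > 0:
            raise SchemaError(f"record {self.id}: wbc must be > 0")
        for col in ("d8_mrd", "d29_mrd"):
            v = getattr(self, col)
            if v is not None and not (0.0 <= v <= 1.0):
                raise SchemaError(f"record {self.id}: {col} outside [0, 1]")


@dataclass(frozen=True)
class SurvivalOutcome:
    """An observed (time, event) pair for a named endpoint."""

    time: float
    event: int
    endpoint: str = "RFS"

    def __post_init__(self):
        if not (math.isfinite(self.time) and self.time >= 0):
            raise ValueError("time must be finite and non-negative")


def derive_endpoint(record: PatientRecord, endpoint: str) -> SurvivalOutcome:
    """Derive the survival outcome for one record and endpoint.

    Raises :class:`CohortExclusionError` for RFS/DFS on records with
    induction death or induction failure.
    """
    endpoint = endpoint.upper()
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    et = record.event_type
    t = record.time_from_eoi_years
    if endpoint in ("RFS", "DFS"):
        if et in ("induction_death", "induction_failure"):
            raise CohortExclusionError(
                f"record {record.id}: {et} is excluded from the {endpoint} cohort"
            )
        if endpoint == "RFS":
            event = int(et in ("relapse", "remission_death"))
        else:
            event = int(et in ("relapse", "remission_death", "smn"))
        return SurvivalOutcome(t, event, endpoint)
    # OS: prefer the explicit death follow-up columns so deaths after
    # relapse are counted; otherwise fall back to the first-event record.
    if record.death_flag is not None:
        time = record.death_time_years if record.death_time_years is not None else t
        return SurvivalOutcome(time, int(record.death_flag), "OS")
    event = int(et in ("remission_death", "induction_death"))
    return SurvivalOutcome(t, event, "OS")


def derive_endpoints(records, endpoint: str):
    """Derive outcomes for a cohort, dropping excluded records.

    Returns ``(kept_records, outcomes, n_excluded)``.
    """
    kept, outcomes, n_excluded = [], [], 0
    for rec in records:
        try:
            out = derive_endpoint(rec, endpoint)
        except CohortExclusionError:
            n_excluded += 1
            continue
        kept.append(rec)
        outcomes.append(out)
    return kept, outcomes, n_excluded


def _parse_cell(value, row: int, col: str):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return value


def _parse_bool(value, row: int, col: str) -> bool:
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("1", "true", "t", "yes"):
            return True
        if v in ("0", "false", "f", "no"):
            return False
        raise SchemaError(f"row {row}, column {col!r}: cannot parse boolean {value!r}")
    return bool(int(value))


def read_cohort(path, mrd_unit: str = "fraction") -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    ``mrd_unit='percent'`` divides the MRD columns by 100 on ingest so the
    records always store fractions. Schema violations raise
    :class:`SchemaError` naming the row and column.
    """
    if mrd_unit not in ("fraction", "percent"):
        raise ValueError(f"mrd_unit must be 'fraction' or 'percent', got {mrd_unit!r}")
    frame = pd.read_csv(path, dtype={"id": str, "cns": str})
    missing_cols = set(CSV_COLUMNS[:11]) - set(frame.columns)
    if missing_cols:
        raise SchemaError(f"missing required columns: {sorted(missing_cols)}")
    scale = 0.01 if mrd_unit == "percent" else 1.0
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        cells = {col: _parse_cell(getattr(row, col, None), i, col) for col in CSV_COLUMNS}
        try:
            rec = PatientRecord(
                id=str(cells["id"]),
                age_years=float(cells["age_years"]),
                wbc=float(cells["wbc"]),
                d8_mrd=None if cells["d8_mrd"] is None else float(cells["d8_mrd"]) * scale,
                d29_mrd=None if cells["d29_mrd"] is None else float(cells["d29_mrd"]) * scale,
                frg=_parse_bool(cells["frg"], i, "frg"),
                urg=_parse_bool(cells["urg"], i, "urg"),
                cns=str(cells["cns"]),
                nci_risk=None if cells["nci_risk"] is None else str(cells["nci_risk"]),
                event_type=str(cells["event_type"]),
                time_from_eoi_years=float(cells["time_from_eoi_years"]),
                death_flag=None if cells["death_flag"] is None else int(cells["death_flag"]),
                death_time_years=(
                    None if cells["death_time_years"] is None else float(cells["death_time_years"])
                ),
                cohort_label=None if cells["cohort_label"] is None else str(cells["cohort_label"]),
            )
        except SchemaError as err:
            raise SchemaError(f"row {i}: {err}") from err
        except (TypeError, ValueError) as err:
            raise SchemaError(f"row {i}: malformed value ({err})") from err
        records.append(rec)
    return records


def cohort_frame(records) -> pd.DataFrame:
    """Cohort as a DataFrame in the documented column order."""
    frame = pd.DataFrame([asdict(r) for r in records])
    for col in CSV_COLUMNS:
        if col not in frame.columns:
            frame[col] = None
    frame["frg"] = frame["frg"].astype(int)
    frame["urg"] = frame["urg"].astype(int)
    return frame[list(CSV_COLUMNS)]


def write_cohort(records, path) -> None:
    """Write records to CSV (missing values as empty cells)."""
    cohort_frame(records).to_csv(path, index=False)
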