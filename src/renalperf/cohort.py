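"""Cohort data model and CSV input/output.

A cohort is a collection of postoperative ICU patients observed on a fixed
hour grid after admission (0, 6, 12, 24, 48 h).  Each observation carries the
four pressures entering the effective renal perfusion pressure score --
mean arterial pressure (MAP), intra-abdominal pressure (IAP), central venous
pressure (CVP) and mean airway pressure (Pmean) -- plus serum creatinine.
Hourly urine output over the first 48 h and static demographics/outcomes live
in companion tables.

Conventions
-----------
* All pressures are mmHg internally; values recorded in cmH2O must pass
  through :func:`cmh2o_to_mmhg` at the boundary (1 mmHg = 1.36 cmH2O).
* Creatinine is µmol/L internally; :func:`creat_mgdl_to_umoll` converts
  mg/dL readings (×88.4) at the boundary.
* Missing values are ``None`` in memory and empty cells on disk.  ``0`` is
  always a measured zero (physiologic for CVP), never a missing marker.
* Pmean exists only while a patient is mechanically ventilated; a recorded
  Pmean on a non-ventilated patient is rejected at load time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "TIME_GRID",
    "SURGERY_TYPES",
    "PlausibilityWindows",
    "PressureObservation",
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "cmh2o_to_mmhg",
    "mmhg_to_cmh2o",
    "creat_mgdl_to_umoll",
    "creat_umoll_to_mgdl",
]

#: Observation grid, hours after ICU admission.
TIME_GRID: tuple[int, ...] = (0, 6, 12, 24, 48)

SURGERY_TYPES = frozenset(
    {"gastric", "bowel", "rectal", "hepatic", "pancreatic", "aortic", "trauma", "other"}
)

#: Conversion constant between mmHg and cmH2O columns of water.
CMH2O_PER_MMHG = 1.36

#: Conversion constant between mg/dL and µmol/L serum creatinine.
UMOLL_PER_MGDL = 88.4


class CohortValidationError(ValueError):
    """A record violates the cohort data contract."""


class SchemaError(ValueError):
    """A CSV file does not match the documented schema."""


def cmh2o_to_mmhg(p_cmh2o: float) -> float:
    """Convert a pressure from cmH2O to mmHg (1 mmHg = 1.36 cmH2O)."""
    return p_cmh2o / CMH2O_PER_MMHG


def mmhg_to_cmh2o(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to cmH2O."""
    return p_mmhg * CMH2O_PER_MMHG


def creat_mgdl_to_umoll(creat_mgdl: float) -> float:
    """Convert serum creatinine from mg/dL to µmol/L (×88.4)."""
    return creat_mgdl * UMOLL_PER_MGDL


def creat_umoll_to_mgdl(creat_umoll: float) -> float:
    """Convert serum creatinine from µmol/L to mg/dL."""
    return creat_umoll / UMOLL_PER_MGDL


@dataclass(frozen=True)
class PlausibilityWindows:
    """Admissible ranges for recorded pressures, mmHg.

    Values outside the window are rejected at load time rather than
    silently clamped: an implausible reading is a data error, not noise.
    """

    map_mmHg: tuple[float, float] = (20.0, 200.0)
    iap_mmHg: tuple[float, float] = (0.0, 50.0)
    cvp_mmHg: tuple[float, float] = (-5.0, 40.0)
    pmean_mmHg: tuple[float, float] = (0.0, 40.0)

    def check(self, field_name: str, value: float | None) -> bool:
        if value is None:
            return True
        lo, hi = getattr(self, field_name)
        return lo <= value <= hi


DEFAULT_WINDOWS = PlausibilityWindows()


@dataclass
class PressureObservation:
    """One patient-timepoint pressure panel; ``None`` marks a missing value."""

    time_h: int
    map_mmHg: float | None = None
    iap_mmHg: float | None = None
    cvp_mmHg: float | None = None
    pmean_mmHg: float | None = None

    def __post_init__(self) -> None:
        if self.time_h not in TIME_GRID:
            raise CohortValidationError(
                f"time_h={self.time_h!r} is not on the observation grid {TIME_GRID}"
            )


@dataclass
class PatientRecord:
    """One study subject with pressures, creatinine, urine output and outcomes."""

    patient_id: str
    age_years: float
    sex: str
    ventilated: bool
    sepsis: bool
    surgery_type: str
    weight_kg: float
    creat_preop_umolL: float
    creat_series: list[tuple[int, float]] = field(default_factory=list)
    urine_series: list[tuple[int, float]] = field(default_factory=list)
    pressures: list[PressureObservation] = field(default_factory=list)
    icu_death: bool = False
    hospital_death: bool = False
    icu_los_days: float = 0.0
    hospital_los_days: float = 0.0
    rrt: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise CohortValidationError(
                f"patient {self.patient_id}: sex must be 'male' or 'female', got {self.sex!r}"
            )
        if self.surgery_type not in SURGERY_TYPES:
            raise CohortValidationError(
                f"patient {self.patient_id}: unknown surgery_type {self.surgery_type!r}"
            )
        if not self.age_years > 0:
            raise CohortValidationError(f"patient {self.patient_id}: age must be positive")
        if not self.weight_kg > 0:
            raise CohortValidationError(f"patient {self.patient_id}: weight must be positive")
        if not self.creat_preop_umolL > 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: preoperative creatinine is mandatory and positive"
            )
        if self.icu_los_days < 0 or self.hospital_los_days < 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: lengths of stay must be non-negative"
            )
        if self.icu_death and not self.hospital_death:
            raise CohortValidationError(
                f"patient {self.patient_id}: ICU death implies hospital death"
            )
        times = [obs.time_h for obs in self.pressures]
        if len(times) != len(set(times)):
            raise CohortValidationError(
                f"patient {self.patient_id}: duplicate pressure observation times {times}"
            )
        for hour, uo in self.urine_series:
            if not 1 <= hour <= 48:
                raise CohortValidationError(
                    f"patient {self.patient_id}: urine hour {hour} outside 1..48"
                )
            if uo is not None and uo < 0:
                raise CohortValidationError(
                    f"patient {self.patient_id}: negative urine output at hour {hour}"
                )

    def observation(self, time_h: int) -> PressureObservation | None:
        """Return the pressure panel at ``time_h``, or ``None`` if absent."""
        for obs in self.pressures:
            if obs.time_h == time_h:
                return obs
        return None

    def validate_pressures(self, windows: PlausibilityWindows = DEFAULT_WINDOWS) -> None:
        """Check plausibility windows and the Pmean/ventilation invariant."""
        for obs in self.pressures:
            for name in ("map_mmHg", "iap_mmHg", "cvp_mmHg", "pmean_mmHg"):
                value = getattr(obs, name)
                if not windows.check(name, value):
                    raise CohortValidationError(
                        f"patient {self.patient_id}, time {obs.time_h} h: "
                        f"{name}={value} outside plausibility window {getattr(windows, name)}"
                    )
            if obs.pmean_mmHg is not None and not self.ventilated:
                raise CohortValidationError(
                    f"patient {self.patient_id}, time {obs.time_h} h: Pmean recorded "
                    "but patient is not ventilated (mean airway pressure exists only "
                    "under mechanical ventilation)"
                )


@dataclass
class Cohort:
    """A labelled list of patients with unique identifiers."""

    patients: list[PatientRecord] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def validate(self, windows: PlausibilityWindows = DEFAULT_WINDOWS) -> None:
        for p in self.patients:
            p.validate_pressures(windows)


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------
# Three comma-delimited UTF-8 files, dot decimal, empty cell = missing:
#   timepoints: patient_id, time_h, map_mmHg, iap_mmHg, cvp_mmHg, pmean_mmHg, creat_umolL
#   patients:   patient_id, age_years, sex, ventilated, sepsis, surgery_type,
#               weight_kg, creat_preop_umolL, icu_death, hospital_death,
#               icu_los_days, hospital_los_days, rrt
#   urine:      patient_id, hour, urine_ml_kg_h
# A JSON or YAML manifest names the three files relative to itself.

SCHEMA_VERSION = "1"

TIMEPOINT_COLUMNS = [
    "patient_id", "time_h", "map_mmHg", "iap_mmHg", "cvp_mmHg", "pmean_mmHg", "creat_umolL",
]
PATIENT_COLUMNS = [
    "patient_id", "age_years", "sex", "ventilated", "sepsis", "surgery_type",
    "weight_kg", "creat_preop_umolL", "icu_death", "hospital_death",
    "icu_los_days", "hospital_los_days", "rrt",
]
URINE_COLUMNS = ["patient_id", "hour", "urine_ml_kg_h"]

_BOOL_COLUMNS = ("ventilated", "sepsis", "icu_death", "hospital_death", "rrt")


def _check_header(df: pd.DataFrame, expected: Sequence[str], which: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{which} file does not match schema v{SCHEMA_VERSION}: "
            f"missing columns {missing}, unexpected columns {extra}"
        )


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def _resolve_manifest(path: Path) -> tuple[dict[str, Path], str | None]:
    """A manifest (JSON/YAML) names the three CSVs; a directory implies defaults."""
    if path.is_dir():
        names = {"timepoints": "timepoints.csv", "patients": "patients.csv", "urine": "urine.csv"}
        label = None
        default_manifest = path / "cohort.json"
        if default_manifest.exists():
            label = json.loads(default_manifest.read_text()).get("label")
        return {k: path / v for k, v in names.items()}, label
    text = path.read_text()
    manifest = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    base = path.parent
    try:
        files = {k: base / manifest[k] for k in ("timepoints", "patients", "urine")}
    except KeyError as exc:
        raise SchemaError(f"manifest {path} lacks required key {exc}") from exc
    return files, manifest.get("label")


def read_cohort(
    path: str | Path,
    schema_version: str = SCHEMA_VERSION,
    windows: PlausibilityWindows = DEFAULT_WINDOWS,
    label: str | None = None,
) -> Cohort:
    """Load and validate a cohort from a manifest file or directory.

    ``path`` may be a directory holding ``timepoints.csv``, ``patients.csv``
    and ``urine.csv``, or a JSON/YAML manifest naming the three files.
    Missing cells become ``None``; any out-of-window pressure or schema
    mismatch raises with the offending patient, time and field named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    files, manifest_label = _resolve_manifest(path)

    patients_df = pd.read_csv(files["patients"], dtype={"patient_id": str})
    _check_header(patients_df, PATIENT_COLUMNS, "patients")
    tp_df = pd.read_csv(files["timepoints"], dtype={"patient_id": str})
    _check_header(tp_df, TIMEPOINT_COLUMNS, "timepoints")
    urine_df = pd.read_csv(files["urine"], dtype={"patient_id": str})
    _check_header(urine_df, URINE_COLUMNS, "urine")

    tp_by_patient = dict(tuple(tp_df.groupby("patient_id", sort=False))) if len(tp_df) else {}
    urine_by_patient = (
        dict(tuple(urine_df.groupby("patient_id", sort=False))) if len(urine_df) else {}
    )

    records: list[PatientRecord] = []
    for row in patients_df.itertuples(index=False):
        pid = row.patient_id
        pressures: list[PressureObservation] = []
        creat_series: list[tuple[int, float]] = []
        for tp in tp_by_patient.get(pid, pd.DataFrame(columns=TIMEPOINT_COLUMNS)).itertuples(
            index=False
        ):
            obs = PressureObservation(
                time_h=int(tp.time_h),
                map_mmHg=_opt(tp.map_mmHg),
                iap_mmHg=_opt(tp.iap_mmHg),
                cvp_mmHg=_opt(tp.cvp_mmHg),
                pmean_mmHg=_opt(tp.pmean_mmHg),
            )
            if any(
                getattr(obs, f) is not None
                for f in ("map_mmHg", "iap_mmHg", "cvp_mmHg", "pmean_mmHg")
            ):
                pressures.append(obs)
            creat = _opt(tp.creat_umolL)
            if creat is not None:
                creat_series.append((int(tp.time_h), creat))
        urine_series = [
            (int(u.hour), float(u.urine_ml_kg_h))
            for u in urine_by_patient.get(pid, pd.DataFrame(columns=URINE_COLUMNS)).itertuples(
                index=False
            )
            if not pd.isna(u.urine_ml_kg_h)
        ]
        record = PatientRecord(
            patient_id=pid,
            age_years=float(row.age_years),
            sex=str(row.sex),
            ventilated=bool(row.ventilated),
            sepsis=bool(row.sepsis),
            surgery_type=str(row.surgery_type),
            weight_kg=float(row.weight_kg),
            creat_preop_umolL=float(row.creat_preop_umolL),
            creat_series=creat_series,
            urine_series=urine_series,
            pressures=pressures,
            icu_death=bool(row.icu_death),
            hospital_death=bool(row.hospital_death),
            icu_los_days=float(row.icu_los_days),
            hospital_los_days=float(row.hospital_los_days),
            rrt=bool(row.rrt),
        )
        record.validate_pressures(windows)
        records.append(record)

    if label is not None:
        cohort_label = label
    elif manifest_label is not None:
        cohort_label = manifest_label
    else:
        cohort_label = path.stem if path.is_file() else path.name
    return Cohort(patients=records, label=cohort_label)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to ``path`` (a directory), returning the manifest path.

    The inverse of :func:`read_cohort`: reading the written directory
    reproduces the cohort field-by-field, including every missing cell.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    tp_rows = []
    urine_rows = []
    patient_rows = []
    for p in cohort:
        creat_by_time = dict(p.creat_series)
        times = sorted(set(o.time_h for o in p.pressures) | set(creat_by_time))
        for t in times:
            obs = p.observation(t) or PressureObservation(time_h=t)
            tp_rows.append(
                {
                    "patient_id": p.patient_id,
                    "time_h": t,
                    "map_mmHg": obs.map_mmHg,
                    "iap_mmHg": obs.iap_mmHg,
                    "cvp_mmHg": obs.cvp_mmHg,
                    "pmean_mmHg": obs.pmean_mmHg,
                    "creat_umolL": creat_by_time.get(t),
                }
            )
        for hour, uo in p.urine_series:
            urine_rows.append({"patient_id": p.patient_id, "hour": hour, "urine_ml_kg_h": uo})
        patient_rows.append(
            {
                "patient_id": p.patient_id,
                "age_years": p.age_years,
                "sex": p.sex,
                "ventilated": p.ventilated,
                "sepsis": p.sepsis,
                "surgery_type": p.surgery_type,
                "weight_kg": p.weight_kg,
                "creat_preop_umolL": p.creat_preop_umolL,
                "icu_death": p.icu_death,
                "hospital_death": p.hospital_death,
                "icu_los_days": p.icu_los_days,
                "hospital_los_days": p.hospital_los_days,
                "rrt": p.rrt,
            }
        )

    pd.DataFrame(tp_rows, columns=TIMEPOINT_COLUMNS).to_csv(path / "timepoints.csv", index=False)
    pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS).to_csv(path / "patients.csv", index=False)
    pd.DataFrame(urine_rows, columns=URINE_COLUMNS).to_csv(path / "urine.csv", index=False)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "timepoints": "timepoints.csv",
        "patients": "patients.csv",
        "urine": "urine.csv",
        "label": cohort.label,
    }
    manifest_path = path / "cohort.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest_path
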