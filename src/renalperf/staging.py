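"""AKIN staging of acute kidney injury from creatinine and urine output.

Stage 0-3 is assigned at 48 h after ICU admission against the mandatory
preoperative creatinine baseline, using both AKIN criteria and taking the
maximum of the two (the AKIN convention when they disagree).

Numeric thresholds (single source of truth, pinned here):

creatinine, within the 0-48 h window
    stage 1   absolute rise >= 26.5 µmol/L (0.3 mg/dL) or ratio >= 1.5x baseline
    stage 2   ratio > 2.0x baseline
    stage 3   ratio > 3.0x baseline, or creatinine >= 354 µmol/L (4.0 mg/dL)
              with an acute rise >= 44 µmol/L (0.5 mg/dL)

urine output (mL/kg/h, hourly grid; a missing hour breaks a run)
    stage 1   < 0.5 for >= 6 consecutive h
    stage 2   < 0.5 for >= 12 consecutive h
    stage 3   < 0.3 for >= 24 consecutive h, or anuria (< 0.05) for >= 12 h

Initiation of renal replacement therapy implies stage 3 (optional flag).
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import PatientRecord

__all__ = [
    "AkiOutcome",
    "StagingError",
    "stage_creatinine",
    "stage_urine",
    "stage_patient",
]

# Creatinine thresholds, µmol/L and ratios
CREAT_ABS_RISE_STAGE1 = 26.5
CREAT_RATIO_STAGE1 = 1.5
CREAT_RATIO_STAGE2 = 2.0
CREAT_RATIO_STAGE3 = 3.0
CREAT_ABS_LEVEL_STAGE3 = 354.0
CREAT_ABS_RISE_STAGE3 = 44.0

# Oliguria thresholds, mL/kg/h and consecutive hours
URINE_OLIGURIA = 0.5
URINE_SEVERE = 0.3
URINE_ANURIA = 0.05
OLIGURIA_HOURS_STAGE1 = 6
OLIGURIA_HOURS_STAGE2 = 12
OLIGURIA_HOURS_STAGE3 = 24
ANURIA_HOURS_STAGE3 = 12

WINDOW_H = 48


class StagingError(ValueError):
    """Staging inputs are absent or invalid."""


@dataclass(frozen=True)
class AkiOutcome:
    """Stage 0-3 with the criteria that produced it.

    ``triggered_by`` lists every criterion achieving the final (maximum)
    stage; it is empty iff stage is 0.  ``creat_ratio`` and
    ``creat_abs_rise_umolL`` describe the worst in-window creatinine
    relative to baseline.
    """

    stage: int
    triggered_by: frozenset[str]
    creat_ratio: float | None = None
    creat_abs_rise_umolL: float | None = None

    @property
    def aki(self) -> bool:
        return self.stage >= 1


def stage_creatinine(baseline_umolL: float, series: list[tuple[int, float]]) -> int:
    """AKIN stage from the worst creatinine within 0-48 h of admission."""
    if not baseline_umolL > 0:
        raise StagingError(f"baseline creatinine must be positive, got {baseline_umolL}")
    in_window = [c for t, c in series if 0 <= t <= WINDOW_H]
    if not in_window:
        raise StagingError("no creatinine values within the 48 h window")
    peak = max(in_window)
    ratio = peak / baseline_umolL
    rise = peak - baseline_umolL
    if ratio > CREAT_RATIO_STAGE3 or (
        peak >= CREAT_ABS_LEVEL_STAGE3 and rise >= CREAT_ABS_RISE_STAGE3
    ):
        return 3
    if ratio > CREAT_RATIO_STAGE2:
        return 2
    if ratio >= CREAT_RATIO_STAGE1 or rise >= CREAT_ABS_RISE_STAGE1:
        return 1
    return 0


def _longest_run(series: dict[int, float], below: float) -> int:
    """Longest run of consecutive recorded hours with output < ``below``."""
    best = run = 0
    prev_hour = None
    for hour in sorted(series):
        qualifies = series[hour] < below
        contiguous = prev_hour is not None and hour == prev_hour + 1
        run = (run + 1) if (qualifies and (contiguous and run > 0)) else (1 if qualifies else 0)
        best = max(best, run)
        prev_hour = hour
    return best


def stage_urine(series: list[tuple[int, float]]) -> int:
    """AKIN stage from the longest qualifying consecutive oliguric run."""
    by_hour: dict[int, float] = {}
    for hour, uo in series:
        if uo < 0:
            raise StagingError(f"negative urine output {uo} at hour {hour}")
        by_hour[hour] = uo
    if not by_hour:
        return 0
    if (
        _longest_run(by_hour, URINE_SEVERE) >= OLIGURIA_HOURS_STAGE3
        or _longest_run(by_hour, URINE_ANURIA) >= ANURIA_HOURS_STAGE3
    ):
        return 3
    oliguric = _longest_run(by_hour, URINE_OLIGURIA)
    if oliguric >= OLIGURIA_HOURS_STAGE2:
        return 2
    if oliguric >= OLIGURIA_HOURS_STAGE1:
        return 1
    return 0


def stage_patient(patient: PatientRecord) -> AkiOutcome:
    """Assign the AKIN outcome at 48 h as the maximum of both criteria.

    Raises :class:`StagingError` when neither a creatinine series nor a
    urine series exists -- an outcome is never silently assumed normal.
    """
    has_creat = bool(patient.creat_series)
    has_urine = bool(patient.urine_series)
    if not has_creat and not has_urine:
        raise StagingError(
            f"patient {patient.patient_id}: no creatinine and no urine data; "
            "AKI outcome cannot be staged"
        )
    creat_stage = (
        stage_creatinine(patient.creat_preop_umolL, patient.creat_series) if has_creat else 0
    )
    urine_stage = stage_urine(patient.urine_series) if has_urine else 0
    stage = max(creat_stage, urine_stage)
    if patient.rrt:
        stage = 3
    triggered = set()
    if stage > 0:
        if has_creat and creat_stage == stage:
            triggered.add("creatinine")
        if has_urine and urine_stage == stage:
            triggered.add("urine_output")
        if patient.rrt and creat_stage < 3 and urine_stage < 3:
            triggered.add("rrt")

    ratio = rise = None
    if has_creat:
        in_window = [c for t, c in patient.creat_series if 0 <= t <= WINDOW_H]
        if in_window:
            peak = max(in_window)
            ratio = peak / patient.creat_preop_umolL
            rise = peak - patient.creat_preop_umolL
    return AkiOutcome(
        stage=stage,
        triggered_by=frozenset(triggered),
        creat_ratio=ratio,
        creat_abs_rise_umolL=rise,
    )
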