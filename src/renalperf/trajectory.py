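"""Admission-threshold + 12-hour trajectory decision rule for AKI prediction.

Patients are partitioned by their admission effective RPP against a
threshold (default 40.7 mmHg, the published admission median) and, for
those at or above it, by the course of the score over the first 12 h:

    A  below threshold on admission            -> AKI predicted
    B  at/above threshold, non-increasing RPP  -> AKI predicted
    C  at/above threshold, increasing RPP      -> no AKI predicted

A delta of exactly zero is grouped with "decreasing" (group B): only an
*increase* of perfusion is protective.  Two delta definitions are offered
because both intervals matter in the first 12 h: ``d0_12`` (admission to
12 h, the default) and ``d6_12`` (the interval whose group difference is
statistically significant and which feeds the ROC analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import Cohort
from .perfusion import DEFAULT_THRESHOLD_MMHG, ScoreSeries, compute_series
from .staging import AkiOutcome

__all__ = [
    "TrajectoryClass",
    "RuleEvaluation",
    "UnclassifiableError",
    "classify",
    "evaluate_rule",
]

_DELTA_INTERVAL = {"d0_12": (0, 12), "d6_12": (6, 12)}


class UnclassifiableError(ValueError):
    """The series lacks the values the rule needs."""


@dataclass(frozen=True)
class TrajectoryClass:
    """One patient's stratum under the decision rule."""

    patient_id: str
    group: str  # A_below_threshold | B_above_decreasing | C_above_increasing
    predicted_aki: bool
    rpp0: float
    delta_0_12: float | None
    delta_6_12: float | None


@dataclass(frozen=True)
class RuleEvaluation:
    """2x2 performance of the rule against observed AKI outcomes.

    Ratios with a zero denominator are ``None`` (undefined), never an
    exception or an infinity.  ``excluded`` counts unclassifiable patients.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    excluded: int

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def lr_pos(self) -> float | None:
        sens, spec = self.sensitivity, self.specificity
        if sens is None or spec is None or spec == 1.0:
            return None
        return sens / (1.0 - spec)

    @property
    def lr_neg(self) -> float | None:
        sens, spec = self.sensitivity, self.specificity
        if sens is None or spec is None or spec == 0.0:
            return None
        return (1.0 - sens) / spec


def classify(
    series: ScoreSeries,
    threshold_mmHg: float = DEFAULT_THRESHOLD_MMHG,
    delta_definition: str = "d0_12",
) -> TrajectoryClass:
    """Assign a patient to stratum A, B or C.

    Raises :class:`UnclassifiableError` when the admission value is missing,
    or when an at/above-threshold patient lacks the selected delta -- an
    unclassifiable patient is reported, never guessed.
    """
    if delta_definition not in _DELTA_INTERVAL:
        raise ValueError(f"delta_definition must be 'd0_12' or 'd6_12', got {delta_definition!r}")
    rpp0 = series.value(0)
    if rpp0 is None:
        raise UnclassifiableError(f"patient {series.patient_id}: admission value missing")
    d_0_12 = series.delta(0, 12)
    d_6_12 = series.delta(6, 12)
    if rpp0 < threshold_mmHg:
        group, predicted = "A_below_threshold", True
    else:
        selected = d_0_12 if delta_definition == "d0_12" else d_6_12
        if selected is None:
            raise UnclassifiableError(
                f"patient {series.patient_id}: above threshold but "
                f"{delta_definition} delta missing"
            )
        if selected > 0:
            group, predicted = "C_above_increasing", False
        else:
            group, predicted = "B_above_decreasing", True
    return TrajectoryClass(
        patient_id=series.patient_id,
        group=group,
        predicted_aki=predicted,
        rpp0=rpp0,
        delta_0_12=d_0_12,
        delta_6_12=d_6_12,
    )


def evaluate_rule(
    cohort: Cohort,
    outcomes: dict[str, AkiOutcome],
    threshold_mmHg: float = DEFAULT_THRESHOLD_MMHG,
    delta_definition: str = "d0_12",
    pmean_policy: str = "zero",
    formula_id: str = "EFFECTIVE_RPP",
) -> tuple[RuleEvaluation, list[TrajectoryClass]]:
    """Run the rule over a cohort and tabulate it against observed AKI.

    Returns the 2x2 evaluation plus the per-patient roster.  Patients whose
    series cannot be classified are excluded and counted.
    """
    tp = fp = tn = fn = excluded = 0
    roster: list[TrajectoryClass] = []
    for patient in cohort:
        series = compute_series(patient, formula_id, pmean_policy=pmean_policy)
        try:
            cls = classify(series, threshold_mmHg, delta_definition)
        except UnclassifiableError:
            excluded += 1
            continue
        roster.append(cls)
        observed = outcomes[patient.patient_id].aki
        if cls.predicted_aki and observed:
            tp += 1
        elif cls.predicted_aki and not observed:
            fp += 1
        elif not cls.predicted_aki and not observed:
            tn += 1
        else:
            fn += 1
    return RuleEvaluation(tp=tp, fp=fp, tn=tn, fn=fn, excluded=excluded), roster
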