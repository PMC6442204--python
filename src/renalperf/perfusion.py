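"""Perfusion-pressure score family and per-patient score series.

The central quantity is the effective renal perfusion pressure

    effective RPP = MAP - (IAP + CVP + Pmean)        [mmHg]

which nets the arterial driving pressure against every upstream source of
renal venous congestion: intra-abdominal pressure, central venous pressure
and the transmitted mean airway pressure of mechanical ventilation.  The
classical alternatives are kept as a score family so the combined formula
can be compared against each component view:

    MAP                  arterial pressure alone
    APP                  MAP - IAP            (abdominal perfusion pressure)
    TRANSRENAL           MAP - CVP
    FG                   MAP - 2*IAP          (withdrawn filtration gradient)
    MAP_minus_IAP_CVP    MAP - (IAP + CVP)
    EFFECTIVE_RPP        MAP - (IAP + CVP + Pmean)

Missingness propagates: a score is ``None`` at a time point unless every
input it needs is present.  The single documented exception is the
``pmean_policy="zero"`` rule, under which a patient who is not mechanically
ventilated contributes Pmean = 0 (there is no airway pressure to transmit);
``pmean_policy="exclude"`` restricts the combined score to the ventilated
subset with recorded Pmean, mirroring how the source data were tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import PatientRecord, PressureObservation

__all__ = [
    "FORMULAS",
    "DELTA_INTERVALS",
    "ScoreSeries",
    "effective_rpp",
    "score_family",
    "compute_series",
    "dichotomize_admission",
]

FORMULAS = ("MAP", "APP", "TRANSRENAL", "FG", "MAP_minus_IAP_CVP", "EFFECTIVE_RPP")

#: Inter-timepoint deltas of the headline analysis (first 12 h in ICU).
DELTA_INTERVALS = ((0, 6), (6, 12), (0, 12))

#: Admission threshold for the effective RPP, mmHg: the previously published
#: cohort median of the score measured on admission.
DEFAULT_THRESHOLD_MMHG = 40.7

_REQUIRED = {
    "MAP": ("map_mmHg",),
    "APP": ("map_mmHg", "iap_mmHg"),
    "TRANSRENAL": ("map_mmHg", "cvp_mmHg"),
    "FG": ("map_mmHg", "iap_mmHg"),
    "MAP_minus_IAP_CVP": ("map_mmHg", "iap_mmHg", "cvp_mmHg"),
    "EFFECTIVE_RPP": ("map_mmHg", "iap_mmHg", "cvp_mmHg", "pmean_mmHg"),
}


def effective_rpp(
    map_mmHg: float | None,
    iap_mmHg: float | None,
    cvp_mmHg: float | None,
    pmean_mmHg: float | None,
) -> float | None:
    """MAP - (IAP + CVP + Pmean); ``None`` if any input is missing."""
    if None in (map_mmHg, iap_mmHg, cvp_mmHg, pmean_mmHg):
        return None
    return map_mmHg - (iap_mmHg + cvp_mmHg + pmean_mmHg)


def score_family(panel: PressureObservation, formula_id: str) -> float | None:
    """Evaluate one member of the perfusion-score family on a pressure panel."""
    if formula_id not in _REQUIRED:
        raise ValueError(f"unknown formula_id {formula_id!r}; expected one of {FORMULAS}")
    if any(getattr(panel, name) is None for name in _REQUIRED[formula_id]):
        return None
    m, i, c, p = panel.map_mmHg, panel.iap_mmHg, panel.cvp_mmHg, panel.pmean_mmHg
    if formula_id == "MAP":
        return m
    if formula_id == "APP":
        return m - i
    if formula_id == "TRANSRENAL":
        return m - c
    if formula_id == "FG":
        return m - 2 * i
    if formula_id == "MAP_minus_IAP_CVP":
        return m - (i + c)
    return effective_rpp(m, i, c, p)


@dataclass
class ScoreSeries:
    """A perfusion score per grid time point, with first-12-h deltas.

    ``values`` maps time (h) to mmHg or ``None``; ``deltas`` maps the
    intervals (0,6), (6,12), (0,12) to value(t_b) - value(t_a), present only
    when both endpoints are.
    """

    patient_id: str
    formula_id: str
    values: dict[int, float | None] = field(default_factory=dict)
    deltas: dict[tuple[int, int], float | None] = field(default_factory=dict)

    def value(self, time_h: int) -> float | None:
        return self.values.get(time_h)

    def delta(self, t_a: int, t_b: int) -> float | None:
        """Generic delta value(t_b) - value(t_a) for any grid pair."""
        a, b = self.values.get(t_a), self.values.get(t_b)
        return None if a is None or b is None else b - a


def compute_series(
    patient: PatientRecord,
    formula_id: str = "EFFECTIVE_RPP",
    pmean_policy: str = "zero",
) -> ScoreSeries:
    """Evaluate a perfusion score on a patient's observation grid.

    ``pmean_policy`` applies only to formulas that use Pmean and only to
    non-ventilated patients: ``"zero"`` substitutes 0 mmHg (extends the
    score to all patients), ``"exclude"`` leaves the score missing.
    """
    if pmean_policy not in ("zero", "exclude"):
        raise ValueError(f"pmean_policy must be 'zero' or 'exclude', got {pmean_policy!r}")
    series = ScoreSeries(patient_id=patient.patient_id, formula_id=formula_id)
    from .cohort import TIME_GRID

    for t in TIME_GRID:
        obs = patient.observation(t)
        if obs is None:
            series.values[t] = None
            continue
        if (
            "pmean_mmHg" in _REQUIRED.get(formula_id, ())
            and obs.pmean_mmHg is None
            and not patient.ventilated
            and pmean_policy == "zero"
        ):
            obs = PressureObservation(
                time_h=obs.time_h,
                map_mmHg=obs.map_mmHg,
                iap_mmHg=obs.iap_mmHg,
                cvp_mmHg=obs.cvp_mmHg,
                pmean_mmHg=0.0,
            )
        series.values[t] = score_family(obs, formula_id)
    for (t_a, t_b) in DELTA_INTERVALS:
        series.deltas[(t_a, t_b)] = series.delta(t_a, t_b)
    return series


def dichotomize_admission(series: ScoreSeries, threshold_mmHg: float) -> str | None:
    """Classify the admission value against a threshold.

    Returns ``"below"`` iff value(0) < threshold, ``"at_or_above"`` iff
    value(0) >= threshold (the boundary counts as at-or-above: injury is
    reported for patients strictly *below* the threshold), or ``None`` when
    the admission value is missing.
    """
    v0 = series.value(0)
    if v0 is None:
        return None
    return "below" if v0 < threshold_mmHg else "at_or_above"
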