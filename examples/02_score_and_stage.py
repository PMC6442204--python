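"""Compute the perfusion-score family and the AKIN outcome for one patient.

The effective renal perfusion pressure MAP - (IAP + CVP + Pmean) nets the
arterial driving pressure against every congestion term; the AKIN stage is
the maximum of the creatinine and urine-output criteria at 48 h.
"""

from renalperf import GeneratorConfig, compute_series, generate, stage_patient

cohort = generate(GeneratorConfig(seed=1))
patient = cohort.patients[0]

print(f"patient {patient.patient_id} (ventilated={patient.ventilated})")
for formula in ("MAP", "APP", "TRANSRENAL", "EFFECTIVE_RPP"):
    series = compute_series(patient, formula)
    vals = {t: (round(v, 1) if v is not None else None) for t, v in series.values.items()}
    print(f"  {formula:14s} {vals}")
series = compute_series(patient, "EFFECTIVE_RPP")
deltas = {
    f"{a}-{b}h": (round(d, 1) if (d := series.deltas[(a, b)]) is not None else None)
    for a, b in series.deltas
}
print(f"  deltas (mmHg): {deltas}")

outcome = stage_patient(patient)
print(f"  AKIN stage {outcome.stage}, triggered by {sorted(outcome.triggered_by) or 'nothing'}")
# A positive 0-12 h delta means renal perfusion improved after admission;
# stage >= 1 means acute kidney injury by creatinine rise or oliguria.
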