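"""Group comparisons, ROC, effect size and stepwise regression on a cohort."""

from renalperf import (
    GeneratorConfig,
    compare_groups_over_time,
    compute_series,
    generate,
    hedges_g,
    roc,
    stage_patient,
)
from renalperf.pipeline import logistic_candidates
from renalperf.stats import stepwise_logistic

cohort = generate(GeneratorConfig(seed=1))
outcomes = {p.patient_id: stage_patient(p) for p in cohort}

table = compare_groups_over_time(cohort, outcomes, "EFFECTIVE_RPP")
print("effective RPP, no-AKI vs AKI (median [q1-q3], Mann-Whitney p):")
for row in table.itertuples():
    if row.computed:
        print(
            f"  {row.time_h:2d} h  n={row.n_no_aki}/{row.n_aki}  "
            f"{row.median_no_aki:.1f} [{row.q1_no_aki:.1f}-{row.q3_no_aki:.1f}] vs "
            f"{row.median_aki:.1f} [{row.q1_aki:.1f}-{row.q3_aki:.1f}]  p={row.p_value:.4f}"
        )

deltas, labels = [], []
for p in cohort:
    d = compute_series(p, "EFFECTIVE_RPP").delta(6, 12)
    if d is not None:
        deltas.append(d)
        labels.append("noAKI" if not outcomes[p.patient_id].aki else "AKI")
summary = roc(list(zip(deltas, labels)), positive_class="noAKI")
print(
    f"ROC of the 6-12 h RPP change (higher -> no AKI): AUC={summary.auc:.3f} "
    f"CI95=({summary.auc_ci95[0]:.3f}, {summary.auc_ci95[1]:.3f}) "
    f"sens={summary.sensitivity:.2f} spec={summary.specificity:.2f}"
)
no_aki = [d for d, l in zip(deltas, labels) if l == "noAKI"]
aki = [d for d, l in zip(deltas, labels) if l == "AKI"]
print(f"Hedges' g of the 6-12 h change: {hedges_g(no_aki, aki).hedges_g:.2f}")

X = logistic_candidates(cohort)
y = [int(outcomes[pid].aki) for pid in X.index]
fit = stepwise_logistic(X, y)
print(f"stepwise logistic selected: {fit.selected_terms}")
for term, s in fit.terms.items():
    print(
        f"  {term}: B={s.b:.3f} SE={s.se:.3f} Wald={s.wald:.2f} p={s.p:.3f} "
        f"ExpB={s.exp_b:.3f} CI=({s.exp_b_ci95[0]:.3f}, {s.exp_b_ci95[1]:.3f})"
    )
# A g near 1 marks a large group difference; a selected delta term with
# Exp(B) < 1 means a falling perfusion pressure raises the odds of AKI.
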