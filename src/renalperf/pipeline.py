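"""End-to-end orchestration: simulate -> score -> stage -> classify -> test -> report.

:func:`run_pipeline` takes a cohort (loaded from CSV or generated
synthetically), runs AKIN staging, the perfusion scores, the trajectory
rule, the group comparisons and the regression analyses, and writes a
reproducible report bundle:

    table1_demographics.csv     counts/percentages and median (IQR) rows
    table2_parameters.csv       per-group median (IQR) per pressure per time
    table3_deltas.csv           effective-RPP changes over the first 12 h
    trajectory_roster.csv       per-patient stratum A/B/C and prediction
    outcomes.csv                per-patient AKIN stage and trigger
    stats_bundle.json           rule evaluation, ROC, effect sizes, logistic fit
    run_log.txt                 resolved config, seed and config hash

Every artifact embeds the resolved-config hash; two runs with the same
hash are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .cohort import Cohort, read_cohort, write_cohort
from .perfusion import DEFAULT_THRESHOLD_MMHG, compute_series
from .staging import AkiOutcome, stage_patient
from .stats import (
    chi_square_2x2,
    compare_groups_over_time,
    hedges_g,
    mann_whitney,
    roc,
    stepwise_logistic,
)
from .synthetic import GeneratorConfig, generate
from .trajectory import evaluate_rule

__all__ = ["RunConfig", "run_pipeline", "percent", "demographics_table", "logistic_candidates"]

logger = logging.getLogger("renalperf")

_PARAMS_TABLE2 = ("map_mmHg", "iap_mmHg", "cvp_mmHg", "pmean_mmHg", "APP", "EFFECTIVE_RPP")
_TIMES_LOGIT = (0, 6, 12)
_INTERVALS = ((0, 6), (6, 12), (0, 12))


def percent(numerator: int, denominator: int) -> float | None:
    """100*numerator/denominator, half-up to one decimal; ``None`` if n/0."""
    if denominator == 0:
        return None
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run (the provenance stamp)."""

    input_path: str | None = None  # cohort manifest/directory; None -> simulate
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    pmean_policy: str = "zero"
    threshold_mmHg: float | str = DEFAULT_THRESHOLD_MMHG  # or "cohort-median"
    delta_definition: str = "d0_12"
    entry_p: float = 0.05
    removal_p: float = 0.10
    out_dir: str = "renalperf_out"
    seed: int = 0
    log_level: str = "INFO"

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        gen = d["generator"]
        gen["group_pressure_medians"] = {
            f"{g}|{t}|{f}": v for (g, t, f), v in gen["group_pressure_medians"].items()
        }
        gen["windows"] = dataclasses.asdict(self.generator.windows)
        return d

    def config_hash(self) -> str:
        payload = self.resolved()
        # where the bundle lands and how chatty the log is do not affect the
        # analysis: equal hashes must mean byte-identical outputs
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def demographics_table(counts: dict) -> pd.DataFrame:
    """Demographics rows (count and percentage per group) from fixed counts.

    ``counts`` has the shape of :func:`renalperf.synthetic.make_table1_fixture`:
    group sizes plus per-group event counts; percentages are computed from
    the counts with half-up rounding to one decimal.
    """
    n = counts["group_sizes"]
    rows = []
    for item in ("sex_male", "sepsis", "ventilated", "icu_death", "hospital_death"):
        if item not in counts:
            continue
        row = {"item": item}
        for g in ("noAKI", "AKI"):
            k = counts[item][g]
            row[f"count_{g}"] = k
            row[f"pct_{g}"] = percent(k, n[g])
        a, b = counts[item]["noAKI"], n["noAKI"] - counts[item]["noAKI"]
        c, d = counts[item]["AKI"], n["AKI"] - counts[item]["AKI"]
        try:
            chi2, p = chi_square_2x2(a, b, c, d)
            row["chi2"], row["p_value"] = round(chi2, 3), p
        except ValueError:
            row["chi2"], row["p_value"] = None, None
        rows.append(row)
    surgery = counts.get("surgery_counts", {})
    for stype, k in surgery.items():
        rows.append({"item": f"surgery_{stype}", "count_total": k})
    rows.append({"item": "surgery_total", "count_total": sum(surgery.values())})
    rows.append({"item": "n", "count_noAKI": n["noAKI"], "count_AKI": n["AKI"]})
    return pd.DataFrame(rows)


def _cohort_counts(cohort: Cohort, outcomes: dict[str, AkiOutcome]) -> dict:
    """Table-1-shaped counts tallied from an actual cohort."""
    groups = {"noAKI": [], "AKI": []}
    for p in cohort:
        groups["AKI" if outcomes[p.patient_id].aki else "noAKI"].append(p)
    out = {"group_sizes": {g: len(ps) for g, ps in groups.items()}}
    for item, pred in [
        ("sex_male", lambda p: p.sex == "male"),
        ("sepsis", lambda p: p.sepsis),
        ("ventilated", lambda p: p.ventilated),
        ("icu_death", lambda p: p.icu_death),
        ("hospital_death", lambda p: p.hospital_death),
    ]:
        out[item] = {g: sum(pred(p) for p in ps) for g, ps in groups.items()}
    surgery: dict[str, int] = {}
    for p in cohort:
        surgery[p.surgery_type] = surgery.get(p.surgery_type, 0) + 1
    out["surgery_counts"] = dict(sorted(surgery.items()))
    return out


def _delta_table(cohort: Cohort, outcomes, pmean_policy: str) -> pd.DataFrame:
    """Table-3-shaped comparison of effective-RPP changes per interval."""
    rows = []
    for (a, b) in _INTERVALS:
        no_aki, aki = [], []
        for p in cohort:
            series = compute_series(p, "EFFECTIVE_RPP", pmean_policy=pmean_policy)
            d = series.delta(a, b)
            if d is None:
                continue
            (aki if outcomes[p.patient_id].aki else no_aki).append(d)
        row = {"interval": f"{a}-{b} h", "n_no_aki": len(no_aki), "n_aki": len(aki)}
        if no_aki and aki:
            cmp_ = mann_whitney(no_aki, aki)
            row.update(
                median_no_aki=cmp_.median1, q1_no_aki=cmp_.iqr1[0], q3_no_aki=cmp_.iqr1[1],
                median_aki=cmp_.median2, q1_aki=cmp_.iqr2[0], q3_aki=cmp_.iqr2[1],
                u_statistic=cmp_.u_statistic, p_value=cmp_.p_value, method=cmp_.method,
                computed=True,
            )
        else:
            row.update(computed=False)
        rows.append(row)
    return pd.DataFrame(rows)


def logistic_candidates(cohort: Cohort, pmean_policy: str = "zero") -> pd.DataFrame:
    """Candidate predictor matrix for the stepwise regression.

    Basic pressures, Pmean and the effective RPP at 0/6/12 h plus all the
    changes between those time points, one column each, indexed by
    patient_id.  Under the "zero" policy non-ventilated patients contribute
    Pmean = 0 (no airway pressure is transmitted).
    """
    rows = {}
    for p in cohort:
        rpp = compute_series(p, "EFFECTIVE_RPP", pmean_policy=pmean_policy)
        row = {}
        for t in _TIMES_LOGIT:
            obs = p.observation(t)
            for f, short in (("map_mmHg", "map"), ("iap_mmHg", "iap"), ("cvp_mmHg", "cvp")):
                row[f"{short}_{t}h"] = None if obs is None else getattr(obs, f)
            pm = None if obs is None else obs.pmean_mmHg
            if pm is None and not p.ventilated and pmean_policy == "zero":
                pm = 0.0
            row[f"pmean_{t}h"] = pm
            row[f"rpp_{t}h"] = rpp.value(t)
        for (a, b) in _INTERVALS:
            for short in ("map", "iap", "cvp", "pmean", "rpp"):
                va, vb = row.get(f"{short}_{a}h"), row.get(f"{short}_{b}h")
                row[f"d_{short}_{a}_{b}h"] = None if va is None or vb is None else vb - va
        rows[p.patient_id] = row
    return pd.DataFrame.from_dict(rows, orient="index").astype(float)


def _json_default(obj):
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Returns the stats bundle as a dict.  Any stage failure raises with the
    stage name; partial bundles are not written.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    # --- input ---
    if config.input_path is not None:
        cohort = read_cohort(config.input_path)
        logger.info("loaded cohort %s (n=%d)", config.input_path, len(cohort))
    else:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        cohort = generate(gen)
        logger.info("generated synthetic cohort (n=%d, seed=%d)", len(cohort), config.seed)
        write_cohort(cohort, out / "cohort")

    # --- staging ---
    try:
        outcomes = {p.patient_id: stage_patient(p) for p in cohort}
    except Exception as exc:
        raise RuntimeError(f"stage 'aki_staging' failed: {exc}") from exc

    pd.DataFrame(
        [
            {
                "patient_id": pid,
                "akin_stage": o.stage,
                "aki_binary": int(o.aki),
                "triggered_by": "|".join(sorted(o.triggered_by)),
            }
            for pid, o in outcomes.items()
        ]
    ).to_csv(out / "outcomes.csv", index=False)

    # --- threshold ---
    if config.threshold_mmHg == "cohort-median":
        admission = [
            v
            for p in cohort
            if (v := compute_series(p, "EFFECTIVE_RPP", config.pmean_policy).value(0)) is not None
        ]
        threshold = float(pd.Series(admission).median())
        logger.info("cohort-median admission threshold: %.1f mmHg", threshold)
    else:
        threshold = float(config.threshold_mmHg)

    # --- tables ---
    demo = demographics_table(_cohort_counts(cohort, outcomes))
    demo.to_csv(out / "table1_demographics.csv", index=False)
    table2 = pd.concat(
        [
            compare_groups_over_time(cohort, outcomes, param, pmean_policy=config.pmean_policy)
            for param in _PARAMS_TABLE2
        ],
        ignore_index=True,
    )
    table2.to_csv(out / "table2_parameters.csv", index=False)
    table3 = _delta_table(cohort, outcomes, config.pmean_policy)
    table3.to_csv(out / "table3_deltas.csv", index=False)

    # --- trajectory rule, both delta definitions ---
    rule = {}
    roster_frames = []
    for dd in ("d0_12", "d6_12"):
        evaluation, roster = evaluate_rule(
            cohort, outcomes, threshold, dd, pmean_policy=config.pmean_policy
        )
        rule[dd] = {
            "tp": evaluation.tp, "fp": evaluation.fp,
            "tn": evaluation.tn, "fn": evaluation.fn,
            "excluded": evaluation.excluded,
            "sensitivity": evaluation.sensitivity,
            "specificity": evaluation.specificity,
            "lr_pos": evaluation.lr_pos, "lr_neg": evaluation.lr_neg,
        }
        frame = pd.DataFrame([dataclasses.asdict(r) for r in roster])
        frame.insert(1, "delta_definition", dd)
        roster_frames.append(frame)
    pd.concat(roster_frames, ignore_index=True).to_csv(out / "trajectory_roster.csv", index=False)

    # --- ROC on the 6-12 h RPP change ---
    scores = []
    for p in cohort:
        d = compute_series(p, "EFFECTIVE_RPP", config.pmean_policy).delta(6, 12)
        if d is not None:
            scores.append((d, "noAKI" if not outcomes[p.patient_id].aki else "AKI"))
    roc_summary = None
    labels = {lab for _, lab in scores}
    if len(labels) == 2:
        # higher (rising) RPP change indicates freedom from AKI
        roc_summary = roc(scores, positive_class="noAKI")

    # --- effect sizes for the effective RPP ---
    effects = {}
    for name, getter in [
        ("rpp_admission", lambda s: s.value(0)),
        ("rpp_12h", lambda s: s.value(12)),
        ("rpp_delta_6_12", lambda s: s.delta(6, 12)),
    ]:
        no_aki, aki = [], []
        for p in cohort:
            v = getter(compute_series(p, "EFFECTIVE_RPP", config.pmean_policy))
            if v is not None:
                (aki if outcomes[p.patient_id].aki else no_aki).append(v)
        if len(no_aki) >= 2 and len(aki) >= 2:
            try:
                effects[name] = dataclasses.asdict(hedges_g(no_aki, aki))
            except ValueError:
                effects[name] = None

    # --- forward stepwise logistic regression ---
    X = logistic_candidates(cohort, config.pmean_policy)
    y = pd.Series(
        {pid: int(o.aki) for pid, o in outcomes.items()}, dtype=float
    ).reindex(X.index)
    logistic_report = None
    complete = (~X.isna().any(axis=1)) & y.notna()
    if complete.sum() >= 10 and y[complete].nunique() == 2:
        fit = stepwise_logistic(
            X.loc[complete], y[complete], entry_p=config.entry_p, removal_p=config.removal_p
        )
        logistic_report = {
            "selected_terms": fit.selected_terms,
            "terms": {t: dataclasses.asdict(s) for t, s in fit.terms.items()},
            "intercept": dataclasses.asdict(fit.intercept) if fit.intercept else None,
            "n_obs": fit.n_obs,
            "separation": fit.separation,
            "history": fit.history,
        }

    bundle = {
        "config_hash": chash,
        "seed": config.seed,
        "n_patients": len(cohort),
        "n_aki": sum(o.aki for o in outcomes.values()),
        "threshold_mmHg": threshold,
        "pmean_policy": config.pmean_policy,
        "trajectory_rule": rule,
        "roc_delta_6_12": dataclasses.asdict(roc_summary) if roc_summary else None,
        "hedges_g": effects,
        "stepwise_logistic": logistic_report,
        "n_statistical_tests": int(len(table2) + len(table3) + len(demo)),
        "multiple_testing_correction": "none",
    }
    (out / "stats_bundle.json").write_text(
        json.dumps(bundle, indent=2, sort_keys=True, default=_json_default) + "\n"
    )

    log_lines = [
        f"config_hash: {chash}",
        f"seed: {config.seed}",
        "resolved_config: " + json.dumps(config.resolved(), sort_keys=True, default=str),
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    # stamp provenance into every CSV via a sidecar (CSV bodies stay clean)
    (out / "provenance.json").write_text(
        json.dumps({"config_hash": chash, "files": sorted(f.name for f in out.glob("*.csv"))})
        + "\n"
    )
    logger.info("report bundle written to %s (hash %s)", out, chash)
    return bundle
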