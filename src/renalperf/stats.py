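"""Statistical machinery for small-sample two-group clinical comparisons.

Everything the evaluation needs in one place: median/IQR summaries,
Mann-Whitney U (exact by enumeration for small groups, normal approximation
with tie and continuity corrections otherwise), Pearson chi-square on 2x2
tables, ROC analysis with Youden operating point and likelihood ratios,
Hedges' g with the small-sample bias correction J = 1 - 3/(4*df - 1), and
forward stepwise logistic regression (score-test entry, Wald removal).

Two-sided p-values throughout.  Quartiles use linear interpolation of order
statistics (numpy's default, the "type 7" rule); SPSS's HAVERAGE rule can
differ in the last digit on small samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "GroupComparison",
    "RocSummary",
    "EffectSize",
    "TermStats",
    "LogisticFit",
    "median_iqr",
    "mann_whitney",
    "chi_square_2x2",
    "roc",
    "hedges_g",
    "stepwise_logistic",
    "compare_groups_over_time",
]

_Z975 = sps.norm.ppf(0.975)

#: Both groups at or below this size triggers exact Mann-Whitney enumeration.
EXACT_MW_MAX_N = 8


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles (q1, q3) by linear interpolation; NaNs dropped."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("median_iqr of an empty sample")
    med, q1, q3 = np.percentile(arr, [50, 25, 75])
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """Two-group Mann-Whitney comparison with median/IQR summaries."""

    n1: int
    n2: int
    median1: float
    median2: float
    iqr1: tuple[float, float]
    iqr2: tuple[float, float]
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx"


def _midranks(combined: np.ndarray) -> np.ndarray:
    return sps.rankdata(combined, method="average")


def _u_from_ranks(rank_sum: float, n1: int) -> float:
    return rank_sum - n1 * (n1 + 1) / 2.0


def _exact_mw_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p by exhaustive enumeration of C(n, n1) labelings.

    Counts labelings whose U is at least as far from the null mean
    n1*n2/2 as the observed U; correct under ties because midranks of the
    pooled sample are fixed across labelings.
    """
    n = ranks.size
    n2 = n - n1
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        u = _u_from_ranks(ranks[list(idx)].sum(), n1)
        total += 1
        # tolerance guards float midrank sums
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def mann_whitney(x, y, mode: str = "auto") -> GroupComparison:
    """Mann-Whitney U test of two independent samples.

    ``mode="auto"`` enumerates all labelings exactly when both groups have
    at most 8 observations (the regime where asymptotics are dubious) and
    otherwise uses the normal approximation with tie and continuity
    corrections.  If every value is tied across both groups, p = 1 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires two non-empty samples")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    u1 = _u_from_ranks(ranks[:n1].sum(), n1)

    if np.all(combined == combined[0]):
        p, method = 1.0, "exact"
    elif mode == "exact" or (mode == "auto" and n1 <= EXACT_MW_MAX_N and n2 <= EXACT_MW_MAX_N):
        p, method = _exact_mw_p(ranks, n1, u1), "exact"
    elif mode in ("auto", "approx"):
        n = n1 + n2
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p, method = 1.0, "normal_approx"
        else:
            z = (abs(u1 - n1 * n2 / 2.0) - 0.5) / math.sqrt(var)
            z = max(z, 0.0)
            p, method = float(2 * sps.norm.sf(z)), "normal_approx"
    else:
        raise ValueError(f"mode must be 'auto', 'exact' or 'approx', got {mode!r}")

    m1, q11, q31 = median_iqr(x)
    m2, q12, q32 = median_iqr(y)
    return GroupComparison(
        n1=n1, n2=n2,
        median1=m1, median2=m2,
        iqr1=(q11, q31), iqr2=(q12, q32),
        u_statistic=float(u1), p_value=min(p, 1.0), method=method,
    )


# ---------------------------------------------------------------------------
# Chi-square 2x2
# ---------------------------------------------------------------------------

def chi_square_2x2(a: int, b: int, c: int, d: int, correction: str = "none") -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]].

    Closed form n*(ad - bc)^2 / (r1*r2*c1*c2); ``correction="yates"``
    subtracts n/2 from |ad - bc| (floored at 0) before squaring.  A zero
    row or column margin is an error naming the degenerate margin.
    """
    for v in (a, b, c, d):
        if not (isinstance(v, (int, np.integer)) and v >= 0):
            raise ValueError("counts must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    margins = {"row 1": a + b, "row 2": c + d, "column 1": a + c, "column 2": b + d}
    for name, m in margins.items():
        if m == 0:
            raise ValueError(f"degenerate margin: {name} sums to zero")
    diff = abs(a * d - b * c)
    if correction == "yates":
        diff = max(diff - n / 2.0, 0.0)
    elif correction != "none":
        raise ValueError(f"correction must be 'none' or 'yates', got {correction!r}")
    chi2 = n * diff**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocSummary:
    """AUC with Hanley-McNeil CI and the Youden-optimal operating point.

    Orientation is explicit: ``positive_class`` names the class that higher
    scores are taken to indicate, so a summary can always be read without
    guessing whether "AUC" or "1-AUC" was meant.
    """

    auc: float
    auc_ci95: tuple[float, float]
    threshold_at_operating_point: float
    sensitivity: float
    specificity: float
    lr_pos: float | None
    lr_neg: float | None
    positive_class: str
    n_positive: int
    n_negative: int


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def roc(scores, positive_class: str, ci_method: str = "hanley_mcneil") -> RocSummary:
    """ROC analysis of ``scores``: an iterable of (value, label) pairs.

    Higher values are taken to indicate ``positive_class``.  AUC is the
    Mann-Whitney probability (ties count 1/2); the operating point
    maximizes Youden's J = sensitivity + specificity - 1 over thresholds of
    the form "predict positive if value >= t".  Likelihood ratios with zero
    denominators are ``None``.
    """
    if ci_method != "hanley_mcneil":
        raise ValueError(f"unknown ci_method {ci_method!r}")
    pairs = [(float(v), lab) for v, lab in scores]
    pos = np.array([v for v, lab in pairs if lab == positive_class])
    neg = np.array([v for v, lab in pairs if lab != positive_class])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("roc requires both classes present")

    combined = np.concatenate([pos, neg])
    ranks = _midranks(combined)
    auc = _u_from_ranks(ranks[: pos.size].sum(), pos.size) / (pos.size * neg.size)

    best = None
    for t in np.unique(combined):
        tp = int(np.sum(pos >= t))
        fn = pos.size - tp
        fp = int(np.sum(neg >= t))
        tn = neg.size - fp
        sens = tp / pos.size
        spec = tn / neg.size
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    _, thr, sens, spec = best

    lr_pos = sens / (1 - spec) if spec < 1 else None
    lr_neg = (1 - sens) / spec if spec > 0 else None
    se = _hanley_mcneil_se(auc, pos.size, neg.size)
    ci = (max(0.0, auc - _Z975 * se), min(1.0, auc + _Z975 * se))
    return RocSummary(
        auc=float(auc),
        auc_ci95=ci,
        threshold_at_operating_point=float(thr),
        sensitivity=float(sens),
        specificity=float(spec),
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        positive_class=positive_class,
        n_positive=int(pos.size),
        n_negative=int(neg.size),
    )


# ---------------------------------------------------------------------------
# Hedges' g
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSize:
    """Standardized mean difference with small-sample correction J."""

    hedges_g: float
    correction_j: float
    cohens_d: float


def hedges_g(x, y) -> EffectSize:
    """Hedges' g: pooled-SD Cohen's d shrunk by J = 1 - 3/(4*df - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("hedges_g requires at least 2 observations per group")
    df = n1 + n2 - 2
    s_pooled = math.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df)
    diff = x.mean() - y.mean()
    if s_pooled == 0:
        if diff == 0:
            d = 0.0
        else:
            raise ValueError("zero pooled variance with unequal means: effect size undefined")
    else:
        d = diff / s_pooled
    j = 1 - 3 / (4 * df - 1)
    return EffectSize(hedges_g=j * d, correction_j=j, cohens_d=d)


# ---------------------------------------------------------------------------
# Forward stepwise logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermStats:
    """Per-term logistic coefficients with Wald inference."""

    b: float
    se: float
    wald: float
    p: float
    exp_b: float
    exp_b_ci95: tuple[float, float]


@dataclass
class LogisticFit:
    """Result of forward stepwise selection.

    ``selected_terms`` is in entry order; an empty selection is a valid
    result.  ``separation`` flags a fit whose likelihood is degenerate
    (perfectly separated data), in which case the coefficients of the
    offending model are not reported.
    """

    selected_terms: list[str]
    terms: dict[str, TermStats]
    intercept: TermStats | None
    entry_p: float
    removal_p: float
    n_obs: int
    separation: bool = False
    history: list[str] = field(default_factory=list)


def _fit_logit(X: np.ndarray, y: np.ndarray, max_iter: int, tol: float):
    import warnings

    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is detected and flagged below
            res = model.fit(disp=0, maxiter=max_iter, tol=tol, warn_convergence=False)
    except (np.linalg.LinAlgError, PerfectSeparationError):
        return None
    if not res.mle_retvals.get("converged", False):
        return None
    if np.any(np.abs(res.params) > 50) or np.any(res.bse > 1e3):
        return None  # coefficients diverging: separation or collinearity
    return res

def _score_test_p(X_cur: np.ndarray, y: np.ndarray, beta: np.ndarray, x_new: np.ndarray) -> float:
    """Rao score test p-value for adding ``x_new`` to a fitted logit model."""
    p_hat = expit(X_cur @ beta)
    w = p_hat * (1 - p_hat)
    Xa = np.column_stack([X_cur, x_new])
    g = Xa.T @ (y - p_hat)
    info = (Xa.T * w) @ Xa
    try:
        stat = float(g @ np.linalg.solve(info, g))
    except np.linalg.LinAlgError:
        return 1.0
    return float(sps.chi2.sf(max(stat, 0.0), df=1))


def _term_stats(b: float, se: float) -> TermStats:
    wald = (b / se) ** 2 if se > 0 else math.inf
    return TermStats(
        b=b,
        se=se,
        wald=wald,
        p=float(sps.chi2.sf(wald, df=1)) if math.isfinite(wald) else 0.0,
        exp_b=math.exp(b),
        exp_b_ci95=(math.exp(b - _Z975 * se), math.exp(b + _Z975 * se)),
    )


def stepwise_logistic(
    candidates: pd.DataFrame,
    outcome,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Forward stepwise logistic regression with backward re-checks.

    At each step the candidate with the smallest Rao score-test p-value
    enters if that p is at most ``entry_p``; included terms whose Wald p
    exceeds ``removal_p`` are then removed.  Fits are maximum likelihood
    (Newton/IRLS) with an always-included intercept, on complete cases.
    """
    if not 0 < entry_p < 1 or not 0 < removal_p < 1:
        raise ValueError("entry_p and removal_p must be in (0, 1)")
    y = np.asarray(outcome, dtype=float)
    X_all = candidates.astype(float)
    mask = ~(np.isnan(y) | X_all.isna().any(axis=1).to_numpy())
    y = y[mask]
    X_all = X_all.loc[mask]
    n = y.size
    if n < 10:
        raise ValueError(f"need at least 10 complete-case rows, got {n}")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")

    names = list(X_all.columns)
    selected: list[str] = []
    history: list[str] = []
    separation = False

    def design(terms: list[str]) -> np.ndarray:
        cols = [np.ones(n)] + [X_all[t].to_numpy() for t in terms]
        return np.column_stack(cols)

    res = _fit_logit(design([]), y, max_iter, tol)
    if res is None:  # intercept-only cannot separate; defensive only
        return LogisticFit([], {}, None, entry_p, removal_p, n, separation=True)

    changed = True
    while changed:
        changed = False
        # forward: best score-test candidate
        remaining = [c for c in names if c not in selected]
        if remaining:
            X_cur = design(selected)
            score_ps = {
                c: _score_test_p(X_cur, y, res.params, X_all[c].to_numpy()) for c in remaining
            }
            best_c = min(score_ps, key=score_ps.get)
            if score_ps[best_c] <= entry_p:
                trial = _fit_logit(design(selected + [best_c]), y, max_iter, tol)
                if trial is None:
                    separation = True
                    history.append(f"entry of {best_c} abandoned: separation detected")
                    names = [c for c in names if c != best_c]  # drop the offender
                    changed = bool([c for c in names if c not in selected])
                    continue
                selected.append(best_c)
                res = trial
                history.append(f"entered {best_c} (score p = {score_ps[best_c]:.4g})")
                changed = True
        # backward: drop worst Wald term if above removal threshold
        if selected:
            walds = {
                t: _term_stats(res.params[1 + selected.index(t)], res.bse[1 + selected.index(t)])
                for t in selected
            }
            worst = max(walds, key=lambda t: walds[t].p)
            if walds[worst].p > removal_p:
                selected.remove(worst)
                res = _fit_logit(design(selected), y, max_iter, tol)
                history.append(f"removed {worst} (Wald p = {walds[worst].p:.4g})")
                changed = True

    terms = {
        t: _term_stats(res.params[1 + selected.index(t)], res.bse[1 + selected.index(t)])
        for t in selected
    }
    intercept = _term_stats(res.params[0], res.bse[0])
    return LogisticFit(
        selected_terms=selected,
        terms=terms,
        intercept=intercept,
        entry_p=entry_p,
        removal_p=removal_p,
        n_obs=n,
        separation=separation,
        history=history,
    )


# ---------------------------------------------------------------------------
# Group comparisons over the time grid
# ---------------------------------------------------------------------------

def compare_groups_over_time(
    cohort,
    outcomes,
    parameter: str,
    pmean_policy: str = "zero",
) -> pd.DataFrame:
    """Per-timepoint no-AKI vs AKI comparison of a pressure or score.

    ``parameter`` is either a raw pressure field (``map_mmHg``, ``iap_mmHg``,
    ``cvp_mmHg``, ``pmean_mmHg``) or a score-family formula id.  Each row is
    the complete-case comparison at one grid time: group sizes, median
    (IQR) per group, U and p.  A timepoint with an empty group is flagged
    ``computed = False``.
    """
    from .cohort import TIME_GRID
    from .perfusion import FORMULAS, compute_series

    raw_fields = ("map_mmHg", "iap_mmHg", "cvp_mmHg", "pmean_mmHg")
    if parameter not in raw_fields and parameter not in FORMULAS:
        raise ValueError(f"unknown parameter {parameter!r}")

    values: dict[str, dict[int, float | None]] = {}
    for patient in cohort:
        if parameter in raw_fields:
            per_time = {}
            for t in TIME_GRID:
                obs = patient.observation(t)
                per_time[t] = None if obs is None else getattr(obs, parameter)
            values[patient.patient_id] = per_time
        else:
            series = compute_series(patient, parameter, pmean_policy=pmean_policy)
            values[patient.patient_id] = series.values

    rows = []
    for t in TIME_GRID:
        no_aki = [
            values[p.patient_id][t]
            for p in cohort
            if not outcomes[p.patient_id].aki and values[p.patient_id][t] is not None
        ]
        aki = [
            values[p.patient_id][t]
            for p in cohort
            if outcomes[p.patient_id].aki and values[p.patient_id][t] is not None
        ]
        row = {"parameter": parameter, "time_h": t, "n_no_aki": len(no_aki), "n_aki": len(aki)}
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
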