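"""Clinical-style statistics: dichotomization, odds ratios, stepwise
logistic selection, marker-ratio comparisons, and survival analysis of
predicted response groups.

The survival machinery (Kaplan-Meier product-limit estimation, log-rank
testing) is delegated to lifelines; hand-computed oracles for both live
in the test suite.  The cutoff heuristic (maximally selected chi-square)
is deliberately anti-conservative — selecting the cutoff that maximizes
association inflates the subsequent test's type-I error, which is
documented rather than corrected, matching common clinical practice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .panelsel import MarkerPanel, _base_model
from .syndata import PathologyTable

logger = logging.getLogger(__name__)

__all__ = ["ContingencyTable", "ORResult", "SurvivalRecord", "KMCurve",
           "LogRankResult", "heuristic_cutoff", "univariate_or",
           "backward_stepwise_logistic", "ratio_analysis", "km_curve",
           "logrank_test", "FittedPanel", "fit_panel_model",
           "stratify_predicted", "class_percentages"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """2x2 counts of (high/low marker) x (R/NR)."""

    a: int  # high & R
    b: int  # high & NR
    c: int  # low & R
    d: int  # low & NR
    marker: str = ""
    cutoff: float = float("nan")

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    correction_applied: bool = False


@dataclass
class SurvivalRecord:
    patient: str
    time: float
    event: int
    group: str

    def __post_init__(self):
        if not (self.time > 0 and np.isfinite(self.time)):
            raise ValueError("survival time must be positive and finite")
        if self.event not in (0, 1):
            raise ValueError("event flag must be 0 or 1")


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# dichotomization and odds ratios
# ---------------------------------------------------------------------------

def _chi_square_stat(table: np.ndarray) -> float:
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    n = table.sum()
    expected = row @ col / n
    if (expected == 0).any():
        return 0.0
    return float(((table - expected) ** 2 / expected).sum())


def heuristic_cutoff(values, labels, marker: str = "") -> tuple[float, ContingencyTable]:
    """Maximally selected chi-square dichotomization.

    Scans midpoints between adjacent distinct observed values and returns
    the cutoff whose high/low split maximizes the 2x2 chi-square
    statistic against the response labels (ties: smaller cutoff).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    distinct = np.unique(values)
    if len(distinct) < 2:
        raise ValueError("heuristic cutoff needs at least two distinct values")
    if len(np.unique(labels)) < 2:
        raise ValueError("both response classes must be present")

    best = None  # (-stat, cutoff)
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cut = 0.5 * (lo + hi)
        high = values > cut
        tab = np.array([
            [np.sum(high & (labels == 1)), np.sum(high & (labels == 0))],
            [np.sum(~high & (labels == 1)), np.sum(~high & (labels == 0))],
        ], dtype=float)
        stat = _chi_square_stat(tab)
        key = (-stat, cut)
        if best is None or key < best[0]:
            best = (key, tab)
    (neg_stat, cutoff), tab = best
    table = ContingencyTable(a=int(tab[0, 0]), b=int(tab[0, 1]),
                             c=int(tab[1, 0]), d=int(tab[1, 1]),
                             marker=marker, cutoff=cutoff)
    return cutoff, table


def univariate_or(table: ContingencyTable) -> ORResult:
    """Odds ratio with Wald 95% CI and chi-square p-value.

    A zero cell triggers the Haldane-Anscombe correction (0.5 added to
    every cell) so the OR and CI stay finite.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    ci_low, ci_high = orr * np.exp(-z * se), orr * np.exp(z * se)
    stat = _chi_square_stat(table.counts())
    p = float(stats.chi2.sf(stat, df=1))
    return ORResult(odds_ratio=float(orr), ci_low=float(ci_low),
                    ci_high=float(ci_high), p_value=p, correction_applied=corrected)


# ---------------------------------------------------------------------------
# multivariate stepwise logistic regression
# ---------------------------------------------------------------------------

def _logit_fit(x: pd.DataFrame, y: np.ndarray):
    design = sm.add_constant(x, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if np.isfinite(res.bse).all():
            return res
    except Exception:
        pass
    logger.warning("logistic fit unstable; refitting with a small ridge")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, design, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-4, L1_wt=0.0)
        # recover Wald statistics from the penalized information matrix
        mu = res.predict(design)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        xm = design.to_numpy(dtype=float)
        info = xm.T @ (xm * w[:, None]) + 1e-4 * np.eye(xm.shape[1])
        cov = np.linalg.inv(info)
    params = pd.Series(np.asarray(res.params), index=design.columns)
    bse = pd.Series(np.sqrt(np.diag(cov)), index=design.columns)
    return _RidgeLogitResult(params, bse)


class _RidgeLogitResult:
    """Minimal Wald-statistics view over a ridge-stabilized logistic fit."""

    def __init__(self, params: pd.Series, bse: pd.Series):
        self.params = params
        self.bse = bse

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)


def backward_stepwise_logistic(predictors: pd.DataFrame, labels,
                               alpha: float = 0.05):
    """Backward stepwise selection by Wald p-values.

    Iteratively drops the predictor with the largest Wald p until every
    remaining predictor has p < ``alpha``.  Returns
    ``(retained_columns, {column: ORResult})``; the final model may be
    empty.  ``alpha = 1`` keeps the full model.
    """
    y = np.asarray(labels, dtype=int)
    if len(predictors) <= predictors.shape[1]:
        raise ValueError("need more observations than predictors")
    cols = list(predictors.columns)
    res = None
    while cols:
        res = _logit_fit(predictors[cols], y)
        pvals = res.pvalues.drop("const", errors="ignore")
        worst = pvals.idxmax()
        if pvals[worst] < alpha:
            break
        cols.remove(worst)
    if not cols:
        return [], {}
    or_results = {}
    z = stats.norm.ppf(0.975)
    for c in cols:
        beta, se = float(res.params[c]), float(res.bse[c])
        or_results[c] = ORResult(
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - z * se)),
            ci_high=float(np.exp(beta + z * se)),
            p_value=float(res.pvalues[c]),
        )
    return cols, or_results


# ---------------------------------------------------------------------------
# per-core marker ratios
# ---------------------------------------------------------------------------

def ratio_analysis(pathology: PathologyTable, denominator_marker: str,
                   compartment: str = "tumor") -> pd.DataFrame:
    """Per-marker expression ratios relative to a denominator protein.

    For each patient and marker the ratio is computed per replicate core
    (marker core value / denominator core value) and averaged over cores
    (ratio-then-mean); cores with a non-positive denominator are skipped
    with a warning, and patients with no usable core are dropped for
    that marker.  Returns one row per marker with the NR and R group
    means, their z-scores across markers, and a Welch t-test p-value.
    """
    cores = pathology.cores
    cores = cores[cores["compartment"] == compartment]
    if denominator_marker not in set(cores["marker"]):
        raise ValueError(f"denominator marker {denominator_marker!r} not present")
    denom = cores[cores["marker"] == denominator_marker].set_index(
        ["patient", "core"])["value"]
    bad = denom[denom <= 0]
    if len(bad):
        logger.warning("%d denominator core(s) <= 0 skipped", len(bad))
        denom = denom[denom > 0]

    labels = pathology.labels
    rows = []
    for marker, grp in cores.groupby("marker"):
        if marker == denominator_marker:
            continue
        vals = grp.set_index(["patient", "core"])["value"]
        common = vals.index.intersection(denom.index)
        ratios = (vals.loc[common] / denom.loc[common]).groupby("patient").mean()
        y = labels.loc[ratios.index]
        r_vals = ratios[y == 1]
        nr_vals = ratios[y == 0]
        if len(r_vals) > 1 and len(nr_vals) > 1:
            _, p = stats.ttest_ind(nr_vals, r_vals, equal_var=False)
        else:
            p = np.nan
        rows.append({"marker": marker, "mean_NR": float(nr_vals.mean()),
                     "mean_R": float(r_vals.mean()), "p_value": float(p)})
    out = pd.DataFrame(rows).set_index("marker")
    for col in ("mean_NR", "mean_R"):
        sd = out[col].std(ddof=0)
        out[f"z_{col[5:]}"] = (out[col] - out[col].mean()) / (sd if sd else 1.0)
    return out


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_curve(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate at the observed event times."""
    if not records:
        raise ValueError("km_curve requires at least one record")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.unique(times[events == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([np.sum(times >= t) for t in event_times])
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk)


def logrank_test(records: list[SurvivalRecord]) -> LogRankResult:
    """Two-group log-rank test (1 df) on grouped survival records."""
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError("log-rank comparison requires exactly two groups")
    by = {g: [r for r in records if r.group == g] for g in groups}
    if any(len(v) == 0 for v in by.values()):
        raise ValueError("both groups must be non-empty")
    if sum(r.event for r in records) == 0:
        raise ValueError("log-rank test requires at least one event")
    t1 = [r.time for r in by[groups[0]]]
    e1 = [r.event for r in by[groups[0]]]
    t2 = [r.time for r in by[groups[1]]]
    e2 = [r.event for r in by[groups[1]]]
    res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return LogRankResult(chi_square=float(res.test_statistic), df=1,
                         p_value=float(res.p_value))


# ---------------------------------------------------------------------------
# predicted-group stratification
# ---------------------------------------------------------------------------

@dataclass
class FittedPanel:
    """A marker panel with its fitted base model."""

    panel: MarkerPanel
    model: object
    positive_index: int

    def predict_groups(self, table: PathologyTable) -> pd.Series:
        data = table if table.data_type == self.panel.data_type else table.standardized()
        x = data.means[self.panel.markers].to_numpy(dtype=float)
        proba = self.model.predict_proba(x)[:, self.positive_index]
        groups = np.where(proba >= 0.5, "response", "nonresponse")
        return pd.Series(groups, index=table.means.index, name="predicted_group")


def fit_panel_model(panel: MarkerPanel, table: PathologyTable,
                    train_cohort: str | None = "NAC", seed: int = 0) -> FittedPanel:
    """Fit the panel's base model, by default on the NAC (training) cohort."""
    data = table if table.data_type == panel.data_type else table.standardized()
    mask = (data.clinical["cohort"] == train_cohort if train_cohort
            else pd.Series(True, index=data.clinical.index))
    x = data.means.loc[mask, panel.markers].to_numpy(dtype=float)
    y = data.clinical.loc[mask, "label"].to_numpy(dtype=int)
    model = _base_model(panel.base, seed)
    model.fit(x, y)
    pos = int(np.where(model.classes_ == 1)[0][0])
    return FittedPanel(panel=panel, model=model, positive_index=pos)


@dataclass
class StratificationResult:
    groups: pd.Series
    tests: dict[tuple[str, str], LogRankResult] = field(default_factory=dict)
    curves: dict[tuple[str, str, str], KMCurve] = field(default_factory=dict)


def stratify_predicted(fitted: FittedPanel, table: PathologyTable,
                       endpoints=("os", "pfs")) -> StratificationResult:
    """Assign predicted response groups and compare survival between them.

    Every patient is assigned to exactly one predicted group; KM curves
    and a log-rank test are computed per cohort (plus the pooled 'ALL'
    stratum) and per endpoint.  Patients missing survival annotations
    are excluded with a warning.
    """
    groups = fitted.predict_groups(table)
    result = StratificationResult(groups=groups)
    cohorts = list(table.clinical["cohort"].unique()) + ["ALL"]
    for cohort in cohorts:
        mask = (pd.Series(True, index=table.clinical.index) if cohort == "ALL"
                else table.clinical["cohort"] == cohort)
        for ep in endpoints:
            tcol, ecol = f"{ep}_time", f"{ep}_event"
            sub = table.clinical.loc[mask, [tcol, ecol]]
            valid = sub.notna().all(axis=1) & (sub[tcol] > 0)
            if (~valid).any():
                logger.warning("%d patient(s) missing %s annotation excluded",
                               int((~valid).sum()), ep.upper())
            records = [
                SurvivalRecord(patient=p, time=float(sub.loc[p, tcol]),
                               event=int(sub.loc[p, ecol]), group=groups[p])
                for p in sub.index[valid]
            ]
            present = {r.group for r in records}
            for g in sorted(present):
                result.curves[(cohort, ep, g)] = km_curve(
                    [r for r in records if r.group == g])
            if len(present) == 2 and sum(r.event for r in records) > 0:
                result.tests[(cohort, ep)] = logrank_test(records)
    return result


def class_percentages(counts: dict[str, int], decimals: int = 2) -> dict[str, float]:
    """Percentage share of each category, rounded to ``decimals`` places."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return {k: round(100.0 * v / total, decimals) for k, v in counts.items()}
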