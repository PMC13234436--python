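"""Expression-matrix scaling transforms and data-driven scaler selection.

Cross-cohort transcriptome modeling is dominated by platform effects:
each cohort arrives with its own location, scale and marginal shape.
Nine per-gene scaling transforms are provided (log2, log2_minmax,
standard, minmax, max_abs, robust, power/Yeo-Johnson, quantile and
RankGauss).  A Gaussianity gate retains the transforms whose output
marginals are approximately normal, and a random-forest premodeling pass
over all (cohort, classifier) combinations picks the single working
scaler by mean Matthews correlation.

Matrices are genes x samples throughout; every transform is fitted per
gene (i.e. along the sample axis) within its fit scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import (
    MaxAbsScaler,
    MinMaxScaler,
    PowerTransformer,
    QuantileTransformer,
    RobustScaler,
    StandardScaler,
)

from .metrics import MetricSet, compute_metrics

logger = logging.getLogger(__name__)

SCALER_METHODS: tuple[str, ...] = (
    "log2", "log2_minmax", "standard", "minmax", "max_abs",
    "robust", "power", "quantile", "rankgauss",
)

#: Transforms whose output is expected to be approximately Gaussian.
GATE_SKEW_DEFAULT = 0.5
GATE_KURT_DEFAULT = 1.0


@dataclass(frozen=True)
class ScaledMatrix:
    """A genes x samples matrix after one scaling transform."""

    values: pd.DataFrame
    method: str
    fit_scope: str = "per-cohort"

    def __post_init__(self):
        if self.method not in SCALER_METHODS:
            raise ValueError(f"unknown scaler method: {self.method!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("scaled matrix contains non-finite values")


@dataclass
class ScalerReport:
    """Outcome of the premodeling pass that selects the working scaler."""

    scores: pd.DataFrame          # methods x metrics (mean over combinations)
    gated_methods: list[str]
    selected: str
    n_combinations: int = 0
    per_method: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "gated_methods": list(self.gated_methods),
            "n_combinations": self.n_combinations,
            "scores": self.scores.to_dict(orient="index"),
        }


def _fix_constant_rows(out: np.ndarray, x: np.ndarray, fill: float) -> np.ndarray:
    const = np.ptp(x, axis=1) == 0
    if const.any():
        logger.warning("%d constant gene(s) mapped to %.1f", int(const.sum()), fill)
        out[const, :] = fill
    return out


def _rankgauss(x: np.ndarray) -> np.ndarray:
    n = x.shape[1]
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    return stats.norm.ppf((ranks - 0.5) / n)


def apply_scaler(matrix: pd.DataFrame, method: str, fit_scope: str = "per-cohort") -> ScaledMatrix:
    """Fit and apply one of the nine transforms per gene.

    ``matrix`` is genes x samples.  ``fit_scope`` is a provenance tag on
    the result; fitting always happens on the matrix that is passed in,
    so pooled fitting is achieved by concatenating cohorts before the
    call (see :func:`scale_cohorts`).

    Constant genes map to 0 under ``standard`` and 0.5 under ``minmax``
    (logged) rather than propagating NaNs.
    """
    if method not in SCALER_METHODS:
        raise ValueError(f"unknown scaler method: {method!r}; choose from {SCALER_METHODS}")
    x = matrix.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("input matrix contains non-finite values")
    n_samples = x.shape[1]

    if method == "log2":
        if (x < 0).any():
            raise ValueError("log2 scaling requires non-negative values")
        out = np.log2(x + 1.0)
    elif method == "log2_minmax":
        if (x < 0).any():
            raise ValueError("log2_minmax scaling requires non-negative values")
        lx = np.log2(x + 1.0)
        out = MinMaxScaler().fit_transform(lx.T).T
        out = _fix_constant_rows(out, lx, 0.5)
    elif method == "standard":
        out = StandardScaler().fit_transform(x.T).T
        out = _fix_constant_rows(out, x, 0.0)
    elif method == "minmax":
        out = MinMaxScaler().fit_transform(x.T).T
        out = _fix_constant_rows(out, x, 0.5)
    elif method == "max_abs":
        out = MaxAbsScaler().fit_transform(x.T).T
    elif method == "robust":
        out = RobustScaler().fit_transform(x.T).T
    elif method == "power":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = PowerTransformer(method="yeo-johnson", standardize=True).fit_transform(x.T).T
        out = _fix_constant_rows(out, x, 0.0)
    elif method == "quantile":
        qt = QuantileTransformer(
            output_distribution="normal",
            n_quantiles=min(n_samples, 1000),
            subsample=1_000_000_000,
            random_state=0,
        )
        out = qt.fit_transform(x.T).T
    else:  # rankgauss
        out = _rankgauss(x)

    out = np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)
    values = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return ScaledMatrix(values=values, method=method, fit_scope=fit_scope)


def scale_cohorts(cohorts, method: str, fit_scope: str = "per-cohort") -> dict:
    """Scale a list of cohorts, fitting per cohort or on the pooled samples.

    Returns ``{cohort_id: ScaledMatrix}``.
    """
    if fit_scope == "per-cohort":
        return {c.cohort_id: apply_scaler(c.values, method, fit_scope) for c in cohorts}
    if fit_scope != "pooled":
        raise ValueError("fit_scope must be 'per-cohort' or 'pooled'")
    common = cohorts[0].values.index
    for c in cohorts[1:]:
        common = common.intersection(c.values.index)
    pooled = pd.concat([c.values.loc[common] for c in cohorts], axis=1)
    scaled = apply_scaler(pooled, method, "pooled")
    return {
        c.cohort_id: ScaledMatrix(scaled.values[c.values.columns], method, "pooled")
        for c in cohorts
    }


def gaussianity_gate(matrices: dict[str, ScaledMatrix],
                     tau_skew: float = GATE_SKEW_DEFAULT,
                     tau_kurt: float = GATE_KURT_DEFAULT) -> list[str]:
    """Return the methods whose per-gene marginals look Gaussian on average.

    A method passes when the mean absolute per-gene skewness is at most
    ``tau_skew`` and the mean absolute per-gene excess kurtosis is at most
    ``tau_kurt``.  Deterministic; output follows the canonical method order.
    """
    if not matrices:
        raise ValueError("gaussianity_gate requires at least one scaled matrix")
    passing = []
    for method in SCALER_METHODS:
        if method not in matrices:
            continue
        x = matrices[method].values.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            skew = np.nan_to_num(stats.skew(x, axis=1))
            kurt = np.nan_to_num(stats.kurtosis(x, axis=1, fisher=True))
        if np.mean(np.abs(skew)) <= tau_skew and np.mean(np.abs(kurt)) <= tau_kurt:
            passing.append(method)
    return passing


def _combination_metrics(values: pd.DataFrame, labels: np.ndarray, genes: list[str],
                         seed: int, n_trees: int = 100, n_splits: int = 3) -> MetricSet:
    x = values.loc[genes].to_numpy(dtype=float).T
    y = np.asarray(labels, dtype=int)
    n_splits = min(n_splits, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    proba = cross_val_predict(model, x, y, cv=cv, method="predict_proba")[:, 1]
    return compute_metrics(y, proba)


def premodel_select_scaler(cohorts, classifiers, methods, seed: int = 0) -> ScalerReport:
    """Pick the working scaler by random-forest premodeling.

    For every gated ``method``, each cohort is scaled and a 100-tree
    random forest is evaluated by stratified threefold cross-validated
    prediction for every (cohort, classifier) combination; the five
    threshold metrics are averaged over combinations.  The method with
    the highest mean MCC wins (ties: higher mean F1, then canonical
    method order).  Combinations whose classifier shares no genes with
    a cohort are skipped with a warning.
    """
    methods = [m for m in SCALER_METHODS if m in set(methods)]
    if not methods:
        raise ValueError("no scaling methods supplied")
    if len(cohorts) < 2:
        raise ValueError("premodeling requires at least two cohorts")

    rows, per_method = {}, {}
    n_comb = 0
    for method in methods:
        scaled = scale_cohorts(cohorts, method)
        combo_metrics = []
        for cohort in cohorts:
            values = scaled[cohort.cohort_id].values
            for clf in classifiers:
                genes = [g for g in clf.genes if g in values.index]
                if not genes:
                    logger.warning("classifier %s shares no genes with cohort %s; skipped",
                                   clf.name, cohort.cohort_id)
                    continue
                ms = _combination_metrics(values, cohort.labels, genes, seed)
                combo_metrics.append(ms)
        if not combo_metrics:
            raise ValueError("all (cohort, classifier) combinations were skipped")
        n_comb = max(n_comb, len(combo_metrics))
        rows[method] = {
            k: float(np.mean([m.as_dict()[k] for m in combo_metrics]))
            for k in ("accuracy", "recall", "precision", "f1", "mcc")
        }
        per_method[method] = combo_metrics

    scores = pd.DataFrame.from_dict(rows, orient="index")
    order = {m: i for i, m in enumerate(SCALER_METHODS)}
    selected = min(scores.index,
                   key=lambda m: (-scores.loc[m, "mcc"], -scores.loc[m, "f1"], order[m]))
    return ScalerReport(scores=scores, gated_methods=list(methods), selected=selected,
                        n_combinations=n_comb, per_method=per_method)
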