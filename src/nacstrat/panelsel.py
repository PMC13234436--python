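"""Immunohistochemistry marker-panel optimization from digital-pathology
tables.

The goal is a clinically manageable panel of 2-5 protein markers (tumor
and/or stroma compartment) that predicts chemotherapy response.  The
search has three layers:

1. :func:`rfecv_rank` — recursive feature elimination under stratified
   k-fold cross-validation: at each round the marker whose removal hurts
   mean balanced accuracy least is eliminated; rank is the reverse
   elimination order (last survivor = rank 1).
2. :func:`build_pools` — ten candidate pools of 5 tumor + 5 stroma
   markers, obtained by repeating the RFECV ranking with re-seeded fold
   assignments (selection stability across fold draws).
3. :func:`forward_select` / :func:`backward_eliminate` /
   :func:`search_best_panel` — greedy stepwise search over panel sizes
   2-5, both base models (depth-3 decision tree, logistic regression),
   both directions and both data types, keeping the configuration with
   the strictly highest threefold cross-validated balanced accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .metrics import MetricSet, balanced_accuracy, compute_metrics
from .syndata import PathologyTable  # canonical container, re-exported here

logger = logging.getLogger(__name__)

__all__ = ["PathologyTable", "FeatureRanking", "GenePool", "MarkerPanel",
           "PanelResult", "rfecv_rank", "build_pools", "forward_select",
           "backward_eliminate", "evaluate_panel", "search_best_panel",
           "BASE_MODELS"]

BASE_MODELS: tuple[str, ...] = ("tree", "logistic")


@dataclass
class FeatureRanking:
    """Markers ordered by elimination (rank 1 = most important)."""

    order: list[str]                 # rank 1 first
    ranks: dict[str, int]
    base: str
    k: int
    seed: int


@dataclass
class GenePool:
    """Five tumor-compartment plus five stroma-compartment candidates."""

    tumor_markers: list[str]
    stroma_markers: list[str]
    pool_id: str

    def __post_init__(self):
        members = self.tumor_markers + self.stroma_markers
        if len(self.tumor_markers) != 5 or len(self.stroma_markers) != 5:
            raise ValueError("a gene pool holds exactly 5 tumor + 5 stroma markers")
        if len(set(members)) != 10:
            raise ValueError("pool markers must be unique")

    @property
    def members(self) -> list[str]:
        return self.tumor_markers + self.stroma_markers

    def content_key(self) -> frozenset:
        return frozenset(self.members)


@dataclass
class MarkerPanel:
    """A final ordered panel of 2-5 effective markers."""

    markers: list[str]
    base: str
    data_type: str
    direction: str
    pool_id: str | None = None

    def __post_init__(self):
        if not (2 <= len(self.markers) <= 5):
            raise ValueError("a marker panel holds between two and five markers")
        if self.base not in BASE_MODELS:
            raise ValueError(f"base model must be one of {BASE_MODELS}")

    @property
    def scope(self) -> str:
        comps = {m.rsplit("__", 1)[-1] for m in self.markers}
        return comps.pop() if len(comps) == 1 else "both"


@dataclass
class PanelResult:
    panel: MarkerPanel
    fold_metrics: list[MetricSet]
    mean_metrics: MetricSet
    criterion: float                  # mean threefold balanced accuracy
    seed: int


def _base_model(base: str, seed: int):
    if base == "tree":
        return DecisionTreeClassifier(criterion="gini", max_depth=3,
                                      min_samples_leaf=2, random_state=seed)
    if base == "logistic":
        return LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
    raise ValueError(f"unknown base model: {base!r}")


def _cv_balanced_accuracy(x: pd.DataFrame, y: np.ndarray, features: list[str],
                          base: str, seed: int, k: int = 3) -> float:
    """Mean balanced accuracy over stratified k folds for one feature set."""
    xv = x[features].to_numpy(dtype=float)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in cv.split(xv, y):
        model = _base_model(base, seed)
        model.fit(xv[train_idx], y[train_idx])
        preds = model.predict(xv[test_idx])
        scores.append(balanced_accuracy(y[test_idx], preds))
    return float(np.mean(scores))


def rfecv_rank(x: pd.DataFrame, labels, base: str = "tree", k: int = 3,
               seed: int = 0) -> FeatureRanking:
    """Rank markers by recursive elimination under k-fold cross-validation.

    At each round the candidate whose removal leaves the best-performing
    remaining set is eliminated (it contributed least); ties eliminate
    the lexicographically smallest marker.  The eliminated marker at a
    round with ``m`` survivors receives rank ``m``.
    """
    y = np.asarray(labels, dtype=int)
    features = sorted(x.columns)
    if len(features) < 2:
        raise ValueError("RFECV needs at least two markers")
    counts = np.bincount(y, minlength=2)
    if k > counts.min():
        raise ValueError(f"k={k} folds exceed the smallest class count {counts.min()}")

    ranks: dict[str, int] = {}
    remaining = list(features)
    while len(remaining) > 1:
        best = None  # (-score, candidate)
        for cand in remaining:
            rest = [f for f in remaining if f != cand]
            score = _cv_balanced_accuracy(x, y, rest, base, seed, k)
            key = (-score, cand)
            if best is None or key < best:
                best = key
        drop = best[1]
        ranks[drop] = len(remaining)
        remaining.remove(drop)
    ranks[remaining[0]] = 1
    order = sorted(features, key=lambda f: ranks[f])
    return FeatureRanking(order=order, ranks=ranks, base=base, k=k, seed=seed)


def build_pools(table: PathologyTable, base: str = "tree", n_pools: int = 10,
                seed: int = 0, k: int = 3, seed_budget_factor: int = 5) -> list[GenePool]:
    """Build candidate pools from repeated re-seeded RFECV rankings.

    Pool ``i`` takes the top-5 tumor and top-5 stroma markers from
    rankings whose fold assignment is seeded with ``seed + i``; pools
    identical in content are dropped and additional seeds consumed, up
    to ``seed_budget_factor * n_pools`` attempts.  Ending with fewer than
    ``n_pools`` distinct pools is reported with a warning.
    """
    y = np.asarray(table.labels, dtype=int)
    for comp in ("tumor", "stroma"):
        if len(table.feature_columns(comp)) < 5:
            raise ValueError(f"need at least five {comp} markers to build pools")

    pools: list[GenePool] = []
    seen: set[frozenset] = set()
    attempt = 0
    while len(pools) < n_pools and attempt < seed_budget_factor * n_pools:
        s = seed + attempt
        attempt += 1
        tumor = rfecv_rank(table.means[table.feature_columns("tumor")], y,
                           base=base, k=k, seed=s).order[:5]
        stroma = rfecv_rank(table.means[table.feature_columns("stroma")], y,
                            base=base, k=k, seed=s).order[:5]
        pool = GenePool(tumor_markers=tumor, stroma_markers=stroma,
                        pool_id=f"pool{len(pools) + 1:02d}")
        if pool.content_key() in seen:
            continue
        seen.add(pool.content_key())
        pools.append(pool)
    if len(pools) < n_pools:
        logger.warning("only %d of %d distinct pools could be formed within the "
                       "seed budget", len(pools), n_pools)
    return pools


def _stepwise(members: list[str], size: int, base: str, x: pd.DataFrame,
              y: np.ndarray, seed: int, direction: str) -> tuple[list[str], float]:
    if direction == "forward":
        selected: list[str] = []
        score = 0.0
        while len(selected) < size:
            best = None
            for cand in sorted(set(members) - set(selected)):
                s = _cv_balanced_accuracy(x, y, selected + [cand], base, seed)
                key = (-s, cand)
                if best is None or key < best:
                    best = key
            selected.append(best[1])
            score = -best[0]
        return selected, score
    if direction != "backward":
        raise ValueError("direction must be 'forward' or 'backward'")
    selected = list(members)
    score = _cv_balanced_accuracy(x, y, selected, base, seed)
    while len(selected) > size:
        best = None
        for cand in sorted(selected):
            rest = [f for f in selected if f != cand]
            s = _cv_balanced_accuracy(x, y, rest, base, seed)
            key = (-s, cand)
            if best is None or key < best:
                best = key
        selected = [f for f in selected if f != best[1]]
        score = -best[0]
    return selected, score


def _data_for(table: PathologyTable, data_type: str) -> PathologyTable:
    if data_type == table.data_type:
        return table
    if data_type == "standardized":
        return table.standardized()
    raise ValueError(f"cannot derive data type {data_type!r} from {table.data_type!r}")


def forward_select(pool: GenePool, size: int, base: str, table: PathologyTable,
                   seed: int = 0) -> MarkerPanel:
    """Greedy forward selection to ``size`` markers from the pool."""
    if size > len(pool.members):
        raise ValueError("requested size exceeds the pool")
    y = np.asarray(table.labels, dtype=int)
    markers, _ = _stepwise(pool.members, size, base, table.means, y, seed, "forward")
    return MarkerPanel(markers=markers, base=base, data_type=table.data_type,
                       direction="forward", pool_id=pool.pool_id)


def backward_eliminate(pool: GenePool, size: int, base: str, table: PathologyTable,
                       seed: int = 0) -> MarkerPanel:
    """Greedy backward elimination from the full pool down to ``size``."""
    if size > len(pool.members):
        raise ValueError("requested size exceeds the pool")
    y = np.asarray(table.labels, dtype=int)
    markers, _ = _stepwise(pool.members, size, base, table.means, y, seed, "backward")
    markers = [m for m in pool.members if m in markers]  # keep pool order
    return MarkerPanel(markers=markers, base=base, data_type=table.data_type,
                       direction="backward", pool_id=pool.pool_id)


def evaluate_panel(panel: MarkerPanel, table: PathologyTable, seed: int = 0,
                   k: int = 3, max_refolds: int = 10) -> PanelResult:
    """Stratified threefold cross-validated metrics on the combined cohorts.

    A fold assignment whose held-out labels collapse to a single class is
    re-drawn with a shifted seed (warned); persistent failure raises.
    """
    data = _data_for(table, panel.data_type)
    missing = [m for m in panel.markers if m not in data.means.columns]
    if missing:
        raise ValueError(f"panel markers absent from the table: {missing}")
    xv = data.means[panel.markers].to_numpy(dtype=float)
    y = np.asarray(data.labels, dtype=int)

    s = seed
    for attempt in range(max_refolds):
        s = seed + 1000 * attempt
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=s)
        splits = list(cv.split(xv, y))
        if all(len(np.unique(y[test])) == 2 for _, test in splits):
            if attempt:
                logger.warning("refolded %d time(s) to avoid single-class folds", attempt)
            break
    else:
        raise ValueError("could not form folds with both classes present")

    fold_metrics, fold_bacc = [], []
    for train_idx, test_idx in splits:
        model = _base_model(panel.base, s)
        model.fit(xv[train_idx], y[train_idx])
        pos = int(np.where(model.classes_ == 1)[0][0])
        proba = model.predict_proba(xv[test_idx])[:, pos]
        fold_metrics.append(compute_metrics(y[test_idx], proba))
        fold_bacc.append(balanced_accuracy(y[test_idx], (proba >= 0.5).astype(int)))

    def _mean(attr):
        vals = [getattr(m, attr) for m in fold_metrics]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    mean_metrics = MetricSet(accuracy=_mean("accuracy"), recall=_mean("recall"),
                             precision=_mean("precision"), f1=_mean("f1"),
                             mcc=_mean("mcc"), auc=_mean("auc"))
    return PanelResult(panel=panel, fold_metrics=fold_metrics,
                       mean_metrics=mean_metrics,
                       criterion=float(np.mean(fold_bacc)), seed=s)


def search_best_panel(pools: list[GenePool], table: PathologyTable,
                      sizes=(2, 3, 4, 5), bases=BASE_MODELS,
                      data_types=("raw", "standardized"),
                      directions=("forward", "backward"),
                      seed: int = 0) -> tuple[MarkerPanel, PanelResult, list[dict]]:
    """Exhaustive search over pools x sizes x bases x directions x data types.

    The incumbent model is replaced only by a configuration with a
    strictly higher mean threefold balanced accuracy; ties keep the
    panel with fewer markers, then the lexicographically smaller marker
    tuple.  Returns the winning panel, its evaluation and the full
    search log.
    """
    if not pools:
        raise ValueError("search requires at least one pool")
    log: list[dict] = []
    best_key: tuple | None = None
    best_panel: MarkerPanel | None = None
    for data_type in data_types:
        data = _data_for(table, data_type)
        y = np.asarray(data.labels, dtype=int)
        for pool in pools:
            for size in sizes:
                for base in bases:
                    for direction in directions:
                        markers, crit = _stepwise(pool.members, size, base,
                                                  data.means, y, seed, direction)
                        if direction == "backward":
                            markers = [m for m in pool.members if m in markers]
                        panel = MarkerPanel(markers=markers, base=base,
                                            data_type=data_type, direction=direction,
                                            pool_id=pool.pool_id)
                        log.append({"pool": pool.pool_id, "size": size, "base": base,
                                    "direction": direction, "data_type": data_type,
                                    "criterion": crit, "markers": list(markers)})
                        key = (-crit, len(markers), tuple(sorted(markers)))
                        if best_key is None or key < best_key:
                            best_key, best_panel = key, panel
    result = evaluate_panel(best_panel, table, seed=seed)
    return best_panel, result, log
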