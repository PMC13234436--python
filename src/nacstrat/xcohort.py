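"""Multicohort cross-validation: gene harmonization, run enumeration and
execution.

The validation design is fully enumerated rather than sampled: with four
cohorts there are 12 ordered (train, validation) assignments, the two
remaining cohorts serving as tests; crossed with 17 classifiers, two
classifier variants (top-10 and union) and three model algorithms this
yields the 2 x 17 x 3 x 12 = 1,224 runs of the complete design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .classifiers import ExpressionCohort, GeneClassifier
from .metrics import MetricSet, compute_metrics  # re-exported surface

__all__ = ["RunSpec", "RunMatrix", "RunResult", "harmonize", "enumerate_runs",
           "execute_run", "compute_metrics", "MetricSet",
           "MODEL_ALGORITHMS", "CLASSIFIER_VARIANTS"]

MODEL_ALGORITHMS: tuple[str, ...] = ("logistic", "tree", "forest")
CLASSIFIER_VARIANTS: tuple[str, ...] = ("top10", "union")


@dataclass(frozen=True)
class RunSpec:
    """One cross-validation run of the enumerated design."""

    train_cohort: str
    validation_cohort: str
    test_cohorts: tuple[str, ...]
    classifier: str
    variant: str
    model: str
    seed: int = 0

    def __post_init__(self):
        roles = (self.train_cohort, self.validation_cohort, *self.test_cohorts)
        if len(set(roles)) != len(roles):
            raise ValueError("cohort roles must be distinct")
        if self.variant not in CLASSIFIER_VARIANTS:
            raise ValueError(f"variant must be one of {CLASSIFIER_VARIANTS}")
        if self.model not in MODEL_ALGORITHMS:
            raise ValueError(f"model must be one of {MODEL_ALGORITHMS}")


@dataclass
class RunMatrix:
    runs: list[RunSpec]

    def __len__(self) -> int:
        return len(self.runs)

    def __iter__(self):
        return iter(self.runs)


@dataclass
class RunResult:
    spec: RunSpec
    metrics: dict[str, MetricSet]        # keyed by cohort id
    roles: dict[str, str]                # cohort id -> train/validation/test
    model_summary: dict = field(default_factory=dict)


def harmonize(cohorts: list[ExpressionCohort], alpha: float = 0.05) -> list[str]:
    """Genes present in every cohort with comparable scaled distributions.

    A gene survives when, for every cohort pair, a Welch two-sample
    t-test on the (already scaled) values does not reject at level
    ``alpha``.  ``alpha = 0`` reduces to the presence filter.
    """
    if len(cohorts) < 2:
        raise ValueError("harmonize requires at least two cohorts")
    common = cohorts[0].values.index
    for c in cohorts[1:]:
        common = common.intersection(c.values.index)
    if len(common) == 0:
        counts = {c.cohort_id: c.values.shape[0] for c in cohorts}
        raise ValueError(f"no genes shared across cohorts (per-cohort counts: {counts})")
    common = sorted(common)
    if alpha <= 0:
        return common

    keep = []
    arrays = {c.cohort_id: c.values.loc[common].to_numpy(dtype=float) for c in cohorts}
    ids = [c.cohort_id for c in cohorts]
    for i, gene in enumerate(common):
        ok = True
        for a, b in itertools.combinations(ids, 2):
            _, p = stats.ttest_ind(arrays[a][i], arrays[b][i], equal_var=False)
            if np.isfinite(p) and p <= alpha:
                ok = False
                break
        if ok:
            keep.append(gene)
    return keep


def enumerate_runs(cohort_ids, classifiers, variants=CLASSIFIER_VARIANTS,
                   models=MODEL_ALGORITHMS, seed: int = 0) -> RunMatrix:
    """Enumerate the full Cartesian design.

    Every ordered (train, validation) pair of distinct cohorts is crossed
    with every classifier, variant and model; the remaining cohorts are
    the test set.  Runs are sorted by (classifier, variant, model, train,
    validation) and each receives a derived seed for its model fits.
    """
    cohort_ids = list(cohort_ids)
    if len(set(cohort_ids)) != len(cohort_ids):
        raise ValueError("duplicate cohort ids")
    if len(cohort_ids) < 2:
        raise ValueError("need at least two cohorts")
    names = [c if isinstance(c, str) else c.name for c in classifiers]

    runs = []
    combos = sorted(itertools.product(
        names, variants, models, itertools.permutations(cohort_ids, 2)))
    for i, (clf, variant, model, (train, val)) in enumerate(combos):
        tests = tuple(c for c in cohort_ids if c not in (train, val))
        runs.append(RunSpec(train_cohort=train, validation_cohort=val,
                            test_cohorts=tests, classifier=clf, variant=variant,
                            model=model, seed=seed + i))
    return RunMatrix(runs=runs)


def _make_model(model: str, seed: int):
    if model == "logistic":
        return LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
    if model == "tree":
        return DecisionTreeClassifier(criterion="gini", max_depth=3,
                                      min_samples_leaf=2, random_state=seed)
    if model == "forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown model algorithm: {model!r}")


def execute_run(spec: RunSpec, data: dict[str, ExpressionCohort],
                classifier_store: dict[str, GeneClassifier],
                threshold: float = 0.5) -> RunResult:
    """Fit on the training cohort only and score every cohort role.

    ``data`` maps cohort id to (already scaled) cohorts on the
    harmonized gene space; ``classifier_store`` maps
    ``f"{classifier}|{variant}"`` (or the bare classifier name) to the
    gene set to use.
    """
    key = f"{spec.classifier}|{spec.variant}"
    clf = classifier_store.get(key) or classifier_store.get(spec.classifier)
    if clf is None:
        raise KeyError(f"no classifier registered under {key!r}")

    train = data[spec.train_cohort]
    genes = [g for g in clf.genes if g in train.values.index]
    for cid in (spec.validation_cohort, *spec.test_cohorts):
        genes = [g for g in genes if g in data[cid].values.index]
    if not genes:
        raise ValueError(f"classifier {clf.name} shares no genes with the "
                         "harmonized cohort space")

    model = _make_model(spec.model, spec.seed)
    x_train = train.values.loc[genes].to_numpy(dtype=float).T
    y_train = np.asarray(train.labels, dtype=int)
    model.fit(x_train, y_train)
    pos = int(np.where(model.classes_ == 1)[0][0])

    roles = {spec.train_cohort: "train", spec.validation_cohort: "validation"}
    roles.update({c: "test" for c in spec.test_cohorts})
    metrics = {}
    for cid in roles:
        cohort = data[cid]
        x = cohort.values.loc[genes].to_numpy(dtype=float).T
        scores = model.predict_proba(x)[:, pos]
        metrics[cid] = compute_metrics(np.asarray(cohort.labels, dtype=int),
                                       scores, threshold=threshold)
    summary = {"model": spec.model, "n_genes": len(genes), "genes": genes}
    return RunResult(spec=spec, metrics=metrics, roles=roles, model_summary=summary)
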