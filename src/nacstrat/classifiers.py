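"""Data-driven gene-classifier extraction and reduction.

The discovery cohorts here are tiny (16-40 patients), so single models
overfit badly.  Gene classifiers are therefore extracted from an
*ensemble* of random forests (10 forests x 100 trees by default): each
sample's prediction score is the mean out-of-bag probability of response
across forests, and each gene's importance is the mean impurity-based
importance.  A top-k sweep (k = 5..30) with hierarchical clustering
picks the smallest gene set whose two-cluster cut best matches the
response labels; a reduction cascade (mutual information -> variance
inflation factor -> cluster representatives) then shrinks a classifier
to a handful of genes while checking that the logistic-regression AUC
does not drop by more than 0.2.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score

from .metrics import auc_mann_whitney
from .scalers import apply_scaler

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionCohort:
    """One cohort: a genes x samples matrix plus binary response labels.

    Labels follow the convention nonresponse (NR) = 0, response (R) = 1.
    """

    values: pd.DataFrame
    labels: pd.Series
    cohort_id: str

    def __post_init__(self):
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("labels length must equal sample count")
        classes = set(np.unique(self.labels))
        if not classes <= {0, 1}:
            raise ValueError("labels must be binary (0=NR, 1=R)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def has_both_classes(self) -> bool:
        return set(np.unique(self.labels)) == {0, 1}

    def subset_genes(self, genes) -> "ExpressionCohort":
        present = [g for g in genes if g in self.values.index]
        return ExpressionCohort(self.values.loc[present], self.labels, self.cohort_id)


@dataclass
class GeneClassifier:
    """A named, ordered gene set with provenance."""

    name: str
    genes: list[str]
    provenance: str = "data-driven"
    source_cohort: str | None = None
    importance: dict[str, float] | None = None

    def __post_init__(self):
        if not self.genes:
            raise ValueError("a gene classifier must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("classifier genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnsembleConfig:
    n_forests: int = 10
    n_trees: int = 100
    seed: int = 0


@dataclass
class EnsembleResult:
    """Mean out-of-bag scores and importances of a forest ensemble."""

    mean_scores: pd.Series      # per sample, in [0, 1]
    mean_importance: pd.Series  # per gene, >= 0
    n_forests: int
    n_trees: int
    seed: int

    def ranked_genes(self) -> list[str]:
        """Genes by decreasing importance, ties broken lexicographically."""
        imp = self.mean_importance
        return sorted(imp.index, key=lambda g: (-imp[g], g))


@dataclass
class ExtractionConfig:
    k_min: int = 5
    k_max: int = 30
    linkage_method: str = "ward"
    metric: str = "euclidean"
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError("require 1 <= k_min <= k_max")


@dataclass
class ReductionReport:
    input_size: int
    output_size: int
    mi_dropped: list[str] = field(default_factory=list)
    vif_dropped: list[str] = field(default_factory=list)
    cluster_dropped: list[str] = field(default_factory=list)
    delta_auc: float = 0.0
    auc_full: float | None = None
    auc_reduced: float | None = None


# ---------------------------------------------------------------------------
# ensemble scoring and extraction
# ---------------------------------------------------------------------------

def rf_ensemble_scores(cohort: ExpressionCohort,
                       config: EnsembleConfig | None = None) -> EnsembleResult:
    """Average out-of-bag scores and importances over a forest ensemble.

    Forest ``f`` is seeded with ``config.seed + f``, which makes the
    ensemble reproducible while decorrelating the bootstrap draws.
    Samples that happen never to be out of bag in one forest fall back
    to that forest's in-bag probability.
    """
    config = config or EnsembleConfig()
    if not cohort.has_both_classes():
        raise ValueError("ensemble scoring requires both response classes")
    counts = np.bincount(np.asarray(cohort.labels, dtype=int))
    if counts.min() < 2:
        raise ValueError("ensemble scoring requires >= 2 samples per class")

    x = cohort.values.to_numpy(dtype=float).T
    y = np.asarray(cohort.labels, dtype=int)
    scores = np.zeros(len(y))
    importance = np.zeros(cohort.values.shape[0])
    for f in range(config.n_forests):
        rf = RandomForestClassifier(n_estimators=config.n_trees, oob_score=True,
                                    bootstrap=True, random_state=config.seed + f)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(x, y)
        pos = int(np.where(rf.classes_ == 1)[0][0])
        oob = rf.oob_decision_function_[:, pos]
        missing = ~np.isfinite(oob)
        if missing.any():
            oob[missing] = rf.predict_proba(x[missing])[:, pos]
        scores += oob
        importance += rf.feature_importances_
    scores /= config.n_forests
    importance /= config.n_forests
    return EnsembleResult(
        mean_scores=pd.Series(scores, index=cohort.values.columns),
        mean_importance=pd.Series(importance, index=cohort.values.index),
        n_forests=config.n_forests, n_trees=config.n_trees, seed=config.seed,
    )


def extract_data_driven_classifier(ensemble: EnsembleResult, cohort: ExpressionCohort,
                                   config: ExtractionConfig | None = None) -> GeneClassifier:
    """Pick the smallest top-k gene set whose 2-cluster cut matches the labels.

    For each k in [k_min, k_max] the top-k genes by mean importance are
    standardized, samples are hierarchically clustered (Ward/Euclidean by
    default) and cut into two clusters, and the agreement with the NR/R
    labels is scored by the adjusted Rand index.  The smallest k attaining
    the maximum ARI wins.
    """
    config = config or ExtractionConfig()
    ranked = ensemble.ranked_genes()
    if config.k_max > len(ranked):
        raise ValueError("k_max exceeds the number of genes in the cohort")
    y = np.asarray(cohort.labels, dtype=int)

    best = None  # (−ari, k, genes)
    for k in range(config.k_min, config.k_max + 1):
        genes = ranked[:k]
        sub = cohort.values.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        z = ((sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]).T  # samples x k
        if np.allclose(z, z[0]):
            raise ValueError("degenerate clustering input: all samples identical")
        lk = linkage(z, method=config.linkage_method, metric=config.metric)
        cut = fcluster(lk, t=2, criterion="maxclust")
        ari = adjusted_rand_score(y, cut)
        key = (-ari, k)
        if best is None or key < best[0]:
            best = (key, genes)
    genes = best[1]
    return GeneClassifier(
        name=f"{cohort.cohort_id}_data_driven", genes=list(genes),
        provenance="data-driven", source_cohort=cohort.cohort_id,
        importance={g: float(ensemble.mean_importance[g]) for g in genes},
    )


# ---------------------------------------------------------------------------
# reduction cascade: mutual information -> VIF -> cluster representatives
# ---------------------------------------------------------------------------

def mutual_information_binned(values: np.ndarray, labels: np.ndarray,
                              n_bins: int = 4) -> float:
    """Plug-in mutual information (nats) between a quantile-binned gene
    and the binary label.

    Quantile binning (4 bins) makes the estimate invariant to monotone
    transforms of the expression values.
    """
    labels = np.asarray(labels, dtype=int)
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.digitize(values, np.unique(edges))
    joint = pd.crosstab(bins, labels).to_numpy(dtype=float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return float(np.nansum(terms))


def variance_inflation_factors(x: np.ndarray) -> np.ndarray:
    """VIF of each column of ``x`` via OLS of the column on the others."""
    n, p = x.shape
    vifs = np.empty(p)
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, x[:, j], rcond=None)
        resid = x[:, j] - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((x[:, j] - x[:, j].mean()) ** 2))
        if ss_tot == 0:
            vifs[j] = np.inf
        else:
            r2 = 1.0 - ss_res / ss_tot
            vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def logistic_scores(cohort: ExpressionCohort, classifier: GeneClassifier):
    """Logistic-regression prediction scores and AUC for one classifier.

    The fit is maximum likelihood stabilized by a very weak ridge
    (C = 1e6), which keeps the optimum finite on separable tiny cohorts
    while leaving non-separable fits numerically at the ML solution.
    Returns ``(scores, auc)`` with scores in [0, 1].
    """
    genes = [g for g in classifier.genes if g in cohort.values.index]
    if not genes:
        raise ValueError(f"classifier {classifier.name} has no genes in cohort "
                         f"{cohort.cohort_id}")
    if not cohort.has_both_classes():
        raise ValueError("logistic scoring requires both classes")
    x = cohort.values.loc[genes].to_numpy(dtype=float).T
    y = np.asarray(cohort.labels, dtype=int)
    model = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, y)
    pos = int(np.where(model.classes_ == 1)[0][0])
    scores = model.predict_proba(x)[:, pos]
    auc = auc_mann_whitney(y, scores)
    return pd.Series(scores, index=cohort.values.columns), auc


def reduce_classifier(cohort: ExpressionCohort, classifier: GeneClassifier,
                      target_max: int = 10, theta_mi: float = 0.01,
                      theta_vif: float = 10.0) -> tuple[GeneClassifier, ReductionReport]:
    """Shrink a classifier with three sequential filters.

    The cohort submatrix is Yeo-Johnson power-scaled first, then:

    1. genes whose label mutual information is below ``theta_mi`` nats
       are dropped (weak discriminators);
    2. while the maximum VIF exceeds ``theta_vif``, the most collinear
       gene is dropped (ties: lexicographically larger ID dropped);
    3. if more than ``target_max`` genes remain, genes are hierarchically
       clustered and the highest-MI representative of each cluster kept.

    If every gene would be filtered, the single highest-MI gene is kept
    with a warning.  The report records each dropped gene and the change
    in logistic-regression AUC between full and reduced sets.
    """
    genes = [g for g in classifier.genes if g in cohort.values.index]
    if not genes:
        raise ValueError("classifier genes absent from cohort")
    report = ReductionReport(input_size=len(genes), output_size=len(genes))
    if len(genes) == 1:
        reduced = GeneClassifier(name=f"{classifier.name}_reduced", genes=list(genes),
                                 provenance="reduced", source_cohort=cohort.cohort_id)
        report.delta_auc = 0.0
        return reduced, report

    scaled = apply_scaler(cohort.values.loc[genes], "power").values
    y = np.asarray(cohort.labels, dtype=int)
    mi = {g: mutual_information_binned(scaled.loc[g].to_numpy(), y) for g in genes}

    # 1) mutual-information filter
    kept = [g for g in genes if mi[g] >= theta_mi]
    report.mi_dropped = [g for g in genes if g not in kept]
    if not kept:
        best = max(genes, key=lambda g: (mi[g], g))
        logger.warning("all genes fell below the MI threshold; keeping %s", best)
        kept = [best]
        report.mi_dropped = [g for g in genes if g != best]

    # 2) iterative VIF filter
    while len(kept) > 1:
        x = scaled.loc[kept].to_numpy(dtype=float).T
        vifs = variance_inflation_factors(x)
        worst = float(np.max(vifs))
        if worst <= theta_vif:
            break
        candidates = [kept[j] for j in range(len(kept)) if vifs[j] == worst]
        drop = max(candidates)  # deterministic: lexicographically larger goes
        kept = [g for g in kept if g != drop]
        report.vif_dropped.append(drop)

    # 3) cluster representatives down to target_max
    if len(kept) > target_max:
        z = scaled.loc[kept].to_numpy(dtype=float)
        # redundancy is judged on within-class residuals: genes that co-vary
        # only through the response signal are not redundant with each other,
        # so the class-mean component is removed before clustering
        for cls in np.unique(y):
            z[:, y == cls] -= z[:, y == cls].mean(axis=1, keepdims=True)
        sd = z.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        z = z / sd[:, None]
        lk = linkage(z, method="ward", metric="euclidean")
        clusters = fcluster(lk, t=target_max, criterion="maxclust")
        reps = []
        for c in np.unique(clusters):
            members = [kept[i] for i in range(len(kept)) if clusters[i] == c]
            reps.append(max(members, key=lambda g: (mi[g], g)))
        report.cluster_dropped = [g for g in kept if g not in reps]
        kept = [g for g in classifier.genes if g in reps]  # original order

    reduced = GeneClassifier(name=f"{classifier.name}_reduced", genes=list(kept),
                             provenance="reduced", source_cohort=cohort.cohort_id)
    _, auc_full = logistic_scores(cohort, classifier)
    _, auc_red = logistic_scores(cohort, reduced)
    report.auc_full, report.auc_reduced = auc_full, auc_red
    report.delta_auc = float(auc_full - auc_red) if (auc_full is not None
                                                     and auc_red is not None) else 0.0
    report.output_size = len(kept)
    return reduced, report


def delta_auc_check(report: ReductionReport, threshold: float = 0.2) -> bool:
    """True when the reduction changed the AUC by less than ``threshold``."""
    return abs(report.delta_auc) < threshold


def top10_refine(cohort: ExpressionCohort, classifier: GeneClassifier,
                 seed: int = 0, max_genes: int = 10) -> GeneClassifier:
    """Keep at most ten key genes, ranked by ensemble importance on this cohort."""
    genes = [g for g in classifier.genes if g in cohort.values.index]
    if not genes:
        raise ValueError("classifier genes absent from cohort")
    if len(genes) <= max_genes:
        return GeneClassifier(name=f"{classifier.name}_top10", genes=list(genes),
                              provenance="top10", source_cohort=cohort.cohort_id)
    sub = cohort.subset_genes(genes)
    ensemble = rf_ensemble_scores(sub, EnsembleConfig(seed=seed))
    top = ensemble.ranked_genes()[:max_genes]
    ordered = [g for g in classifier.genes if g in top]
    return GeneClassifier(name=f"{classifier.name}_top10", genes=ordered,
                          provenance="top10", source_cohort=cohort.cohort_id)


def build_union(refined: list[GeneClassifier], name: str | None = None) -> GeneClassifier:
    """Deduplicated union of refined classifiers, genes in first-seen order."""
    if not refined:
        raise ValueError("build_union requires at least one classifier")
    seen: dict[str, None] = {}
    for clf in refined:
        for g in clf.genes:
            seen.setdefault(g)
    base = name or refined[0].name.rsplit("_top10", 1)[0]
    return GeneClassifier(name=f"{base}_union", genes=list(seen), provenance="union")
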