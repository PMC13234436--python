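"""Ensemble scoring, extraction and the MI -> VIF -> cluster reduction
cascade, with independent oracles for MI and VIF."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import mutual_info_score
from statsmodels.stats.outliers_influence import variance_inflation_factor

import nacstrat as ns
from nacstrat.classifiers import (EnsembleConfig, ExpressionCohort,
                                  ExtractionConfig, GeneClassifier, build_union,
                                  delta_auc_check,
                                  extract_data_driven_classifier,
                                  logistic_scores, mutual_information_binned,
                                  reduce_classifier, rf_ensemble_scores,
                                  top10_refine, variance_inflation_factors)


def _small_cohort(seed=0, n_genes=40, n=30, n_planted=4, effect=2.0):
    spec = ns.CohortSimSpec(cohort_sizes=(n,), n_genes=n_genes,
                            n_informative=n_planted, effect_size=effect,
                            shape="gaussian", cohort_shift=0.0, cohort_scale=1.0,
                            seed=seed)
    cohorts, truth = ns.generate_cohorts(spec)
    return cohorts[0], truth


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def test_cohort_and_classifier_validation():
    values = pd.DataFrame(np.zeros((2, 3)), index=["a", "b"], columns=list("xyz"))
    with pytest.raises(ValueError):
        ExpressionCohort(values, pd.Series([0, 1], index=["x", "y"]), "c")
    with pytest.raises(ValueError):
        ExpressionCohort(values, pd.Series([0, 1, 2], index=list("xyz")), "c")
    with pytest.raises(ValueError):
        GeneClassifier(name="empty", genes=[])
    with pytest.raises(ValueError):
        GeneClassifier(name="dup", genes=["g1", "g1"])


# ---------------------------------------------------------------------------
# ensemble scoring
# ---------------------------------------------------------------------------

def test_ensemble_deterministic_and_bounded():
    cohort, _ = _small_cohort(seed=1)
    a = rf_ensemble_scores(cohort, EnsembleConfig(n_forests=3, n_trees=50, seed=2))
    b = rf_ensemble_scores(cohort, EnsembleConfig(n_forests=3, n_trees=50, seed=2))
    assert a.mean_scores.equals(b.mean_scores)
    assert a.mean_importance.equals(b.mean_importance)
    assert ((a.mean_scores >= 0) & (a.mean_scores <= 1)).all()
    assert (a.mean_importance >= 0).all()
    assert a.mean_importance.sum() == pytest.approx(1.0, abs=1e-9)


def test_ensemble_requires_both_classes():
    cohort, _ = _small_cohort()
    cohort = ExpressionCohort(cohort.values, pd.Series(1, index=cohort.labels.index),
                              cohort.cohort_id)
    with pytest.raises(ValueError):
        rf_ensemble_scores(cohort)


def test_planted_genes_dominate_importance():
    hits = 0
    for seed in range(10):
        cohort, truth = _small_cohort(seed=seed, n_genes=100, n=30, n_planted=5)
        res = rf_ensemble_scores(cohort, EnsembleConfig(seed=seed))
        top5 = set(res.ranked_genes()[:5])
        if len(top5 & set(truth.informative_genes)) >= 4:
            hits += 1
    assert hits >= 9


def test_ranked_genes_tie_break_lexicographic():
    res = ns.classifiers.EnsembleResult(
        mean_scores=pd.Series(dtype=float),
        mean_importance=pd.Series({"b": 0.3, "a": 0.3, "c": 0.4}),
        n_forests=1, n_trees=1, seed=0)
    assert res.ranked_genes() == ["c", "a", "b"]


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def test_extraction_fixed_k_and_bounds():
    cohort, _ = _small_cohort(seed=3)
    res = rf_ensemble_scores(cohort, EnsembleConfig(n_forests=3, seed=3))
    clf = extract_data_driven_classifier(res, cohort, ExtractionConfig(k_min=5, k_max=5))
    assert len(clf.genes) == 5
    assert clf.genes == res.ranked_genes()[:5]
    clf2 = extract_data_driven_classifier(res, cohort, ExtractionConfig(k_min=5, k_max=12))
    assert 5 <= len(clf2.genes) <= 12
    with pytest.raises(ValueError):
        extract_data_driven_classifier(res, cohort, ExtractionConfig(k_min=5, k_max=10**4))
    with pytest.raises(ValueError):
        ExtractionConfig(k_min=0)


def test_extraction_recovers_planted_genes():
    cohort, truth = _small_cohort(seed=5, n_genes=100, n=40, n_planted=5)
    res = rf_ensemble_scores(cohort, EnsembleConfig(seed=5))
    clf = extract_data_driven_classifier(res, cohort)
    assert len(set(clf.genes) & set(truth.informative_genes)) >= 4


# ---------------------------------------------------------------------------
# mutual information oracle
# ---------------------------------------------------------------------------

def test_mi_matches_sklearn_on_identical_binning(rng):
    for _ in range(50):
        values = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        edges = np.quantile(values, np.linspace(0, 1, 5)[1:-1])
        bins = np.digitize(values, np.unique(edges))
        expected = mutual_info_score(bins, labels)
        got = mutual_information_binned(values, labels)
        assert got == pytest.approx(expected, abs=1e-12)


def test_mi_nonnegative_and_monotone_invariant(rng):
    values = rng.normal(size=60)
    labels = rng.integers(0, 2, size=60)
    mi = mutual_information_binned(values, labels)
    assert mi >= 0
    assert mutual_information_binned(np.exp(values), labels) == pytest.approx(mi, abs=1e-12)


def test_mi_zero_for_constant_gene(rng):
    labels = rng.integers(0, 2, size=30)
    assert mutual_information_binned(np.full(30, 2.0), labels) == pytest.approx(0.0)


def test_mi_high_for_perfect_separation():
    labels = np.repeat([0, 1], 20)
    values = labels + 0.01 * np.arange(40)
    assert mutual_information_binned(values, labels) > 0.4  # near log 2 nats


# ---------------------------------------------------------------------------
# VIF oracle
# ---------------------------------------------------------------------------

def test_vif_matches_statsmodels(rng):
    x = rng.normal(size=(50, 4))
    x[:, 3] = x[:, 0] + 0.5 * x[:, 1] + 0.3 * rng.normal(size=50)
    design = np.column_stack([np.ones(50), x])
    expected = [variance_inflation_factor(design, j + 1) for j in range(4)]
    got = variance_inflation_factors(x)
    assert np.allclose(got, expected, atol=1e-8)


def test_vif_duplicate_columns_are_infinite(rng):
    x = rng.normal(size=(30, 3))
    x[:, 2] = x[:, 0]
    vifs = variance_inflation_factors(x)
    assert np.isinf(vifs[0]) and np.isinf(vifs[2])
    assert np.isfinite(vifs[1])


def test_vif_independent_columns_near_one(rng):
    vifs = variance_inflation_factors(rng.normal(size=(5000, 4)))
    assert np.allclose(vifs, 1.0, atol=0.05)


# ---------------------------------------------------------------------------
# reduction cascade
# ---------------------------------------------------------------------------

def test_reduce_single_gene_is_identity():
    cohort, truth = _small_cohort(seed=6)
    clf = GeneClassifier(name="one", genes=[truth.informative_genes[0]])
    reduced, report = reduce_classifier(cohort, clf)
    assert reduced.genes == clf.genes
    assert report.delta_auc == 0.0 and delta_auc_check(report)


def test_reduce_drops_duplicate_gene():
    cohort, truth = _small_cohort(seed=7)
    g = truth.informative_genes[0]
    values = cohort.values.copy()
    values.loc["GDUP"] = values.loc[g]    # perfect collinearity
    dup = ExpressionCohort(values, cohort.labels, cohort.cohort_id)
    clf = GeneClassifier(name="dup", genes=[g, "GDUP"])
    reduced, report = reduce_classifier(dup, clf)
    assert len(reduced.genes) == 1
    assert report.vif_dropped == ["GDUP"]  # lexicographically larger goes


def test_reduce_respects_target_and_retains_signal():
    cohort, truth = _small_cohort(seed=8, n_genes=60, n=40, n_planted=5)
    clf = GeneClassifier(name="big", genes=list(cohort.values.index))
    reduced, report = reduce_classifier(cohort, clf, target_max=10)
    assert len(reduced.genes) <= 10
    assert report.output_size == len(reduced.genes)
    assert set(report.mi_dropped).isdisjoint(reduced.genes)
    assert delta_auc_check(report)


def test_reduce_keeps_best_gene_when_all_below_threshold():
    cohort, _ = _small_cohort(seed=9, n_planted=0, effect=0.0)
    clf = GeneClassifier(name="null", genes=list(cohort.values.index[:8]))
    reduced, _ = reduce_classifier(cohort, clf, theta_mi=10.0)  # nothing passes
    assert len(reduced.genes) == 1


def test_logistic_scores_separable_auc_one():
    cohort, truth = _small_cohort(seed=10, effect=6.0)
    clf = GeneClassifier(name="strong", genes=truth.informative_genes)
    scores, auc = logistic_scores(cohort, clf)
    assert auc == pytest.approx(1.0)
    assert ((scores >= 0) & (scores <= 1)).all()


def test_logistic_scores_require_shared_genes():
    cohort, _ = _small_cohort()
    with pytest.raises(ValueError):
        logistic_scores(cohort, GeneClassifier(name="alien", genes=["NOPE"]))


# ---------------------------------------------------------------------------
# top-10 refinement and unions
# ---------------------------------------------------------------------------

def test_top10_refine_truncates_and_orders():
    cohort, _ = _small_cohort(seed=11, n_genes=40)
    clf = GeneClassifier(name="wide", genes=list(cohort.values.index[:25]))
    refined = top10_refine(cohort, clf, seed=11)
    assert len(refined.genes) == 10
    assert set(refined.genes) <= set(clf.genes)
    # original classifier order preserved
    pos = [clf.genes.index(g) for g in refined.genes]
    assert pos == sorted(pos)
    small = GeneClassifier(name="small", genes=list(cohort.values.index[:4]))
    assert top10_refine(cohort, small).genes == small.genes


def test_union_dedup_first_seen_order():
    a = GeneClassifier(name="a_top10", genes=["g3", "g1"])
    b = GeneClassifier(name="b_top10", genes=["g1", "g2"])
    union = build_union([a, b])
    assert union.genes == ["g3", "g1", "g2"]
    assert set(union.genes) == set(a.genes) | set(b.genes)
    assert union.provenance == "union"
    with pytest.raises(ValueError):
        build_union([])
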