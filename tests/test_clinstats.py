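"""Clinical statistics: cutoffs, odds ratios, stepwise logistic selection,
ratio tables and the survival machinery with hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.contingency_tables import Table2x2

import nacstrat as ns
from nacstrat.clinstats import (ContingencyTable, SurvivalRecord,
                                backward_stepwise_logistic, class_percentages,
                                fit_panel_model, heuristic_cutoff, km_curve,
                                logrank_test, ratio_analysis,
                                stratify_predicted, univariate_or)
from nacstrat.panelsel import MarkerPanel


# ---------------------------------------------------------------------------
# oracles written independently of the implementation
# ---------------------------------------------------------------------------

def km_oracle(times, events):
    """Product-limit by hand: deaths precede censorings at tied times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    event_times = np.unique(times[events == 1])
    surv, s = [], 1.0
    for t in event_times:
        n = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / n
        surv.append(s)
    return event_times, np.array(surv)


def logrank_oracle(t1, e1, t2, e2):
    """Hand tabulation of observed-minus-expected and hypergeometric variance."""
    t1, e1 = np.asarray(t1, float), np.asarray(e1, int)
    t2, e2 = np.asarray(t2, float), np.asarray(e2, int)
    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1, e2])
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(all_t[all_e == 1]):
        n1 = np.sum(t1 >= t)
        n2 = np.sum(t2 >= t)
        n = n1 + n2
        d = np.sum((all_t == t) & (all_e == 1))
        d1 = np.sum((t1 == t) & (e1 == 1))
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


# ---------------------------------------------------------------------------
# dichotomization and odds ratios
# ---------------------------------------------------------------------------

def test_cutoff_on_separable_values():
    values = [1, 2, 3, 10, 11, 12]
    labels = [0, 0, 0, 1, 1, 1]
    cutoff, table = heuristic_cutoff(values, labels)
    assert cutoff == pytest.approx(6.5)
    assert (table.a, table.b, table.c, table.d) == (3, 0, 0, 3)


def test_cutoff_matches_brute_force_oracle(rng):
    for _ in range(20):
        values = rng.normal(size=25)
        labels = rng.integers(0, 2, size=25)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        cutoff, _ = heuristic_cutoff(values, labels)
        distinct = np.unique(values)
        stats_by_cut = {}
        for lo, hi in zip(distinct[:-1], distinct[1:]):
            cut = 0.5 * (lo + hi)
            high = values > cut
            tab = np.array([[np.sum(high & (labels == 1)), np.sum(high & (labels == 0))],
                            [np.sum(~high & (labels == 1)), np.sum(~high & (labels == 0))]])
            try:
                s, _, _, _ = stats.chi2_contingency(tab, correction=False)
            except ValueError:
                s = 0.0
            stats_by_cut[cut] = s
        best = max(stats_by_cut.values())
        assert stats_by_cut[cutoff] == pytest.approx(best, abs=1e-10)
        # tie rule: no smaller cutoff attains the same statistic
        assert all(s < best - 1e-10 or c >= cutoff
                   for c, s in stats_by_cut.items())


def test_cutoff_validation():
    with pytest.raises(ValueError):
        heuristic_cutoff([2.0, 2.0, 2.0], [0, 1, 0])
    with pytest.raises(ValueError):
        heuristic_cutoff([1.0, 2.0], [1, 1])


def test_odds_ratio_hand_example():
    res = univariate_or(ContingencyTable(a=10, b=5, c=4, d=20))
    assert res.odds_ratio == pytest.approx(10.0)
    assert not res.correction_applied
    assert res.ci_low < 10.0 < res.ci_high
    assert 0.0 <= res.p_value <= 1.0


def test_odds_ratio_ci_matches_statsmodels():
    table = ContingencyTable(a=12, b=7, c=5, d=18)
    res = univariate_or(table)
    sm_table = Table2x2(table.counts())
    assert res.odds_ratio == pytest.approx(sm_table.oddsratio, abs=1e-12)
    lo, hi = sm_table.oddsratio_confint(0.05)
    assert res.ci_low == pytest.approx(lo, abs=1e-10)
    assert res.ci_high == pytest.approx(hi, abs=1e-10)


def test_odds_ratio_zero_cell_correction_and_reciprocal():
    res = univariate_or(ContingencyTable(a=10, b=0, c=4, d=20))
    assert res.correction_applied and np.isfinite(res.odds_ratio)
    a = univariate_or(ContingencyTable(a=9, b=4, c=6, d=11))
    b = univariate_or(ContingencyTable(a=4, b=9, c=11, d=6))  # exposure transposed
    assert a.odds_ratio == pytest.approx(1.0 / b.odds_ratio, abs=1e-12)


def test_balanced_table_gives_unit_or():
    res = univariate_or(ContingencyTable(a=5, b=5, c=5, d=5))
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# stepwise logistic
# ---------------------------------------------------------------------------

def _stepwise_data(seed=0, n=200):
    rng = np.random.default_rng(seed)
    x = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("wxyz"))
    logits = 2.0 * x["x"] - 0.5
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    return x, y


def test_stepwise_alpha_one_is_identity():
    x, y = _stepwise_data()
    cols, ors = backward_stepwise_logistic(x, y, alpha=1.0)
    assert cols == list(x.columns)
    assert set(ors) == set(cols)


def test_stepwise_retains_true_predictor():
    x, y = _stepwise_data(seed=3)
    cols, ors = backward_stepwise_logistic(x, y, alpha=0.05)
    assert "x" in cols
    assert ors["x"].odds_ratio > 1.0
    assert ors["x"].p_value < 0.05
    assert ors["x"].ci_low < ors["x"].odds_ratio < ors["x"].ci_high


def test_stepwise_drops_pure_noise():
    rng = np.random.default_rng(5)
    x = pd.DataFrame(rng.normal(size=(150, 3)), columns=list("abc"))
    y = rng.integers(0, 2, size=150)
    cols, _ = backward_stepwise_logistic(x, y, alpha=0.01)
    assert len(cols) <= 1  # at most a chance survivor at the 1% level


def test_stepwise_requires_enough_observations():
    rng = np.random.default_rng(6)
    x = pd.DataFrame(rng.normal(size=(4, 5)))
    with pytest.raises(ValueError):
        backward_stepwise_logistic(x, [0, 1, 0, 1])


# ---------------------------------------------------------------------------
# ratio analysis
# ---------------------------------------------------------------------------

def test_ratio_analysis_scale_invariance(pathology_small):
    table, _ = pathology_small
    denom = table.markers("tumor")[0]
    base = ratio_analysis(table, denom, compartment="tumor")
    scaled_cores = table.cores.copy()
    scaled_cores["value"] *= 3.0
    scaled = ns.PathologyTable(table.clinical, table.means, scaled_cores)
    rescaled = ratio_analysis(scaled, denom, compartment="tumor")
    assert np.allclose(base[["mean_NR", "mean_R"]].to_numpy(),
                       rescaled[["mean_NR", "mean_R"]].to_numpy(), atol=1e-12)


def test_ratio_analysis_zscores_and_missing_denominator(pathology_small):
    table, _ = pathology_small
    denom = table.markers("tumor")[0]
    out = ratio_analysis(table, denom, compartment="tumor")
    assert denom not in out.index
    for col in ("z_NR", "z_R"):
        assert out[col].mean() == pytest.approx(0.0, abs=1e-10)
        assert out[col].std(ddof=0) == pytest.approx(1.0, abs=1e-10)
    with pytest.raises(ValueError):
        ratio_analysis(table, "NOT_A_MARKER")


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def _records(times, events, group="g"):
    return [SurvivalRecord(patient=f"p{i}", time=float(t), event=int(e), group=group)
            for i, (t, e) in enumerate(zip(times, events))]


def test_km_worked_three_patient_examples():
    curve = km_curve(_records([1, 2, 3], [1, 1, 1]))
    assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0], atol=1e-12)
    assert np.array_equal(curve.at_risk, [3, 2, 1])

    censored = km_curve(_records([1, 2, 3], [1, 0, 1]))
    assert np.allclose(censored.times, [1, 3])
    assert np.allclose(censored.survival, [2 / 3, 0.0], atol=1e-12)

    all_censored = km_curve(_records([1, 2, 3], [0, 0, 0]))
    assert len(all_censored.times) == 0  # no events -> S stays at 1


def test_km_worked_six_patient_example():
    curve = km_curve(_records([1, 2, 2, 3, 4, 5], [1, 1, 0, 1, 0, 1]))
    assert np.allclose(curve.times, [1, 2, 3, 5])
    assert np.allclose(curve.survival, [5 / 6, 2 / 3, 4 / 9, 0.0], atol=1e-12)


def test_km_matches_hand_oracle_with_ties(rng):
    for _ in range(50):
        n = int(rng.integers(3, 25))
        times = rng.integers(1, 8, size=n).astype(float)  # integer times force ties
        events = rng.integers(0, 2, size=n)
        if events.sum() == 0:
            events[0] = 1
        curve = km_curve(_records(times, events))
        o_times, o_surv = km_oracle(times, events)
        assert np.allclose(curve.times, o_times)
        assert np.allclose(curve.survival, o_surv, atol=1e-12)


def test_survival_record_validation():
    with pytest.raises(ValueError):
        SurvivalRecord(patient="p", time=0.0, event=1, group="g")
    with pytest.raises(ValueError):
        SurvivalRecord(patient="p", time=1.0, event=2, group="g")
    with pytest.raises(ValueError):
        km_curve([])


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def test_logrank_identical_groups_null():
    recs = _records([1, 2, 3, 4], [1, 1, 1, 0], "a") + \
        _records([1, 2, 3, 4], [1, 1, 1, 0], "b")
    res = logrank_test(recs)
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0, abs=1e-12)


def test_logrank_matches_hand_tabulation():
    t1, e1 = [1, 3, 5], [1, 1, 1]
    t2, e2 = [2, 4, 6], [1, 1, 0]
    recs = _records(t1, e1, "a") + _records(t2, e2, "b")
    res = logrank_test(recs)
    assert res.chi_square == pytest.approx(logrank_oracle(t1, e1, t2, e2), abs=1e-8)
    assert res.df == 1


def test_logrank_group_label_swap_invariance(rng):
    t1 = rng.exponential(10, size=15)
    t2 = rng.exponential(5, size=15)
    recs_a = _records(t1, np.ones(15), "a") + _records(t2, np.ones(15), "b")
    recs_b = _records(t1, np.ones(15), "b") + _records(t2, np.ones(15), "a")
    assert logrank_test(recs_a).chi_square == pytest.approx(
        logrank_test(recs_b).chi_square, abs=1e-12)


def test_logrank_validation():
    with pytest.raises(ValueError):
        logrank_test(_records([1, 2], [1, 1], "only_one_group"))
    recs = _records([1, 2], [0, 0], "a") + _records([3], [0], "b")
    with pytest.raises(ValueError):
        logrank_test(recs)  # no events at all


def test_logrank_power_under_strong_hazard_ratio():
    rejections = 0
    rng = np.random.default_rng(17)
    for _ in range(100):
        t1 = rng.exponential(1.0 / 0.02, size=200)          # responders
        t2 = rng.exponential(1.0 / 0.04, size=200)          # HR = 2
        recs = _records(t1, np.ones(200), "r") + _records(t2, np.ones(200), "nr")
        if logrank_test(recs).p_value < 0.05:
            rejections += 1
    assert rejections >= 95


# ---------------------------------------------------------------------------
# predicted-group stratification
# ---------------------------------------------------------------------------

def test_stratify_partitions_patients(pathology_small):
    table, _ = pathology_small
    markers = table.feature_columns("tumor")[:2]
    panel = MarkerPanel(markers, "logistic", "raw", "forward")
    fitted = fit_panel_model(panel, table, seed=0)
    strat = stratify_predicted(fitted, table)
    assert len(strat.groups) == len(table.means)
    assert set(strat.groups.unique()) <= {"response", "nonresponse"}
    assert set(k[0] for k in strat.tests) <= {"NAC", "PCT", "ALL"}
    for key, test in strat.tests.items():
        assert 0.0 <= test.p_value <= 1.0
    # curves exist for each tested (cohort, endpoint)
    for cohort, ep in strat.tests:
        assert any(c == cohort and e == ep for c, e, _ in strat.curves)


def test_stratify_with_recovered_panel_separates_survival(pathology_small):
    table, truth = pathology_small
    planted = [f"{m}__tumor" for m in truth.predictive_markers["tumor"]] + \
              [f"{m}__stroma" for m in truth.predictive_markers["stroma"]]
    panel = MarkerPanel(planted[:4], "logistic", "raw", "forward")
    fitted = fit_panel_model(panel, table, seed=0)
    strat = stratify_predicted(fitted, table)
    assert ("ALL", "os") in strat.tests
    assert strat.tests[("ALL", "os")].p_value < 0.05


def test_class_percentages_exact_and_validated():
    pct = class_percentages({"Ba/Sq": 11, "LumU": 10, "LumP": 18})
    assert pct == {"Ba/Sq": 28.21, "LumU": 25.64, "LumP": 46.15}
    with pytest.raises(ValueError):
        class_percentages({"a": 0})
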