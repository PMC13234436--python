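"""Stratify predicted response groups and compare their survival.

Fits the winning marker panel on the NAC cohort, assigns every patient a
predicted response group, and compares overall survival between groups
with Kaplan-Meier curves and the log-rank test, per cohort and pooled.
"""

import nacstrat as ns
from nacstrat.clinstats import fit_panel_model, stratify_predicted
from nacstrat.panelsel import build_pools, search_best_panel


def main():
    spec = ns.PathologySimSpec(n_patients=(110, 90), n_markers=12, n_predictive=2,
                               seed=7)
    table, _ = ns.generate_pathology(spec)
    pools = build_pools(table, n_pools=3, seed=7)
    best, _, _ = search_best_panel(pools, table, sizes=(2, 3, 4),
                                   data_types=("raw",), seed=7)
    print(f"panel: {best.markers} (base={best.base})")

    fitted = fit_panel_model(best, table, train_cohort="NAC", seed=7)
    strat = stratify_predicted(fitted, table)
    counts = strat.groups.value_counts()
    print(f"predicted groups: {counts.to_dict()} (partition of "
          f"{len(table.means)} patients)")

    print("\nlog-rank comparisons (predicted response vs nonresponse):")
    for (cohort, endpoint), test in sorted(strat.tests.items()):
        print(f"  {cohort:>4} {endpoint.upper():>3}: chi2 = {test.chi_square:6.2f}, "
              f"p = {test.p_value:.4f}")
    p = strat.tests[("ALL", "os")].p_value
    print(f"\npooled OS p-value {p:.4g}: the panel-predicted groups separate "
          "survival, as expected when hazard is coupled to the latent response "
          "(HR = 2.5)")


if __name__ == "__main__":
    main()
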