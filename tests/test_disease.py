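import numpy as np
import pandas as pd
import pytest

import pregmeth as pm
from pregmeth.disease import (
    DMCriterion,
    cpg_enrichment,
    direction_correlation,
    fisher_margin_scan,
    fisher_table,
    geneset_enrichment,
    vista_subgroups,
)
from pregmeth.experiments import fisher_oracle_margin


class TestFisherEnrichment:
    def test_fold_enrichment_arithmetic(self):
        bg = [f"g{i}" for i in range(1000)]
        target = bg[:100]
        query = bg[80:130]  # overlap 20, query 50
        res = geneset_enrichment(query, target, bg)
        assert res.fold_enrichment == pytest.approx(4.0)
        assert (res.a, res.b, res.c, res.d) == (20, 30, 80, 870)
        assert res.a + res.b + res.c + res.d == res.background

    def test_query_equals_target_maximal_fe(self):
        bg = [f"g{i}" for i in range(200)]
        target = bg[:20]
        res = geneset_enrichment(target, target, bg)
        assert res.fold_enrichment == pytest.approx(200 / 20)

    def test_two_sided_p_matches_hypergeometric_oracle(self):
        for n, r, c, a in [(60, 10, 15, 5), (40, 8, 8, 0), (25, 5, 20, 4), (12, 6, 6, 6)]:
            b, cc, d = r - a, c - a, n - r - c + a
            if min(b, cc, d) < 0 or a + b == 0 or a + cc == 0:
                continue
            fe, p = fisher_table(a, b, cc, d)
            fe_o, p_o = fisher_oracle_margin(r, c, n)
            support = np.arange(max(0, r + c - n), min(r, c) + 1)
            k = int(np.where(support == a)[0][0])
            assert p == pytest.approx(p_o[k], rel=1e-7)
            assert fe == pytest.approx(fe_o[k], rel=1e-12)

    def test_margin_scan_agrees_with_single_table_route(self):
        support, fe, p = fisher_margin_scan(10, 15, 60)
        for i, a in enumerate(support):
            b, c, d = 10 - a, 15 - a, 60 - 25 + a
            if a + b == 0 or a + c == 0:
                continue
            fe_s, p_s = fisher_table(int(a), int(b), int(c), int(d))
            assert p_s == pytest.approx(p[i], rel=1e-7)
            assert fe_s == pytest.approx(fe[i], rel=1e-12)

    def test_empty_query_or_target_raise(self):
        bg = list("abcdefgh")
        with pytest.raises(ValueError):
            geneset_enrichment([], ["a"], bg)
        with pytest.raises(ValueError):
            geneset_enrichment(["a"], [], bg)

    def test_disjoint_sets_fe_zero(self):
        bg = [f"c{i}" for i in range(100)]
        res = cpg_enrichment(bg[:10], bg[50:60], bg)
        assert res.fold_enrichment == 0.0
        assert res.overlap_ids == []

    def test_nested_sets_fe(self):
        bg = [f"c{i}" for i in range(100)]
        module = bg[:10]
        disease = bg[:30]
        res = cpg_enrichment(module, disease, bg)
        assert res.a == 10
        assert res.fold_enrichment == pytest.approx(100 / 30)


class TestDirectionCorrelation:
    def test_exact_anticorrelation(self):
        x = pd.Series(np.linspace(-0.1, 0.1, 10), index=[f"c{i}" for i in range(10)])
        res = direction_correlation(x, -1.0 * x)
        assert res.pearson_r == pytest.approx(-1.0)
        assert res.spearman_rho == pytest.approx(-1.0)
        assert res.sign == -1

    def test_exact_correlation(self):
        x = pd.Series([0.05, -0.1, 0.2, 0.08], index=list("abcd"))
        res = direction_correlation(x, x)
        assert res.pearson_r == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        x = pd.Series([0.1, 0.1, 0.1], index=list("abc"))
        y = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        with pytest.raises(ValueError, match="zero variance"):
            direction_correlation(x, y)

    def test_too_small_overlap_raises(self):
        x = pd.Series([0.1, 0.2], index=list("ab"))
        with pytest.raises(ValueError):
            direction_correlation(x, x)


class TestVista:
    def test_zero_removal_budget_is_identity(self, small_cohort):
        (_, truth), cfg = small_cohort
        ddata, _ = pm.simulate_disease_cohort(cfg, truth)
        sel = vista_subgroups(ddata, max_removed_fraction=0.0)
        assert sel.removed == []
        assert len(sel.retained_controls) == 10
        assert len(sel.retained_cases) == 15

    def test_planted_controls_removed(self, small_cohort):
        (_, truth), cfg = small_cohort
        ddata, dtruth = pm.simulate_disease_cohort(cfg, truth)
        sel = vista_subgroups(ddata, max_removed_fraction=0.6)
        assert sorted(sel.removed_ids) == sorted(dtruth.overlap_controls)

    def test_never_removes_cases_by_default(self, small_cohort):
        (_, truth), cfg = small_cohort
        ddata, _ = pm.simulate_disease_cohort(cfg, truth)
        sel = vista_subgroups(ddata, max_removed_fraction=0.6)
        assert len(sel.retained_cases) == 15

    def test_score_trace_monotone(self, small_cohort):
        (_, truth), cfg = small_cohort
        ddata, _ = pm.simulate_disease_cohort(cfg, truth)
        sel = vista_subgroups(ddata, max_removed_fraction=0.6)
        assert all(b > a for a, b in zip(sel.score_trace, sel.score_trace[1:]))

    def test_small_groups_rejected(self, small_cohort):
        (ds, _), _ = small_cohort
        with pytest.raises(ValueError):
            vista_subgroups(ds, case_label="T2", control_label="missing")
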