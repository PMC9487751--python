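import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import procrustes

import pregmeth as pm
from pregmeth.diffmeth import (
    DesignError,
    adjust_fdr,
    build_design,
    call_dmps,
    compute_delta_beta,
    fit_probe_models,
    map_dmps_to_genes,
    mds_coordinates,
)


def _two_group_design(n1=3, n2=3):
    ids = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    samples = pd.DataFrame({"group": ["A"] * n1 + ["B"] * n2}, index=ids)
    return samples, build_design(samples, reference_group="A")


class TestBuildDesign:
    def test_full_omega_block_is_collinear(self, small_cohort):
        (ds, truth), _ = small_cohort
        with pytest.raises(DesignError, match="collinear"):
            build_design(ds.samples, truth.omega, drop_omega_column=None)

    def test_default_drops_one_omega_column(self, small_cohort):
        (ds, truth), _ = small_cohort
        design = build_design(ds.samples, truth.omega)
        omega_cols = [c for c in design.columns if c.startswith("omega_")]
        assert len(omega_cols) == truth.omega.shape[1] - 1

    def test_unknown_reference_raises(self, small_cohort):
        (ds, _), _ = small_cohort
        with pytest.raises(DesignError):
            build_design(ds.samples, reference_group="nope")


class TestFitProbeModels:
    def test_identical_residual_variances_make_moderation_a_noop(self):
        samples, design = _two_group_design()
        rng = np.random.default_rng(0)
        base = rng.normal(size=6)
        # every probe shares the same residual pattern, hence the same s2
        y = pd.DataFrame(
            [base + shift for shift in np.linspace(-1, 1, 8)],
            index=[f"p{i}" for i in range(8)],
            columns=samples.index,
        )
        fit_mod = fit_probe_models(y, design, moderated=True)
        fit_plain = fit_probe_models(y, design, moderated=False)
        assert np.allclose(fit_mod["t"].to_numpy(), fit_plain["t"].to_numpy(), rtol=1e-9)

    def test_separated_toy_groups_closed_form(self):
        samples, design = _two_group_design()
        y = pd.DataFrame([[1, 1, 1, 3, 3, 3]], index=["p1"], columns=samples.index)
        fit = fit_probe_models(y, design, moderated=False)
        row = fit.xs("B_vs_A", level="contrast").iloc[0]
        assert row["coef"] == pytest.approx(2.0)
        assert row["p"] < 1e-6

    def test_ols_coefficient_matches_group_mean_difference(self, rng):
        samples, design = _two_group_design(6, 6)
        y = pd.DataFrame(
            rng.normal(size=(30, 12)), index=[f"p{i}" for i in range(30)], columns=samples.index
        )
        fit = fit_probe_models(y, design, moderated=False)
        coefs = fit.xs("B_vs_A", level="contrast")["coef"]
        manual = y.iloc[:, 6:].mean(axis=1) - y.iloc[:, :6].mean(axis=1)
        assert np.allclose(coefs.to_numpy(), manual.to_numpy(), atol=1e-10)

    def test_rank_deficient_design_raises(self):
        samples = pd.DataFrame({"group": ["A", "A", "B", "B"]}, index=list("wxyz"))
        design = build_design(samples, reference_group="A")
        design.matrix["dup"] = design.matrix["group_B"]
        with pytest.raises(DesignError):
            fit_probe_models(
                pd.DataFrame(np.zeros((3, 4)), columns=samples.index), design
            )


class TestAdjustFdr:
    def test_hand_computed_bh(self):
        assert np.allclose(adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_degenerate_inputs(self):
        assert np.allclose(adjust_fdr([1.0, 1.0]), [1.0, 1.0])
        assert adjust_fdr([0.2]) == pytest.approx([0.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_matches_manual_step_up_and_dominates_p(self, pvals):
        """BH against a from-scratch step-up computation."""
        p = np.array(pvals)
        q = adjust_fdr(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        manual = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            manual[i] = running
        assert np.allclose(q, manual, atol=1e-12)
        assert np.all(q >= p - 1e-12)


class TestDeltaBetaAndCalling:
    def test_arithmetic(self):
        betas = pd.DataFrame(
            {"s1": [0.55], "s2": [0.55], "s3": [0.45], "s4": [0.45]}, index=["p"]
        )
        groups = pd.Series(["B", "B", "A", "A"], index=betas.columns)
        db = compute_delta_beta(betas, groups, ("A", "B"))
        assert db.loc["p"] == pytest.approx(0.10)
        assert compute_delta_beta(betas, groups, ("B", "B")).loc["p"] == 0

    def test_empty_group_raises(self):
        betas = pd.DataFrame({"s1": [0.5]}, index=["p"])
        groups = pd.Series(["A"], index=["s1"])
        with pytest.raises(ValueError):
            compute_delta_beta(betas, groups, ("A", "Z"))

    @pytest.mark.parametrize(
        "p,db,expected_dmp,expected_dir",
        [
            (1e-4, 0.04, False, "hyper"),  # fails the 5% effect rule
            (0.9, 0.20, False, "hyper"),  # fails FDR
            (1e-4, -0.08, True, "hypo"),  # passes both, negative sign
        ],
    )
    def test_joint_criterion(self, p, db, expected_dmp, expected_dir):
        stats_table = pd.DataFrame({"p": [p] + [0.5] * 9}, index=[f"p{i}" for i in range(10)])
        delta = pd.Series([db] + [0.0] * 9, index=stats_table.index)
        out = call_dmps(stats_table, delta)
        row = out.loc["p0"]
        assert bool(row["is_dmp"]) is expected_dmp
        assert row["direction"] == expected_dir

    def test_boundary_values_excluded(self):
        stats_table = pd.DataFrame({"p": [0.05]}, index=["p0"])
        delta = pd.Series([0.05], index=["p0"])
        assert not call_dmps(stats_table, delta)["is_dmp"].iloc[0]

    def test_tightening_thresholds_is_monotone(self, rng):
        stats_table = pd.DataFrame({"p": rng.uniform(size=200)}, index=range(200))
        delta = pd.Series(rng.uniform(-0.2, 0.2, size=200), index=range(200))
        loose = call_dmps(stats_table, delta, q_thresh=0.2, db_thresh=0.02)
        tight = call_dmps(stats_table, delta, q_thresh=0.05, db_thresh=0.08)
        assert set(tight.index[tight["is_dmp"]]) <= set(loose.index[loose["is_dmp"]])


class TestDmgMapping:
    def _table(self, rows):
        df = pd.DataFrame(
            rows, columns=["probe_id", "q", "direction", "is_dmp", "delta_beta"]
        ).set_index("probe_id")
        return df

    def _annotation(self, mapping):
        return pd.DataFrame({"gene": pd.Series(mapping)})

    def test_majority_rule(self):
        table = self._table(
            [
                ["p1", 0.01, "hyper", True, 0.1],
                ["p2", 0.02, "hyper", True, 0.1],
                ["p3", 0.03, "hypo", True, -0.1],
            ]
        )
        ann = self._annotation({"p1": "G1", "p2": "G1", "p3": "G1"})
        dmgs = map_dmps_to_genes(table, ann)
        assert dmgs.loc["G1", "direction"] == "hyper"
        assert dmgs.loc["G1", "n_dmps"] == 3

    def test_single_dmp_majority_of_one(self):
        table = self._table([["p1", 0.01, "hypo", True, -0.1]])
        dmgs = map_dmps_to_genes(table, self._annotation({"p1": "G1"}))
        assert dmgs.loc["G1", "direction"] == "hypo"

    def test_tie_broken_by_smallest_q(self):
        table = self._table(
            [["p1", 0.001, "hyper", True, 0.1], ["p2", 0.04, "hypo", True, -0.1]]
        )
        dmgs = map_dmps_to_genes(table, self._annotation({"p1": "G1", "p2": "G1"}))
        assert dmgs.loc["G1", "direction"] == "hyper"
        assert dmgs.loc["G1", "representative_probe"] == "p1"

    def test_multi_gene_probes_count_for_each(self):
        table = self._table([["p1", 0.01, "hyper", True, 0.1]])
        dmgs = map_dmps_to_genes(table, self._annotation({"p1": "G1;G2"}))
        assert set(dmgs.index) == {"G1", "G2"}

    def test_genes_without_dmps_excluded(self):
        table = self._table([["p1", 0.01, "hyper", False, 0.1]])
        dmgs = map_dmps_to_genes(table, self._annotation({"p1": "G1"}))
        assert len(dmgs) == 0


class TestMDS:
    def test_exact_planar_embedding_recovered(self, rng):
        pts = rng.normal(size=(10, 2))
        betas = pd.DataFrame(
            np.tile(pts.T, (5, 1)) / 10 + 0.5, columns=[f"s{i}" for i in range(10)]
        )
        coords, varexp = mds_coordinates(betas, n_top=10, n_components=2)
        _, _, disparity = procrustes(pts, coords.to_numpy())
        assert disparity < 1e-8

    def test_duplicate_samples_coincide(self, small_cohort):
        (ds, _), _ = small_cohort
        betas = ds.betas.copy()
        betas["dup"] = betas[betas.columns[0]]
        coords, _ = mds_coordinates(betas, n_top=200, n_components=3)
        assert np.allclose(
            coords.loc["dup"].to_numpy(), coords.iloc[0].to_numpy(), atol=1e-8
        )

    def test_variance_explained_ordered_and_bounded(self, small_cohort):
        (ds, _), _ = small_cohort
        _, varexp = mds_coordinates(ds.betas, n_top=300, n_components=6)
        assert varexp.sum() <= 1 + 1e-9
        assert np.all(np.diff(varexp) <= 1e-12)

    def test_components_truncated_to_samples(self):
        betas = pd.DataFrame(np.random.default_rng(0).uniform(size=(50, 4)))
        coords, varexp = mds_coordinates(betas, n_components=10)
        assert coords.shape[1] == 3
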