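"""Count generator, injection protocol and evaluation-harness metrics."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nhoodde.de import DesignSpec, aggregate_pseudobulk, ql_fit_and_test
from nhoodde.errors import InvalidInputError, InvalidParameterError
from nhoodde.graph import NeighborhoodAssignment
from nhoodde.results import DEResultMatrices
from nhoodde.simulate import (
    CONTROL,
    SimulationParams,
    SimulationTruth,
    decompose_to_cell_z,
    evaluate_detection,
    inject_perturbation,
    nhood_composition_metrics,
    power_curve,
    roc_auc,
    select_candidate_genes,
    simulate_counts,
)

SMALL = SimulationParams(
    n_genes=400, cells_per_batch=40, n_batches_per_condition=3, seed=5
)


class TestSimulateCounts:
    def test_same_seed_identical(self):
        a = simulate_counts(SMALL)
        b = simulate_counts(SMALL)
        assert (a.counts != b.counts).nnz == 0
        assert np.allclose(a.embedding.coords, b.embedding.coords)

    def test_null_simulation_is_calibrated(self):
        from dataclasses import replace

        params = replace(
            SMALL,
            n_genes=1200,
            cells_per_batch=50,
            de_prob=0.0,
            group_assignment="by_condition",
            group_fractions=(0.5, 0.5),
        )
        ds = simulate_counts(params)
        design = DesignSpec("condition", CONTROL)
        pb = aggregate_pseudobulk(ds, np.arange(ds.n_cells), design)
        table = ql_fit_and_test(pb, design)
        frac = (table["PValue"] < 0.05).mean()
        assert 0.02 <= frac <= 0.09

    def test_de_fraction_matches_de_prob(self):
        from dataclasses import replace

        params = replace(
            SMALL,
            n_genes=2000,
            cells_per_batch=160,  # enough cells for the pseudo-bulk mean to converge
            de_prob=0.25,
            de_facLoc=1.0,
            group_assignment="by_condition",
            group_fractions=(0.5, 0.5),
        )
        ds = simulate_counts(params)
        # pseudo-bulk logFC between conditions from normalized means
        counts = np.asarray(ds.counts.todense(), dtype=float)
        cond = ds.cell_meta["condition"].to_numpy()
        cpm = counts / counts.sum(axis=0) * 1e6
        lfc = np.log2(
            (cpm[:, cond == "case"].mean(axis=1) + 0.5)
            / (cpm[:, cond == CONTROL].mean(axis=1) + 0.5)
        )
        frac = (np.abs(lfc) > 0.5).mean()
        assert abs(frac - 0.25) < 0.05

    def test_invalid_params(self):
        from dataclasses import replace

        with pytest.raises(InvalidParameterError):
            simulate_counts(replace(SMALL, group_fractions=(0.6, 0.6)))
        with pytest.raises(InvalidParameterError):
            simulate_counts(replace(SMALL, de_prob=1.5))


class TestInjection:
    def test_max_add_zero_is_identity(self):
        ds = simulate_counts(SMALL)
        out, truth = inject_perturbation(
            ds, ds.gene_ids[:3], ds.cell_ids[:10], max_add=0, seed=1
        )
        assert (out.counts != ds.counts).nnz == 0
        assert np.allclose(truth.expected_logfc, 0.0, atol=0.5)

    def test_only_targets_change_and_never_decrease(self):
        ds = simulate_counts(SMALL)
        genes = ds.gene_ids[[5, 17]]
        cells = ds.cell_ids[30:60]
        out, _ = inject_perturbation(ds, genes, cells, max_add=2, seed=2)
        before = np.asarray(ds.counts.todense())
        after = np.asarray(out.counts.todense())
        delta = after - before
        assert np.all(delta >= 0)
        changed = np.argwhere(delta > 0)
        assert set(changed[:, 0]) <= {5, 17}
        assert set(changed[:, 1]) <= set(range(30, 60))

    def test_mean_added_count(self):
        ds = simulate_counts(
            SimulationParams(n_genes=30, cells_per_batch=170, n_batches_per_condition=3, seed=2)
        )
        cells = ds.cell_ids[:1000]
        out, _ = inject_perturbation(ds, ds.gene_ids[:5], cells, max_add=2, seed=3)
        delta = (out.counts - ds.counts).sum() / (5 * 1000)
        assert 0.9 <= delta <= 1.1

    def test_unknown_ids_rejected(self):
        ds = simulate_counts(SMALL)
        with pytest.raises(InvalidInputError):
            inject_perturbation(ds, np.array(["nope"]), ds.cell_ids[:5], 1)


class TestCandidateGenes:
    def test_shifted_gene_excluded_flat_gene_kept(self):
        from dataclasses import replace

        params = replace(SMALL, n_genes=300, cells_per_batch=80, seed=9)
        ds = simulate_counts(params)
        ds.cell_meta["cell_type"] = np.where(
            np.arange(ds.n_cells) % 2 == 0, "typeA", "typeB"
        )
        # inject a strong condition shift into one gene within typeA
        target = ds.cell_ids[
            ((ds.cell_meta["cell_type"] == "typeA")
             & (ds.cell_meta["condition"] == "case")).to_numpy()
        ]
        counts = ds.counts.tolil()
        counts[10] = counts[10].toarray() * 1
        ds.counts = counts.tocsr()
        shifted, _ = inject_perturbation(ds, ds.gene_ids[[10]], target, max_add=6, seed=4)
        shifted.counts[33] = sp.csr_matrix((1, shifted.n_cells))  # all-zero gene
        design = DesignSpec("condition", CONTROL, min_count=0)
        cands = select_candidate_genes(shifted, design, min_cells_per_type=50)
        assert "g00010" not in cands
        assert "g00033" not in cands
        assert len(cands) > 100


def assignment_from_membership(m):
    m = sp.csc_matrix(np.asarray(m, dtype=bool))
    return NeighborhoodAssignment(
        membership=m, index_cells=np.arange(m.shape[1]), order=1, k=1
    )


class TestCompositionMetrics:
    def test_pure_neighborhood(self):
        m = np.ones((4, 1))
        table = nhood_composition_metrics(assignment_from_membership(m), ["T"] * 4)
        assert table["T"].iloc[0] == 1.0
        assert table["enrichment_score"].iloc[0] == 1.0

    def test_fraction_and_sum_to_one(self, rng):
        m = rng.random((40, 6)) < 0.5
        m[0] = True
        labels = rng.choice(["a", "b", "c"], size=40)
        table = nhood_composition_metrics(assignment_from_membership(m), labels)
        purity = table[["a", "b", "c"]].to_numpy()
        assert np.allclose(purity.sum(axis=1), 1.0)
        assert np.allclose(table["enrichment_score"], purity.max(axis=1))
        # direct tabulation oracle for one neighborhood
        cells = np.where(m[:, 2])[0]
        for lab in "abc":
            assert table.loc[2, lab] == pytest.approx(
                np.mean(labels[cells] == lab)
            )


class TestEvaluateDetection:
    def make_results(self, p_rows):
        p = np.asarray(p_rows, dtype=float)
        res = DEResultMatrices.allocate([f"g{i}" for i in range(p.shape[0])], p.shape[1])
        res.p_adj_nhoods = p
        res.tested = ~np.isnan(p)
        return res

    def truth_for(self, res):
        return SimulationTruth(
            perturbed_genes=res.gene_ids,
            perturbed_cells=np.array(["c0"]),
            expected_logfc=pd.Series(1.0, index=res.gene_ids),
            max_add=2,
        )

    def test_perfect_detection(self):
        purity = np.array([0.5, 0.5, 0.0, 0.0])
        res = self.make_results([[0.01, 0.01, 0.5, 0.5]])
        out = evaluate_detection(res, self.truth_for(res), purity, 0.1)
        assert out["sensitivity"].iloc[0] == 1.0
        assert out["FDR"].iloc[0] == 0.0

    def test_no_detection(self):
        purity = np.array([0.5, 0.0])
        res = self.make_results([[0.9, 0.9]])
        out = evaluate_detection(res, self.truth_for(res), purity, 0.1)
        assert out["sensitivity"].iloc[0] == 0.0
        assert out["FDR"].iloc[0] == 0.0

    def test_confusion_arithmetic(self):
        purity = np.concatenate([np.full(10, 0.5), np.zeros(5)])
        p = np.full(15, 1.0)
        p[:7] = 0.01  # 7 true positives
        p[10] = 0.01  # 1 false positive
        res = self.make_results([p])
        out = evaluate_detection(res, self.truth_for(res), purity, 0.1)
        assert out["sensitivity"].iloc[0] == pytest.approx(0.7)
        assert out["FDR"].iloc[0] == pytest.approx(1 / 8)

    def test_zero_ground_truth_warns(self):
        res = self.make_results([[0.5, 0.5]])
        with pytest.warns(UserWarning):
            out = evaluate_detection(res, self.truth_for(res), np.zeros(2), 0.5)
        assert np.isnan(out["sensitivity"].iloc[0])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_equal_scores(self):
        assert roc_auc([1, 1, 1, 1], [0, 1, 0, 1]) == 0.5

    def test_matches_pair_counting(self, rng):
        scores = rng.choice(np.linspace(0, 1, 20), size=60)
        labels = rng.random(60) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        auc = roc_auc(scores, labels)
        pos = scores[labels]
        neg = scores[~labels]
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p, n in itertools.product(pos, neg)
        )
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(roc_auc([1, 2], [1, 1]))

    def test_nan_scores_excluded(self):
        assert roc_auc([np.nan, 1, 2], [1, 0, 1]) == 1.0


class TestDecomposeZ:
    def build(self, p_row, membership):
        res = DEResultMatrices.allocate(["g0"], len(p_row))
        res.p_adj_nhoods[0] = p_row
        res.tested[0] = ~np.isnan(np.asarray(p_row, dtype=float))
        return res, assignment_from_membership(membership)

    def test_p_half_gives_zero(self):
        res, a = self.build([0.5], np.ones((3, 1)))
        z = decompose_to_cell_z(res, a, "g0")
        assert np.allclose(z, 0.0)

    def test_mean_across_neighborhoods(self):
        res, a = self.build([0.5, 0.5], np.ones((3, 2)))
        assert np.allclose(decompose_to_cell_z(res, a, "g0"), 0.0)

    def test_inverse_normal_value(self):
        res, a = self.build([0.0013], np.ones((2, 1)))
        z = decompose_to_cell_z(res, a, "g0")
        assert np.allclose(z, 3.0114, atol=1e-3)

    def test_uncovered_cell_nan(self):
        m = np.array([[1], [0]])
        res, a = self.build([0.5], m)
        z = decompose_to_cell_z(res, a, "g0")
        assert z[0] == 0.0 and np.isnan(z[1])


class TestPowerCurve:
    def test_determinism_and_structure(self):
        params = SimulationParams(
            n_genes=250, cells_per_batch=60, n_batches_per_condition=3, seed=3
        )
        t1 = power_curve(params, n_grid_bounds=(50, 300), n_draws=10, seed=4, window=5)
        t2 = power_curve(params, n_grid_bounds=(50, 300), n_draws=10, seed=4, window=5)
        pd.testing.assert_frame_equal(t1, t2)
        assert t1["n_cells"].is_monotonic_increasing
        assert set(t1.columns) >= {"n_cells", "sensitivity", "specificity", "FDR",
                                   "sensitivity_rm"}

    def test_null_detections_near_alpha(self):
        params = SimulationParams(
            n_genes=800, cells_per_batch=100, n_batches_per_condition=3,
            de_prob=0.0, seed=6,
        )
        tab = power_curve(params, n_grid_bounds=(200, 600), n_draws=10, seed=6, window=5)
        assert tab["sensitivity"].isna().all()
        # fraction of null genes detected ~ alpha
        assert abs((1 - tab["specificity"]).mean() - 0.05) < 0.04
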