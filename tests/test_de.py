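"""Pseudo-bulk aggregation, filtering, TMM, dispersions and the QL F-test."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import kstest, rankdata

from nhoodde._glm import estimate_nb_dispersions, fit_nb_glm
from nhoodde.de import (
    DesignSpec,
    PseudobulkMatrix,
    aggregate_pseudobulk,
    build_design_matrix,
    select_genes_for_testing,
    ql_fit_and_test,
    tmm_norm_factors,
)
from nhoodde.errors import InvalidInputError

from conftest import make_dataset


def make_pb(counts, condition=None, **extra):
    counts = np.asarray(counts, dtype=float)
    s = counts.shape[1]
    if condition is None:
        condition = ["control"] * (s // 2) + ["case"] * (s - s // 2)
    meta = pd.DataFrame(
        {"condition": condition, **extra}, index=[f"s{i}" for i in range(s)]
    )
    return PseudobulkMatrix(
        counts=counts,
        sample_meta=meta,
        gene_ids=np.array([f"g{i}" for i in range(counts.shape[0])]),
        lib_sizes=counts.sum(axis=0),
    )


class TestAggregate:
    def test_counts_are_summed_per_sample(self, design):
        import nhoodde.dataset as dsm

        counts = sp.csr_matrix(np.array([[1, 3], [2, 4]]))
        meta = pd.DataFrame({"sample": ["a", "a"], "condition": ["control", "control"]})
        ds = dsm.CellDataset(
            counts=counts,
            gene_ids=["g0", "g1"],
            cell_ids=["c0", "c1"],
            cell_meta=meta,
        )
        d = DesignSpec("condition", "control", min_n_cells_per_sample=1)
        pb = aggregate_pseudobulk(ds, [0, 1], d)
        assert pb.counts[:, 0].tolist() == [4, 6]

    def test_small_samples_dropped(self, small_dataset, design):
        # sample s0 contributes only 2 cells to this subset: dropped at min 3
        cells = np.where(small_dataset.cell_meta["sample"] == "s0")[0][:2]
        other = np.where(small_dataset.cell_meta["sample"] != "s0")[0]
        pb = aggregate_pseudobulk(small_dataset, np.concatenate([cells, other]), design)
        assert "s0" not in pb.sample_meta.index

    def test_count_conservation(self, small_dataset, design, rng):
        cells = rng.choice(small_dataset.n_cells, size=80, replace=False)
        d = DesignSpec("condition", "control", min_n_cells_per_sample=1)
        pb = aggregate_pseudobulk(small_dataset, cells, d)
        assert pb.counts.sum() == small_dataset.counts[:, cells].sum()
        # per-sample oracle
        samples = small_dataset.cell_meta["sample"].to_numpy()[cells]
        for s in pb.sample_meta.index:
            expected = small_dataset.counts[:, cells[samples == s]].sum(axis=1)
            assert np.array_equal(pb.counts[:, list(pb.sample_meta.index).index(s)],
                                  np.asarray(expected).ravel())


class TestGeneSelection:
    def test_min_count_zero_keeps_everything(self):
        pb = make_pb(np.zeros((5, 4)))
        d = DesignSpec("condition", "control", min_count=0)
        assert select_genes_for_testing(pb, d).all()

    def test_zero_gene_dropped(self, rng):
        counts = rng.poisson(20, size=(10, 6)).astype(float)
        counts[3] = 0
        pb = make_pb(counts)
        keep = select_genes_for_testing(pb, DesignSpec("condition", "control"))
        assert not keep[3]

    def test_matches_literal_rule(self, rng):
        counts = rng.poisson(rng.gamma(0.5, 8, size=(200, 1)), size=(200, 8)).astype(float)
        pb = make_pb(counts)
        d = DesignSpec("condition", "control", min_count=3)
        keep = select_genes_for_testing(pb, d)
        # independent gene-by-gene re-evaluation of the published rule
        lib = counts.sum(axis=0)
        cutoff = 3 / np.median(lib) * 1e6
        n_min = min((pb.sample_meta["condition"] == "control").sum(),
                    (pb.sample_meta["condition"] == "case").sum())
        for g in range(200):
            cpm = counts[g] / lib * 1e6
            expected = (np.sum(cpm >= cutoff) >= n_min) and (counts[g].sum() >= 15)
            assert keep[g] == expected


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile(np.arange(1, 21)[:, None], (1, 4)).astype(float)
        assert np.allclose(tmm_norm_factors(counts), 1.0)

    def test_pure_depth_difference_gives_unit_factors(self, rng):
        col = rng.poisson(50, size=100).astype(float) + 1
        counts = np.column_stack([col, 2 * col, col, 4 * col])
        assert np.allclose(tmm_norm_factors(counts), 1.0)

    def test_hand_computed_asymmetric_gene(self):
        # 3 samples, mostly flat, one strongly asymmetric gene in sample 2
        base = np.full(50, 100.0)
        s0, s1 = base.copy(), base.copy()
        s2 = base.copy()
        s2[0] = 3000.0
        counts = np.column_stack([s0, s1, s2])
        factors = tmm_norm_factors(counts)
        # oracle: independent step-by-step evaluation of the TMM formula
        lib = counts.sum(axis=0)
        f75 = np.quantile(counts / lib, 0.75, axis=0)
        ref = int(np.argmin(np.abs(f75 - f75.mean())))

        def pair(s):
            po, pr = counts[:, s] / lib[s], counts[:, ref] / lib[ref]
            m = np.log2(po / pr)
            a = 0.5 * np.log2(po * pr)
            w = (lib[s] - counts[:, s]) / (lib[s] * counts[:, s]) + (
                lib[ref] - counts[:, ref]
            ) / (lib[ref] * counts[:, ref])
            if np.max(np.abs(m)) < 1e-6:
                return 1.0
            n = len(m)
            rm, ra = rankdata(m), rankdata(a)
            keep = (
                (rm >= np.floor(0.3 * n) + 1)
                & (rm <= n - np.floor(0.3 * n))
                & (ra >= np.floor(0.05 * n) + 1)
                & (ra <= n - np.floor(0.05 * n))
            )
            return 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

        raw = np.array([pair(s) for s in range(3)])
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(factors, expected)
        assert factors[2] < 1.0  # the asymmetric sample is down-weighted

    def test_geometric_mean_one_and_relabel_invariance(self, rng):
        counts = rng.poisson(rng.gamma(1, 30, size=(80, 1)), size=(80, 5)).astype(float) + 1
        f = tmm_norm_factors(counts)
        assert abs(np.exp(np.mean(np.log(f))) - 1) < 1e-10
        perm = rng.permutation(5)
        assert np.allclose(tmm_norm_factors(counts[:, perm]), f[perm])

    def test_zero_library_rejected(self):
        counts = np.zeros((5, 3))
        counts[:, 0] = 1
        with pytest.raises(InvalidInputError):
            tmm_norm_factors(counts)


class TestDispersions:
    def _fit(self, counts, n):
        X = np.column_stack([np.ones(n), np.repeat([0, 1], n // 2)])
        offset = np.log(counts.sum(axis=0))
        return estimate_nb_dispersions(counts, X, offset)

    def test_poisson_counts_give_near_zero_dispersion(self, rng):
        mu = rng.gamma(2, 40, size=300)
        counts = rng.poisson(mu[:, None], size=(300, 20)).astype(float)
        fit = self._fit(counts, 20)
        assert np.median(fit.tagwise) < 0.05

    def test_nb_dispersion_recovered(self, rng):
        mu = rng.gamma(2, 60, size=300)
        disp = 0.4
        counts = rng.poisson(
            rng.gamma(1 / disp, mu[:, None] * disp, size=(300, 20))
        ).astype(float)
        fit = self._fit(counts, 20)
        assert 0.2 < np.median(fit.tagwise) < 0.8

    def test_single_gene_trend_degenerates_to_genewise(self, rng):
        counts = rng.poisson(50, size=(1, 8)).astype(float)
        fit = self._fit(counts, 8)
        assert np.allclose(fit.trended, fit.genewise)


class TestQLTest:
    def test_identical_counts_give_null_result(self):
        counts = np.tile(np.arange(20, 70)[:, None], (1, 6)).astype(float)
        pb = make_pb(counts)
        table = ql_fit_and_test(pb, DesignSpec("condition", "control"))
        assert np.allclose(table["logFC"], 0.0, atol=1e-6)
        assert np.allclose(table["PValue"], 1.0, atol=1e-2)

    def test_twofold_shift_recovers_unit_logfc(self, rng):
        # zero-dispersion limit with equal offsets: case exactly 2x control
        ctrl = rng.poisson(1000, size=(30, 1)).astype(float)
        y = np.column_stack([ctrl, ctrl, ctrl, 2 * ctrl, 2 * ctrl, 2 * ctrl])
        X = np.column_stack([np.ones(6), np.repeat([0, 1], 3)])
        beta, _, _, _ = fit_nb_glm(y, X, np.zeros(6), 1e-8)
        assert np.allclose(beta[:, 1] / np.log(2), 1.0, atol=1e-3)

    def test_irls_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        y = rng.poisson(rng.gamma(5, 10, size=(5, 1)), size=(5, 8)).astype(float)
        X = np.column_stack([np.ones(8), np.repeat([0, 1], 4), rng.normal(size=8)])
        offset = np.log(y.sum(axis=0))
        disp = 0.1
        beta, _, _, _ = fit_nb_glm(y, X, offset, disp)
        for g in range(5):
            ref = sm.GLM(
                y[g], X, family=sm.families.NegativeBinomial(alpha=disp), offset=offset
            ).fit()
            assert np.allclose(beta[g], ref.params, atol=1e-5)

    def test_label_swap_flips_logfc_keeps_p(self, rng):
        counts = rng.poisson(rng.gamma(2, 30, size=(60, 1)), size=(60, 8)).astype(float)
        pb = make_pb(counts)
        t1 = ql_fit_and_test(pb, DesignSpec("condition", "control"))
        t2 = ql_fit_and_test(pb, DesignSpec("condition", "case"))
        assert np.allclose(t1["logFC"], -t2["logFC"], atol=1e-8)
        assert np.allclose(t1["PValue"], t2["PValue"], atol=1e-8)

    def test_global_null_p_uniform(self, rng):
        mu = rng.gamma(1.0, 40, size=2000)
        disp = 0.2
        counts = rng.poisson(
            rng.gamma(1 / disp, mu[:, None] * disp, size=(2000, 10))
        ).astype(float)
        pb = make_pb(counts)
        table = ql_fit_and_test(pb, DesignSpec("condition", "control"))
        pv = table["PValue"].to_numpy()
        assert kstest(pv, "uniform").statistic < 0.05
        assert (pv < 0.05).mean() <= 0.07  # type-I control at nominal 0.05

    def test_untestable_single_condition(self):
        counts = np.tile(np.arange(20, 40)[:, None], (1, 4)).astype(float)
        pb = make_pb(counts, condition=["control"] * 4)
        assert ql_fit_and_test(pb, DesignSpec("condition", "control")) is None

    def test_covariate_design_matrix(self):
        pb = make_pb(np.ones((3, 4)) * 50, batch=["b1", "b2", "b1", "b2"])
        d = DesignSpec("condition", "control", covariates=("batch",))
        X, names, cidx = build_design_matrix(pb.sample_meta, d)
        assert X.shape == (4, 3)
        assert names[cidx].startswith("condition[")
        assert np.array_equal(X[:, 1], [0, 1, 0, 1])
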