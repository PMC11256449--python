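"""Synthetic scRNA-seq counts, count-injection perturbations and benchmarks.

The generator follows the standard hierarchical NB model for scRNA-seq:
per-cell library sizes are lognormal, per-gene base means are gamma,
differential-expression and batch factors are lognormal multipliers applied to
subsets of genes, per-cell expected proportions are rescaled to the library
size, and counts are negative binomial with a gene-wise dispersion from the
mean-BCV (biological coefficient of variation) curve.  A self-contained latent
embedding is computed as the top principal components of log1p-CPM.

Ground-truth DE for benchmarking is created by *count injection*: adding a
uniform random integer (0..max_add) to selected genes in selected cells, which
perturbs expression without touching any other matrix entry.  The evaluation
harness measures neighborhood composition (purity/enrichment),
sensitivity/FDR against purity-thresholded ground truth, rank-based ROC AUCs
at neighborhood and (via p-to-z decomposition) single-cell resolution, and
power curves of the pseudo-bulk QL test as a function of the number of tested
cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import ndtri
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from .dataset import CellDataset, LatentEmbedding
from .de import DesignSpec, aggregate_pseudobulk, ql_fit_and_test
from .errors import InvalidInputError, InvalidParameterError
from .graph import NeighborhoodAssignment, build_neighborhood_assignment
from .results import DEResultMatrices

logger = logging.getLogger(__name__)

CONTROL, CASE = "control", "case"


@dataclass
class SimulationParams:
    """Parameters of the hierarchical NB count generator.

    Defaults emulate a mouse-embryo-like scRNA-seq sample: ~11k counts per
    cell (lib_loc 9.3, lib_scale 0.25 on the natural-log scale), gamma gene
    means (shape 0.6, rate 0.3), and a BCV curve with bcv_common 0.4 and
    bcv_df 22.  ``de_prob``/``de_facLoc``/``de_facScale`` control lognormal DE
    factors that distinguish every non-reference cell group from group 0;
    with ``group_assignment="by_condition"`` the two groups coincide with the
    control/case conditions, giving condition-associated DE in ``de_prob`` of
    the genes.  With ``group_assignment="random"`` the groups are sub-cell
    types drawn per cell from ``group_fractions`` and conditions carry no
    intrinsic DE.
    """

    n_genes: int = 4000
    cells_per_batch: int = 200
    n_batches_per_condition: int = 10
    lib_loc: float = 9.3
    lib_scale: float = 0.25
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    bcv_common: float = 0.4
    bcv_df: float = 22.0
    de_prob: float = 0.25
    de_facLoc: float = 1.0
    de_facScale: float = 0.4
    group_fractions: tuple = (1.0,)
    group_assignment: str = "random"  # or "by_condition"
    batch_facLoc: float = 0.0
    batch_facScale: float = 0.0
    n_pcs: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.cells_per_batch < 1 or self.n_batches_per_condition < 1:
            raise InvalidParameterError("counts of genes/cells/batches must be positive")
        for name in ("lib_scale", "mean_shape", "mean_rate", "bcv_df"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not (0 <= self.de_prob <= 1):
            raise InvalidParameterError("de_prob must be in [0, 1]")
        fr = np.asarray(self.group_fractions, dtype=float)
        if np.any(fr < 0) or not np.isclose(fr.sum(), 1.0):
            raise InvalidParameterError("group_fractions must be non-negative and sum to 1")
        if self.group_assignment not in ("random", "by_condition"):
            raise InvalidParameterError("group_assignment must be 'random' or 'by_condition'")
        if self.group_assignment == "by_condition" and len(fr) != 2:
            raise InvalidParameterError("by_condition grouping requires exactly 2 groups")


@dataclass
class SimulationTruth:
    """Ground truth of an injection perturbation."""

    perturbed_genes: np.ndarray
    perturbed_cells: np.ndarray
    expected_logfc: pd.Series
    max_add: int


def _lognormal_factors(rng, n, loc, scale, prob):
    """Lognormal multipliers applied with probability ``prob``, direction +/-."""
    fac = rng.lognormal(loc, scale, n)
    down = rng.random(n) < 0.5
    fac = np.where(down, 1.0 / fac, fac)
    hit = rng.random(n) < prob
    return np.where(hit, fac, 1.0), hit


def simulate_counts(params: SimulationParams, seed: int | None = None) -> CellDataset:
    """Draw a two-condition count dataset from the hierarchical NB model.

    Returns a :class:`CellDataset` whose ``gene_meta`` records the base mean,
    the DE flag and the per-group factor of every gene (the simulation truth
    used by the benchmarks), and whose embedding holds the top ``n_pcs``
    principal components of log1p-CPM.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    G = params.n_genes
    n_batches = 2 * params.n_batches_per_condition
    n_cells = n_batches * params.cells_per_batch

    batch = np.repeat(np.arange(n_batches), params.cells_per_batch)
    condition = np.where(batch < params.n_batches_per_condition, CONTROL, CASE)
    n_groups = len(params.group_fractions)
    if params.group_assignment == "by_condition":
        group = (condition == CASE).astype(int)
    else:
        group = rng.choice(n_groups, size=n_cells, p=np.asarray(params.group_fractions))

    lib = rng.lognormal(params.lib_loc, params.lib_scale, n_cells)
    base_mean = rng.gamma(params.mean_shape, 1.0 / params.mean_rate, G)

    group_factors = np.ones((G, n_groups))
    de_flags = np.zeros((G, n_groups), dtype=bool)
    for kk in range(1, n_groups):
        group_factors[:, kk], de_flags[:, kk] = _lognormal_factors(
            rng, G, params.de_facLoc, params.de_facScale, params.de_prob
        )
    batch_factors = np.ones((G, n_batches))
    if params.batch_facScale > 0:
        for b in range(n_batches):
            batch_factors[:, b], _ = _lognormal_factors(
                rng, G, params.batch_facLoc, params.batch_facScale, 1.0
            )

    base = base_mean[:, None] * group_factors[:, group] * batch_factors[:, batch]
    mu = base * (lib / base.sum(axis=0))
    mean_g = mu.mean(axis=1)
    bcv = params.bcv_common + 1.0 / np.sqrt(np.maximum(mean_g, 1e-8))
    disp = bcv**2 * params.bcv_df / rng.chisquare(params.bcv_df, G)
    shape = (1.0 / disp)[:, None]
    counts = rng.poisson(rng.gamma(shape, mu * disp[:, None]))

    gene_ids = np.array([f"g{i:05d}" for i in range(G)])
    cell_ids = np.array([f"c{i:06d}" for i in range(n_cells)])
    cell_meta = pd.DataFrame(
        {
            "sample": np.array([f"s{b:02d}" for b in batch]),
            "condition": condition,
            "group": np.array([f"group{g}" for g in group]),
        },
        index=cell_ids,
    )
    gene_meta = pd.DataFrame({"base_mean": base_mean}, index=gene_ids)
    for kk in range(1, n_groups):
        gene_meta[f"group{kk}_factor"] = group_factors[:, kk]
        gene_meta[f"group{kk}_is_de"] = de_flags[:, kk]
    if params.group_assignment == "by_condition":
        gene_meta["is_de"] = de_flags[:, 1]
        gene_meta["condition_log2fc"] = np.log2(group_factors[:, 1])

    embedding = _pca_embedding(counts, cell_ids, params.n_pcs, params.seed if seed is None else seed)
    return CellDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_meta=cell_meta,
        embedding=embedding,
        gene_meta=gene_meta,
    )


def _pca_embedding(counts: np.ndarray, cell_ids, n_pcs: int, seed: int) -> LatentEmbedding:
    if sp.issparse(counts):
        counts = np.asarray(counts.todense())
    lib = counts.sum(axis=0)
    logcpm = np.log1p(counts / np.maximum(lib, 1.0) * 1e6).T.astype(np.float32)
    pca = PCA(n_components=min(n_pcs, *logcpm.shape), svd_solver="randomized", random_state=seed)
    return LatentEmbedding(coords=pca.fit_transform(logcpm), cell_ids=np.asarray(cell_ids))


def inject_perturbation(
    dataset: CellDataset, genes, target_cells, max_add: int, seed: int = 0
):
    """Add uniform integer counts (0..max_add) to (gene, target cell) entries.

    Only the selected entries change, and only upward.  The expected log2
    effect size of every perturbed gene is re-estimated by a pseudo-bulk
    case-vs-control contrast restricted to the cells' group.
    """
    if max_add < 0:
        raise InvalidParameterError("max_add must be >= 0")
    genes = np.asarray(genes)
    target_cells = np.asarray(target_cells)
    if target_cells.size == 0:
        raise InvalidParameterError("target_cells must be nonempty")
    gene_pos = _positions(dataset.gene_ids, genes, "gene")
    cell_pos = _positions(dataset.cell_ids, target_cells, "cell")

    rng = np.random.default_rng(seed)
    adds = rng.integers(0, max_add + 1, size=(len(genes), len(target_cells)))
    counts = dataset.counts.tolil(copy=True)
    for i, gp in enumerate(gene_pos):
        row = counts[gp, cell_pos].toarray().ravel()
        counts[gp, cell_pos] = row + adds[i]
    perturbed = CellDataset(
        counts=counts.tocsr(),
        gene_ids=dataset.gene_ids,
        cell_ids=dataset.cell_ids,
        cell_meta=dataset.cell_meta,
        embedding=dataset.embedding,
        gene_meta=dataset.gene_meta,
    )
    expected = _expected_logfc(perturbed, gene_pos, cell_pos)
    truth = SimulationTruth(
        perturbed_genes=genes,
        perturbed_cells=target_cells,
        expected_logfc=pd.Series(expected, index=pd.Index(genes)),
        max_add=max_add,
    )
    return perturbed, truth


def _positions(ids: np.ndarray, query: np.ndarray, what: str) -> np.ndarray:
    lookup = {v: i for i, v in enumerate(ids)}
    try:
        return np.array([lookup[q] for q in query], dtype=np.int64)
    except KeyError as err:
        raise InvalidInputError(f"unknown {what} ID: {err.args[0]!r}") from None


def _expected_logfc(dataset: CellDataset, gene_pos, cell_pos) -> np.ndarray:
    """Pseudo-bulk case/control contrast over the group of the target cells."""
    meta = dataset.cell_meta
    groups = meta["group"].iloc[cell_pos].unique() if "group" in meta else [None]
    if len(groups) == 1 and groups[0] is not None:
        in_group = (meta["group"] == groups[0]).to_numpy()
    else:
        in_group = np.zeros(dataset.n_cells, dtype=bool)
        in_group[cell_pos] = True
    cond = meta["condition"].to_numpy()
    out = np.empty(len(gene_pos))
    sub = dataset.counts[gene_pos][:, in_group]
    sub = np.asarray(sub.todense(), dtype=float)
    cond_g = cond[in_group]
    mean_case = sub[:, cond_g == CASE].mean(axis=1)
    mean_ctrl = sub[:, cond_g == CONTROL].mean(axis=1)
    eps = 1e-8
    out[:] = np.log2((mean_case + eps) / (mean_ctrl + eps))
    return out


def select_candidate_genes(
    dataset: CellDataset,
    design: DesignSpec,
    cell_type_column: str = "cell_type",
    min_cells_per_type: int = 50,
    fdr_floor: float = 0.5,
    max_abs_logfc: float = 0.25,
) -> np.ndarray:
    """Genes showing no condition DE within any abundant cell type.

    For every cell type with more than ``min_cells_per_type`` cells a
    pseudo-bulk QL test is run; a gene remains a candidate only if its BH FDR
    is >= ``fdr_floor`` and |logFC| < ``max_abs_logfc`` in every cell type,
    and it has nonzero total expression.  Genes not tested in a cell type
    (insufficient counts there) are not evidence of DE and remain candidates.
    """
    from .correction import weighted_bh

    dataset.require_columns([cell_type_column, "sample", design.condition])
    total = np.asarray(dataset.counts.sum(axis=1)).ravel()
    candidate = total > 0
    labels = dataset.cell_meta[cell_type_column]
    for ct, cnt in labels.value_counts().items():
        if cnt <= min_cells_per_type:
            continue
        cells = np.where((labels == ct).to_numpy())[0]
        pb = aggregate_pseudobulk(dataset, cells, design)
        table = ql_fit_and_test(pb, design)
        if table is None:
            continue
        fdr = weighted_bh(table["PValue"].to_numpy(), np.ones(len(table)))
        bad = (fdr < fdr_floor) | (np.abs(table["logFC"].to_numpy()) >= max_abs_logfc)
        bad_pos = _positions(dataset.gene_ids, table.index.to_numpy()[bad], "gene")
        candidate[bad_pos] = False
    return dataset.gene_ids[candidate]


def nhood_composition_metrics(
    assignment: NeighborhoodAssignment, labels
) -> pd.DataFrame:
    """Per-neighborhood label purity, enriched label and enrichment score.

    purity(nhood, label) = fraction of the neighborhood's cells carrying the
    label; the enriched label is the most abundant one (ties broken by
    ascending label) and its purity is the relative enrichment score.
    """
    labels = pd.Series(np.asarray(labels).astype(str))
    if len(labels) != assignment.n_cells:
        raise InvalidInputError("labels must cover all cells")
    level_names = sorted(labels.unique())
    indicator = sp.csr_matrix(
        pd.get_dummies(pd.Categorical(labels, categories=level_names)).to_numpy(dtype=float)
    )
    m = assignment.membership.tocsc().astype(float)
    counts = np.asarray((m.T @ indicator).todense())
    sizes = counts.sum(axis=1, keepdims=True)
    purity = counts / sizes
    enriched_idx = np.argmax(purity, axis=1)  # argmax takes first max: ascending label
    table = pd.DataFrame(purity, columns=level_names)
    table.insert(0, "nhood", np.arange(assignment.n_nhoods))
    table["enriched_label"] = [level_names[i] for i in enriched_idx]
    table["enrichment_score"] = purity[np.arange(len(purity)), enriched_idx]
    return table


def evaluate_detection(
    results: DEResultMatrices,
    truth: SimulationTruth,
    purity: np.ndarray,
    threshold: float,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Per-gene sensitivity and FDR of neighborhood-level DE detection.

    Ground-truth DE neighborhoods are those whose purity for the perturbed
    population exceeds ``threshold``; a neighborhood detects a gene when its
    across-neighborhood corrected p-value is below ``alpha``.
    """
    purity = np.asarray(purity, dtype=float)
    if len(purity) != results.n_nhoods:
        raise InvalidInputError("purity not aligned with result neighborhoods")
    gt = purity > threshold
    if not gt.any():
        warnings.warn("zero ground-truth neighborhoods at this purity threshold")
    gene_index = {g: i for i, g in enumerate(results.gene_ids)}
    records = []
    for gene in truth.perturbed_genes:
        p = results.p_adj_nhoods[gene_index[gene]]
        detected = np.nan_to_num(p, nan=1.0) < alpha
        tp = int(np.sum(detected & gt))
        fp = int(np.sum(detected & ~gt))
        fn = int(np.sum(~detected & gt))
        sens = tp / (tp + fn) if (tp + fn) > 0 else np.nan
        fdr = fp / max(tp + fp, 1)
        records.append({"gene": gene, "sensitivity": sens, "FDR": fdr, "TP": tp, "FP": fp, "FN": fn})
    return pd.DataFrame.from_records(records).set_index("gene")


def roc_auc(scores, labels, warn: bool = True) -> float:
    """Rank-based (Mann-Whitney) ROC AUC with average ranks for ties.

    NaN scores are excluded pairwise; a single-class label vector yields NaN
    (with a warning).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise InvalidInputError("scores and labels must have equal length")
    ok = ~np.isnan(scores)
    scores, labels = scores[ok], labels[ok]
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        if warn:
            warnings.warn("single-class labels: AUC undefined")
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def decompose_to_cell_z(
    results: DEResultMatrices, assignment: NeighborhoodAssignment, gene
) -> np.ndarray:
    """Per-cell z-score of a gene from its across-neighborhood corrected p.

    Each tested neighborhood contributes z = Phi^-1(1 - p_adj_nhoods); each
    cell receives the mean z over the tested neighborhoods containing it
    (NaN for cells in no tested neighborhood).
    """
    gene_index = {g: i for i, g in enumerate(results.gene_ids)}
    p = results.p_adj_nhoods[gene_index[gene]]
    tested = ~np.isnan(p)
    if not tested.any():
        raise InvalidInputError(f"gene {gene!r} was not tested in any neighborhood")
    z = np.zeros_like(p)
    z[tested] = -ndtri(np.clip(p[tested], 1e-300, 1.0 - 1e-16))
    m = assignment.membership.tocsr().astype(float)
    zsum = np.asarray(m[:, tested] @ z[tested]).ravel()
    ncount = np.asarray(m[:, tested].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore"):
        out = np.where(ncount > 0, zsum / np.maximum(ncount, 1.0), np.nan)
    return out


def running_median(values: np.ndarray, window: int = 101) -> np.ndarray:
    """Centered running median with edge-clipped windows."""
    values = np.asarray(values, dtype=float)
    half = window // 2
    n = len(values)
    out = np.empty(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            out[i] = np.nanmedian(values[lo:hi])
    return out


def power_curve(
    params: SimulationParams,
    n_grid_bounds: tuple[int, int] = (50, 3000),
    n_draws: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    window: int | None = None,
    design: DesignSpec | None = None,
    effect_bin: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """DE detection power of the pseudo-bulk QL test vs number of tested cells.

    Simulates one two-condition dataset (``group_assignment="by_condition"``
    is forced so DE separates the conditions), then repeatedly subsamples a
    uniform random number of cells within ``n_grid_bounds``, aggregates
    pseudo-bulk per sample, runs the QL F-test and records sensitivity,
    specificity and FDR at raw p < ``alpha``.  Genes filtered out of a draw
    count as undetected.  Rows are sorted by subsample size with running
    medians (window ``window``) appended.

    The default window covers 5% of the draws (101 at the reference budget of
    2000 draws), so the smoother spans a comparable band of subsample sizes
    at any draw budget; a window fixed in *draws* would otherwise stop being
    local in *cells* when fewer draws are spread over the same size range.

    ``effect_bin=(lo, hi)`` restricts the sensitivity numerator and
    denominator to true-DE genes whose realized |log2 fold change| lies in
    [lo, hi), giving the power to detect a specific effect size; specificity
    and FDR are always computed over all genes.
    """
    if n_draws < 10:
        raise InvalidParameterError("n_draws must be >= 10")
    if window is None:
        window = max(5, int(round(0.05 * n_draws)) | 1)  # odd, 5% of draws
    params = replace(params, group_assignment="by_condition", group_fractions=(0.5, 0.5))
    dataset = simulate_counts(params, seed=seed)
    is_de = dataset.gene_meta["is_de"].to_numpy()
    sens_genes = is_de
    if effect_bin is not None:
        lfc = np.abs(dataset.gene_meta["condition_log2fc"].to_numpy())
        sens_genes = is_de & (lfc >= effect_bin[0]) & (lfc < effect_bin[1])
        if not sens_genes.any():
            raise InvalidParameterError("no true-DE gene falls in effect_bin")
    n_sens = int(sens_genes.sum())
    n_null = int((~is_de).sum())
    design = design or DesignSpec(condition="condition", reference_level=CONTROL)
    gene_index = {g: i for i, g in enumerate(dataset.gene_ids)}

    rng = np.random.default_rng(seed + 1)
    lo, hi = n_grid_bounds
    hi = min(hi, dataset.n_cells)
    records = []
    for _ in range(n_draws):
        n = int(rng.integers(lo, hi + 1))
        cells = rng.choice(dataset.n_cells, size=n, replace=False)
        pb = aggregate_pseudobulk(dataset, cells, design)
        table = ql_fit_and_test(pb, design)
        detected = np.zeros(dataset.n_genes, dtype=bool)
        if table is not None:
            sig = table.index.to_numpy()[table["PValue"].to_numpy() < alpha]
            detected[[gene_index[g] for g in sig]] = True
        tp = int(np.sum(detected & is_de))
        fp = int(np.sum(detected & ~is_de))
        records.append(
            {
                "n_cells": n,
                "sensitivity": (
                    np.sum(detected & sens_genes) / n_sens if n_sens else np.nan
                ),
                "specificity": (n_null - fp) / n_null if n_null else np.nan,
                "FDR": fp / max(tp + fp, 1),
            }
        )
    table = pd.DataFrame.from_records(records).sort_values("n_cells", kind="stable")
    table = table.reset_index(drop=True)
    for col in ("sensitivity", "specificity", "FDR"):
        table[f"{col}_rm"] = running_median(table[col].to_numpy(), window)
    return table


def running_median_at(table: pd.DataFrame, n_cells: int, column: str = "sensitivity_rm") -> float:
    """Running-median value at the draw whose size is nearest ``n_cells``."""
    idx = int(np.argmin(np.abs(table["n_cells"].to_numpy() - n_cells)))
    return float(table[column].iloc[idx])


# ---------------------------------------------------------------------------
# Injection benchmark: neighborhood- and cell-level AUC over a simulation grid
# ---------------------------------------------------------------------------


def pick_injection_genes(
    dataset: CellDataset,
    candidates,
    target_cells,
    effect_targets,
    max_add: int,
) -> np.ndarray:
    """Choose candidate genes whose predicted injection logFC spans the targets.

    Injection adds on average max_add/2 counts to each target (case) cell, so
    the predicted pseudo-bulk case-vs-control contrast within the target
    cells' group is log2((m_case + max_add/2)/m_ctrl); for each requested
    effect size the unused candidate with the nearest prediction is selected.
    Genes silent in the control cells of the group are never picked (their
    post-injection contrast is unbounded).
    """
    candidates = np.asarray(candidates)
    cand_pos = _positions(dataset.gene_ids, candidates, "gene")
    cell_pos = _positions(dataset.cell_ids, np.asarray(target_cells), "cell")
    meta = dataset.cell_meta
    if "group" in meta:
        groups = meta["group"].iloc[cell_pos].unique()
        in_group = meta["group"].isin(groups).to_numpy()
    else:
        in_group = np.zeros(dataset.n_cells, dtype=bool)
        in_group[cell_pos] = True
    cond = meta["condition"].to_numpy()
    case_cells = np.where(in_group & (cond == CASE))[0]
    ctrl_cells = np.where(in_group & (cond == CONTROL))[0]
    m_case = np.asarray(
        dataset.counts[cand_pos][:, case_cells].mean(axis=1)
    ).ravel()
    m_ctrl = np.asarray(
        dataset.counts[cand_pos][:, ctrl_cells].mean(axis=1)
    ).ravel()
    add = max_add / 2.0
    with np.errstate(divide="ignore"):
        predicted = np.log2((m_case + add) / np.maximum(m_ctrl, 1e-12))
    predicted[m_ctrl == 0] = np.inf
    chosen = []
    used = np.zeros(len(candidates), dtype=bool)
    for t in effect_targets:
        score = np.abs(predicted - t)
        score[used] = np.inf
        j = int(np.argmin(score))
        used[j] = True
        chosen.append(candidates[j])
    return np.asarray(chosen)


def injection_benchmark(
    fractions=(0.01, 0.05, 0.25, 0.5),
    n_assignments: int = 2,
    k: int = 25,
    order: int = 2,
    effect_targets=(1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0),
    max_add: int = 3,
    seed: int = 0,
    purity_thresholds=(0.1, 0.25),
    sim_params: SimulationParams | None = None,
    separation: dict | None = None,
    replicate_arms=((5, 5), (2, 2)),
) -> pd.DataFrame:
    """Count-injection benchmark of neighborhood DE detection.

    For each perturbed-group fraction a two-group dataset is simulated, counts
    are injected into the perturbed group's case cells for genes spanning the
    requested effect sizes, the full neighborhood pipeline is run
    (``n_assignments`` independent assignments), and per (dataset, arm,
    assignment, gene) the ROC AUC of the per-neighborhood significance
    statistic against purity-thresholded ground-truth neighborhoods is
    recorded, alongside the single-cell AUC of the decomposed z-scores
    against the injected cells.

    ``replicate_arms`` lists (n_control, n_case) replicate counts: each arm
    randomly keeps that many samples per condition before the pipeline runs,
    probing how detection degrades with fewer biological replicates.  Arms
    requesting more replicates than simulated use all of them.

    ``separation`` maps a fraction to (de_prob, de_facLoc) overriding the
    between-group DE settings.  The defaults are calibrated per fraction on
    an input-side criterion: the groups must be distinct enough that some
    neighborhoods concentrate the perturbed group (ground truth exists) yet
    *not entirely separated*, so that neighborhoods mixing both groups also
    occur where the dataset size permits.  The rarer the group, the stronger
    the separation this requires; at the rarest fraction the purity
    distribution is effectively bimodal at this scale.

    Dataset size also scales with rarity: a neighborhood can only be dominated
    by the perturbed group if that group clearly exceeds k cells (otherwise
    every group cell is forced to link outside the group and 2nd-order edges
    dilute it), so cells_per_batch is raised when needed to keep the expected
    group size at or above ~2.4k.
    """
    from .de import run_neighborhood_de

    base = sim_params or SimulationParams(
        n_genes=1500,
        cells_per_batch=300,
        n_batches_per_condition=5,
        de_prob=0.2,
        de_facLoc=1.0,
        de_facScale=0.4,
    )
    design = DesignSpec(
        condition="condition", reference_level=CONTROL, covariates=(), min_count=0
    )
    records = []
    for d, frac in enumerate(fractions):
        if separation is not None and frac in separation:
            de_prob, de_facloc = separation[frac]
        elif frac < 0.025:
            de_prob, de_facloc = 0.3, 2.0
        elif frac < 0.1:
            de_prob, de_facloc = 0.2, 0.85
        elif frac < 0.4:
            de_prob, de_facloc = 0.15, 0.5
        else:
            de_prob, de_facloc = 0.1, 0.6
        # the containment rule must hold in the smallest replicate arm too,
        # otherwise downsampled arms lose every ground-truth neighborhood
        min_group = int(np.ceil(2.4 * k))
        min_batches = min(sum(arm) for arm in replicate_arms)
        cpb = max(
            base.cells_per_batch,
            int(np.ceil(min_group / frac / min_batches)),
        )
        params = replace(
            base,
            group_fractions=(1.0 - frac, frac),
            group_assignment="random",
            de_prob=de_prob,
            de_facLoc=de_facloc,
            cells_per_batch=cpb,
            seed=seed + 1000 * d,
        )
        dataset = simulate_counts(params)
        in_group = (dataset.cell_meta["group"] == "group1").to_numpy()
        is_case = (dataset.cell_meta["condition"] == CASE).to_numpy()
        target_cells = dataset.cell_ids[in_group & is_case]
        candidates = dataset.gene_ids[~dataset.gene_meta["group1_is_de"].to_numpy()]
        genes = pick_injection_genes(
            dataset, candidates, target_cells, effect_targets, max_add
        )
        perturbed, truth = inject_perturbation(
            dataset, genes, target_cells, max_add, seed=seed + 1000 * d + 1
        )
        samples = perturbed.cell_meta["sample"].to_numpy()
        cond = perturbed.cell_meta["condition"].to_numpy()
        ctrl_samples = np.unique(samples[cond == CONTROL])
        case_samples = np.unique(samples[cond == CASE])
        arm_rng = np.random.default_rng(seed + 1000 * d + 500)
        for n_ctrl, n_case in replicate_arms:
            keep_s = np.concatenate(
                [
                    arm_rng.choice(
                        ctrl_samples, size=min(n_ctrl, len(ctrl_samples)), replace=False
                    ),
                    arm_rng.choice(
                        case_samples, size=min(n_case, len(case_samples)), replace=False
                    ),
                ]
            )
            sub = perturbed.subset_cells(np.where(np.isin(samples, keep_s))[0])
            truth_cells = np.isin(sub.cell_ids, truth.perturbed_cells)
            for a in range(n_assignments):
                assignment = build_neighborhood_assignment(
                    sub.embedding, k=k, order=order, seed=seed + 1000 * d + 10 + a
                )
                results = run_neighborhood_de(sub, assignment, design)
                comp = nhood_composition_metrics(
                    assignment, sub.cell_meta["group"].to_numpy()
                )
                purity = comp["group1"].to_numpy()
                gene_index = {g: i for i, g in enumerate(results.gene_ids)}
                for gene in genes:
                    p = results.p_adj_nhoods[gene_index[gene]]
                    score = 1.0 - np.nan_to_num(p, nan=1.0)  # untested: p = 1
                    rec = {
                        "fraction": frac,
                        "n_replicates": n_ctrl + n_case,
                        "assignment": a,
                        "gene": gene,
                        "expected_logfc": truth.expected_logfc.loc[gene],
                    }
                    for thr in purity_thresholds:
                        rec[f"auc_nhood_{thr}"] = roc_auc(
                            score, purity > thr, warn=False
                        )
                    z_cell = decompose_to_cell_z(results, assignment, gene)
                    rec["auc_cell"] = roc_auc(z_cell, truth_cells, warn=False)
                    records.append(rec)
        logger.info("injection benchmark: fraction %.3f done", frac)
    return pd.DataFrame.from_records(records)
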