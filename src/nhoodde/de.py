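"""Per-neighborhood pseudo-bulk differential expression testing.

For every neighborhood, counts of its cells are summed per biological sample
("pseudo-bulk"), samples with too few cells are dropped, lowly expressed genes
are filtered, trimmed-mean-of-M-values (TMM) offsets correct compositional
bias, negative-binomial dispersions are estimated as a function of abundance,
and each gene is tested for a condition effect with a quasi-likelihood F-test
under a covariate-aware log-link NB GLM.  An optional random-forest classifier
pre-filter scores each neighborhood's separability between conditions (AUC)
so that unperturbed neighborhoods can be skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2, f as f_dist, rankdata

from . import _glm
from .correction import apply_dual_correction, nhood_density_weights
from .dataset import CellDataset
from .errors import ConfigurationError, InvalidInputError, InvalidParameterError
from .graph import NeighborhoodAssignment
from .results import DEResultMatrices

logger = logging.getLogger(__name__)

# sufficient-counts rule: floor on the total count of a kept gene
MIN_TOTAL_COUNT = 15
MIN_QUASI_DISP = 1e-8


@dataclass
class DesignSpec:
    """Two-level condition contrast with optional sample-level covariates.

    ``condition`` names a metadata column with exactly two levels;
    ``reference_level`` is the control label (logFC > 0 means higher in the
    other, "case", level).  Covariates must be constant within each sample.
    """

    condition: str
    reference_level: str
    covariates: tuple = ()
    min_count: float = 3
    min_n_cells_per_sample: int = 3


@dataclass
class PseudobulkMatrix:
    """Gene x sample summed counts with per-sample metadata."""

    counts: np.ndarray
    sample_meta: pd.DataFrame
    gene_ids: np.ndarray
    lib_sizes: np.ndarray | None = None
    norm_factors: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def aggregate_pseudobulk(
    dataset: CellDataset, cells, design: DesignSpec
) -> PseudobulkMatrix:
    """Sum counts per sample over the given cells, dropping sparse samples.

    Samples contributing fewer than ``design.min_n_cells_per_sample`` cells to
    the neighborhood are removed.  Whether the result supports testing at all
    (two samples, both condition levels, ...) is decided later by
    :func:`ql_fit_and_test`; degenerate pseudo-bulks are returned, not raised.
    """
    cells = np.asarray(cells)
    if cells.size == 0:
        raise InvalidParameterError("cells must be nonempty")
    meta = dataset.cell_meta.iloc[cells]
    samples = meta["sample"].to_numpy()
    uniq, inverse, ncells = np.unique(samples, return_inverse=True, return_counts=True)
    keep = ncells >= design.min_n_cells_per_sample
    kept_samples = uniq[keep]
    col_of = -np.ones(len(uniq), dtype=np.int64)
    col_of[keep] = np.arange(keep.sum())
    cols = col_of[inverse]
    in_keep = cols >= 0
    indicator = sp.coo_matrix(
        (np.ones(in_keep.sum()), (np.arange(len(cells))[in_keep], cols[in_keep])),
        shape=(len(cells), int(keep.sum())),
    ).tocsr()
    pb = np.asarray((dataset.counts[:, cells] @ indicator).todense(), dtype=float)
    rows = []
    for s in kept_samples:
        r = meta[samples == s].iloc[0]
        rec = {"sample": s, design.condition: r[design.condition]}
        for cov in design.covariates:
            rec[cov] = r[cov]
        rows.append(rec)
    sample_meta = pd.DataFrame(rows).set_index("sample") if rows else pd.DataFrame(
        columns=[design.condition]
    )
    sample_meta["n_cells"] = ncells[keep]
    return PseudobulkMatrix(
        counts=pb,
        sample_meta=sample_meta,
        gene_ids=dataset.gene_ids,
        lib_sizes=pb.sum(axis=0),
    )


def select_genes_for_testing(pb: PseudobulkMatrix, design: DesignSpec) -> np.ndarray:
    """Boolean mask of genes with sufficient counts for DE testing.

    A gene is kept if its CPM exceeds the CPM equivalent of ``min_count`` at
    the median library size in at least n_min samples (n_min = size of the
    smaller condition group) and its total count is at least 15.
    ``min_count = 0`` disables filtering entirely.
    """
    G = pb.counts.shape[0]
    if design.min_count == 0:
        return np.ones(G, dtype=bool)
    lib = pb.counts.sum(axis=0)
    if pb.n_samples == 0 or np.all(lib == 0):
        return np.zeros(G, dtype=bool)
    median_lib = np.median(lib)
    cpm_cutoff = design.min_count / median_lib * 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        cpm = np.where(lib > 0, pb.counts / lib * 1e6, 0.0)
    group_sizes = pb.sample_meta[design.condition].value_counts()
    n_min = int(group_sizes.min()) if len(group_sizes) else 1
    keep = (cpm >= cpm_cutoff).sum(axis=1) >= n_min
    keep &= pb.counts.sum(axis=1) >= MIN_TOTAL_COUNT
    return keep


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference sample."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return 1.0
    po = obs[pos] / lib_obs
    pr = ref[pos] / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # delta-method weights: inverse asymptotic variance of each M-value
    w = (lib_obs - obs[pos]) / (lib_obs * obs[pos]) + (lib_ref - ref[pos]) / (
        lib_ref * ref[pos]
    )
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    return float(f) if np.isfinite(f) and f > 0 else 1.0


def tmm_norm_factors(counts, lib_sizes=None) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors (geometric mean 1).

    The reference is the sample whose upper-quartile count fraction is closest
    to the mean upper quartile; per-sample factors are weighted means of
    M-values after trimming 30% of M-values and 5% of A-values.  Accepts a
    :class:`PseudobulkMatrix` or a plain gene x sample array.
    """
    if isinstance(counts, PseudobulkMatrix):
        counts = counts.counts
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise InvalidParameterError("TMM requires at least 2 samples")
    lib = np.asarray(lib_sizes, dtype=float) if lib_sizes is not None else counts.sum(axis=0)
    if np.any(lib <= 0):
        raise InvalidInputError("sample with zero library size")
    f75 = np.quantile(counts / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(counts[:, s], counts[:, ref], lib[s], lib[ref])
            for s in range(counts.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def build_design_matrix(sample_meta: pd.DataFrame, design: DesignSpec):
    """Intercept + covariate columns + condition indicator (case = 1).

    Categorical covariates are dummy-encoded dropping the first (sorted)
    level; numeric covariates enter as-is.  Returns (X, column names, index of
    the condition column).
    """
    cond = sample_meta[design.condition]
    levels = sorted(pd.unique(cond.astype(str)))
    if design.reference_level not in levels:
        raise ConfigurationError(
            f"reference level {design.reference_level!r} absent from condition column"
        )
    if len(levels) != 2:
        raise ConfigurationError(
            f"condition must have exactly 2 levels, found {levels}"
        )
    cols = [np.ones(len(sample_meta))]
    names = ["intercept"]
    for cov in design.covariates:
        v = sample_meta[cov]
        if pd.api.types.is_numeric_dtype(v):
            cols.append(v.to_numpy(dtype=float))
            names.append(cov)
        else:
            lv = sorted(pd.unique(v.astype(str)))
            for level in lv[1:]:
                cols.append((v.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{cov}[{level}]")
    case = (cond.astype(str) != design.reference_level).to_numpy(dtype=float)
    cols.append(case)
    case_level = [l for l in levels if l != design.reference_level][0]
    names.append(f"{design.condition}[{case_level}]")
    return np.column_stack(cols), names, len(names) - 1


def estimate_dispersions(pb: PseudobulkMatrix, design_matrix: np.ndarray, gene_mask=None):
    """NB dispersions (genewise/trended/tagwise) for a pseudo-bulk matrix.

    Thin wrapper around the grid-based CR-APL estimator; offsets are the log
    effective library sizes (TMM-normalized if factors are present).
    """
    counts = pb.counts if gene_mask is None else pb.counts[gene_mask]
    lib = counts.sum(axis=0) if pb.lib_sizes is None else pb.lib_sizes
    nf = pb.norm_factors if pb.norm_factors is not None else np.ones(pb.n_samples)
    offset = np.log(lib * nf)
    return _glm.estimate_nb_dispersions(counts, design_matrix, offset)


def ql_fit_and_test(pb: PseudobulkMatrix, design: DesignSpec) -> pd.DataFrame | None:
    """Quasi-likelihood F-test of the condition contrast for every kept gene.

    Returns a DataFrame indexed by gene id with columns ``logFC`` (log2,
    positive = higher in case), ``F`` and ``PValue``, or None when the
    neighborhood is untestable (fewer than 2 samples, a missing condition
    level, a rank-deficient design, or no residual degrees of freedom).
    """
    meta = pb.sample_meta
    if pb.n_samples < 2:
        return None
    if meta[design.condition].astype(str).nunique() < 2:
        return None
    try:
        X, _, cidx = build_design_matrix(meta, design)
    except ConfigurationError:
        return None
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p or n - p < 1:
        return None

    keep = select_genes_for_testing(pb, design)
    if keep.sum() == 0:
        return None
    y = pb.counts[keep]
    lib = y.sum(axis=0)
    ok = lib > 0
    if ok.sum() < n:  # a sample empty on the kept genes cannot be offset
        y = y[:, ok]
        X = X[ok]
        meta = meta.loc[ok]
        n = int(ok.sum())
        if (
            n < 2
            or meta[design.condition].astype(str).nunique() < 2
            or np.linalg.matrix_rank(X) < p
            or n - p < 1
        ):
            return None
        lib = y.sum(axis=0)
    nf = tmm_norm_factors(y, lib)
    offset = np.log(lib * nf)

    disp = _glm.estimate_nb_dispersions(y, X, offset)
    beta, _, dev_full, _ = _glm.fit_nb_glm(y, X, offset, disp.tagwise)
    X0 = np.delete(X, cidx, axis=1)
    _, _, dev_red, _ = _glm.fit_nb_glm(y, X0, offset, disp.tagwise)

    res_df = n - p
    s2 = np.maximum(dev_full / res_df, MIN_QUASI_DISP)
    d0, _, s2_post = _glm.squeeze_var(s2, res_df)
    F = np.maximum(dev_red - dev_full, 0.0) / s2_post
    if np.isinf(d0):
        pvals = chi2.sf(F, 1)
    else:
        pvals = f_dist.sf(F, 1, d0 + res_df)
    logfc = beta[:, cidx] / np.log(2.0)
    return pd.DataFrame(
        {"logFC": logfc, "F": F, "PValue": pvals},
        index=pd.Index(np.asarray(pb.gene_ids)[keep]),
    )


def classifier_auc_filter(
    dataset: CellDataset,
    assignment: NeighborhoodAssignment,
    design: DesignSpec,
    seed: int = 0,
    max_cells_per_condition: int = 50,
    n_splits: int = 3,
    n_repeats: int = 3,
    min_cells: int = 3,
    n_estimators: int = 50,
) -> np.ndarray:
    """Per-neighborhood condition-separability AUC from random forests.

    For each neighborhood a classifier predicts condition labels from
    log-normalized expression on repeated balanced subsamples (up to
    ``max_cells_per_condition`` cells per condition, stratified
    ``n_splits``-fold cross-validation, ``n_repeats`` repeats); the mean AUC is
    returned.  Neighborhoods with fewer than ``min_cells`` cells in either
    condition (or one condition absent) get AUC NaN and are retained for
    testing.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import StratifiedKFold

    from .simulate import roc_auc

    lib = np.asarray(dataset.counts.sum(axis=0)).ravel()
    scale = np.median(lib[lib > 0]) / np.maximum(lib, 1.0)
    lognorm = dataset.counts.T.tocsr().astype(float)
    lognorm = sp.diags(scale) @ lognorm
    lognorm.data = np.log1p(lognorm.data)

    cond = dataset.cell_meta[design.condition].astype(str).to_numpy()
    rng = np.random.default_rng(seed)
    aucs = np.full(assignment.n_nhoods, np.nan)
    for j in range(assignment.n_nhoods):
        cells = assignment.cells_in(j)
        labels = (cond[cells] != design.reference_level).astype(int)
        n1 = int(labels.sum())
        n0 = len(labels) - n1
        if min(n0, n1) < min_cells:
            continue
        n_take = min(max_cells_per_condition, n0, n1)
        fold_aucs = []
        for _ in range(n_repeats):
            pick0 = rng.choice(cells[labels == 0], size=n_take, replace=False)
            pick1 = rng.choice(cells[labels == 1], size=n_take, replace=False)
            pick = np.concatenate([pick0, pick1])
            yb = np.repeat([0, 1], n_take)
            Xb = np.asarray(lognorm[pick].todense())
            skf = StratifiedKFold(
                n_splits=n_splits, shuffle=True, random_state=int(rng.integers(2**31))
            )
            for tr, te in skf.split(Xb, yb):
                clf = RandomForestClassifier(
                    n_estimators=n_estimators,
                    random_state=int(rng.integers(2**31)),
                    n_jobs=1,
                )
                clf.fit(Xb[tr], yb[tr])
                score = clf.predict_proba(Xb[te])[:, 1]
                a = roc_auc(score, yb[te].astype(bool), warn=False)
                if np.isfinite(a):
                    fold_aucs.append(a)
        if fold_aucs:
            aucs[j] = float(np.mean(fold_aucs))
    return aucs


def run_neighborhood_de(
    dataset: CellDataset,
    assignment: NeighborhoodAssignment,
    design: DesignSpec,
    auc_threshold: float | None = None,
    seed: int = 0,
) -> DEResultMatrices:
    """Per-neighborhood pseudo-bulk QL testing plus the dual correction.

    Orchestrates aggregate -> filter -> normalize -> dispersion -> QL test for
    every neighborhood, fills the four gene x neighborhood matrices (NaN for
    untested combinations) and applies both multiple-testing corrections.
    ``auc_threshold`` enables the classifier pre-filter: neighborhoods whose
    AUC falls below it (NaN excepted) are left untested.
    """
    dataset.require_columns(["sample", design.condition, *design.covariates])
    _check_covariates_constant(dataset, design)
    results = DEResultMatrices.allocate(dataset.gene_ids, assignment.n_nhoods)
    gene_index = {g: i for i, g in enumerate(dataset.gene_ids)}

    test_mask = np.ones(assignment.n_nhoods, dtype=bool)
    if auc_threshold is not None:
        aucs = classifier_auc_filter(dataset, assignment, design, seed=seed)
        test_mask = np.isnan(aucs) | (aucs >= auc_threshold)
        logger.info(
            "AUC pre-filter: %d/%d neighborhoods retained",
            int(test_mask.sum()),
            assignment.n_nhoods,
        )

    n_tested = 0
    for j in range(assignment.n_nhoods):
        if not test_mask[j]:
            continue
        cells = assignment.cells_in(j)
        pb = aggregate_pseudobulk(dataset, cells, design)
        table = ql_fit_and_test(pb, design)
        if table is None:
            continue
        rows = np.fromiter((gene_index[g] for g in table.index), dtype=np.int64)
        results.logfc[rows, j] = table["logFC"].to_numpy()
        results.p_raw[rows, j] = table["PValue"].to_numpy()
        results.tested[rows, j] = True
        n_tested += 1
    if n_tested == 0:
        raise RuntimeError(
            "no testable neighborhood: check that at least one neighborhood has "
            ">= 2 samples (after the min_n_cells_per_sample filter) covering "
            "both condition levels"
        )
    weights = nhood_density_weights(assignment)
    return apply_dual_correction(results, weights)


def _check_covariates_constant(dataset: CellDataset, design: DesignSpec) -> None:
    meta = dataset.cell_meta
    for col in (design.condition, *design.covariates):
        per_sample = meta.groupby("sample", observed=True)[col].nunique()
        if (per_sample > 1).any():
            bad = per_sample[per_sample > 1].index.tolist()
            raise ConfigurationError(
                f"column {col!r} is not constant within sample(s) {bad}"
            )
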