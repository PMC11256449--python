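"""Downstream characterization of gene x neighborhood DE patterns.

Builds "corrected logFC" matrices (logFC zeroed wherever the
across-neighborhood corrected p exceeds the cutoff or the combination was
untested), ranks neighborhoods by their degree of perturbation, selects
strongly and consistently DE genes, clusters genes by the shape of their
logFC profile across neighborhoods (PCA + shared-nearest-neighbor graph +
Louvain), aggregates DE along a per-neighborhood covariate axis such as a
differential-abundance logFC, and classifies genes by which neighborhood
group carries their DE signal (Fisher exact tests).
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .correction import weighted_bh
from .errors import InvalidInputError, InvalidParameterError
from .results import DEResultMatrices


@dataclass
class CorrectedLogFCMatrix:
    """logFC with non-significant / untested entries set to zero."""

    values: np.ndarray
    gene_ids: np.ndarray
    alpha: float = 0.1


def corrected_logfc_matrix(results: DEResultMatrices, alpha: float = 0.1) -> CorrectedLogFCMatrix:
    """Zero the logFC wherever p_adj_nhoods > alpha or the entry is untested."""
    p = np.nan_to_num(results.p_adj_nhoods, nan=1.0)
    values = np.where((p <= alpha) & results.tested, np.nan_to_num(results.logfc, nan=0.0), 0.0)
    return CorrectedLogFCMatrix(values=values, gene_ids=results.gene_ids, alpha=alpha)


def rank_nhood_perturbation(
    results: DEResultMatrices, alpha: float = 0.1, z_cut: float = -3.0
) -> pd.DataFrame:
    """Count total and neighborhood-specific DE genes per neighborhood.

    ``n_DE`` counts genes with p_adj_genes < alpha in the neighborhood.  For
    specificity, each gene's across-neighborhood vector of p_adj_nhoods
    (untested entries set to 1) is standardized to mean 0 / sample sd 1;
    ``n_specific_DE`` counts genes whose z falls below ``z_cut`` there, i.e.
    genes whose significance is concentrated in this neighborhood.
    """
    if results.n_nhoods < 2:
        raise InvalidParameterError("ranking requires >= 2 neighborhoods")
    n_de = np.nansum(
        np.where(results.tested, results.p_adj_genes < alpha, False), axis=0
    ).astype(int)
    p = np.nan_to_num(results.p_adj_nhoods, nan=1.0)
    mean = p.mean(axis=1, keepdims=True)
    sd = p.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (p - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0  # constant p: undefined z, no contribution
    n_specific = (z < z_cut).sum(axis=0).astype(int)
    return pd.DataFrame(
        {"nhood": np.arange(results.n_nhoods), "n_DE": n_de, "n_specific_DE": n_specific}
    ).set_index("nhood")


def select_upregulated_genes(
    results: DEResultMatrices,
    clfc: CorrectedLogFCMatrix,
    frac_sig: float = 0.25,
    min_abs_lfc: float = 1.0,
    frac_direction: float = 0.75,
    direction: int = -1,
) -> np.ndarray:
    """Genes consistently and strongly DE in one direction.

    Keeps genes that are (i) significant (p_adj_nhoods < alpha) in at least
    ``frac_sig`` of neighborhoods, (ii) have absolute mean logFC over the
    significant neighborhoods above ``min_abs_lfc``, and (iii) carry the
    requested sign of logFC in at least ``frac_direction`` of neighborhoods
    (``direction=-1``: negative logFC means up in the case group when the
    contrast was fitted case-under-reference, as in the fibrosis analysis).
    """
    p = np.nan_to_num(results.p_adj_nhoods, nan=1.0)
    sig = p < clfc.alpha
    n_nhoods = results.n_nhoods
    frac_significant = sig.sum(axis=1) / n_nhoods
    with np.errstate(invalid="ignore"):
        mean_sig_lfc = np.where(
            sig.any(axis=1),
            np.nansum(np.where(sig, results.logfc, 0.0), axis=1) / np.maximum(sig.sum(axis=1), 1),
            0.0,
        )
    lfc = np.nan_to_num(results.logfc, nan=0.0)
    frac_dir = (np.sign(lfc) == direction).sum(axis=1) / n_nhoods
    keep = (
        (frac_significant >= frac_sig)
        & (np.abs(mean_sig_lfc) > min_abs_lfc)
        & (frac_dir >= frac_direction)
    )
    return results.gene_ids[keep]


def _snn_graph(coords: np.ndarray, k: int):
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Neighbor sets include the point itself; two points are connected when the
    sets intersect, weighted by their Jaccard index.
    """
    from sklearn.neighbors import NearestNeighbors

    n = coords.shape[0]
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    member = np.zeros((n, n), dtype=bool)
    member[np.repeat(np.arange(n), k_eff + 1), idx.ravel()] = True
    member[np.arange(n), np.arange(n)] = True
    shared = member.astype(np.int32) @ member.astype(np.int32).T
    set_sizes = member.sum(axis=1)
    union = set_sizes[:, None] + set_sizes[None, :] - shared
    jaccard = shared / union
    np.fill_diagonal(jaccard, 0.0)
    edges = np.argwhere(np.triu(shared, 1) > 0)
    weights = jaccard[edges[:, 0], edges[:, 1]]
    return edges, weights


def cluster_logfc_patterns(
    clfc: CorrectedLogFCMatrix,
    genes=None,
    n_pcs: int = 5,
    snn_k: int = 10,
    resolution: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Louvain communities of genes sharing a corrected-logFC profile.

    PCA of the gene x neighborhood corrected-logFC matrix (first ``n_pcs``
    components), SNN graph with Jaccard weights over ``snn_k`` nearest
    neighbors, Louvain community detection at the given resolution with a
    fixed seed.  Returns a gene -> cluster label Series.
    """
    import igraph as ig
    from sklearn.decomposition import PCA

    if genes is None:
        gene_ids = np.asarray(clfc.gene_ids)
        values = clfc.values
    else:
        genes = np.asarray(genes)
        pos = {g: i for i, g in enumerate(clfc.gene_ids)}
        rows = np.array([pos[g] for g in genes])
        gene_ids = genes
        values = clfc.values[rows]
    n = values.shape[0]
    if n <= n_pcs:
        raise InvalidParameterError("need more genes than principal components")
    if np.allclose(values, 0):
        warnings.warn("all-zero corrected logFC matrix: returning a single cluster")
        return pd.Series(np.zeros(n, dtype=int), index=pd.Index(gene_ids))
    coords = PCA(n_components=min(n_pcs, n - 1, values.shape[1]), svd_solver="full").fit_transform(values)
    edges, weights = _snn_graph(coords, snn_k)
    g = ig.Graph(n=n, edges=[tuple(e) for e in edges])
    random.seed(seed)  # igraph's default RNG is Python's random module
    part = g.community_multilevel(weights=list(weights), resolution=resolution)
    return pd.Series(np.asarray(part.membership, dtype=int), index=pd.Index(gene_ids))


def bin_by_covariate(
    clfc: CorrectedLogFCMatrix,
    nhood_covariate,
    gene_sets: dict,
    n_bins: int = 50,
    equal_width: bool = False,
) -> pd.DataFrame:
    """Average DE pattern of gene sets along a per-neighborhood covariate axis.

    Neighborhoods are grouped into ``n_bins`` equal-frequency bins on the
    covariate (sizes differ by at most 1; ``equal_width=True`` switches to
    equal-width intervals).  For each gene set and bin the mean corrected
    logFC over (set genes x bin neighborhoods) and the mean fraction of set
    genes significant per neighborhood are reported.
    """
    cov = np.asarray(nhood_covariate, dtype=float)
    n_nhoods = clfc.values.shape[1]
    if len(cov) != n_nhoods:
        raise InvalidInputError("covariate not aligned with neighborhoods")
    if n_bins > n_nhoods:
        raise InvalidParameterError("n_bins must not exceed the number of neighborhoods")
    if equal_width:
        edges = np.linspace(cov.min(), cov.max(), n_bins + 1)
        bin_of = np.clip(np.digitize(cov, edges[1:-1]), 0, n_bins - 1)
        bins = [np.where(bin_of == b)[0] for b in range(n_bins)]
    else:
        order = np.argsort(cov, kind="stable")
        bins = [np.asarray(b) for b in np.array_split(order, n_bins)]
    pos = {g: i for i, g in enumerate(clfc.gene_ids)}
    records = []
    for name, genes in gene_sets.items():
        rows = np.array([pos[g] for g in genes])
        sub = clfc.values[rows]
        sig = sub != 0
        for b, nh in enumerate(bins):
            if len(nh) == 0:
                continue
            block = sub[:, nh]
            records.append(
                {
                    "gene_set": name,
                    "bin": b,
                    "covariate_mean": float(cov[nh].mean()),
                    "n_nhoods": len(nh),
                    "mean_logfc": float(block.mean()),
                    "mean_frac_significant": float(sig[:, nh].mean(axis=0).mean()),
                }
            )
    return pd.DataFrame.from_records(records)


def fisher_group_classification(
    results: DEResultMatrices,
    group_flags,
    alpha: float = 0.1,
    class_fdr: float = 0.1,
    group_a: str = "enriched",
    group_b: str = "mixed",
) -> pd.DataFrame:
    """Classify genes by which neighborhood group concentrates their DE.

    For every gene a 2x2 table of (DE / not DE) x (group A / group B)
    neighborhoods is tested with a two-sided Fisher exact test; p-values are
    BH-corrected across genes, and genes are labelled ``groupA-biased`` /
    ``groupB-biased`` when significant (corrected p < ``class_fdr``) in the
    corresponding direction, else ``both``.
    """
    flags = np.asarray(group_flags)
    if len(flags) != results.n_nhoods:
        raise InvalidInputError("group_flags not aligned with neighborhoods")
    in_a = flags == group_a
    in_b = flags == group_b
    if not in_a.any() or not in_b.any():
        raise InvalidParameterError("both neighborhood groups must be nonempty")
    p = np.nan_to_num(results.p_adj_nhoods, nan=1.0)
    de = p < alpha
    pvals = np.empty(results.n_genes)
    frac_a = np.empty(results.n_genes)
    frac_b = np.empty(results.n_genes)
    for g in range(results.n_genes):
        a_de = int(np.sum(de[g] & in_a))
        b_de = int(np.sum(de[g] & in_b))
        table = [[a_de, int(in_a.sum()) - a_de], [b_de, int(in_b.sum()) - b_de]]
        pvals[g] = fisher_exact(table, alternative="two-sided")[1]
        frac_a[g] = a_de / in_a.sum()
        frac_b[g] = b_de / in_b.sum()
    adj = weighted_bh(pvals, np.ones_like(pvals))
    label = np.where(
        (adj < class_fdr) & (frac_a > frac_b),
        "groupA-biased",
        np.where((adj < class_fdr) & (frac_b > frac_a), "groupB-biased", "both"),
    )
    return pd.DataFrame(
        {
            "p_fisher": pvals,
            "p_adj": adj,
            "frac_de_groupA": frac_a,
            "frac_de_groupB": frac_b,
            "classification": label,
        },
        index=pd.Index(results.gene_ids),
    )
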