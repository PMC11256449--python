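"""Dual multiple-testing correction for overlapping neighborhoods.

Within each neighborhood, p-values are corrected across the tested genes with
standard Benjamini-Hochberg.  Within each gene, p-values are corrected across
the tested neighborhoods with a *weighted* BH step-up in which each
neighborhood's p-value is weighted by the reciprocal of its local graph
density, so that densely overlapping regions of the manifold do not dominate
the false-discovery budget.  The density of a neighborhood is the sum, over
its member cells, of the number of neighborhoods each cell belongs to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .graph import NeighborhoodAssignment
from .results import DEResultMatrices


@dataclass
class DensityWeights:
    """Per-neighborhood local density and its reciprocal weight."""

    density: np.ndarray
    weight: np.ndarray


def nhood_density_weights(assignment: NeighborhoodAssignment) -> DensityWeights:
    """Graph-based neighborhood density: sum of member-cell multiplicities.

    density_j = sum over cells i in neighborhood j of m_i, where m_i is the
    number of neighborhoods containing cell i (computed on the refined
    assignment actually used for testing).
    """
    m = assignment.membership.tocsc()
    sizes = np.asarray(m.getnnz(axis=0))
    if np.any(sizes == 0):
        raise InvalidInputError("empty neighborhood in assignment")
    multiplicity = np.asarray(m.getnnz(axis=1), dtype=float)  # m_i per cell
    density = np.asarray(m.T @ multiplicity).ravel()
    return DensityWeights(density=density, weight=1.0 / density)


def weighted_bh(p, w) -> np.ndarray:
    """Weighted Benjamini-Hochberg step-up adjustment.

    Non-NaN p-values are ordered ascending; the adjusted value at rank i is
    min over j >= i of p_(j) * W / C_(j) with W the total weight and C_(j) the
    cumulative weight through rank j, clipped at 1.  Equal weights reduce this
    to textbook BH; NaN entries pass through untouched and contribute neither
    to W nor to C.  The min-over-suffix form makes the result independent of
    how ties in p are ordered.
    """
    p = np.asarray(p, dtype=float)
    w = np.asarray(w, dtype=float)
    if p.shape != w.shape:
        raise InvalidInputError("p and w must have equal length")
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if not mask.any():
        return out
    pm = p[mask]
    wm = w[mask]
    if np.any(wm <= 0) or np.any(~np.isfinite(wm)):
        raise InvalidInputError("weights must be positive and finite")
    order = np.argsort(pm, kind="stable")
    c = np.cumsum(wm[order])
    W = c[-1]
    adj = pm[order] * W / c
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    restored = np.empty_like(adj)
    restored[order] = np.clip(adj, 0.0, 1.0)
    out[mask] = restored
    return out


def apply_dual_correction(
    raw: DEResultMatrices, weights: DensityWeights
) -> DEResultMatrices:
    """Fill ``p_adj_genes`` (BH per neighborhood) and ``p_adj_nhoods``
    (density-weighted BH per gene) from the raw p-value matrix.

    Only tested combinations participate; untested entries stay NaN.
    """
    if len(weights.weight) != raw.n_nhoods:
        raise InvalidInputError("weights not aligned with the neighborhoods")
    p_adj_genes = np.full_like(raw.p_raw, np.nan)
    p_adj_nhoods = np.full_like(raw.p_raw, np.nan)
    ones = np.ones(raw.n_genes)
    for j in range(raw.n_nhoods):
        p_adj_genes[:, j] = weighted_bh(raw.p_raw[:, j], ones)
    for g in range(raw.n_genes):
        p_adj_nhoods[g, :] = weighted_bh(raw.p_raw[g, :], weights.weight)
    return DEResultMatrices(
        logfc=raw.logfc,
        p_raw=raw.p_raw,
        p_adj_genes=p_adj_genes,
        p_adj_nhoods=p_adj_nhoods,
        tested=raw.tested,
        gene_ids=raw.gene_ids,
        nhood_ids=raw.nhood_ids,
    )
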