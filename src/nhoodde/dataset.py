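"""In-memory containers for single-cell count data and latent embeddings.

The central object is :class:`CellDataset`, a gene x cell raw count matrix plus
per-cell metadata (sample of origin, condition, optional covariates and cell
type labels) and a pre-computed latent embedding in which cell-cell distances
are measured.  Conversion to/from :class:`anndata.AnnData` is provided so that
datasets can round-trip through h5ad files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import InvalidInputError, ConfigurationError


@dataclass
class LatentEmbedding:
    """Cell x dimension coordinates of a pre-computed latent space.

    The package never computes embeddings itself; any joint reduced-dimension
    representation (PCA, MNN-corrected PCs, scVI latent space, ...) may be
    supplied.  Distances between cells are Euclidean in these coordinates.
    """

    coords: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids)
        if self.coords.ndim != 2:
            raise InvalidInputError("embedding coordinates must be 2-dimensional")
        n, d = self.coords.shape
        if n < 2:
            raise InvalidInputError("embedding must contain at least 2 cells")
        if d < 1:
            raise InvalidInputError("embedding must have at least 1 dimension")
        if not np.all(np.isfinite(self.coords)):
            raise InvalidInputError("embedding coordinates contain NaN/inf")
        if len(self.cell_ids) != n:
            raise InvalidInputError("cell_ids length does not match coordinates")
        if len(np.unique(self.cell_ids)) != n:
            raise InvalidInputError("cell_ids are not unique")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class CellDataset:
    """Raw counts (gene x cell) with cell metadata and an optional embedding.

    Parameters
    ----------
    counts
        Sparse or dense gene x cell matrix of non-negative integer counts.
    gene_ids, cell_ids
        Unique string identifiers for rows and columns of ``counts``.
    cell_meta
        Per-cell table indexed like ``cell_ids``.  DE testing requires at
        least ``sample`` and the condition column of the design.
    embedding
        Optional :class:`LatentEmbedding` over the same cells.
    gene_meta
        Optional per-gene table (e.g. simulation ground truth).
    """

    counts: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    embedding: LatentEmbedding | None = None
    gene_meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.gene_ids = np.asarray(self.gene_ids)
        self.cell_ids = np.asarray(self.cell_ids)
        g, c = self.counts.shape
        if len(self.gene_ids) != g:
            raise InvalidInputError("gene_ids length does not match counts rows")
        if len(self.cell_ids) != c:
            raise InvalidInputError("cell_ids length does not match counts columns")
        if len(self.cell_meta) != c:
            raise InvalidInputError("cell_meta length does not match counts columns")
        self.cell_meta = self.cell_meta.copy()
        self.cell_meta.index = pd.Index(self.cell_ids)
        if self.embedding is not None and self.embedding.n_cells != c:
            raise InvalidInputError("embedding does not cover the same cells as counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def require_columns(self, columns) -> None:
        """Raise :class:`ConfigurationError` naming any missing metadata column."""
        missing = [c for c in columns if c not in self.cell_meta.columns]
        if missing:
            raise ConfigurationError(
                f"cell metadata is missing required column(s): {', '.join(missing)}"
            )

    def validate_counts(self) -> None:
        """Check that counts are non-negative integers (loud, O(nnz))."""
        data = self.counts.data
        if data.size and data.min() < 0:
            raise InvalidInputError("counts contain negative values")
        if data.size and not np.allclose(data, np.round(data)):
            raise InvalidInputError("counts are not integer-valued")

    def subset_cells(self, index) -> "CellDataset":
        """Positional subset of cells, propagating metadata and embedding."""
        index = np.asarray(index)
        emb = None
        if self.embedding is not None:
            emb = LatentEmbedding(
                coords=self.embedding.coords[index],
                cell_ids=self.embedding.cell_ids[index],
            )
        return CellDataset(
            counts=self.counts[:, index],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[index],
            cell_meta=self.cell_meta.iloc[index],
            embedding=emb,
            gene_meta=self.gene_meta,
        )

    # -- AnnData interop ---------------------------------------------------

    @classmethod
    def from_anndata(cls, adata, obsm_key: str = "X_pca") -> "CellDataset":
        """Build a dataset from an AnnData object (cells x genes convention)."""
        counts = adata.X
        if not sp.issparse(counts):
            counts = sp.csr_matrix(np.asarray(counts))
        emb = None
        if obsm_key is not None and obsm_key in adata.obsm:
            emb = LatentEmbedding(
                coords=np.asarray(adata.obsm[obsm_key]),
                cell_ids=adata.obs_names.to_numpy(),
            )
        gene_meta = adata.var.copy() if adata.var.shape[1] else None
        return cls(
            counts=counts.T.tocsr(),
            gene_ids=adata.var_names.to_numpy(),
            cell_ids=adata.obs_names.to_numpy(),
            cell_meta=adata.obs.copy(),
            embedding=emb,
            gene_meta=gene_meta,
        )

    def to_anndata(self, obsm_key: str = "X_pca"):
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids)),
        )
        if self.embedding is not None:
            adata.obsm[obsm_key] = self.embedding.coords
        return adata
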