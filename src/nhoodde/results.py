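"""Gene x neighborhood DE result matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError


@dataclass
class DEResultMatrices:
    """Four gene x neighborhood matrices plus a tested mask.

    ``logfc`` is the log2 fold change (positive = higher in the case
    condition), ``p_raw`` the raw quasi-likelihood F-test p-value,
    ``p_adj_genes`` the BH-corrected p across tested genes within each
    neighborhood, and ``p_adj_nhoods`` the density-weighted BH-corrected p
    across tested neighborhoods within each gene.  Entries are NaN exactly
    where ``tested`` is False.
    """

    logfc: np.ndarray
    p_raw: np.ndarray
    p_adj_genes: np.ndarray
    p_adj_nhoods: np.ndarray
    tested: np.ndarray
    gene_ids: np.ndarray
    nhood_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        shape = self.logfc.shape
        for name in ("p_raw", "p_adj_genes", "p_adj_nhoods", "tested"):
            if getattr(self, name).shape != shape:
                raise InvalidInputError(f"{name} shape does not match logfc")
        if len(self.gene_ids) != shape[0]:
            raise InvalidInputError("gene_ids length does not match matrices")
        if self.nhood_ids is None:
            self.nhood_ids = np.arange(shape[1])

    @property
    def n_genes(self) -> int:
        return self.logfc.shape[0]

    @property
    def n_nhoods(self) -> int:
        return self.logfc.shape[1]

    @classmethod
    def allocate(cls, gene_ids, n_nhoods: int) -> "DEResultMatrices":
        g = len(gene_ids)
        nan = lambda: np.full((g, n_nhoods), np.nan)
        return cls(
            logfc=nan(),
            p_raw=nan(),
            p_adj_genes=nan(),
            p_adj_nhoods=nan(),
            tested=np.zeros((g, n_nhoods), dtype=bool),
            gene_ids=np.asarray(gene_ids),
        )
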