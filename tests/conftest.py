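"""Shared fixtures: small synthetic datasets built programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nhoodde.dataset import CellDataset, LatentEmbedding
from nhoodde.de import DesignSpec


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_dataset(
    n_genes: int = 50,
    n_cells: int = 120,
    n_samples: int = 6,
    seed: int = 0,
    n_dims: int = 3,
    cell_types=None,
) -> CellDataset:
    """Small NB-ish random dataset with half the samples in each condition."""
    r = np.random.default_rng(seed)
    means = r.gamma(2.0, 2.0, size=n_genes)
    counts = r.poisson(means[:, None] * r.lognormal(0, 0.3, size=n_cells), size=(n_genes, n_cells))
    sample = np.array([f"s{i % n_samples}" for i in range(n_cells)])
    condition = np.where(
        np.array([int(s[1:]) for s in sample]) < n_samples // 2, "control", "case"
    )
    meta = pd.DataFrame({"sample": sample, "condition": condition})
    if cell_types is not None:
        meta["cell_type"] = r.choice(cell_types, size=n_cells)
    gene_ids = np.array([f"g{i}" for i in range(n_genes)])
    cell_ids = np.array([f"c{i}" for i in range(n_cells)])
    emb = LatentEmbedding(coords=r.normal(size=(n_cells, n_dims)), cell_ids=cell_ids)
    return CellDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_meta=meta,
        embedding=emb,
    )


@pytest.fixture
def small_dataset() -> CellDataset:
    return make_dataset()


@pytest.fixture
def design() -> DesignSpec:
    return DesignSpec(condition="condition", reference_level="control")


@pytest.fixture
def random_embedding(rng) -> LatentEmbedding:
    coords = rng.uniform(size=(200, 2))
    return LatentEmbedding(coords=coords, cell_ids=np.arange(200))
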