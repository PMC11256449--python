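"""Readers and writers for the package's on-disk formats.

Counts travel as MatrixMarket MTX (gene x row convention, 1-based indices per
the standard) with gene/cell TSV annotation, or as HDF5-based AnnData h5ad
files; embeddings as TSV (cell_id + numeric columns) or an obsm slot of the
h5ad.  Neighborhood assignments are written as a boolean membership MTX plus
a neighborhood TSV; DE results as a deterministic long-format TSV plus a
run-metadata JSON.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .dataset import CellDataset, LatentEmbedding
from .errors import ConfigurationError, InvalidInputError
from .graph import NeighborhoodAssignment
from .results import DEResultMatrices


def load_embedding_tsv(path) -> LatentEmbedding:
    """TSV with a cell_id column followed by numeric coordinate columns."""
    table = pd.read_csv(path, sep="\t")
    if "cell_id" not in table.columns:
        raise ConfigurationError("embedding TSV must have a 'cell_id' column")
    coords = table.drop(columns=["cell_id"]).to_numpy(dtype=float)
    return LatentEmbedding(coords=coords, cell_ids=table["cell_id"].to_numpy())


def load_dataset_mtx(
    counts_mtx,
    genes_tsv,
    cells_tsv,
    embedding_tsv=None,
    condition_column: str = "condition",
) -> CellDataset:
    """Load a dataset from MTX counts + gene/cell TSVs (+ optional embedding TSV)."""
    counts = sp.csr_matrix(mmread(counts_mtx))
    genes = pd.read_csv(genes_tsv, sep="\t")
    cells = pd.read_csv(cells_tsv, sep="\t")
    if "gene_id" not in genes.columns:
        raise ConfigurationError("gene TSV must have a 'gene_id' column")
    if "cell_id" not in cells.columns:
        raise ConfigurationError("cell TSV must have a 'cell_id' column")
    for required in ("sample", condition_column):
        if required not in cells.columns:
            raise ConfigurationError(
                f"cell TSV is missing required column {required!r}"
            )
    if counts.shape != (len(genes), len(cells)):
        raise InvalidInputError(
            f"counts shape {counts.shape} does not match {len(genes)} genes x {len(cells)} cells"
        )
    embedding = load_embedding_tsv(embedding_tsv) if embedding_tsv else None
    cell_ids = cells["cell_id"].to_numpy()
    if embedding is not None:
        if not np.array_equal(embedding.cell_ids, cell_ids):
            order = pd.Index(embedding.cell_ids).get_indexer(cell_ids)
            if (order < 0).any():
                raise InvalidInputError("embedding does not cover all cells")
            embedding = LatentEmbedding(
                coords=embedding.coords[order], cell_ids=cell_ids
            )
    dataset = CellDataset(
        counts=counts,
        gene_ids=genes["gene_id"].to_numpy(),
        cell_ids=cell_ids,
        cell_meta=cells.drop(columns=["cell_id"]),
        embedding=embedding,
    )
    dataset.validate_counts()
    return dataset


def load_dataset_h5ad(path, obsm_key: str = "X_pca", condition_column: str = "condition") -> CellDataset:
    import anndata as ad

    adata = ad.read_h5ad(path)
    dataset = CellDataset.from_anndata(adata, obsm_key=obsm_key)
    dataset.require_columns(["sample", condition_column])
    dataset.validate_counts()
    return dataset


def save_dataset(dataset: CellDataset, outdir) -> dict:
    """Write MTX + gene/cell TSVs + embedding TSV; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.mtx",
        "genes": outdir / "genes.tsv",
        "cells": outdir / "cells.tsv",
    }
    mmwrite(str(paths["counts"]), sp.coo_matrix(dataset.counts))
    genes = pd.DataFrame({"gene_id": dataset.gene_ids})
    if dataset.gene_meta is not None:
        genes = pd.concat([genes, dataset.gene_meta.reset_index(drop=True)], axis=1)
    genes.to_csv(paths["genes"], sep="\t", index=False)
    cells = dataset.cell_meta.reset_index(names="cell_id")
    cells.to_csv(paths["cells"], sep="\t", index=False)
    if dataset.embedding is not None:
        paths["embedding"] = outdir / "embedding.tsv"
        emb = pd.DataFrame(
            dataset.embedding.coords,
            columns=[f"dim{i}" for i in range(dataset.embedding.coords.shape[1])],
        )
        emb.insert(0, "cell_id", dataset.embedding.cell_ids)
        emb.to_csv(paths["embedding"], sep="\t", index=False)
    return paths


def write_assignment(assignment: NeighborhoodAssignment, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "membership": outdir / "membership.mtx",
        "nhoods": outdir / "nhoods.tsv",
    }
    mmwrite(str(paths["membership"]), sp.coo_matrix(assignment.membership).astype(np.int8))
    pd.DataFrame(
        {
            "nhood_id": np.arange(assignment.n_nhoods),
            "index_cell": assignment.index_cells,
            "size": assignment.sizes(),
        }
    ).to_csv(paths["nhoods"], sep="\t", index=False)
    meta = {
        "order": assignment.order,
        "k": assignment.k,
        "prop": assignment.prop,
        "seed": assignment.seed,
    }
    (outdir / "assignment.json").write_text(json.dumps(meta, indent=1))
    return paths


def read_assignment(indir) -> NeighborhoodAssignment:
    indir = Path(indir)
    membership = sp.csc_matrix(mmread(indir / "membership.mtx")).astype(bool)
    nhoods = pd.read_csv(indir / "nhoods.tsv", sep="\t")
    meta = json.loads((indir / "assignment.json").read_text())
    return NeighborhoodAssignment(
        membership=membership,
        index_cells=nhoods["index_cell"].to_numpy(),
        order=meta["order"],
        k=meta["k"],
        prop=meta.get("prop"),
        seed=meta.get("seed"),
    )


def write_results(results: DEResultMatrices, path, run_params: dict | None = None) -> Path:
    """Long-format results TSV (gene, nhood, logFC, p_raw, p_adj_genes,
    p_adj_nhoods, tested), rows ordered by gene then neighborhood, plus a
    run-metadata JSON next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g, n = results.logfc.shape
    table = pd.DataFrame(
        {
            "gene": np.repeat(results.gene_ids, n),
            "nhood": np.tile(results.nhood_ids, g),
            "logFC": results.logfc.ravel(),
            "p_raw": results.p_raw.ravel(),
            "p_adj_genes": results.p_adj_genes.ravel(),
            "p_adj_nhoods": results.p_adj_nhoods.ravel(),
            "tested": results.tested.ravel(),
        }
    )
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {
        "n_genes": g,
        "n_nhoods": n,
        "python": platform.python_version(),
        "params": run_params or {},
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, default=str))
    return path


def read_results(path) -> DEResultMatrices:
    table = pd.read_csv(path, sep="\t")
    genes = table["gene"].unique()
    nhoods = np.sort(table["nhood"].unique())
    g, n = len(genes), len(nhoods)

    def mat(col, dtype=float):
        return table[col].to_numpy(dtype=dtype).reshape(g, n)

    return DEResultMatrices(
        logfc=mat("logFC"),
        p_raw=mat("p_raw"),
        p_adj_genes=mat("p_adj_genes"),
        p_adj_nhoods=mat("p_adj_nhoods"),
        tested=mat("tested", dtype=bool),
        gene_ids=genes,
        nhood_ids=nhoods,
    )


def file_checksum(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
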