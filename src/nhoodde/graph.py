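"""kNN graphs, waypoint index-cell selection and overlapping neighborhoods.

Cells are connected in a 1st-order kNN graph (standard k nearest neighbors,
Euclidean distance in the latent embedding, symmetrized) or a 2nd-order kNN
graph in which two cells are additionally connected whenever they share at
least one common neighbor.  Neighborhood centers ("index cells") are picked by
waypoint sampling with triangle counting, each neighborhood is the index cell
plus all its graph neighbors, and a greedy set-cover refinement discards
neighborhoods whose cells are already covered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .dataset import LatentEmbedding
from .errors import InvalidInputError, InvalidParameterError

# waypoint selection always runs on a "shallow" graph with k capped here
SHALLOW_K = 50


@dataclass
class KnnGraph:
    """Symmetric boolean adjacency without self-loops."""

    adjacency: sp.csr_matrix
    order: int
    k: int

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        a = self.adjacency
        return a.indices[a.indptr[i] : a.indptr[i + 1]]


@dataclass
class NeighborhoodAssignment:
    """Boolean cell x neighborhood membership, one index cell per neighborhood.

    Each neighborhood j is exactly {index_cells[j]} plus the graph neighbors of
    that index cell; neighborhoods overlap and some cells may be unassigned
    until refinement guarantees coverage of all covered cells.
    """

    membership: sp.csc_matrix
    index_cells: np.ndarray
    order: int
    k: int
    prop: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.membership = self.membership.tocsc().astype(bool)
        self.index_cells = np.asarray(self.index_cells)
        if self.membership.shape[1] != len(self.index_cells):
            raise InvalidInputError("one index cell per neighborhood is required")

    @property
    def n_cells(self) -> int:
        return self.membership.shape[0]

    @property
    def n_nhoods(self) -> int:
        return self.membership.shape[1]

    def sizes(self) -> np.ndarray:
        return np.asarray(self.membership.getnnz(axis=0))

    def cells_in(self, j: int) -> np.ndarray:
        m = self.membership
        return m.indices[m.indptr[j] : m.indptr[j + 1]]


def _knn_adjacency(coords: np.ndarray, k: int) -> sp.csr_matrix:
    """Symmetrized kNN adjacency; self excluded; distance ties by ascending index."""
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 2, n)).fit(coords)
    dist, idx = nn.kneighbors(coords)
    rows = np.empty(n * k, dtype=np.int64)
    cols = np.empty(n * k, dtype=np.int64)
    for i in range(n):
        order = np.lexsort((idx[i], dist[i]))
        cand = idx[i][order]
        cand = cand[cand != i][:k]
        rows[i * k : (i + 1) * k] = i
        cols[i * k : i * k + len(cand)] = cand
        if len(cand) < k:  # only when k+2 candidates included self twice (dup coords)
            cols[i * k + len(cand) : (i + 1) * k] = cand[-1] if len(cand) else i
    a = sp.coo_matrix((np.ones(n * k, dtype=bool), (rows, cols)), shape=(n, n)).tocsr()
    a = (a + a.T).astype(bool)
    a.setdiag(False)
    a.eliminate_zeros()
    return a.tocsr()


def _second_order(adj: sp.csr_matrix) -> sp.csr_matrix:
    """Add an edge between any two vertices sharing >= 1 common neighbor."""
    a = adj.astype(np.int32)
    a2 = (a + a @ a).tocsr()
    a2.setdiag(0)
    a2.eliminate_zeros()
    return (a2 > 0).tocsr()


def build_graph(embedding: LatentEmbedding, k: int, order: int = 2) -> KnnGraph:
    """Build the 1st- or 2nd-order kNN graph on the latent embedding.

    The 1st-order graph links each cell to its k nearest neighbors and is then
    symmetrized; the 2nd-order graph is the 1st-order graph augmented with
    edges between cells that share at least one neighbor.  Every vertex thus
    keeps degree >= k, and 2nd-order edges are a superset of 1st-order edges.
    """
    coords = embedding.coords
    n = coords.shape[0]
    if not (1 <= k < n):
        raise InvalidParameterError(f"k must satisfy 1 <= k < n_cells (got k={k}, n={n})")
    if order not in (1, 2):
        raise InvalidParameterError("order must be 1 or 2")
    adj = _knn_adjacency(coords, k)
    if order == 2:
        adj = _second_order(adj)
    return KnnGraph(adjacency=adj, order=order, k=k)


def _induced_triangle_counts(adj: sp.csr_matrix, c: int):
    """Per-vertex triangle counts on the subgraph induced by {c} + neighbors(c).

    Returns (vertices, counts) with the sampled cell first.  The count for a
    vertex is the number of 3-cycles through it, i.e. diag(A^3)/2 of the
    induced adjacency.
    """
    nbrs = adj.indices[adj.indptr[c] : adj.indptr[c + 1]]
    verts = np.concatenate(([c], np.sort(nbrs)))
    s = adj[verts][:, verts].toarray().astype(np.int64)
    tri = np.diag(s @ s @ s) // 2
    return verts, tri


def _pick_index_cell(adj: sp.csr_matrix, c: int) -> int:
    """Waypoint rule: most-triangled vertex near c; ties prefer c, then min index."""
    verts, tri = _induced_triangle_counts(adj, c)
    best = tri.max()
    if tri[0] == best:
        return int(c)
    return int(verts[tri == best].min())


def _waypoint_index_cells(adj: sp.csr_matrix, prop: float, seed: int) -> np.ndarray:
    n = adj.shape[0]
    if not (0 < prop <= 1):
        raise InvalidParameterError("prop must be in (0, 1]")
    n_sample = int(np.floor(prop * n))
    if n_sample < 1:
        raise InvalidParameterError(f"prop * n_cells = {prop * n:.3f} < 1: no cells sampled")
    rng = np.random.default_rng(seed)
    sampled = rng.choice(n, size=n_sample, replace=False)
    chosen = [_pick_index_cell(adj, int(c)) for c in sampled]
    return np.unique(chosen)


def select_index_cells(
    embedding: LatentEmbedding, k: int, prop: float, seed: int
) -> np.ndarray:
    """Select neighborhood centers by waypoint sampling with triangle counting.

    A shallow 1st-order graph with k' = min(50, k) is built; floor(prop * n)
    cells are sampled uniformly without replacement; for each sampled cell the
    vertex with the most triangles in the induced subgraph on the cell and its
    neighbors becomes an index cell.  Duplicates collapse, so the result may
    be smaller than the sample.
    """
    shallow = build_graph(embedding, k=min(SHALLOW_K, k), order=1)
    return _waypoint_index_cells(shallow.adjacency, prop, seed)


def assign_neighborhoods(graph: KnnGraph, index_cells) -> NeighborhoodAssignment:
    """One neighborhood per index cell: the cell itself plus its graph neighbors."""
    index_cells = np.unique(np.asarray(index_cells, dtype=np.int64))
    if index_cells.size == 0:
        raise InvalidParameterError("index_cells must be nonempty")
    n = graph.n_cells
    if index_cells.min() < 0 or index_cells.max() >= n:
        raise InvalidParameterError("index_cells outside the vertex range")
    rows, cols = [], []
    for j, c in enumerate(index_cells):
        members = np.concatenate(([c], graph.neighbors(int(c))))
        rows.append(members)
        cols.append(np.full(len(members), j, dtype=np.int64))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    membership = sp.coo_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n, len(index_cells))
    ).tocsc()
    return NeighborhoodAssignment(
        membership=membership, index_cells=index_cells, order=graph.order, k=graph.k
    )


def refine_assignment(assignment: NeighborhoodAssignment) -> NeighborhoodAssignment:
    """Greedy set-cover refinement of the neighborhood assignment.

    Neighborhoods are visited in decreasing order of size (ties by ascending
    neighborhood index) and kept only if they contain at least one cell not
    covered by previously kept neighborhoods.  The kept set covers exactly the
    cells covered by the input.
    """
    m = assignment.membership.tocsc()
    sizes = np.asarray(m.getnnz(axis=0))
    visit = np.lexsort((np.arange(len(sizes)), -sizes))
    covered = np.zeros(assignment.n_cells, dtype=bool)
    keep = []
    for j in visit:
        cells = m.indices[m.indptr[j] : m.indptr[j + 1]]
        if not np.all(covered[cells]):
            keep.append(j)
            covered[cells] = True
    keep = np.sort(np.asarray(keep, dtype=np.int64))
    return NeighborhoodAssignment(
        membership=m[:, keep],
        index_cells=assignment.index_cells[keep],
        order=assignment.order,
        k=assignment.k,
        prop=assignment.prop,
        seed=assignment.seed,
    )


def build_neighborhood_assignment(
    embedding: LatentEmbedding,
    k: int = 20,
    order: int = 2,
    prop: float = 0.2,
    seed: int = 0,
    refine: bool = True,
) -> NeighborhoodAssignment:
    """Full assignment pipeline: shallow graph, waypoint centers, assignment, refinement.

    The shallow 1st-order graph (k' = min(50, k)) used for index selection is
    reused as the assignment backbone when k <= 50; for larger k the 1st-order
    graph is rebuilt at the requested k before the optional order-2
    augmentation.
    """
    shallow = build_graph(embedding, k=min(SHALLOW_K, k), order=1)
    index_cells = _waypoint_index_cells(shallow.adjacency, prop, seed)
    if k <= SHALLOW_K:
        base = shallow.adjacency
    else:
        base = build_graph(embedding, k=k, order=1).adjacency
    adj = _second_order(base) if order == 2 else base
    graph = KnnGraph(adjacency=adj, order=order, k=k)
    assignment = assign_neighborhoods(graph, index_cells)
    assignment.prop = prop
    assignment.seed = seed
    if refine:
        assignment = refine_assignment(assignment)
    return assignment


def estimate_neighborhood_sizes(
    embedding: LatentEmbedding, grid, seed: int = 0, prop: float = 0.2
) -> pd.DataFrame:
    """Refined neighborhood-size distributions over a grid of (order, k).

    Useful for choosing order/k so that the average neighborhood comfortably
    exceeds the few-hundred-cell target at which pseudo-bulk testing becomes
    sensitive.
    """
    grid = list(grid)
    if not grid:
        raise InvalidParameterError("grid must be nonempty")
    records = []
    for i, (order, k) in enumerate(grid):
        assignment = build_neighborhood_assignment(
            embedding, k=k, order=order, prop=prop, seed=seed + i
        )
        sizes = assignment.sizes()
        records.append(
            {
                "order": order,
                "k": k,
                "n_nhoods": assignment.n_nhoods,
                "min": sizes.min(),
                "q25": float(np.quantile(sizes, 0.25)),
                "median": float(np.median(sizes)),
                "q75": float(np.quantile(sizes, 0.75)),
                "mean": float(sizes.mean()),
                "max": sizes.max(),
            }
        )
    return pd.DataFrame.from_records(records)
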