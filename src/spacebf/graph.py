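"""Spatial adjacency graphs and their incidence / Laplacian algebra.

The fusion prior lives on the edges of a graph connecting the measured
locations.  Four constructions are supported:

* minimum spanning tree (``mst``) — acyclic, the backbone on which the
  per-edge horseshoe scale updates are exact;
* k-nearest-neighbour union graph (``knn``);
* Delaunay triangulation (``delaunay``);
* epsilon-neighbourhood graph (``eps``), with an automatic radius equal to
  the maximum nearest-neighbour distance.

All distances are Euclidean (L2).  The oriented incidence matrix ``D`` puts
+1 on the lower-indexed endpoint of each edge, and the weighted Laplacian
is ``L(lambda) = D' diag(lambda^-2) D``, a positive semidefinite matrix of
rank ``n - C`` where ``C`` is the number of connected components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial import Delaunay, QhullError, cKDTree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SpatialGraph",
    "IncidenceMatrix",
    "WeightedLaplacian",
    "build_mst",
    "build_knn",
    "build_delaunay",
    "build_eps_graph",
    "incidence",
    "weighted_laplacian",
    "save_graph",
    "load_graph",
]


@dataclass
class SpatialGraph:
    """Undirected graph over ``n`` spatial locations.

    ``edges`` is a (p, 2) integer array with ``edges[i, 0] < edges[i, 1]``,
    sorted lexicographically; no self-loops or duplicates.
    """

    coords: np.ndarray
    edges: np.ndarray
    kind: str
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def n_components(self) -> int:
        adj = self.adjacency()
        return int(connected_components(adj, directed=False)[0])

    @property
    def l_rank(self) -> int:
        """Rank of the graph Laplacian, n - C."""
        return self.n_vertices - self.n_components

    def adjacency(self) -> sp.csr_matrix:
        n = self.n_vertices
        if self.n_edges == 0:
            return sp.csr_matrix((n, n))
        u, v = self.edges[:, 0], self.edges[:, 1]
        ones = np.ones(self.n_edges)
        a = sp.coo_matrix((ones, (u, v)), shape=(n, n))
        return (a + a.T).tocsr()

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size:
            self.edges = np.sort(self.edges, axis=1)
            order = np.lexsort((self.edges[:, 1], self.edges[:, 0]))
            self.edges = self.edges[order]
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            if np.any(self.edges < 0) or np.any(self.edges >= len(self.coords)):
                raise ValueError("edge index out of range")
            dup = np.all(np.diff(self.edges, axis=0) == 0, axis=1)
            if np.any(dup):
                raise ValueError("duplicate edges are not allowed")


@dataclass
class IncidenceMatrix:
    """Oriented incidence matrix: row i has +1 at the lower endpoint index."""

    D: sp.csr_matrix
    edges: np.ndarray


@dataclass
class WeightedLaplacian:
    L: sp.csr_matrix
    lambda2: np.ndarray
    l_rank: int


def _check_coords(coords) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    return coords


def build_mst(coords, jitter_scale: float = 0.0, seed: int | None = None) -> SpatialGraph:
    """Euclidean minimum spanning tree, with optional distance jitter.

    On regular grids the MST is non-unique; adding i.i.d.
    Uniform(0, jitter_scale * d_min) noise to the candidate edge distances
    (d_min = smallest positive pairwise distance) selects one tree
    reproducibly given ``seed``.
    """
    coords = _check_coords(coords)
    n = len(coords)
    if n < 2:
        raise ValueError("MST needs at least 2 points")
    if jitter_scale < 0:
        raise ValueError("jitter_scale must be nonnegative")

    # Candidate edges: Delaunay edges contain the Euclidean MST; fall back
    # to the complete graph when the triangulation is unavailable.
    cand = None
    if n >= 4:
        try:
            cand = build_delaunay(coords).edges
        except (ValueError, QhullError):
            cand = None
    if cand is None:
        iu = np.triu_indices(n, k=1)
        cand = np.column_stack(iu)
    d = np.linalg.norm(coords[cand[:, 0]] - coords[cand[:, 1]], axis=1)

    pos = d[d > 0]
    if pos.size == 0:
        raise ValueError("all coordinates coincide; MST undefined")
    d_min = pos.min()
    # scipy's csgraph drops explicit zeros: keep duplicate-point edges alive
    d[d == 0] = d_min * 1e-9
    if jitter_scale > 0:
        rng = np.random.default_rng(seed)
        d = d + rng.uniform(0.0, jitter_scale * d_min, size=d.shape)
    elif _has_ties(d):
        warnings.warn(
            "tied pairwise distances with jitter_scale=0: the MST is "
            "non-unique; pass jitter_scale>0 for a reproducible random tree",
            stacklevel=2,
        )

    g = sp.coo_matrix((d, (cand[:, 0], cand[:, 1])), shape=(n, n))
    tree = minimum_spanning_tree(g.tocsr())
    u, v = tree.nonzero()
    graph = SpatialGraph(coords, np.column_stack([u, v]), kind="mst", seed=seed,
                         meta={"jitter_scale": jitter_scale})
    if graph.n_edges != n - graph.n_components:
        raise RuntimeError("MST construction produced a cyclic edge set")
    return graph


def _has_ties(d: np.ndarray) -> bool:
    ds = np.sort(d)
    return bool(np.any(np.isclose(np.diff(ds), 0.0, atol=1e-12)))


def build_knn(coords, k: int) -> SpatialGraph:
    """Union-symmetrised k-nearest-neighbour graph (may be disconnected)."""
    coords = _check_coords(coords)
    n = len(coords)
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n, got k={k}, n={n}")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    src = np.repeat(np.arange(n), k)
    dst = idx[:, 1:].ravel()
    edges = np.sort(np.column_stack([src, dst]), axis=1)
    edges = np.unique(edges, axis=0)
    return SpatialGraph(coords, edges, kind="knn", meta={"k": k})


def build_delaunay(coords) -> SpatialGraph:
    """Edge set of the Delaunay triangulation."""
    coords = _check_coords(coords)
    n = len(coords)
    if n < 3:
        raise ValueError("Delaunay triangulation needs at least 3 points")
    try:
        tri = Delaunay(coords)
    except QhullError as exc:
        raise ValueError(
            "degenerate input for Delaunay triangulation (points may be "
            "collinear or coincident): " + str(exc).splitlines()[0]
        ) from exc
    s = tri.simplices
    edges = np.vstack([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    return SpatialGraph(coords, edges, kind="delaunay")


def build_eps_graph(coords, eps: float | str = "auto") -> SpatialGraph:
    """Connect all pairs with 0 < d <= eps.

    ``eps='auto'`` uses the maximum nearest-neighbour distance, which
    guarantees minimum degree >= 1 (but not global connectivity).
    """
    coords = _check_coords(coords)
    n = len(coords)
    if n < 2:
        raise ValueError("eps graph needs at least 2 points")
    dmat = squareform(pdist(coords))
    if isinstance(eps, str):
        if eps != "auto":
            raise ValueError("eps must be a positive number or 'auto'")
        with np.errstate(invalid="ignore"):
            dd = dmat + np.diag(np.full(n, np.inf))
        eps_val = float(dd.min(axis=1).max())
    else:
        eps_val = float(eps)
        if eps_val <= 0:
            raise ValueError("eps must be positive")
    iu = np.triu_indices(n, k=1)
    d = dmat[iu]
    keep = (d > 0) & (d <= eps_val)
    edges = np.column_stack([iu[0][keep], iu[1][keep]])
    return SpatialGraph(coords, edges, kind="eps", meta={"eps": eps_val})


def save_graph(graph: SpatialGraph, prefix) -> None:
    """Write <prefix>.edges.tsv (u, v, weight = Euclidean length),
    <prefix>.coords.csv and <prefix>.json metadata (kind, seed, C)."""
    import json
    from pathlib import Path

    prefix = Path(prefix)
    w = np.linalg.norm(graph.coords[graph.edges[:, 0]]
                       - graph.coords[graph.edges[:, 1]], axis=1) \
        if graph.n_edges else np.empty(0)
    lines = ["u\tv\tweight"] + [
        f"{u}\t{v}\t{wi:.10g}" for (u, v), wi in zip(graph.edges, w)]
    prefix.with_suffix(".edges.tsv").write_text("\n".join(lines) + "\n")
    np.savetxt(prefix.with_suffix(".coords.csv"), graph.coords,
               delimiter=",", header="x,y", comments="")
    prefix.with_suffix(".json").write_text(json.dumps({
        "kind": graph.kind, "seed": graph.seed,
        "n_components": graph.n_components, "meta": graph.meta}, indent=1))


def load_graph(prefix) -> SpatialGraph:
    import json
    from pathlib import Path

    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    coords = np.loadtxt(prefix.with_suffix(".coords.csv"),
                        delimiter=",", skiprows=1, ndmin=2)
    rows = prefix.with_suffix(".edges.tsv").read_text().strip().splitlines()[1:]
    edges = (np.array([r.split("\t")[:2] for r in rows], dtype=np.int64)
             if rows else np.empty((0, 2), dtype=np.int64))
    return SpatialGraph(coords, edges, kind=meta["kind"], seed=meta["seed"],
                        meta=meta.get("meta", {}))


def incidence(graph: SpatialGraph) -> IncidenceMatrix:
    """Oriented incidence matrix D (p x n): +1 at min index, -1 at max.

    D'D equals the unweighted graph Laplacian.
    """
    p, n = graph.n_edges, graph.n_vertices
    if p == 0:
        return IncidenceMatrix(sp.csr_matrix((0, n)), graph.edges)
    rows = np.repeat(np.arange(p), 2)
    cols = graph.edges.ravel()
    vals = np.tile([1.0, -1.0], p)
    D = sp.coo_matrix((vals, (rows, cols)), shape=(p, n)).tocsr()
    return IncidenceMatrix(D, graph.edges)


def weighted_laplacian(D: IncidenceMatrix, lambda2) -> WeightedLaplacian:
    """L(lambda) = D' diag(lambda^-2) D, PSD with L 1 = 0."""
    lambda2 = np.asarray(lambda2, dtype=float)
    p, n = D.D.shape
    if lambda2.shape != (p,):
        raise ValueError(f"lambda2 must have length p={p}")
    if np.any(lambda2 <= 0) or not np.all(np.isfinite(lambda2)):
        raise ValueError("lambda2 entries must be strictly positive and finite")
    W = sp.diags(1.0 / lambda2)
    L = (D.D.T @ W @ D.D).tocsr()
    n_comp = connected_components(
        sp.csr_matrix((np.ones(p), (D.edges[:, 0], D.edges[:, 1])), shape=(n, n)),
        directed=False,
    )[0] if p else n
    return WeightedLaplacian(L, lambda2, l_rank=n - n_comp)
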