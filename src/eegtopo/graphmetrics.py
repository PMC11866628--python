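"""Binary graph construction by sparsity thresholding and global topology metrics.

A weighted band adjacency matrix is binarized by keeping the K
largest-weight edges, K = round(sparsity * n(n-1)/2), over a grid of
sparsity levels (default 5% to 95% in 5% steps, 19 levels). On each
binary graph seven global metrics are computed:

* Cp   — mean nodal clustering coefficient (triangles / possible);
* Lp   — characteristic path length, averaged over reachable pairs;
* Eg   — global efficiency, mean inverse shortest-path distance;
* Eloc — local efficiency, mean over nodes of Eg on each node's
         neighbor-induced subgraph;
* gamma, lambda — Cp and Lp normalized by their means over
  degree-preserving rewired null graphs;
* sigma = gamma / lambda — the small-world index (> 1 indicates
  small-world organization).

Shortest paths use breadth-first search via scipy's csgraph; the null
model is the standard degree-preserving double-edge-swap randomization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

try:  # numba accelerates the swap loop; the numpy fallback is semantically identical
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


from .spectral import BandAdjacency

METRIC_NAMES: tuple[str, ...] = ("Cp", "Lp", "gamma", "lambda", "sigma", "Eg", "Eloc")

#: 5% to 95% in steps of 5% — 19 levels.
DEFAULT_SPARSITY_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(1, 20) * 0.05, 10)
)

DEFAULT_N_NULL = 100
DEFAULT_SWAPS_PER_EDGE = 10


@dataclass
class BinaryGraph:
    """Simple undirected graph as a symmetric boolean adjacency matrix."""

    adjacency: np.ndarray
    sparsity: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise ValueError("self-loops are not allowed")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def edge_list(self) -> np.ndarray:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([i, j])


@dataclass
class GlobalMetrics:
    """The seven global topology metrics of one binary graph."""

    Cp: float
    Lp: float
    gamma_: float
    lambda_: float
    sigma_: float
    Eg: float
    Eloc: float
    unreachable_pairs: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "Cp": self.Cp, "Lp": self.Lp, "gamma": self.gamma_,
            "lambda": self.lambda_, "sigma": self.sigma_,
            "Eg": self.Eg, "Eloc": self.Eloc,
        }


@dataclass
class MetricCurves:
    """metric x band x sparsity array of global metrics; NaN marks undefined."""

    values: np.ndarray
    sparsity_grid: tuple[float, ...]
    bands: tuple[str, ...]
    metrics: tuple[str, ...] = METRIC_NAMES

    def __post_init__(self) -> None:
        grid = np.asarray(self.sparsity_grid, float)
        if grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("sparsity grid must be strictly increasing and non-empty")
        if self.values.shape != (len(self.metrics), len(self.bands), grid.size):
            raise ValueError("values shape must be (metrics, bands, sparsity levels)")

    def get(self, metric: str, band: str) -> np.ndarray:
        return self.values[self.metrics.index(metric), self.bands.index(band)]


def sparsity_threshold(adj: BandAdjacency | np.ndarray, s: float) -> BinaryGraph:
    """Keep the round(s * n(n-1)/2) largest-weight edges and binarize.

    Rounding is round-half-up; ties in weight are broken by lexicographic
    (row, column) channel-pair order, so the result is deterministic.
    """
    W = adj.W if isinstance(adj, BandAdjacency) else np.asarray(adj, float)
    n = W.shape[0]
    if not 0.0 < s <= 1.0:
        raise ValueError(f"sparsity must be in (0, 1], got {s}")
    if np.all(W == 0):
        raise ValueError("cannot threshold an all-zero adjacency matrix")
    iu, ju = np.triu_indices(n, 1)
    w = W[iu, ju]
    k = int(np.floor(s * iu.size + 0.5))
    # sort by descending weight, then ascending (i, j) for tie stability
    order = np.lexsort((ju, iu, -w))
    keep = order[:k]
    a = np.zeros((n, n), dtype=bool)
    a[iu[keep], ju[keep]] = True
    return BinaryGraph(adjacency=a | a.T, sparsity=s)


@njit(cache=True)
def _bfs_all(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths of a boolean adjacency matrix (BFS)."""
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    queue = np.empty(n, np.int64)
    for s in range(n):
        d[s, s] = 0.0
        head = 0
        tail = 1
        queue[0] = s
        while head < tail:
            u = queue[head]
            head += 1
            du = d[s, u]
            for v in range(n):
                if a[u, v] and d[s, v] == np.inf:
                    d[s, v] = du + 1.0
                    queue[tail] = v
                    tail += 1
    return d


def _distances(a: np.ndarray) -> np.ndarray:
    return _bfs_all(np.ascontiguousarray(a, dtype=np.bool_))


def _clustering(a: np.ndarray) -> float:
    ai = a.astype(np.int64)
    deg = ai.sum(axis=1)
    tri2 = np.einsum("ij,jk,ki->i", ai, ai, ai)  # 2 x triangles per node
    possible = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(possible > 0, tri2 / np.where(possible > 0, possible, 1), 0.0)
    return float(c.mean())


def _path_length(d: np.ndarray) -> tuple[float, int]:
    n = d.shape[0]
    iu, ju = np.triu_indices(n, 1)
    dv = d[iu, ju]
    reachable = np.isfinite(dv)
    if not np.any(reachable):
        raise ValueError("no connected pair of nodes")
    return float(dv[reachable].mean()), int((~reachable).sum())


def _efficiency(d: np.ndarray) -> float:
    n = d.shape[0]
    iu, ju = np.triu_indices(n, 1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[iu, ju]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


@njit(cache=True)
def _eloc_kernel(a: np.ndarray) -> float:
    n = a.shape[0]
    total = 0.0
    nbrs = np.empty(n, np.int64)
    for v in range(n):
        cnt = 0
        for u in range(n):
            if a[v, u]:
                nbrs[cnt] = u
                cnt += 1
        if cnt < 2:
            continue
        sub = np.empty((cnt, cnt), np.bool_)
        for i in range(cnt):
            for j in range(cnt):
                sub[i, j] = a[nbrs[i], nbrs[j]]
        d = _bfs_all(sub)
        acc = 0.0
        for i in range(cnt):
            for j in range(i + 1, cnt):
                if d[i, j] != np.inf:
                    acc += 1.0 / d[i, j]
        total += acc / (cnt * (cnt - 1) / 2.0)
    return total / n


def _local_efficiency(a: np.ndarray) -> float:
    return float(_eloc_kernel(np.ascontiguousarray(a, dtype=np.bool_)))


def clustering_coefficient(g: BinaryGraph) -> float:
    """Mean nodal clustering: triangles through a node over choose(degree, 2).

    Nodes with degree < 2 contribute 0 to the unweighted mean.
    """
    return _clustering(g.adjacency)


def characteristic_path_length(g: BinaryGraph) -> tuple[float, int]:
    """Mean shortest-path length over reachable pairs.

    Returns (Lp, number of unreachable unordered pairs, excluded from the
    mean). Raises if no pair is connected.
    """
    if g.n_nodes < 2:
        raise ValueError("graph must have at least 2 nodes")
    return _path_length(_distances(g.adjacency))


def global_efficiency(g: BinaryGraph) -> float:
    """Mean of 1/distance over all unordered pairs; unreachable pairs count 0."""
    if g.n_nodes < 2:
        raise ValueError("graph must have at least 2 nodes")
    return _efficiency(_distances(g.adjacency))


def local_efficiency(g: BinaryGraph) -> float:
    """Mean over nodes of the global efficiency of the neighbor-induced subgraph.

    Nodes with fewer than 2 neighbors contribute 0.
    """
    return _local_efficiency(g.adjacency)


@njit(cache=True)
def _swap_kernel(
    a: np.ndarray,
    edges: np.ndarray,
    picks: np.ndarray,
    orient: np.ndarray,
    target: int,
) -> int:
    """Apply double edge swaps in place; returns the number completed."""
    n_edges = edges.shape[0]
    done = 0
    for t in range(picks.shape[0]):
        if done >= target:
            break
        e1 = picks[t, 0]
        e2 = picks[t, 1]
        if e1 == e2:
            continue
        x1, y1 = edges[e1, 0], edges[e1, 1]
        x2, y2 = edges[e2, 0], edges[e2, 1]
        if orient[t]:
            x2, y2 = y2, x2
        # proposed replacement: (x1, y2) and (x2, y1)
        if x1 == y2 or x2 == y1:
            continue
        if a[x1, y2] or a[x2, y1]:
            continue
        a[x1, y1] = a[y1, x1] = False
        a[x2, y2] = a[y2, x2] = False
        a[x1, y2] = a[y2, x1] = True
        a[x2, y1] = a[y1, x2] = True
        edges[e1, 0], edges[e1, 1] = x1, y2
        edges[e2, 0], edges[e2, 1] = x2, y1
        done += 1
    return done


def rewire_null(
    g: BinaryGraph,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int | np.random.Generator = 0,
) -> BinaryGraph:
    """Degree-preserving randomization by repeated double edge swaps.

    Picks two edges (a, b), (c, d) and rewires to (a, d), (c, b) when the
    swap creates neither a self-loop nor a duplicate edge. Degree
    sequence and edge count are invariant. If the attempt budget runs out
    before the requested number of swaps, the partially rewired graph is
    returned with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = g.adjacency.copy()
    edges = g.edge_list().astype(np.int64)
    n_edges = len(edges)
    if n_edges < 2:
        raise ValueError("graph needs at least 2 edges to rewire")
    target = swaps_per_edge * n_edges
    max_attempts = 20 * target
    picks = rng.integers(n_edges, size=(max_attempts, 2))
    orient = rng.integers(2, size=max_attempts).astype(np.bool_)
    done = _swap_kernel(a, edges, picks, orient, target)
    if done < target:
        # near-complete graphs admit few valid swaps; the partial null is
        # still exactly degree-preserving
        warnings.warn(
            "rewire_null exhausted its attempt budget before the requested swap count",
            RuntimeWarning,
        )
    return BinaryGraph(adjacency=a, sparsity=g.sparsity)


def small_world_indices(
    g: BinaryGraph,
    n_null: int = DEFAULT_N_NULL,
    seed: int | np.random.Generator = 0,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) against degree-preserving rewired nulls.

    gamma = Cp / <Cp_null>, lambda = Lp / <Lp_null>, sigma = gamma / lambda.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cp = clustering_coefficient(g)
    lp, _ = characteristic_path_length(g)
    null_cp = np.empty(n_null)
    null_lp = np.empty(n_null)
    for i in range(n_null):
        null = rewire_null(g, swaps_per_edge=swaps_per_edge, seed=rng)
        null_cp[i] = clustering_coefficient(null)
        null_lp[i], _ = characteristic_path_length(null)
    mean_cp = null_cp.mean()
    if mean_cp <= 0:
        raise ValueError("null ensemble has zero mean clustering; graph too sparse")
    gamma = cp / mean_cp
    lam = lp / null_lp.mean()
    return float(gamma), float(lam), float(gamma / lam)


def compute_metrics(
    g: BinaryGraph,
    n_null: int = DEFAULT_N_NULL,
    seed: int | np.random.Generator = 0,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> GlobalMetrics:
    """All seven global metrics of one binary graph; NaN where undefined."""
    d = _distances(g.adjacency)
    cp = _clustering(g.adjacency)
    try:
        lp, unreachable = _path_length(d)
    except ValueError:
        lp, unreachable = np.nan, g.n_nodes * (g.n_nodes - 1) // 2
    eg = _efficiency(d)
    eloc = _local_efficiency(g.adjacency)
    gamma = lam = sigma = np.nan
    if np.isfinite(lp) and n_null >= 2 and g.n_edges >= 2:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        null_cp = np.empty(n_null)
        null_lp = np.empty(n_null)
        for i in range(n_null):
            null = rewire_null(g, swaps_per_edge=swaps_per_edge, seed=rng)
            null_cp[i] = _clustering(null.adjacency)
            null_lp[i], _ = _path_length(_distances(null.adjacency))
        if null_cp.mean() > 0:
            gamma = cp / null_cp.mean()
            lam = lp / null_lp.mean()
            sigma = gamma / lam
    return GlobalMetrics(
        Cp=cp, Lp=lp, gamma_=gamma, lambda_=lam, sigma_=sigma,
        Eg=eg, Eloc=eloc, unreachable_pairs=unreachable,
    )


def sweep_metrics(
    adjacencies: BandAdjacency | list[BandAdjacency],
    grid: tuple[float, ...] = DEFAULT_SPARSITY_GRID,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> MetricCurves:
    """Global metrics at every sparsity level for one or more band adjacencies.

    Levels where a metric is undefined (e.g. disconnected graph, null
    ensemble with zero clustering) are recorded as NaN, never fabricated.
    """
    if isinstance(adjacencies, BandAdjacency):
        adjacencies = [adjacencies]
    grid = tuple(float(s) for s in grid)
    if not grid:
        raise ValueError("sparsity grid must be non-empty")
    bands = tuple(a.band for a in adjacencies)
    values = np.full((len(METRIC_NAMES), len(bands), len(grid)), np.nan)
    rng = np.random.default_rng(seed)
    for b, adj in enumerate(adjacencies):
        for s_idx, s in enumerate(grid):
            g = sparsity_threshold(adj, s)
            m = compute_metrics(g, n_null=n_null, seed=rng, swaps_per_edge=swaps_per_edge)
            d = m.as_dict()
            for m_idx, name in enumerate(METRIC_NAMES):
                values[m_idx, b, s_idx] = d[name]
    return MetricCurves(values=values, sparsity_grid=grid, bands=bands)
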