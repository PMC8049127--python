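"""STAD-R: distance-preserving graph abstraction of a distance matrix.

The algorithm turns a pairwise distance matrix D_X into an *unweighted*
graph U whose shortest-path (hop) distances D_U echo D_X:

1. enumerate all node pairs as edge candidates, sorted ascending by
   distance (ties broken lexicographically by node pair);
2. seed the network with the minimum spanning tree (MST), which guarantees
   connectivity — the zero-added-edges iteration;
3. add the remaining candidates in ranked order, one prefix at a time;
4. at each prefix, score the network by the Pearson correlation rho between
   D_X and the hop matrix D_U, multiplied by the edge ratio

       R = sum(1 - d_e) / sum(1 + d_e)   over every edge e in the network,

   where d_e is the edge's original distance in D_X;
5. keep the prefix maximizing the objective rho * R.

The ratio R penalizes inclusion of dissimilar (large-d) links.  On the
left-skewed distance distributions typical of sparse categorical data —
most pairs nearly maximally distant — maximizing rho alone floods the graph
with long-distance edges; the product objective keeps the network sparse
while preserving structure.  Maximizing plain rho (the original objective,
available via ``objective="correlation"``) is retained for comparison.

Everything in this module is deterministic: no randomness, fixed
tie-breaks (first argmax, i.e. fewest added edges, wins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .errors import DataError
from .similarity import DistanceMatrix

Objective = Literal["ratio", "correlation"]
SearchMode = Literal["auto", "exhaustive", "coarse"]

#: Largest candidate count for which "auto" search runs the exhaustive scan.
AUTO_EXHAUSTIVE_LIMIT = 3000


class EdgeCandidate(NamedTuple):
    """An unordered node pair with its original distance; node_a < node_b."""

    node_a: int
    node_b: int
    distance: float
    in_mst: bool


@dataclass(frozen=True)
class StadNetwork:
    """A connected network: the MST plus ``added_edge_count`` extra edges."""

    node_ids: tuple[str, ...]
    edges: tuple[EdgeCandidate, ...]
    added_edge_count: int

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def __post_init__(self) -> None:
        n_mst = sum(e.in_mst for e in self.edges)
        if n_mst != self.n - 1:
            raise ValueError(f"expected {self.n - 1} MST edges, found {n_mst}")
        if len(self.edges) != (self.n - 1) + self.added_edge_count:
            raise ValueError("edge count inconsistent with added_edge_count")

    def to_networkx(self):
        """Undirected networkx graph with distance / in_mst edge attributes."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for e in self.edges:
            g.add_edge(
                self.node_ids[e.node_a],
                self.node_ids[e.node_b],
                distance=e.distance,
                in_mst=bool(e.in_mst),
            )
        return g


class TracePoint(NamedTuple):
    """Objective evaluation of one prefix (MST + ``added_edges`` candidates)."""

    added_edges: int
    rho: float
    ratio_r: float
    objective: float


@dataclass(frozen=True)
class ObjectiveTrace:
    """Evaluated prefixes (ascending in added_edges) and the argmax index."""

    points: tuple[TracePoint, ...]
    best_index: int

    @property
    def best(self) -> TracePoint:
        return self.points[self.best_index]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.points)
        frame["is_best"] = False
        frame.loc[self.best_index, "is_best"] = True
        return frame

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def rank_edge_candidates(dist: DistanceMatrix) -> list[EdgeCandidate]:
    """All n(n-1)/2 pairs sorted ascending by distance, then by node pair.

    MST membership (Kruskal on this very ordering) is flagged on each
    candidate, making the seed tree unique even under distance ties.
    """
    n = dist.n
    if n < 2:
        raise DataError("need at least 2 nodes")
    iu = np.triu_indices(n, k=1)
    d = dist.values[iu]
    order = np.lexsort((iu[1], iu[0], d))

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    out: list[EdgeCandidate] = []
    for k in order:
        a, b = int(iu[0][k]), int(iu[1][k])
        ra, rb = find(a), find(b)
        in_mst = ra != rb
        if in_mst:
            parent[ra] = rb
        out.append(EdgeCandidate(a, b, float(d[k]), in_mst))
    return out


def build_mst(dist: DistanceMatrix) -> StadNetwork:
    """Minimum spanning tree under the fixed candidate ordering (Kruskal)."""
    mst_edges = tuple(e for e in rank_edge_candidates(dist) if e.in_mst)
    return StadNetwork(dist.ids, mst_edges, added_edge_count=0)


def _hop_matrix(n: int, edges: Sequence[EdgeCandidate]) -> np.ndarray:
    rows = np.fromiter((e.node_a for e in edges), dtype=np.int32, count=len(edges))
    cols = np.fromiter((e.node_b for e in edges), dtype=np.int32, count=len(edges))
    data = np.ones(len(edges), dtype=np.int8)
    adj = csr_matrix(
        (np.concatenate([data, data]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    )
    hops = shortest_path(adj, method="D", unweighted=True, directed=False)
    return hops


def hop_distance_matrix(net: StadNetwork) -> np.ndarray:
    """Matrix of minimum edge counts between all node pairs.

    Raises
    ------
    DataError
        If the network is disconnected (cannot happen for MST-seeded output).
    """
    hops = _hop_matrix(net.n, net.edges)
    if not np.isfinite(hops).all():
        raise DataError("network is disconnected")
    return hops.astype(np.int64)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(xc @ xc))
    sy = float(np.sqrt(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        warnings.warn(
            "zero-variance distance vector; correlation set to 0", stacklevel=3
        )
        return 0.0
    return float((xc @ yc) / (sx * sy))


def network_correlation(dist: DistanceMatrix, hops: np.ndarray) -> float:
    """Pearson rho between D_X and the hop matrix over upper-triangle pairs.

    Returns 0 (with a warning) when either vector is constant, e.g. on the
    complete graph where every hop distance is 1.
    """
    if hops.shape != dist.values.shape:
        raise DataError(
            f"hop matrix shape {hops.shape} does not match distance "
            f"matrix shape {dist.values.shape}"
        )
    iu = np.triu_indices(dist.n, k=1)
    return _pearson(dist.values[iu], hops[iu].astype(float))


def edge_ratio(edges: Iterable[EdgeCandidate | float]) -> float:
    """R = sum(1 - d) / sum(1 + d) over all edges currently in the network.

    Always in [0, 1] for distances in [0, 1]: 1 when every included edge has
    distance 0, falling toward 0 as dissimilar links are included.
    """
    d = np.asarray(
        [e.distance if isinstance(e, EdgeCandidate) else float(e) for e in edges]
    )
    if d.size == 0:
        raise DataError("edge ratio undefined for an empty edge set")
    return float((1.0 - d).sum() / (1.0 + d).sum())


class _PrefixEvaluator:
    """Scores MST + first-k-candidate networks against a distance matrix."""

    def __init__(self, dist: DistanceMatrix, ranked: Sequence[EdgeCandidate]):
        self.dist = dist
        self.n = dist.n
        self.mst = [e for e in ranked if e.in_mst]
        self.extra = [e for e in ranked if not e.in_mst]
        iu = np.triu_indices(self.n, k=1)
        self._dx = dist.values[iu]
        self._iu = iu
        # Cumulative sums over [MST..., extra...] let R come out in O(1).
        d_all = np.array([e.distance for e in self.mst + self.extra])
        self._cum_lo = np.concatenate([[0.0], np.cumsum(1.0 - d_all)])
        self._cum_hi = np.concatenate([[0.0], np.cumsum(1.0 + d_all)])

    @property
    def max_added(self) -> int:
        return len(self.extra)

    def evaluate(self, k_added: int) -> TracePoint:
        if not 0 <= k_added <= self.max_added:
            raise DataError(
                f"k_added must be in [0, {self.max_added}], got {k_added}"
            )
        edges = self.mst + self.extra[:k_added]
        hops = _hop_matrix(self.n, edges)
        rho = _pearson(self._dx, hops[self._iu])
        m = len(self.mst) + k_added
        r = float(self._cum_lo[m] / self._cum_hi[m])
        return TracePoint(k_added, rho, r, rho * r)

    def network(self, k_added: int) -> StadNetwork:
        edges = sorted(
            self.mst + self.extra[:k_added],
            key=lambda e: (e.distance, e.node_a, e.node_b),
        )
        return StadNetwork(self.dist.ids, tuple(edges), added_edge_count=k_added)


def evaluate_prefix(
    dist: DistanceMatrix, ranked: Sequence[EdgeCandidate], k_added: int
) -> TracePoint:
    """Score the network formed by the MST plus the first ``k_added``
    non-MST candidates in ranked order."""
    return _PrefixEvaluator(dist, ranked).evaluate(k_added)


def _criterion(point: TracePoint, objective: Objective) -> float:
    return point.objective if objective == "ratio" else point.rho


def _coarse_schedule(max_added: int) -> list[int]:
    """Deterministic log-spaced prefix grid: dense start, geometric tail."""
    ks = set(range(0, min(max_added, 32) + 1))
    if max_added > 32:
        grid = np.unique(
            np.geomspace(32, max_added, num=64).round().astype(int)
        )
        ks.update(int(k) for k in grid)
        ks.add(max_added)
    return sorted(ks)


def run_stad_r(
    dist: DistanceMatrix,
    mode: SearchMode = "auto",
    objective: Objective = "ratio",
) -> tuple[StadNetwork, ObjectiveTrace]:
    """Build the network at the objective-maximizing prefix.

    Parameters
    ----------
    dist
        Pairwise distance matrix (n >= 3) with entries in [0, 1].
    mode
        ``exhaustive`` scores every prefix 0..K; ``coarse`` scores a
        log-spaced grid and then refines the bracket around the best grid
        point down to single-prefix resolution; ``auto`` (default) picks
        exhaustive when K <= 3000 candidates, else coarse.
    objective
        ``ratio`` maximizes rho * R (the default), ``correlation`` maximizes
        plain rho — the original objective, kept for comparison.

    Returns the chosen network and the full evaluation trace (ascending in
    added edges, first argmax flagged; ties resolve to the sparsest network).
    """
    if dist.n < 3:
        raise DataError(f"need at least 3 nodes, got {dist.n}")
    ev = _PrefixEvaluator(dist, rank_edge_candidates(dist))
    if mode == "auto":
        mode = "exhaustive" if ev.max_added <= AUTO_EXHAUSTIVE_LIMIT else "coarse"

    with warnings.catch_warnings():
        # The complete-graph prefix always has constant hop distances; its
        # rho := 0 convention is expected, not worth a warning per prefix.
        warnings.filterwarnings("ignore", message="zero-variance")
        if mode == "exhaustive":
            evaluated = {k: ev.evaluate(k) for k in range(ev.max_added + 1)}
        elif mode == "coarse":
            evaluated = {k: ev.evaluate(k) for k in _coarse_schedule(ev.max_added)}
            while True:
                ks = sorted(evaluated)
                best_k = max(ks, key=lambda k: (_criterion(evaluated[k], objective), -k))
                i = ks.index(best_k)
                lo = ks[i - 1] if i > 0 else best_k
                hi = ks[i + 1] if i + 1 < len(ks) else best_k
                if hi - lo <= 2:
                    break
                step = max(1, (hi - lo) // 16)
                new = [k for k in range(lo + step, hi, step) if k not in evaluated]
                if not new:
                    new = [k for k in range(lo + 1, hi) if k not in evaluated]
                if not new:
                    break
                for k in new:
                    evaluated[k] = ev.evaluate(k)
        else:
            raise DataError(f"unknown search mode {mode!r}")

    points = tuple(evaluated[k] for k in sorted(evaluated))
    crits = [_criterion(p, objective) for p in points]
    best_index = int(np.argmax(crits))  # first argmax -> fewest added edges
    trace = ObjectiveTrace(points, best_index)
    return ev.network(points[best_index].added_edges), trace


def oracle_best_prefix(dist: DistanceMatrix, max_n: int = 10) -> TracePoint:
    """Exhaustive argmax over every prefix, for validating the search.

    Deliberately restricted to tiny instances (n <= ``max_n``); first argmax
    wins under ties.
    """
    if dist.n > max_n:
        raise DataError(f"oracle limited to n <= {max_n}, got {dist.n}")
    ev = _PrefixEvaluator(dist, rank_edge_candidates(dist))
    best: TracePoint | None = None
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="zero-variance")
        for k in range(ev.max_added + 1):
            point = ev.evaluate(k)
            if best is None or point.objective > best.objective:
                best = point
    assert best is not None
    return best
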