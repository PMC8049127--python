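"""Global and local distance-preservation metrics for projections.

A projection of a cohort — either the abstract graph itself (hop distances)
or a 2-D embedding of it (Euclidean distances between node coordinates) —
is scored against the original distance matrix D_X on two axes:

* global structure: Spearman rank correlation between the n(n-1)/2 original
  pairwise distances and the projected ones;
* local structure: the mean, over nodes, of the fraction of each node's k
  nearest original-space neighbors that remain among its k nearest
  neighbors in the projection (k = 14 by default, a typical community size
  in ICU diagnosis cohorts).

Both metrics depend only on distance ranks / neighbor sets, so they are
invariant under rotation, translation and uniform scaling of coordinate
views, and under any strictly monotone transform of the distances.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .errors import ConfigurationError, DataError
from .similarity import DistanceMatrix
from .stadr import StadNetwork, hop_distance_matrix

DEFAULT_K = 14


@dataclass(frozen=True)
class ProjectionView:
    """A projection to score: graph hop distances or 2-D coordinates.

    Node order must match the reference distance matrix.
    """

    kind: Literal["graph_hops", "coordinates_2d"]
    payload: np.ndarray

    @classmethod
    def from_network(cls, net: StadNetwork) -> "ProjectionView":
        return cls("graph_hops", hop_distance_matrix(net))

    @classmethod
    def from_coordinates(cls, coords: np.ndarray) -> "ProjectionView":
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise DataError(f"expected (n, 2) coordinates, got {coords.shape}")
        return cls("coordinates_2d", coords)

    def distance_matrix(self) -> np.ndarray:
        """Square pairwise distances induced by the view."""
        if self.kind == "graph_hops":
            return np.asarray(self.payload, dtype=float)
        return squareform(pdist(self.payload))


def _check_match(dist: DistanceMatrix, view_d: np.ndarray) -> None:
    if view_d.shape != dist.values.shape:
        raise DataError(
            f"view induces {view_d.shape} distances, reference is "
            f"{dist.values.shape}"
        )


def spearman_global(dist: DistanceMatrix, view: ProjectionView) -> float:
    """Spearman rank correlation of all pairwise distances, original vs view.

    Average ranks under ties; 0 (with a warning) if either distance vector
    is constant.
    """
    if dist.n < 3:
        raise DataError("Spearman correlation needs at least 3 nodes")
    view_d = view.distance_matrix()
    _check_match(dist, view_d)
    iu = np.triu_indices(dist.n, k=1)
    x, y = dist.values[iu], view_d[iu]
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn("zero-variance distance vector; Spearman set to 0")
        return 0.0
    return float(spearmanr(x, y).statistic)


def _neighbor_sets(d: np.ndarray, k: int) -> list[frozenset[int]]:
    # Stable argsort on each row -> ties broken by ascending node index.
    n = d.shape[0]
    out = []
    for i in range(n):
        order = np.argsort(d[i], kind="stable")
        order = order[order != i]
        out.append(frozenset(order[:k].tolist()))
    return out


def knn_preservation(
    dist: DistanceMatrix, view: ProjectionView, k: int = DEFAULT_K
) -> float:
    """Mean fraction of each node's k nearest neighbors kept by the view."""
    if not 1 <= k <= dist.n - 1:
        raise DataError(f"k must be in [1, {dist.n - 1}], got {k}")
    view_d = view.distance_matrix()
    _check_match(dist, view_d)
    original = _neighbor_sets(dist.values, k)
    projected = _neighbor_sets(view_d, k)
    return float(
        np.mean([len(a & b) / k for a, b in zip(original, projected)])
    )


@dataclass(frozen=True)
class EvaluationReport:
    """Global and local projection quality against a distance matrix."""

    spearman_global: float
    knn_preservation: float
    k: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def evaluate_projection(
    dist: DistanceMatrix, view: ProjectionView, k: int = DEFAULT_K
) -> EvaluationReport:
    """Bundle both metrics at neighborhood size ``k``."""
    return EvaluationReport(
        spearman_global=spearman_global(dist, view),
        knn_preservation=knn_preservation(dist, view, k),
        k=k,
    )


def read_coordinates(path: str | Path, ids: tuple[str, ...]) -> ProjectionView:
    """Read a (node_id, x, y) TSV and align rows to the given node order."""
    frame = pd.read_csv(path, sep="\t", dtype={"node_id": str})
    for col in ("node_id", "x", "y"):
        if col not in frame.columns:
            raise ConfigurationError(f"coordinate file lacks column {col!r}")
    frame = frame.set_index("node_id")
    missing = [i for i in ids if i not in frame.index]
    if missing:
        raise DataError(f"coordinate file lacks nodes: {missing[:5]}")
    aligned = frame.loc[list(ids), ["x", "y"]].to_numpy(dtype=float)
    return ProjectionView.from_coordinates(aligned)
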