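"""Post-hoc network annotation and serialization.

Community structure (Louvain modularity maximization on the unweighted
graph) and a deterministic force-directed layout are computed as *optional
annotations*: they decorate nodes and never alter the underlying network.
Annotated networks serialize to GraphML or node-link JSON, the data
contract consumed by downstream dashboards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import ConfigurationError, DataError
from .stadr import EdgeCandidate, StadNetwork

LAYOUT_ALGORITHM = "fruchterman_reingold"  # networkx spring layout


@dataclass(frozen=True)
class CommunityLabeling:
    """Per-node community labels, contiguous from 0."""

    labels: tuple[int, ...]
    resolution: float
    seed: int

    @property
    def n_communities(self) -> int:
        return max(self.labels) + 1

    def partition(self) -> list[frozenset[int]]:
        """Label-agnostic view: the induced partition of node indices."""
        groups: dict[int, set[int]] = {}
        for i, lab in enumerate(self.labels):
            groups.setdefault(lab, set()).add(i)
        return [frozenset(g) for _, g in sorted(groups.items())]

    def write(self, path: str | Path, node_ids: tuple[str, ...]) -> None:
        lines = ["node_id\tcommunity"]
        lines += [f"{i}\t{c}" for i, c in zip(node_ids, self.labels)]
        Path(path).write_text("\n".join(lines) + "\n")


def detect_communities(
    net: StadNetwork, resolution: float = 1.0, seed: int = 0
) -> CommunityLabeling:
    """Louvain modularity communities on the unweighted network.

    Labels are renumbered so community 0 contains the lowest node index,
    making the labeling deterministic given the seed.
    """
    g = nx.Graph()
    g.add_nodes_from(range(net.n))
    g.add_edges_from((e.node_a, e.node_b) for e in net.edges)
    communities = nx.community.louvain_communities(
        g, resolution=resolution, seed=seed
    )
    labels = [0] * net.n
    for lab, members in enumerate(sorted(communities, key=min)):
        for node in members:
            labels[node] = lab
    return CommunityLabeling(tuple(labels), resolution, seed)


@dataclass(frozen=True)
class LayoutCoordinates:
    """Deterministic 2-D force-directed placement of the network's nodes."""

    coords: np.ndarray  # shape (n, 2)
    seed: int
    iterations: int
    algorithm: str = LAYOUT_ALGORITHM


def compute_layout(
    net: StadNetwork, seed: int = 0, iterations: int = 100
) -> LayoutCoordinates:
    """Force-directed layout; identical (network, seed, iterations) give
    identical coordinates."""
    g = nx.Graph()
    g.add_nodes_from(range(net.n))
    g.add_edges_from((e.node_a, e.node_b) for e in net.edges)
    pos = nx.spring_layout(g, seed=seed, iterations=iterations)
    coords = np.array([pos[i] for i in range(net.n)], dtype=float)
    if not np.isfinite(coords).all():
        raise DataError("layout produced non-finite coordinates")
    return LayoutCoordinates(coords, seed=seed, iterations=iterations)


def _annotated_graph(
    net: StadNetwork,
    labeling: CommunityLabeling | None,
    layout: LayoutCoordinates | None,
) -> nx.Graph:
    g = net.to_networkx()
    if labeling is not None:
        if len(labeling.labels) != net.n:
            raise DataError("community labeling does not match node count")
        for i, node in enumerate(net.node_ids):
            g.nodes[node]["community"] = int(labeling.labels[i])
    if layout is not None:
        if layout.coords.shape != (net.n, 2):
            raise DataError("layout does not match node count")
        for i, node in enumerate(net.node_ids):
            g.nodes[node]["x"] = float(layout.coords[i, 0])
            g.nodes[node]["y"] = float(layout.coords[i, 1])
    return g


def write_network(
    net: StadNetwork,
    path: str | Path,
    labeling: CommunityLabeling | None = None,
    layout: LayoutCoordinates | None = None,
    fmt: str = "json",
    meta: dict | None = None,
) -> None:
    """Serialize to node-link JSON (sorted keys, byte-stable) or GraphML.

    Nodes carry id plus any community / x / y annotation; edges carry the
    original distance and the MST flag.
    """
    if fmt == "json":
        g = _annotated_graph(net, labeling, layout)
        doc = {
            "meta": dict(meta or {}),
            "nodes": [
                {"id": node, **{k: v for k, v in attrs.items()}}
                for node, attrs in g.nodes(data=True)
            ],
            "links": [
                {"source": a, "target": b, **attrs}
                for a, b, attrs in g.edges(data=True)
            ],
        }
        if layout is not None:
            doc["meta"].setdefault("layout_algorithm", layout.algorithm)
        Path(path).write_text(
            json.dumps(doc, indent=1, sort_keys=True) + "\n"
        )
    elif fmt == "graphml":
        nx.write_graphml(_annotated_graph(net, labeling, layout), path)
    else:
        raise ConfigurationError(f"unknown network format {fmt!r}")


def read_network(
    path: str | Path, fmt: str = "json"
) -> tuple[StadNetwork, CommunityLabeling | None, LayoutCoordinates | None]:
    """Inverse of :func:`write_network`; annotations are returned when
    present (community labeling reports resolution/seed 0 placeholders)."""
    if fmt == "json":
        doc = json.loads(Path(path).read_text())
        node_ids = tuple(n["id"] for n in doc["nodes"])
        index = {node: i for i, node in enumerate(node_ids)}
        edges = []
        for link in doc["links"]:
            a, b = index[link["source"]], index[link["target"]]
            if a > b:
                a, b = b, a
            edges.append(
                EdgeCandidate(a, b, float(link["distance"]), bool(link["in_mst"]))
            )
        nodes = doc["nodes"]
    elif fmt == "graphml":
        g = nx.read_graphml(path)
        node_ids = tuple(g.nodes())
        index = {node: i for i, node in enumerate(node_ids)}
        edges = []
        nodes = [{"id": node, **attrs} for node, attrs in g.nodes(data=True)]
        for u, v, attrs in g.edges(data=True):
            a, b = index[u], index[v]
            if a > b:
                a, b = b, a
            edges.append(
                EdgeCandidate(a, b, float(attrs["distance"]), bool(attrs["in_mst"]))
            )
    else:
        raise ConfigurationError(f"unknown network format {fmt!r}")

    edges.sort(key=lambda e: (e.distance, e.node_a, e.node_b))
    added = sum(not e.in_mst for e in edges)
    net = StadNetwork(node_ids, tuple(edges), added_edge_count=added)

    labeling = None
    if all("community" in n for n in nodes):
        labels = [0] * len(node_ids)
        for n in nodes:
            labels[index[n["id"]]] = int(n["community"])
        labeling = CommunityLabeling(tuple(labels), resolution=1.0, seed=0)
    layout = None
    if all("x" in n and "y" in n for n in nodes):
        coords = np.zeros((len(node_ids), 2))
        for n in nodes:
            coords[index[n["id"]]] = (float(n["x"]), float(n["y"]))
        layout = LayoutCoordinates(coords, seed=0, iterations=0)
    return net, labeling, layout
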