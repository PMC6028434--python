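"""Directed-network container, edge-list I/O, merging, LCC extraction,
degree-preserving randomization and topology diagnostics.

The container wraps :class:`networkx.DiGraph` and keeps, per directed edge,
a set of provenance tags (``regulatory``, ``kinase``, ``signaling``,
``prior``) plus an optional real-valued score.  Duplicate edges collapse into
a single simple edge whose tag sets merge: the control-centrality theory
downstream assumes a simple digraph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

PROVENANCE_TAGS = ("regulatory", "kinase", "signaling", "prior")


class NetworkParseError(ValueError):
    """Raised for malformed edge-list input."""


class EmptyNetworkError(ValueError):
    """Raised when an operation requires a non-empty network."""


class DirectedNetwork:
    """Simple directed network with per-edge provenance tags.

    Parameters
    ----------
    edges
        Iterable of ``(source, target)`` pairs.
    provenance
        Tag applied to every edge in ``edges``.
    nodes
        Extra isolated nodes to include beyond edge endpoints.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        provenance: str = "regulatory",
        nodes: Iterable[str] = (),
        scores: Mapping[tuple[str, str], float] | None = None,
    ) -> None:
        self._g = nx.DiGraph()
        self._g.add_nodes_from(nodes)
        for u, v in edges:
            self.add_edge(u, v, provenance)
        if scores:
            for (u, v), s in scores.items():
                if self._g.has_edge(u, v):
                    self._g[u][v]["score"] = float(s)

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._g.edges)

    @property
    def N(self) -> int:
        return self._g.number_of_nodes()

    @property
    def M(self) -> int:
        return self._g.number_of_edges()

    def provenance(self, u: str, v: str) -> set[str]:
        return set(self._g[u][v]["provenance"])

    def score(self, u: str, v: str) -> float | None:
        return self._g[u][v].get("score")

    def successors(self, u: str) -> list[str]:
        return list(self._g.successors(u))

    def predecessors(self, u: str) -> list[str]:
        return list(self._g.predecessors(u))

    def in_degree(self, u: str) -> int:
        return self._g.in_degree(u)

    def out_degree(self, u: str) -> int:
        return self._g.out_degree(u)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def add_edge(self, u: str, v: str, provenance: str = "regulatory",
                 score: float | None = None) -> None:
        if self._g.has_edge(u, v):
            self._g[u][v]["provenance"].add(provenance)
        else:
            self._g.add_edge(u, v, provenance={provenance})
        if score is not None:
            self._g[u][v]["score"] = float(score)

    def add_node(self, u: str) -> None:
        self._g.add_node(u)

    def copy(self) -> "DirectedNetwork":
        out = DirectedNetwork()
        out._g = self._g.copy()
        # deep-copy the mutable tag sets
        for u, v in out._g.edges:
            out._g[u][v]["provenance"] = set(out._g[u][v]["provenance"])
        return out

    def to_networkx(self) -> nx.DiGraph:
        return self._g.copy()

    def undirected(self) -> nx.Graph:
        """Undirected projection (reciprocal edges collapse)."""
        return nx.Graph(self._g)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:  # pragma: no cover
        return f"DirectedNetwork(N={self.N}, M={self.M})"


@dataclass
class TopologySummary:
    """Small-world diagnostics against a degree-preserving null ensemble."""

    avg_shortest_path: float
    clustering_coefficient: float
    avg_neighbors: float
    z_aspl: float
    z_clustering: float
    n_random: int
    disconnected: bool = False


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_network(path, provenance: str = "regulatory") -> DirectedNetwork:
    """Read a whitespace/TAB-separated edge list (or 3-column SIF) file.

    Two-column lines are ``source target``; three-column lines are either
    ``source target score`` (numeric third field) or the SIF dialect
    ``source interaction target``.  Four-column lines are this package's
    own output (``source target provenance score``) and round-trip their
    provenance tags.  A leading ``source target ...`` header is skipped.
    """
    net = DirectedNetwork()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if lineno == 1 and fields[:2] == ["source", "target"]:
                continue  # header of our own TSV output
            n_lines += 1
            if len(fields) == 4:
                u, v, prov, score = fields
                for tag in prov.split(","):
                    net.add_edge(u, v, tag)
                if score not in ("", "NA", "None"):
                    net._g[u][v]["score"] = float(score)
            elif len(fields) == 2:
                u, v = fields
                net.add_edge(u, v, provenance)
            elif len(fields) == 3:
                a, b, c = fields
                try:
                    score = float(c)
                except ValueError:
                    # SIF dialect: source interaction target
                    net.add_edge(a, c, provenance)
                else:
                    net.add_edge(a, b, provenance, score=score)
            else:
                raise NetworkParseError(
                    f"{path}: line {lineno}: expected 2-3 fields, "
                    f"got {len(fields)}: {line!r}"
                )
    if n_lines == 0:
        raise EmptyNetworkError(f"{path}: no edges found")
    return net


def write_network(net: DirectedNetwork, path) -> None:
    """Write a TSV edge list with a provenance column (and score if any)."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tprovenance\tscore\n")
        for u, v in sorted(net.edges):
            prov = ",".join(sorted(net.provenance(u, v)))
            score = net.score(u, v)
            fh.write(f"{u}\t{v}\t{prov}\t{'NA' if score is None else score}\n")


# ---------------------------------------------------------------------------
# Merging and components
# ---------------------------------------------------------------------------

def merge_networks(base: DirectedNetwork,
                   extensions: list[DirectedNetwork]) -> DirectedNetwork:
    """Union of node and edge sets; provenance tags union per edge."""
    out = base.copy()
    for ext in extensions:
        for node in ext.nodes:
            out.add_node(node)
        for u, v in ext.edges:
            for tag in ext.provenance(u, v):
                out.add_edge(u, v, tag)
            s = ext.score(u, v)
            if s is not None and out.score(u, v) is None:
                out._g[u][v]["score"] = s
    return out


def largest_connected_component(net: DirectedNetwork) -> DirectedNetwork:
    """Largest weakly connected component; ties broken by the
    lexicographically smallest member node."""
    if net.N == 0:
        raise EmptyNetworkError("cannot take LCC of an empty network")
    comps = list(nx.weakly_connected_components(net._g))
    comps.sort(key=lambda c: (-len(c), min(c)))
    keep = comps[0]
    sub = net._g.subgraph(keep)
    out = DirectedNetwork(nodes=keep)
    for u, v, data in sub.edges(data=True):
        for tag in data["provenance"]:
            out.add_edge(u, v, tag)
        if "score" in data:
            out._g[u][v]["score"] = data["score"]
    return out


# ---------------------------------------------------------------------------
# Degree-preserving randomization
# ---------------------------------------------------------------------------

def degree_preserving_randomize(net: DirectedNetwork,
                                n_swaps_per_edge: int = 10,
                                seed: int = 0) -> DirectedNetwork:
    """Randomize by attempted directed double-edge swaps.

    Each attempt picks two distinct edges (a→b, c→d) and proposes
    (a→d, c→b); the swap is rejected if it would create a self-loop or a
    multi-edge.  In- and out-degrees of every node are preserved exactly.
    Provenance tags do not survive rewiring; rewired edges are tagged
    ``regulatory``.
    """
    if n_swaps_per_edge < 1:
        raise ValueError("n_swaps_per_edge must be >= 1")
    if net.M < 2:
        warnings.warn("network has fewer than 2 edges; returning a copy")
        return net.copy()
    rng = np.random.default_rng(seed)
    edges = sorted(net.edges)
    edge_set = set(edges)
    m = len(edges)
    n_attempts = n_swaps_per_edge * m
    for _ in range(n_attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b:
            continue  # would create a self-loop
        if (a, d) in edge_set or (c, b) in edge_set:
            continue  # would create a multi-edge
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[i] = (a, d)
        edges[j] = (c, b)
    out = DirectedNetwork(edges=edge_set, nodes=net.nodes)
    return out


# ---------------------------------------------------------------------------
# Topology diagnostics
# ---------------------------------------------------------------------------

def _aspl_clustering(g: nx.Graph) -> tuple[float, float, bool]:
    """ASPL over connected pairs of the undirected projection, plus average
    local clustering.  Returns (aspl, clustering, was_disconnected)."""
    disconnected = not nx.is_connected(g) if g.number_of_nodes() else True
    total = 0.0
    n_pairs = 0
    for _source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, dist in lengths.items():
            if dist > 0:
                total += dist
                n_pairs += 1
    aspl = total / n_pairs if n_pairs else float("nan")
    clustering = nx.average_clustering(g) if g.number_of_nodes() else float("nan")
    return aspl, clustering, disconnected


def topology_summary(net: DirectedNetwork, n_random: int = 100,
                     seed: int = 0) -> TopologySummary:
    """Undirected-projection ASPL, clustering and neighbor count with
    z-scores against ``n_random`` degree-preserving randomizations."""
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    g = net.undirected()
    aspl, clustering, disconnected = _aspl_clustering(g)
    avg_neighbors = (2.0 * g.number_of_edges() / g.number_of_nodes()
                     if g.number_of_nodes() else float("nan"))

    rand_aspl = np.empty(n_random)
    rand_clust = np.empty(n_random)
    rng = np.random.default_rng(seed)
    for k in range(n_random):
        rnet = degree_preserving_randomize(net, seed=int(rng.integers(2**31)))
        ra, rc, _ = _aspl_clustering(rnet.undirected())
        rand_aspl[k] = ra
        rand_clust[k] = rc

    def _z(obs: float, samples: np.ndarray) -> float:
        sd = samples.std(ddof=1) if len(samples) > 1 else 0.0
        if sd == 0:
            return float("nan") if obs != samples.mean() else 0.0
        return float((obs - samples.mean()) / sd)

    return TopologySummary(
        avg_shortest_path=aspl,
        clustering_coefficient=clustering,
        avg_neighbors=avg_neighbors,
        z_aspl=_z(aspl, rand_aspl),
        z_clustering=_z(clustering, rand_clust),
        n_random=n_random,
        disconnected=disconnected,
    )
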