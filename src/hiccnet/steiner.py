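"""Node-weighted Steiner tree by the Klein–Ravi greedy approximation.

Terminals (e.g., eQTL genes) are connected into one component of an
undirected interaction network by iteratively merging terminal trees: at
each step the algorithm picks the node *v* and node-cost-shortest paths
from *v* to two or more trees minimizing (cost of v + path costs) per tree
merged.  The approximation guarantee is 2·ln(#terminals).  Edge weights are
ignored; the objective is the total cost of non-terminal nodes added.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import networkx as nx


@dataclass
class SteinerSolution:
    terminals: set[str]
    linkers: set[str]
    edges: set[tuple[str, str]]
    total_node_cost: float
    partial: bool = False
    components: list[set[str]] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return self.terminals | self.linkers


def _node_cost_dijkstra(g: nx.Graph, sources: set[str],
                        costs: dict[str, float],
                        zero_cost: set[str]) -> tuple[dict, dict]:
    """Shortest node-cost distance from a tree (sources, cost 0) to every
    node; the distance to v excludes v's own cost.  Nodes in ``zero_cost``
    (current tree members) are free to traverse.  Ties resolved toward
    lexicographically smaller predecessor chains by heap ordering."""
    # dist[v] = summed cost of nodes strictly between the tree and v
    # (v's own cost and tree-node costs are charged by the caller)
    dist: dict[str, float] = {s: 0.0 for s in sources}
    pred: dict[str, str | None] = {s: None for s in sources}
    heap = [(0.0, s) for s in sorted(sources)]
    heapq.heapify(heap)
    done: set[str] = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        step = 0.0 if u in zero_cost or u in sources else costs.get(u, 1.0)
        for v in sorted(g.neighbors(u)):
            if v in done:
                continue
            nd = d + step
            if v not in dist or nd < dist[v]:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
    return dist, pred


def _path_to(v: str, pred: dict[str, str | None]) -> list[str]:
    path = [v]
    while pred[path[-1]] is not None:
        path.append(pred[path[-1]])
    return path


def klein_ravi_steiner(net: nx.Graph, terminals: set[str],
                       node_costs: dict[str, float] | None = None,
                       ) -> SteinerSolution:
    """Greedy Klein–Ravi node-weighted Steiner tree.

    Terminals absent from the network are dropped with a warning; when the
    terminals span several connected components the solution is a forest
    flagged ``partial``.  Degree-1 non-terminals are pruned, and each
    component is reduced to a spanning tree.  Ties break by node id.
    """
    costs = dict(node_costs or {})
    present = set(t for t in terminals if t in net)
    missing = set(terminals) - present
    if missing:
        warnings.warn(f"terminals not in network, dropped: {sorted(missing)}")
    if len(present) < 1:
        raise ValueError("need at least one terminal present in the network")

    # group terminals by connected component of the full network
    comp_of: dict[str, int] = {}
    comps = list(nx.connected_components(net))
    for k, comp in enumerate(comps):
        for t in present & comp:
            comp_of[t] = k
    groups: dict[int, set[str]] = {}
    for t in present:
        groups.setdefault(comp_of[t], set()).add(t)
    partial = len(groups) > 1

    all_nodes: set[str] = set()
    all_edges: set[tuple[str, str]] = set()
    comp_nodes: list[set[str]] = []
    for k in sorted(groups):
        nodes, edges = _solve_component(net.subgraph(comps[k]), groups[k],
                                        costs)
        comp_nodes.append(nodes)
        all_nodes |= nodes
        all_edges |= edges

    linkers = all_nodes - present
    total_cost = sum(costs.get(v, 1.0) for v in linkers)
    return SteinerSolution(terminals=present, linkers=linkers,
                           edges=all_edges, total_node_cost=total_cost,
                           partial=partial, components=comp_nodes)


def _solve_component(g: nx.Graph, terminals: set[str],
                     costs: dict[str, float]) -> tuple[set, set]:
    """Klein–Ravi greedy on one connected component."""
    # forest of trees, each a set of nodes; initially one per terminal
    trees: list[set[str]] = [{t} for t in sorted(terminals)]
    while len(trees) > 1:
        in_tree: dict[str, int] = {}
        for k, tr in enumerate(trees):
            for u in tr:
                in_tree[u] = k
        # node-cost distance from each tree to every node
        dists, preds = [], []
        for tr in trees:
            d, p = _node_cost_dijkstra(g, tr, costs, zero_cost=tr)
            dists.append(d)
            preds.append(p)
        best = None  # (ratio, node, [tree indices])
        for v in sorted(g.nodes):
            v_cost = 0.0 if v in in_tree else costs.get(v, 1.0)
            reach = sorted(
                ((dists[k][v], k) for k in range(len(trees)) if v in dists[k]),
                key=lambda x: (x[0], x[1]))
            if len(reach) < 2:
                continue
            acc = v_cost
            for j in range(2):
                acc += reach[j][0]
            ratio = acc / 2.0
            cand = (ratio, v, [reach[0][1], reach[1][1]])
            for j in range(2, len(reach)):
                acc += reach[j][0]
                r = acc / (j + 1)
                if r < cand[0] - 1e-12:
                    cand = (r, v, [k for _, k in reach[:j + 1]])
            if best is None or cand[0] < best[0] - 1e-12 or (
                    abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1]):
                best = cand
        if best is None:  # pragma: no cover - component is connected
            raise RuntimeError("greedy step found no merging node")
        _, v, tree_idx = best
        merged: set[str] = {v}
        for k in tree_idx:
            merged |= trees[k]
            merged |= set(_path_to(v, preds[k]))
        trees = [tr for k, tr in enumerate(trees) if k not in set(tree_idx)]
        trees.append(merged)

    nodes = set(trees[0])
    sub = g.subgraph(nodes).copy()
    tree = nx.minimum_spanning_tree(sub) if sub.number_of_edges() else sub
    # prune degree-1 non-terminals left over by the greedy merges
    changed = True
    while changed:
        changed = False
        for v in sorted(tree.nodes):
            if v not in terminals and tree.degree(v) <= 1:
                tree.remove_node(v)
                changed = True
    edges = {tuple(sorted(e)) for e in tree.edges}
    return set(tree.nodes), edges


def brute_force_steiner(net: nx.Graph, terminals: set[str],
                        node_costs: dict[str, float] | None = None,
                        ) -> tuple[set[str], float]:
    """Exact minimum-node-cost Steiner set by subset enumeration (small
    instances only).  Returns (linker set, total linker cost)."""
    from itertools import combinations

    costs = node_costs or {}
    terminals = set(terminals)
    if len(terminals) < 2:
        raise ValueError("need at least two terminals")
    others = sorted(set(net.nodes) - terminals)
    if len(others) > 20:
        raise ValueError("instance too large for brute force")
    best: tuple[set[str], float] | None = None
    for r in range(len(others) + 1):
        for combo in combinations(others, r):
            sub = net.subgraph(terminals | set(combo))
            if nx.is_connected(sub):
                cost = sum(costs.get(v, 1.0) for v in combo)
                if best is None or cost < best[1]:
                    best = (set(combo), cost)
        if best is not None and not costs:
            break  # unit costs: first feasible cardinality is optimal
    if best is None:
        raise ValueError("terminals cannot be connected")
    return best
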