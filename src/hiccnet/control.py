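"""Control centrality of nodes in a directed network.

The control centrality of node *i*, ``C_c(i)``, is the generic dimension of
the controllable subspace of the structured linear system ``x' = A x + b u``
where ``A`` has the network's adjacency structure with generic (free) weights
and ``b`` is the indicator of node *i*.  Equivalently (Hosoe's theorem) it is
the largest number of edges over all stem-cycle disjoint subgraphs — a
vertex-disjoint union of one directed path (stem) starting at the input and
directed cycles, all lying in the set reachable from *i* — counting the edge
from the external input to *i* itself.  ``C_c`` is an integer in ``[1, N]``.

Three routes are provided:

``control_centrality``
    The production algorithm: rank of the Krylov matrix
    ``[b, Ab, A²b, ...]`` with weights drawn uniformly from the prime field
    GF(p), p = 2³¹ − 1, computed by incremental Gaussian elimination with
    early stop once the Krylov space becomes invariant.  By the
    Schwartz–Zippel lemma a random evaluation attains the generic rank
    except with probability ≲ N²/p per trial; the maximum over ``n_trials``
    independent weight draws makes the failure probability negligible.

``krylov_rank_oracle``
    A deliberately naive cross-check: materialize the full Krylov matrix on
    the whole node set and row-reduce it, no restriction to the reachable
    set, no early stop.

``stem_cycle_cc``
    Exact combinatorial brute force for small graphs (bitmask dynamic
    programs over simple paths from *i* and disjoint-cycle covers of the
    reachable set).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_core import DirectedNetwork

_P = 2**31 - 1  # Mersenne prime field modulus


@dataclass
class CcResult:
    """Per-node control centrality over one network."""

    cc: dict[str, int]
    normalized_cc: dict[str, float]
    N: int

    @classmethod
    def from_cc(cls, cc: dict[str, int], N: int) -> "CcResult":
        return cls(cc=cc, normalized_cc={k: v / N for k, v in cc.items()}, N=N)


# ---------------------------------------------------------------------------
# GF(p) linear algebra helpers
# ---------------------------------------------------------------------------

def _matvec_mod(a_hi: np.ndarray, a_lo: np.ndarray, v: np.ndarray) -> np.ndarray:
    # A @ v mod p with A split as A = a_hi * 2^16 + a_lo to keep int64
    # accumulation overflow-free (entries < p < 2^31, dims <= ~4000).
    hi = (a_hi @ v) % _P
    lo = (a_lo @ v) % _P
    return ((hi << 16) + lo) % _P


def _reduce(v: np.ndarray, basis: list[tuple[int, np.ndarray]]) -> np.ndarray:
    """Reduce v against a row-echelon basis (pivot entries normalized to 1)."""
    for piv, w in basis:
        c = int(v[piv])
        if c:
            v = (v - c * w) % _P
    return v


def _krylov_rank(indices: dict[str, int], edge_list: list[tuple[int, int]],
                 source_idx: int, rng: np.random.Generator,
                 max_rank: int) -> int:
    """Rank of the Krylov sequence from e_source with one random weight draw."""
    n = len(indices)
    a = np.zeros((n, n), dtype=np.int64)
    if edge_list:
        src = np.array([e[0] for e in edge_list])
        dst = np.array([e[1] for e in edge_list])
        a[dst, src] = rng.integers(1, _P, size=len(edge_list))
    a_hi, a_lo = a >> 16, a & 0xFFFF

    v = np.zeros(n, dtype=np.int64)
    v[source_idx] = 1
    basis: list[tuple[int, np.ndarray]] = []
    rank = 0
    for _ in range(max_rank):
        r = _reduce(v.copy(), basis)
        nz = np.nonzero(r)[0]
        if nz.size == 0:
            break  # Krylov space is invariant: saturated
        piv = int(nz[0])
        inv = pow(int(r[piv]), _P - 2, _P)
        basis.append((piv, (r * inv) % _P))
        rank += 1
        v = _matvec_mod(a_hi, a_lo, v)
    return rank


def _reachable(net: DirectedNetwork, node: str) -> set[str]:
    g = net.to_networkx()
    return nx.descendants(g, node) | {node}


def control_centrality(net: DirectedNetwork, node: str,
                       n_trials: int = 3, seed: int = 0) -> int:
    """Control centrality of ``node``: generic Krylov rank over GF(2³¹−1).

    The computation is restricted to the set reachable from ``node`` (states
    outside it are never excited, so they contribute no rank).
    """
    if node not in net.nodes:
        raise KeyError(f"node {node!r} not in network")
    reach = sorted(_reachable(net, node))
    indices = {u: k for k, u in enumerate(reach)}
    edge_list = [(indices[u], indices[v]) for u, v in net.edges
                 if u in indices and v in indices]
    rng = np.random.default_rng(seed)
    best = 0
    for _ in range(n_trials):
        best = max(best, _krylov_rank(indices, edge_list, indices[node],
                                      rng, max_rank=len(reach)))
        if best == len(reach):
            break  # saturated the reachability upper bound
    return best


def control_centrality_all(net: DirectedNetwork, n_trials: int = 3,
                           seed: int = 0) -> CcResult:
    """Control centrality of every node."""
    cc = {}
    for k, node in enumerate(sorted(net.nodes)):
        cc[node] = control_centrality(net, node, n_trials=n_trials,
                                      seed=seed + k)
    return CcResult.from_cc(cc, net.N)


# ---------------------------------------------------------------------------
# Independent oracle 1: full dense Krylov matrix over GF(p)
# ---------------------------------------------------------------------------

def krylov_rank_oracle(net: DirectedNetwork, node: str,
                       n_trials: int = 3, seed: int = 0) -> int:
    """Rank of the full controllability matrix ``[b, Ab, …, A^{N-1} b]``
    over GF(p), maximized over independent random weight draws.

    Unlike :func:`control_centrality` this builds the whole matrix on the
    whole node set and row-reduces it wholesale — an intentionally separate
    code path for cross-validation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if node not in net.nodes:
        raise KeyError(f"node {node!r} not in network")
    order = sorted(net.nodes)
    idx = {u: k for k, u in enumerate(order)}
    n = len(order)
    rng = np.random.default_rng(seed)
    best = 0
    for _ in range(n_trials):
        a = np.zeros((n, n), dtype=np.int64)
        for u, v in net.edges:
            a[idx[v], idx[u]] = rng.integers(1, _P)
        a_hi, a_lo = a >> 16, a & 0xFFFF
        cols = np.zeros((n, n), dtype=np.int64)
        v = np.zeros(n, dtype=np.int64)
        v[idx[node]] = 1
        for k in range(n):
            cols[:, k] = v
            v = _matvec_mod(a_hi, a_lo, v)
        best = max(best, _rank_mod_p(cols))
    return best


def _rank_mod_p(m: np.ndarray) -> int:
    """Gaussian-elimination rank of an integer matrix over GF(p)."""
    m = m % _P
    n_rows, n_cols = m.shape
    rank = 0
    row = 0
    for col in range(n_cols):
        piv = None
        for r in range(row, n_rows):
            if m[r, col]:
                piv = r
                break
        if piv is None:
            continue
        m[[row, piv]] = m[[piv, row]]
        inv = pow(int(m[row, col]), _P - 2, _P)
        m[row] = (m[row] * inv) % _P
        mask = np.nonzero(m[:, col])[0]
        mask = mask[mask != row]
        if mask.size:
            m[mask] = (m[mask] - np.outer(m[mask, col], m[row])) % _P
        row += 1
        rank += 1
        if row == n_rows:
            break
    return rank


# ---------------------------------------------------------------------------
# Independent oracle 2: brute-force stem-cycle enumeration (small graphs)
# ---------------------------------------------------------------------------

def stem_cycle_cc(net: DirectedNetwork, node: str, max_n: int = 18) -> int:
    """Exact ``C_c`` by enumerating stem-cycle disjoint subgraphs.

    ``C_c(i)`` = max over (simple path from *i*) ∪ (vertex-disjoint cycles)
    within the reachable set of the number of covered nodes (path nodes count
    the input edge; each cycle node contributes its in-cycle edge).
    Exponential in the reachable-set size; guarded by ``max_n``.
    """
    if node not in net.nodes:
        raise KeyError(f"node {node!r} not in network")
    reach = sorted(_reachable(net, node))
    n = len(reach)
    if n > max_n:
        raise ValueError(f"reachable set of size {n} exceeds max_n={max_n}")
    idx = {u: k for k, u in enumerate(reach)}
    succ = [0] * n
    for u, v in net.edges:
        if u in idx and v in idx:
            succ[idx[u]] |= 1 << idx[v]

    # all masks of simple paths starting at node (any end point)
    start = idx[node]
    path_masks: set[int] = set()
    seen: set[tuple[int, int]] = set()
    stack = [(start, 1 << start)]
    while stack:
        end, mask = stack.pop()
        if (end, mask) in seen:
            continue
        seen.add((end, mask))
        path_masks.add(mask)
        nxt = succ[end] & ~mask
        while nxt:
            b = nxt & -nxt
            stack.append((b.bit_length() - 1, mask | b))
            nxt ^= b

    # all simple-cycle masks, grouped by their minimum member node
    cycles_by_min: list[list[int]] = [[] for _ in range(n)]
    for s in range(n):
        # DFS over nodes >= s, cycle closes by an edge back to s
        stack2 = [(s, 1 << s)]
        seen2: set[tuple[int, int]] = set()
        while stack2:
            cur, mask = stack2.pop()
            if (cur, mask) in seen2:
                continue
            seen2.add((cur, mask))
            if succ[cur] >> s & 1 and mask.bit_count() >= 2:
                cycles_by_min[s].append(mask)
            nxt = succ[cur] & ~mask & ~((1 << (s + 1)) - 1)
            while nxt:
                b = nxt & -nxt
                stack2.append((b.bit_length() - 1, mask | b))
                nxt ^= b
    cycles_by_min = [sorted(set(c)) for c in cycles_by_min]

    # g[S] = max nodes coverable by vertex-disjoint cycles within S
    g = [0] * (1 << n)
    for s_mask in range(1, 1 << n):
        low = (s_mask & -s_mask).bit_length() - 1
        best = g[s_mask & (s_mask - 1)]  # lowest node left uncovered
        for c in cycles_by_min[low]:
            if c & s_mask == c:
                cand = c.bit_count() + g[s_mask ^ c]
                if cand > best:
                    best = cand
        g[s_mask] = best

    full = (1 << n) - 1
    return max(pm.bit_count() + g[full ^ pm] for pm in path_masks)
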