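"""Clustering the weighted orthology graph into orthologous groups.

Two algorithms are provided:

* Markov clustering (MCL): alternating expansion (squaring the
  column-stochastic flow matrix) and inflation (elementwise power followed by
  column renormalization and pruning).  Because flow never crosses connected
  components, each component is clustered independently, which bounds the
  dense working set by the largest component rather than the whole graph.

* Affinity propagation (APC): message passing on the sparse similarity
  graph.  Responsibilities ``R(i,k)`` say how well node k would serve as the
  exemplar of node i; availabilities ``A(i,k)`` say how appropriate it is for
  i to choose k.  Messages exist only on graph edges plus the diagonal, so
  one sweep costs O(E); the node k maximizing ``A(i,k) + R(i,k)`` is node i's
  exemplar and groups are the nodes sharing an exemplar.
"""

from __future__ import annotations

import logging
import statistics
from collections import defaultdict, deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, TextIO, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologyGraph",
    "OrthoGroup",
    "connected_components",
    "mcl",
    "apc_iterate",
    "apc_cluster",
    "write_groups",
    "format_groups",
]

NEG_INF = float("-inf")


@dataclass
class OrthologyGraph:
    """Undirected weighted graph of orthology relations.

    Self-edges are dropped at load; duplicate edges collapse to the maximum
    weight; weights must be finite and positive.
    """

    adjacency: Dict[str, Dict[str, float]] = field(default_factory=dict)

    @property
    def nodes(self) -> List[str]:
        return sorted(self.adjacency)

    def edges(self) -> Iterable[Tuple[str, str, float]]:
        for a in sorted(self.adjacency):
            for b, w in sorted(self.adjacency[a].items()):
                if a < b:
                    yield a, b, w

    def n_edges(self) -> int:
        return sum(1 for _ in self.edges())

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            return
        if not (weight > 0.0 and np.isfinite(weight)):
            raise ValueError(f"edge {a}-{b}: weight must be finite and > 0")
        for x, y in ((a, b), (b, a)):
            cur = self.adjacency.setdefault(x, {}).get(y)
            if cur is None or weight > cur:
                self.adjacency[x][y] = weight

    def add_node(self, a: str) -> None:
        self.adjacency.setdefault(a, {})

    @staticmethod
    def from_edges(edges: Iterable[Tuple[str, str, float]]) -> "OrthologyGraph":
        g = OrthologyGraph()
        for a, b, w in edges:
            g.add_edge(a, b, w)
        return g

    @staticmethod
    def from_relations(relations) -> "OrthologyGraph":
        """Build from :class:`~orthoswift.inference.OrthologyRelation` rows."""
        g = OrthologyGraph()
        for r in relations:
            g.add_edge(r.gene_a, r.gene_b, r.weight if r.weight > 0 else r.bit_score)
        return g


@dataclass(frozen=True)
class OrthoGroup:
    """A named set of genes — the pipeline's terminal product."""

    group_id: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.group_id}: empty member set")


def connected_components(graph: OrthologyGraph) -> List[OrthologyGraph]:
    """Maximal connected subgraphs, ordered by their smallest member id."""
    seen: Set[str] = set()
    components: List[OrthologyGraph] = []
    for start in graph.nodes:
        if start in seen:
            continue
        queue = deque([start])
        seen.add(start)
        members: List[str] = []
        while queue:
            node = queue.popleft()
            members.append(node)
            for nbr in graph.adjacency[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    queue.append(nbr)
        sub = OrthologyGraph()
        mset = set(members)
        for node in members:
            sub.add_node(node)
            for nbr, w in graph.adjacency[node].items():
                if nbr in mset:
                    sub.add_edge(node, nbr, w)
        components.append(sub)
    components.sort(key=lambda g: min(g.adjacency))
    return components


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def _mcl_component(
    nodes: Sequence[str],
    adjacency: Dict[str, Dict[str, float]],
    inflation: float,
    max_iter: int,
    prune_below: float,
    tol: float,
) -> List[Set[str]]:
    n = len(nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    M = np.zeros((n, n), dtype=np.float64)
    for a in nodes:
        for b, w in adjacency[a].items():
            M[idx[b], idx[a]] = w
    # self-loops at the node's strongest incident weight stabilize the flow
    for a in nodes:
        incident = adjacency[a].values()
        M[idx[a], idx[a]] = max(incident) if incident else 1.0
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M                      # expansion
        np.power(M, inflation, out=M)  # inflation
        M /= M.sum(axis=0, keepdims=True)
        M[M < prune_below] = 0.0
        M /= M.sum(axis=0, keepdims=True)
        if prev.shape == M.shape and np.max(np.abs(M - prev)) < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "MCL did not converge in %d iterations on a %d-node component; "
            "returning the current partition", max_iter, n
        )

    # attractors are rows with mass on the diagonal; each attractor row's
    # support is one cluster, overlapping clusters merge
    tau = 1e-6
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    attractors = [i for i in range(n) if M[i, i] > tau]
    assigned = np.zeros(n, dtype=bool)
    for i in attractors:
        support = np.nonzero(M[i] > tau)[0]
        for j in support:
            union(i, j)
            assigned[j] = True
    # orphans (numerically possible after pruning) follow their largest flow
    for j in range(n):
        if not assigned[j]:
            if attractors:
                best = max(attractors, key=lambda i: (M[i, j], -i))
                union(best, j)
            assigned[j] = True

    clusters: Dict[int, Set[str]] = defaultdict(set)
    for j in range(n):
        clusters[find(j)].add(nodes[j])
    return [clusters[r] for r in sorted(clusters)]


def mcl(
    graph: OrthologyGraph,
    inflation: float = 1.5,
    max_iter: int = 100,
    prune_below: float = 1e-5,
    tol: float = 1e-6,
) -> List[OrthoGroup]:
    """Markov clustering, run per connected component.

    ``inflation`` (> 1) controls granularity; 1.5 is the pipeline default.
    Entries below ``prune_below`` are zeroed (then columns renormalized) to
    keep the flow matrix sparse in spirit.
    """
    if not inflation > 1:
        raise ValueError("inflation must be > 1")
    member_sets: List[Set[str]] = []
    for component in connected_components(graph):
        nodes = component.nodes
        member_sets.extend(
            _mcl_component(
                nodes, component.adjacency, inflation, max_iter, prune_below, tol
            )
        )
    return _name_groups(member_sets)


# ---------------------------------------------------------------------------
# Affinity propagation
# ---------------------------------------------------------------------------

@dataclass
class SparseMessages:
    """Responsibilities/availabilities/similarities on graph edges + diagonal.

    Directed candidate pairs are stored in flat arrays sorted by (i, k); the
    same arrays back both message matrices, so per-iteration work is O(E).
    """

    nodes: List[str]
    ii: np.ndarray          # candidate source index per entry
    kk: np.ndarray          # candidate exemplar index per entry
    S: np.ndarray
    R: np.ndarray
    A: np.ndarray
    row_start: np.ndarray   # entries for node i: row_start[i]:row_start[i+1]
    diag_pos: np.ndarray    # entry index of (i, i)


def _build_messages(
    graph: OrthologyGraph, preference: Dict[str, float]
) -> SparseMessages:
    nodes = graph.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    entries: List[Tuple[int, int, float]] = []
    for a in nodes:
        i = idx[a]
        entries.append((i, i, preference[a]))
        for b, w in graph.adjacency[a].items():
            entries.append((i, idx[b], w))
    entries.sort()
    ii = np.array([e[0] for e in entries], dtype=np.int64)
    kk = np.array([e[1] for e in entries], dtype=np.int64)
    S = np.array([e[2] for e in entries], dtype=np.float64)
    n = len(nodes)
    row_start = np.zeros(n + 1, dtype=np.int64)
    np.add.at(row_start, ii + 1, 1)
    row_start = np.cumsum(row_start)
    diag_pos = np.zeros(n, dtype=np.int64)
    for pos, (i, k, _) in enumerate(entries):
        if i == k:
            diag_pos[i] = pos
    return SparseMessages(
        nodes=nodes,
        ii=ii,
        kk=kk,
        S=S,
        R=np.zeros_like(S),
        A=np.zeros_like(S),
        row_start=row_start,
        diag_pos=diag_pos,
    )


def _current_exemplars(msg: SparseMessages) -> np.ndarray:
    """argmax_k of A + R per node; ties break to the smallest node id.

    Candidates are sorted by (i, k), so the first maximum is the smallest k.
    """
    n = len(msg.nodes)
    ex = np.empty(n, dtype=np.int64)
    crit = msg.A + msg.R
    for i in range(n):
        lo, hi = msg.row_start[i], msg.row_start[i + 1]
        ex[i] = msg.kk[lo + int(np.argmax(crit[lo:hi]))]
    return ex


def apc_iterate(
    msg: SparseMessages,
    damping: float = 0.5,
    max_iter: int = 200,
    convergence_window: int = 15,
) -> Tuple[SparseMessages, Dict[str, str]]:
    """Run damped message passing until exemplar choices are stable.

    One iteration updates every responsibility as
    ``R(i,k) <- (1-d)*(S(i,k) - max_{k' != k}(A(i,k') + S(i,k'))) + d*R(i,k)``
    and every availability as
    ``A(i,k) <- min(0, R(k,k) + sum_{i' not in {i,k}} max(0, R(i',k)))`` for
    ``i != k`` (the sum alone on the diagonal), likewise damped.  Iteration
    stops when the exemplar map is unchanged for ``convergence_window``
    consecutive sweeps, or at ``max_iter`` with a warning.
    """
    if not 0.0 <= damping < 1.0:
        raise ValueError("damping must be in [0, 1)")
    n = len(msg.nodes)
    stable = 0
    prev_ex: Optional[np.ndarray] = None
    converged = False

    for _ in range(max_iter):
        # responsibilities
        AS = msg.A + msg.S
        new_R = np.empty_like(msg.R)
        for i in range(n):
            lo, hi = msg.row_start[i], msg.row_start[i + 1]
            seg = AS[lo:hi]
            top = int(np.argmax(seg))
            max1 = seg[top]
            seg2 = np.delete(seg, top)
            max2 = seg2.max() if seg2.size else NEG_INF
            new_R[lo:hi] = msg.S[lo:hi] - max1
            new_R[lo + top] = msg.S[lo + top] - max2
        msg.R = (1.0 - damping) * new_R + damping * msg.R

        # availabilities
        rp = np.maximum(msg.R, 0.0)
        rp[msg.diag_pos] = 0.0          # R(k,k) enters separately
        col_sum = np.zeros(n, dtype=np.float64)
        np.add.at(col_sum, msg.kk, rp)
        r_diag = msg.R[msg.diag_pos]
        new_A = np.minimum(
            0.0, r_diag[msg.kk] + col_sum[msg.kk] - rp
        )
        new_A[msg.diag_pos] = col_sum
        msg.A = (1.0 - damping) * new_A + damping * msg.A

        ex = _current_exemplars(msg)
        if prev_ex is not None and np.array_equal(ex, prev_ex):
            stable += 1
            if stable >= convergence_window:
                converged = True
                break
        else:
            stable = 0
        prev_ex = ex

    if not converged:
        logger.warning(
            "affinity propagation did not stabilize within %d iterations "
            "(%d nodes); using the current exemplar map", max_iter, n
        )
    ex = _current_exemplars(msg)
    exemplar_map = {msg.nodes[i]: msg.nodes[ex[i]] for i in range(n)}
    return msg, exemplar_map


def apc_cluster(
    graph: OrthologyGraph,
    preference="median",
    damping: float = 0.5,
    max_iter: int = 200,
    convergence_window: int = 15,
) -> List[OrthoGroup]:
    """Affinity-propagation clustering of the orthology graph.

    Similarities are the edge weights; diagonal preferences are the median
    edge weight by default (or a fixed float / per-node mapping).  Nodes
    sharing an exemplar form a group; nodes whose chosen exemplar is not
    self-consistent are reassigned to their most similar self-exemplar, and
    isolated nodes become singletons.
    """
    nodes = graph.nodes
    if not nodes:
        return []
    weights = [w for _, _, w in graph.edges()]
    if preference == "median":
        pref_value = statistics.median(weights) if weights else 1.0
        pref = {a: pref_value for a in nodes}
    elif isinstance(preference, dict):
        pref = {a: float(preference[a]) for a in nodes}
    else:
        pref = {a: float(preference) for a in nodes}

    msg = _build_messages(graph, pref)
    msg, exemplar_map = apc_iterate(
        msg, damping=damping, max_iter=max_iter,
        convergence_window=convergence_window,
    )

    centers = {a for a, e in exemplar_map.items() if a == e}
    assignment: Dict[str, str] = {}
    for a in nodes:
        e = exemplar_map[a]
        if e in centers:
            assignment[a] = e
            continue
        # chosen exemplar is itself ruled by another: fall back to the most
        # similar reachable center (ties to the smallest id), else singleton
        candidates = [
            (w, b) for b, w in graph.adjacency[a].items() if b in centers
        ]
        if a in centers:
            assignment[a] = a
        elif candidates:
            best_w = max(w for w, _ in candidates)
            assignment[a] = min(b for w, b in candidates if w == best_w)
        else:
            assignment[a] = a

    clusters: Dict[str, Set[str]] = defaultdict(set)
    for a, e in assignment.items():
        clusters[e].add(a)
    return _name_groups([clusters[e] for e in sorted(clusters)])


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def _name_groups(member_sets: List[Set[str]]) -> List[OrthoGroup]:
    ordered = sorted(member_sets, key=lambda s: (-len(s), min(s)))
    return [
        OrthoGroup(group_id=f"OG{i:07d}", members=frozenset(s))
        for i, s in enumerate(ordered, start=1)
    ]


def format_groups(groups: Sequence[OrthoGroup]) -> str:
    """OrthoMCL-style group lines: ``<id>: member1 member2 ...``."""
    lines = []
    ordered = sorted(groups, key=lambda g: (-len(g.members), min(g.members)))
    for g in ordered:
        lines.append(f"{g.group_id}: " + " ".join(sorted(g.members)))
    return "".join(line + "\n" for line in lines)


def write_groups(groups: Sequence[OrthoGroup], sink: TextIO) -> None:
    """Write groups deterministically: sorted members, size-then-id order."""
    sink.write(format_groups(groups))
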