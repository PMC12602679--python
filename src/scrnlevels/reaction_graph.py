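"""The species digraph of a unit-transfer network and its structure.

Every unit-transfer reaction vector moves one molecule from species ``i`` to
species ``j`` and therefore defines a directed edge ``(i, j)``. Components,
bipartiteness and cycles of this graph decide everything about which level
functions exist:

* a level function exists iff every multi-species component is bipartite;
* each weakly directed cycle, encoded as a signed incidence vector over the
  reaction vectors, lies in the kernel of the stoichiometric matrix and
  obstructs any edge sign pattern not orthogonal to it.

Antiparallel edge pairs (a reversible conversion) are kept as two distinct
edges for cycle vectors, but count as a single undirected edge for
connectivity and two-coloring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NonBipartiteError, UnitTransferError
from .network_model import (
    ReactionNetwork,
    check_unit_transfer,
    reaction_vector_set,
    stoichiometric_matrix,
)
from . import _rational

__all__ = [
    "SpeciesGraph",
    "build_graph",
    "weakly_connected_components",
    "is_bipartite",
    "deficiency",
    "cycle_basis_vectors",
    "partition_obstructed",
]


@dataclass
class SpeciesGraph:
    """Directed species graph: one edge per distinct reaction vector."""

    vertex_count: int
    edges: list[tuple[int, int]]          # edge k = (i, j): vector k moves i -> j
    reverse_pair: dict[int, int]          # k -> k' when vector k' = -vector k
    component_of: np.ndarray              # vertex -> component id (0-based)
    components: list[list[int]]           # vertices per component, sorted

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def component_edges(self, q: int) -> list[int]:
        """Edge indices whose endpoints lie in component q."""
        return [k for k, (i, _) in enumerate(self.edges)
                if self.component_of[i] == q]

    def undirected_adjacency(self) -> list[dict[int, list[int]]]:
        """Neighbor -> edge-index lists of the underlying undirected multigraph."""
        adj: list[dict[int, list[int]]] = [dict() for _ in range(self.vertex_count)]
        for k, (i, j) in enumerate(self.edges):
            adj[i].setdefault(j, []).append(k)
            adj[j].setdefault(i, []).append(k)
        return adj


def build_graph(net: ReactionNetwork) -> SpeciesGraph:
    """Build the species digraph; raises UnitTransferError if any reaction
    vector is not of unit-transfer form."""
    ok, violators = check_unit_transfer(net)
    if not ok:
        raise UnitTransferError(violators)
    vs = reaction_vector_set(net)
    edges = []
    for v in vs.vectors:
        i = int(np.flatnonzero(v == -1)[0])
        j = int(np.flatnonzero(v == 1)[0])
        edges.append((i, j))
    reverse_pair: dict[int, int] = {}
    key_to_idx = {tuple(int(x) for x in v): k for k, v in enumerate(vs.vectors)}
    for k, v in enumerate(vs.vectors):
        neg = tuple(int(-x) for x in v)
        if neg in key_to_idx:
            reverse_pair[k] = key_to_idx[neg]

    d = net.n_species
    component_of = np.full(d, -1, dtype=int)
    comp = 0
    adj = [set() for _ in range(d)]
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    for root in range(d):
        if component_of[root] != -1:
            continue
        stack = [root]
        component_of[root] = comp
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if component_of[w] == -1:
                    component_of[w] = comp
                    stack.append(w)
        comp += 1
    components = [sorted(np.flatnonzero(component_of == q).tolist())
                  for q in range(comp)]
    return SpeciesGraph(
        vertex_count=d,
        edges=edges,
        reverse_pair=reverse_pair,
        component_of=component_of,
        components=components,
    )


def weakly_connected_components(g: SpeciesGraph) -> tuple[list[list[int]], int]:
    """Vertex partition into weakly connected components and their count."""
    return g.components, g.n_components


def is_bipartite(g: SpeciesGraph, component: int | None = None
                 ) -> tuple[bool, list[int], list[int]]:
    """Two-color the underlying undirected graph.

    Deterministic: BFS from the lowest-index vertex of each (or the given)
    component, root colored into class B. Returns (flag, B, C); on failure
    the partial coloring is returned with flag False.
    """
    targets = range(g.n_components) if component is None else [component]
    color = {}
    ok = True
    for q in targets:
        verts = g.components[q]
        root = verts[0]
        color[root] = 0
        queue = [root]
        adj = g.undirected_adjacency()
        while queue:
            v = queue.pop(0)
            for w in adj[v]:
                if w == v:
                    continue
                if w not in color:
                    color[w] = 1 - color[v]
                    queue.append(w)
                elif color[w] == color[v]:
                    ok = False
    b = sorted(v for v, c in color.items() if c == 0)
    c = sorted(v for v, c_ in color.items() if c_ == 1)
    return ok, b, c


def deficiency(net: ReactionNetwork, g: SpeciesGraph) -> int:
    """d - (weakly connected components) - rank(S); zero for every
    unit-transfer network."""
    s = stoichiometric_matrix(net)
    return net.n_species - g.n_components - _rational.rank(s)


def cycle_basis_vectors(g: SpeciesGraph) -> list[np.ndarray]:
    """A cycle basis of the undirected multigraph as signed vectors over edges.

    Each basis element is a length-n vector with entries in {-1, 0, +1}:
    +1 if the edge is traversed along its direction when walking the cycle,
    -1 against it. An antiparallel pair contributes the 2-cycle with both
    entries +1. Every returned vector lies in ker(S).
    """
    n = g.n_edges
    # spanning forest over the simple graph (one representative edge per
    # unordered vertex pair: the lowest edge index)
    rep: dict[frozenset, int] = {}
    for k, (i, j) in enumerate(g.edges):
        key = frozenset((i, j))
        if key not in rep or k < rep[key]:
            rep[key] = k
    parent_edge: dict[int, tuple[int, int, int]] = {}  # vertex -> (parent, edge k, dir)
    in_tree: set[int] = set()
    simple_adj: list[list[tuple[int, int]]] = [[] for _ in range(g.vertex_count)]
    for key, k in rep.items():
        i, j = g.edges[k]
        simple_adj[i].append((j, k))
        simple_adj[j].append((i, k))
    visited = set()
    for root in range(g.vertex_count):
        if root in visited:
            continue
        visited.add(root)
        queue = [root]
        while queue:
            v = queue.pop(0)
            for w, k in sorted(simple_adj[v]):
                if w not in visited:
                    visited.add(w)
                    i, j = g.edges[k]
                    # dir = +1 if walking v -> w follows the edge direction
                    parent_edge[w] = (v, k, +1 if (i, j) == (v, w) else -1)
                    in_tree.add(k)
                    queue.append(w)

    def path_to_root(v: int) -> list[tuple[int, int]]:
        """List of (edge, sign) walking v up to its root, signed along the walk."""
        out = []
        while v in parent_edge:
            p, k, direction = parent_edge[v]
            # walking v -> p is against the stored v->w=child direction
            out.append((k, -direction))
            v = p
        return out

    basis: list[np.ndarray] = []
    non_tree = [k for k in range(n) if k not in in_tree]
    for k in sorted(non_tree):
        i, j = g.edges[k]
        theta = np.zeros(n, dtype=int)
        theta[k] = 1  # traverse k along its direction i -> j
        # close the cycle: walk back j -> i through the tree
        pi = {e: s for e, s in path_to_root(i)}
        pj = {e: s for e, s in path_to_root(j)}
        # cancel shared suffix to the common ancestor
        for e in set(pi) & set(pj):
            del pi[e], pj[e]
        for e, s in pj.items():
            theta[e] += s
        for e, s in pi.items():
            theta[e] -= s
        basis.append(theta)
    return basis


def partition_obstructed(w, cycles: list[np.ndarray]) -> bool:
    """True iff some cycle vector is not orthogonal to the sign vector ``w``.

    A non-orthogonal cycle certifies that the sign-pattern system has no
    solution; for unit-transfer networks (cycle space = ker S) the test is
    also complete.
    """
    w = np.asarray(w)
    return any(int(w @ theta) != 0 for theta in cycles)
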