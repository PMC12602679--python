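"""Enumeration of coclique level functions.

A coclique level function of the projected chain is an integer-linear
``L(x) = b^T x`` whose value changes by exactly +1 or -1 on every reaction
vector. Its level sets partition the projected state space into cocliques
(no direct transition stays within a level), which is what later turns the
level process into a comparable birth-death chain.

Each candidate L corresponds to a signing of the species-graph edges: edges
on which L increases versus edges on which it decreases. Given a signing,
``b`` is the unique exact solution (if any) of the overdetermined integer
system ``S_proj^T b = w``; L and -L give the same level structure, so one
sign is fixed by convention. Reversible pairs must carry opposite signs and
are collapsed to a single free sign, leaving ``2^(|reduced| - 1)`` candidate
signings per weakly connected component. Components compose additively: the
level functions of a multi-component network are all signed sums of
per-component level functions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from . import _rational
from .errors import InternalConsistencyError, NonBipartiteError
from .network_model import ReactionNetwork, stoichiometric_matrix
from .reaction_graph import (
    SpeciesGraph,
    build_graph,
    cycle_basis_vectors,
    is_bipartite,
    partition_obstructed,
)

__all__ = [
    "Projection",
    "EdgePartition",
    "CocliqueLevelFunction",
    "reduced_vector_set",
    "solve_partition_system",
    "enumerate_component",
    "bipartite_level_function",
    "compose_components",
    "enumerate_level_functions",
]


@dataclass
class Projection:
    """Mapping from full species coordinates to projected coordinates.

    Per weakly connected component the conserved total fixes the copy number
    of that component's last species (highest declared index), which is
    dropped; singleton components are dropped entirely. ``kept`` lists the
    surviving species indices in component order, which is the coordinate
    order of every projected vector and of the coefficient vector ``b``.
    """

    net: ReactionNetwork
    graph: SpeciesGraph
    kept: list[int]
    dropped: list[int]                 # one per multi-vertex component
    block_of: dict[int, slice]         # component id -> slice into kept coords

    @classmethod
    def build(cls, net: ReactionNetwork, graph: SpeciesGraph | None = None
              ) -> "Projection":
        graph = graph or build_graph(net)
        kept: list[int] = []
        dropped: list[int] = []
        block_of: dict[int, slice] = {}
        for q, verts in enumerate(graph.components):
            if len(verts) == 1:
                continue
            start = len(kept)
            kept.extend(verts[:-1])
            dropped.append(verts[-1])
            block_of[q] = slice(start, len(kept))
        return cls(net=net, graph=graph, kept=kept, dropped=dropped,
                   block_of=block_of)

    @property
    def dim(self) -> int:
        return len(self.kept)

    def project_vector(self, v) -> np.ndarray:
        return np.asarray(v)[self.kept]

    def projected_matrix(self) -> np.ndarray:
        """Rows of the stoichiometric matrix at the kept coordinates."""
        return stoichiometric_matrix(self.net)[self.kept, :]

    def multi_components(self) -> list[int]:
        return sorted(self.block_of)


@dataclass(frozen=True)
class EdgePartition:
    """A signing of the species-graph edges: +1 on ``plus_set``, -1 on
    ``minus_set``. One of the two sets may be empty."""

    plus_set: frozenset[int]
    minus_set: frozenset[int]

    def sign_vector(self, n_edges: int) -> np.ndarray:
        w = np.zeros(n_edges, dtype=int)
        for k in self.plus_set:
            w[k] = 1
        for k in self.minus_set:
            w[k] = -1
        return w

    @classmethod
    def from_signs(cls, signs: dict[int, int]) -> "EdgePartition":
        return cls(
            plus_set=frozenset(k for k, s in signs.items() if s == 1),
            minus_set=frozenset(k for k, s in signs.items() if s == -1),
        )


@dataclass
class CocliqueLevelFunction:
    """An integer level function over the full projected coordinates.

    ``coefficients[i]`` multiplies the copy number of species
    ``projection.kept[i]``. ``signs[k]`` is the change of L along reaction
    vector k, for every edge the function covers (all edges for a composed
    function; one component's edges for a component-local one).
    """

    coefficients: np.ndarray
    signs: dict[int, int]
    projection: Projection
    partition: EdgePartition = field(default=None)

    def __post_init__(self):
        if self.partition is None:
            self.partition = EdgePartition.from_signs(self.signs)

    def level(self, x_proj) -> int:
        return int(np.dot(self.coefficients, np.asarray(x_proj)))

    def canonical(self) -> "CocliqueLevelFunction":
        """Representative of the {L, -L} pair: first non-zero coefficient
        positive (L and -L induce the same level structure)."""
        lead = next((c for c in self.coefficients if c != 0), 1)
        if lead >= 0:
            return self
        return CocliqueLevelFunction(
            coefficients=-self.coefficients,
            signs={k: -s for k, s in self.signs.items()},
            projection=self.projection,
        )

    def key(self) -> tuple:
        return tuple(int(c) for c in self.canonical().coefficients)

    def __repr__(self) -> str:
        names = [self.projection.net.species[i] for i in self.projection.kept]
        terms = [f"{'+' if c > 0 else '-'}{abs(c)}*{nm}"
                 for c, nm in zip(self.coefficients, names) if c != 0]
        return f"CocliqueLevelFunction(L = {' '.join(terms) or '0'})"


def reduced_vector_set(net: ReactionNetwork, graph: SpeciesGraph | None = None
                       ) -> list[int]:
    """Indices of a maximal antiparallel-free subset of the reaction vectors:
    the lower-index member of each reversible pair plus all unpaired vectors."""
    graph = graph or build_graph(net)
    return [k for k in range(graph.n_edges)
            if graph.reverse_pair.get(k, graph.n_edges) >= k]


def _solve(proj: Projection, edge_idx: list[int], coord_slice: slice | None,
           w: np.ndarray) -> np.ndarray | None:
    """Exact solve of S_proj[coords, edges]^T b = w; None if inconsistent."""
    s_proj = proj.projected_matrix()
    if coord_slice is not None:
        s_proj = s_proj[coord_slice, :]
    a = s_proj[:, edge_idx].T
    try:
        sol = _rational.solve_unique(a, w)
    except ValueError as exc:
        raise InternalConsistencyError(
            f"sign-pattern system unexpectedly rank-deficient: {exc}"
        ) from exc
    if sol is None:
        return None
    if any(f.denominator != 1 for f in sol):
        raise InternalConsistencyError(
            f"sign-pattern solution is non-integer: {sol}"
        )
    return np.array([int(f) for f in sol], dtype=int)


def solve_partition_system(
    net: ReactionNetwork,
    partition: EdgePartition,
    graph: SpeciesGraph | None = None,
) -> np.ndarray | None:
    """Solve ``S_proj^T b = w`` for the given edge signing, over all edges.

    Returns the integer coefficient vector over the full projected
    coordinates, or None when the system is inconsistent. Exactness matters:
    a solution is accepted only with identically zero residual, and an
    existing solution is always integral.
    """
    proj = Projection.build(net, graph)
    n = proj.graph.n_edges
    if len(partition.plus_set | partition.minus_set) != n or \
            partition.plus_set & partition.minus_set:
        raise ValueError("partition must cover every edge exactly once")
    w = partition.sign_vector(n)
    return _solve(proj, list(range(n)), None, w)


def enumerate_component(
    net: ReactionNetwork,
    component: int,
    graph: SpeciesGraph | None = None,
    projection: Projection | None = None,
    prune: bool = True,
) -> list[CocliqueLevelFunction]:
    """All coclique level functions of one weakly connected component.

    Iterates the ``2^(|reduced|-1)`` canonical edge signings (first reduced
    vector fixed to +1, reversible partners opposite), solves each system
    exactly, and returns the solutions embedded in the full projected
    coordinates, each canonicalized and in lexicographic signing order
    (+1 before -1).

    With ``prune=True`` non-bipartite components short-circuit to an empty
    list and cycle-obstructed signings are skipped before solving; both are
    pure optimizations, the solver alone decides with ``prune=False``.
    """
    proj = projection or Projection.build(net, graph)
    graph = proj.graph
    edges_q = graph.component_edges(component)
    if component not in proj.block_of or not edges_q:
        return []
    if prune:
        ok, _, _ = is_bipartite(graph, component)
        if not ok:
            return []
        cycles = [theta for theta in cycle_basis_vectors(graph)
                  if set(np.flatnonzero(theta)) <= set(edges_q)]
    reduced = [k for k in reduced_vector_set(net, graph) if k in edges_q]
    free = reduced[1:]
    out: list[CocliqueLevelFunction] = []
    for combo in itertools.product((1, -1), repeat=len(free)):
        signs = {reduced[0]: 1}
        signs.update(dict(zip(free, combo)))
        for k in list(signs):
            partner = graph.reverse_pair.get(k)
            if partner is not None:
                signs[partner] = -signs[k]
        w = np.array([signs[k] for k in edges_q], dtype=int)
        if prune:
            w_full = np.zeros(graph.n_edges, dtype=int)
            w_full[edges_q] = w
            if partition_obstructed(w_full, cycles):
                continue
        b = _solve(proj, edges_q, proj.block_of[component], w)
        if b is None:
            continue
        full = np.zeros(proj.dim, dtype=int)
        full[proj.block_of[component]] = b
        out.append(CocliqueLevelFunction(
            coefficients=full, signs=signs, projection=proj
        ).canonical())
    return out


def bipartite_level_function(
    net: ReactionNetwork,
    component: int,
    graph: SpeciesGraph | None = None,
    projection: Projection | None = None,
) -> CocliqueLevelFunction:
    """The indicator level function obtained from a two-coloring.

    For a bipartite component, summing the copy numbers of one color class
    gives a level function directly: every reaction moves one molecule
    across the bipartition, changing the sum by exactly one. The class not
    containing the dropped species is used so the function is expressible in
    projected coordinates.
    """
    proj = projection or Projection.build(net, graph)
    graph = proj.graph
    ok, b_class, c_class = is_bipartite(graph, component)
    if not ok:
        raise NonBipartiteError(
            f"component {component} is not bipartite; no level function exists"
        )
    verts = graph.components[component]
    dropped = verts[-1]
    chosen = set(c_class if dropped in b_class else b_class) & set(verts)
    full = np.zeros(proj.dim, dtype=int)
    for pos, sp in enumerate(proj.kept):
        if sp in chosen:
            full[pos] = 1
    signs = {}
    for k in graph.component_edges(component):
        i, j = graph.edges[k]
        signs[k] = 1 if j in chosen else -1
    lf = CocliqueLevelFunction(coefficients=full, signs=signs, projection=proj)
    for k, s in signs.items():
        v_proj = proj.project_vector(
            stoichiometric_matrix(net)[:, k]
        )
        if int(full @ v_proj) != s:
            raise InternalConsistencyError("bipartite indicator failed sign check")
    return lf.canonical()


def compose_components(
    per_component: list[list[CocliqueLevelFunction]],
    projection: Projection,
    dedupe: bool = True,
) -> list[CocliqueLevelFunction]:
    """Signed sums of one level function per multi-species component.

    Empty if any multi-species component contributes none (no global level
    function exists then). With ``dedupe=True`` the global L ~ -L
    identification is applied and one canonical representative per distinct
    level structure is returned; with ``dedupe=False`` every signed
    combination is kept.
    """
    if any(len(lst) == 0 for lst in per_component):
        return []
    combos = []
    for choices in itertools.product(*per_component):
        for signing in itertools.product((1, -1), repeat=len(choices)):
            coeff = np.zeros(projection.dim, dtype=int)
            signs: dict[int, int] = {}
            for lf, s in zip(choices, signing):
                coeff = coeff + s * lf.coefficients
                signs.update({k: s * v for k, v in lf.signs.items()})
            combos.append(CocliqueLevelFunction(
                coefficients=coeff, signs=signs, projection=projection))
    if not dedupe:
        return combos
    seen: dict[tuple, CocliqueLevelFunction] = {}
    for lf in combos:
        seen.setdefault(lf.key(), lf.canonical())
    return list(seen.values())


def enumerate_level_functions(
    net: ReactionNetwork, prune: bool = True
) -> list[CocliqueLevelFunction]:
    """All distinct coclique level structures of the full projected chain."""
    proj = Projection.build(net)
    per_component = [
        enumerate_component(net, q, projection=proj, prune=prune)
        for q in proj.multi_components()
    ]
    return compose_components(per_component, proj)
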