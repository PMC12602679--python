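"""Projected state space, generator, level sets and bounding chains.

Per weakly connected component the total copy number is conserved, so the
chain is projected onto all-but-the-last species of each component; the
dropped species count is reconstructed from the total. States live on a
product of integer simplices. The generator follows mass-action rates
evaluated at the lifted full state, so a reaction's rate may legitimately
depend on species in other components (catalysts).

For a level function L the state space splits into level sets
``L_z = {x : L(x) = z}``. Each transition changes L by exactly one, so no
transition stays inside a level set (the coclique property). Replacing, at
every state of level z, the total up-rate by the level extremum (max or min
over ``L_z``) and likewise the down-rate yields two bounding generators
whose level processes are exact birth-death chains; their hitting times
bracket the original chain's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .coclique_enum import CocliqueLevelFunction, Projection
from .errors import (
    DegenerateSpaceError,
    EmptyLevelError,
    FeasibilityError,
    LiftError,
    NotCocliqueError,
)
from .network_model import (
    ReactionNetwork,
    mass_action_propensity,
    reaction_vector_set,
)

__all__ = [
    "ProjectedStateSpace",
    "GeneratorMatrix",
    "LevelDecomposition",
    "LevelRateSummary",
    "enumerate_state_space",
    "build_generator",
    "level_decomposition",
    "level_rate_summary",
    "bounding_generators",
]


def _simplex(dim: int, total: int) -> list[tuple[int, ...]]:
    """Lexicographically ordered lattice simplex {x in Z_+^dim : sum <= total}."""
    if dim == 0:
        return [()]
    out = []
    for first in range(total + 1):
        for rest in _simplex(dim - 1, total - first):
            out.append((first,) + rest)
    return out


@dataclass
class ProjectedStateSpace:
    """Enumerated projected states on the conservation simplices."""

    projection: Projection
    states: np.ndarray                       # N x dim, lexicographic order
    index: dict[tuple[int, ...], int]
    component_totals: list[int]              # per graph component (all of them)

    def __len__(self) -> int:
        return len(self.states)

    def lift(self, x_proj) -> np.ndarray:
        """Reconstruct the full species-count vector from a projected state."""
        net = self.projection.net
        graph = self.projection.graph
        full = np.zeros(net.n_species, dtype=int)
        x_proj = np.asarray(x_proj)
        for pos, sp_idx in enumerate(self.projection.kept):
            full[sp_idx] = x_proj[pos]
        for q, verts in enumerate(graph.components):
            tot = self.component_totals[q]
            if len(verts) == 1:
                full[verts[0]] = tot
            else:
                last = verts[-1]
                rest = int(sum(full[v] for v in verts[:-1]))
                if rest > tot:
                    raise LiftError(
                        f"component {q} total {tot} exceeded by projected state"
                    )
                full[last] = tot - rest
        return full


def enumerate_state_space(
    net: ReactionNetwork,
    totals: dict[int, int] | None = None,
    projection: Projection | None = None,
) -> ProjectedStateSpace:
    """Enumerate the product of per-component simplices.

    ``totals`` maps component id to its conserved total; by default they are
    read off ``net.initial_state``. States are ordered lexicographically.
    """
    proj = projection or Projection.build(net)
    graph = proj.graph
    if totals is None:
        if net.initial_state is None:
            raise ValueError("network has no initial_state; pass totals")
        totals = {
            q: int(net.initial_state[verts].sum())
            for q, verts in enumerate(graph.components)
        }
    component_totals = [int(totals.get(q, 0)) for q in range(graph.n_components)]
    blocks = []
    for q in proj.multi_components():
        dim_q = proj.block_of[q].stop - proj.block_of[q].start
        blocks.append(_simplex(dim_q, component_totals[q]))
    states = []

    def rec(i, prefix):
        if i == len(blocks):
            states.append(prefix)
            return
        for s in blocks[i]:
            rec(i + 1, prefix + s)

    rec(0, ())
    arr = np.array(states, dtype=int).reshape(len(states), proj.dim)
    if len(arr) <= 1:
        raise DegenerateSpaceError(
            f"projected state space has {len(arr)} state(s); nothing to analyze"
        )
    return ProjectedStateSpace(
        projection=proj,
        states=arr,
        index={tuple(int(v) for v in s): i for i, s in enumerate(arr)},
        component_totals=component_totals,
    )


@dataclass
class GeneratorMatrix:
    """Sparse generator of the projected chain plus per-vector transitions."""

    space: ProjectedStateSpace
    Q: sp.csr_matrix
    # per reaction vector k: (source state rows, destination rows, rates)
    moves: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    projected_vectors: list[np.ndarray]


def build_generator(net: ReactionNetwork, space: ProjectedStateSpace
                    ) -> GeneratorMatrix:
    """Assemble the generator: rate from x to x + v_k is the summed
    mass-action propensity of the reactions sharing vector k, evaluated at
    the lifted state; off-simplex moves get rate zero."""
    proj = space.projection
    vs = reaction_vector_set(net)
    v_proj = [proj.project_vector(v) for v in vs.vectors]
    kappa = [net.reactions[r].rate_constant for r in range(len(net.reactions))]
    vminus = [net.reactant_counts(r) for r in range(len(net.reactions))]
    lifted = np.stack([space.lift(s) for s in space.states])
    n_states = len(space)
    moves = []
    rows_all, cols_all, vals_all = [], [], []
    for k, vk in enumerate(v_proj):
        rows, cols, vals = [], [], []
        for i in range(n_states):
            target = tuple(int(x) for x in (space.states[i] + vk))
            j = space.index.get(target)
            if j is None:
                continue
            rate = 0.0
            for r in vs.groups[k]:
                rate += mass_action_propensity(kappa[r], vminus[r], lifted[i])
            if rate > 0.0:
                rows.append(i)
                cols.append(j)
                vals.append(rate)
        moves.append((np.array(rows, dtype=int), np.array(cols, dtype=int),
                      np.array(vals)))
        rows_all.extend(rows)
        cols_all.extend(cols)
        vals_all.extend(vals)
    q = sp.coo_matrix((vals_all, (rows_all, cols_all)),
                      shape=(n_states, n_states)).tocsr()
    diag = -np.asarray(q.sum(axis=1)).ravel()
    q = (q + sp.diags(diag)).tocsr()
    return GeneratorMatrix(space=space, Q=q, moves=moves,
                           projected_vectors=v_proj)


@dataclass
class LevelDecomposition:
    """Level values and level sets of a coclique level function."""

    level_of: np.ndarray                 # per state
    ell: int
    u: int
    level_sets: dict[int, np.ndarray]    # z -> state indices

    def states_at(self, z: int) -> np.ndarray:
        return self.level_sets[z]


def level_decomposition(
    lf: CocliqueLevelFunction,
    space: ProjectedStateSpace,
    generator: GeneratorMatrix,
) -> LevelDecomposition:
    """Split the state space into level sets and verify the coclique property.

    Raises NotCocliqueError if some reaction vector does not change L by
    exactly one on this space, and EmptyLevelError if an intermediate level
    is unpopulated (the rate extrema below would be over empty sets).
    """
    b = lf.coefficients
    for k, vk in enumerate(generator.projected_vectors):
        change = int(b @ vk)
        if change not in (-1, 1):
            raise NotCocliqueError(
                f"L changes by {change} on reaction vector {k}; "
                "not a coclique level function for this space"
            )
    levels = space.states @ b
    ell, u = int(levels.min()), int(levels.max())
    level_sets = {}
    for z in range(ell, u + 1):
        idx = np.flatnonzero(levels == z)
        if idx.size == 0:
            raise EmptyLevelError(
                f"level set at z={z} is empty (range {ell}..{u}); "
                "bound construction undefined"
            )
        level_sets[z] = idx
    return LevelDecomposition(level_of=levels, ell=ell, u=u,
                              level_sets=level_sets)


@dataclass
class LevelRateSummary:
    """Per-state and per-level aggregated up/down rates of L.

    ``lam`` / ``gam`` are the per-state total rates of L-increasing and
    L-decreasing moves; ``lam_max[z]`` etc. are their extrema over the level
    set at z. ``feasible_up[i]`` / ``feasible_down[i]`` list the reaction
    vectors whose move from state i stays inside the state space.
    """

    decomposition: LevelDecomposition
    g_plus: list[int]
    g_minus: list[int]
    lam: np.ndarray
    gam: np.ndarray
    lam_max: dict[int, float]
    lam_min: dict[int, float]
    gam_max: dict[int, float]
    gam_min: dict[int, float]
    feasible_up: list[list[int]]
    feasible_down: list[list[int]]
    level_function: CocliqueLevelFunction = None


def level_rate_summary(
    lf: CocliqueLevelFunction,
    space: ProjectedStateSpace,
    generator: GeneratorMatrix,
    decomposition: LevelDecomposition | None = None,
) -> LevelRateSummary:
    decomp = decomposition or level_decomposition(lf, space, generator)
    b = lf.coefficients
    vector_sign = [int(b @ vk) for vk in generator.projected_vectors]
    g_plus = [k for k, s in enumerate(vector_sign) if s == 1]
    g_minus = [k for k, s in enumerate(vector_sign) if s == -1]
    n_states = len(space)
    lam = np.zeros(n_states)
    gam = np.zeros(n_states)
    feasible_up: list[list[int]] = [[] for _ in range(n_states)]
    feasible_down: list[list[int]] = [[] for _ in range(n_states)]
    for k, vk in enumerate(generator.projected_vectors):
        up = vector_sign[k] == 1
        rows, _, vals = generator.moves[k]
        if up:
            lam[rows] += vals
        else:
            gam[rows] += vals
        for i in range(n_states):
            target = tuple(int(x) for x in (space.states[i] + vk))
            if target in space.index:
                (feasible_up if up else feasible_down)[i].append(k)
    # standing assumption: off the top level every state must have an
    # in-space upward move (when any up vector exists), and symmetrically.
    for i in range(n_states):
        z = decomp.level_of[i]
        if g_plus and z != decomp.u and not feasible_up[i]:
            raise FeasibilityError(
                f"state {tuple(space.states[i])} (level {z}) has no in-space "
                "upward move; bounding chains undefined"
            )
        if g_minus and z != decomp.ell and not feasible_down[i]:
            raise FeasibilityError(
                f"state {tuple(space.states[i])} (level {z}) has no in-space "
                "downward move; bounding chains undefined"
            )
    lam_max, lam_min, gam_max, gam_min = {}, {}, {}, {}
    for z, idx in decomp.level_sets.items():
        lam_max[z] = float(lam[idx].max())
        lam_min[z] = float(lam[idx].min())
        gam_max[z] = float(gam[idx].max())
        gam_min[z] = float(gam[idx].min())
    return LevelRateSummary(
        decomposition=decomp, g_plus=g_plus, g_minus=g_minus,
        lam=lam, gam=gam,
        lam_max=lam_max, lam_min=lam_min, gam_max=gam_max, gam_min=gam_min,
        feasible_up=feasible_up, feasible_down=feasible_down,
        level_function=lf,
    )


def bounding_generators(
    summary: LevelRateSummary,
    space: ProjectedStateSpace,
    generator: GeneratorMatrix,
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Build the two bounding generators on the same state space.

    The fast chain spreads the level-maximal up-rate and level-minimal
    down-rate equally over the feasible moves of each state; the slow chain
    uses the level-minimal up-rate and level-maximal down-rate. Both level
    processes are birth-death chains by construction.
    """
    decomp = summary.decomposition
    n_states = len(space)

    def assemble(up_rate: dict[int, float], down_rate: dict[int, float]
                 ) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for i in range(n_states):
            z = int(decomp.level_of[i])
            ups = summary.feasible_up[i]
            downs = summary.feasible_down[i]
            if ups:
                share = up_rate[z] / len(ups)
                for k in ups:
                    j = space.index[tuple(int(x) for x in
                                          (space.states[i]
                                           + generator.projected_vectors[k]))]
                    rows.append(i)
                    cols.append(j)
                    vals.append(share)
            if downs:
                share = down_rate[z] / len(downs)
                for k in downs:
                    j = space.index[tuple(int(x) for x in
                                          (space.states[i]
                                           + generator.projected_vectors[k]))]
                    rows.append(i)
                    cols.append(j)
                    vals.append(share)
        q = sp.coo_matrix((vals, (rows, cols)),
                          shape=(n_states, n_states)).tocsr()
        diag = -np.asarray(q.sum(axis=1)).ravel()
        return (q + sp.diags(diag)).tocsr()

    fast = assemble(summary.lam_max, summary.gam_min)
    slow = assemble(summary.lam_min, summary.gam_max)
    return fast, slow
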