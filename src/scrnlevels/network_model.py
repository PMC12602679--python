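"""Reaction networks, stoichiometry and mass-action propensities.

A stochastic chemical reaction network (SCRN) is a continuous-time Markov
chain on species copy-number vectors. Each reaction consumes the molecules
counted by its reactant vector and produces the ones counted by its product
vector, firing with a mass-action propensity: the rate constant times the
falling-factorial product of reactant copy numbers. Distinct reactions may
share a net reaction vector (e.g. a plain conversion and its catalysed
variant); such reactions are grouped and their propensities summed.

Rate constants are taken as already volume-scaled: a bimolecular constant
``k`` in a reaction volume ``V`` should be supplied as ``k / V``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import _rational
from .errors import InvalidNetworkError

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "ReactionVectorSet",
    "reaction_vector_set",
    "stoichiometric_matrix",
    "stoichiometric_rank",
    "conservation_vectors",
    "check_unit_transfer",
    "mass_action_propensity",
    "total_propensity",
    "read_network",
    "write_network",
    "network_to_dict",
    "network_from_dict",
]


@dataclass(frozen=True)
class Reaction:
    """A single chemical reaction with a mass-action rate constant.

    ``reactants`` and ``products`` map species names to non-negative integer
    stoichiometric coefficients; species absent from a map have coefficient 0.
    The net change (products minus reactants) must be non-zero.
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_constant: float

    def __post_init__(self):
        for side, counts in (("reactant", self.reactants), ("product", self.products)):
            for name, c in counts.items():
                if not (isinstance(c, (int, np.integer)) and c >= 0):
                    raise InvalidNetworkError(
                        f"{side} count of {name!r} must be a non-negative integer, got {c!r}"
                    )
        if self.rate_constant < 0:
            raise InvalidNetworkError("rate_constant must be >= 0")
        species = set(self.reactants) | set(self.products)
        if all(self.products.get(s, 0) == self.reactants.get(s, 0) for s in species):
            raise InvalidNetworkError(
                "reaction has zero net change (reactant vector equals product vector)"
            )


class ReactionNetwork:
    """An ordered species list plus a list of reactions.

    The species order is authoritative: stoichiometric matrices, graphs and
    projected coordinates all follow it. ``initial_state`` (optional) fixes
    the conserved totals used when enumerating the projected state space.
    """

    def __init__(
        self,
        species: Sequence[str],
        reactions: Sequence[Reaction],
        initial_state: Mapping[str, int] | Sequence[int] | None = None,
    ):
        self.species = list(species)
        self.reactions = list(reactions)
        d = len(self.species)
        if d < 2:
            raise InvalidNetworkError("a network needs at least two species")
        if len(set(self.species)) != d:
            raise InvalidNetworkError("species names must be unique")
        if not self.reactions:
            raise InvalidNetworkError("a network needs at least one reaction")
        self._index = {name: i for i, name in enumerate(self.species)}
        # per-reaction integer count arrays in species order
        self._vminus = np.zeros((len(self.reactions), d), dtype=int)
        self._vplus = np.zeros((len(self.reactions), d), dtype=int)
        for r, rxn in enumerate(self.reactions):
            for name, c in rxn.reactants.items():
                self._vminus[r, self._species_pos(name)] = c
            for name, c in rxn.products.items():
                self._vplus[r, self._species_pos(name)] = c
        used = (self._vminus.sum(axis=0) + self._vplus.sum(axis=0)) > 0
        if not used.all():
            idle = [self.species[i] for i in np.flatnonzero(~used)]
            raise InvalidNetworkError(
                f"species never appear in any reaction: {idle}"
            )
        if initial_state is None:
            self.initial_state = None
        else:
            if isinstance(initial_state, Mapping):
                x0 = np.zeros(d, dtype=int)
                for name, c in initial_state.items():
                    x0[self._species_pos(name)] = c
            else:
                x0 = np.asarray(initial_state, dtype=int)
                if x0.shape != (d,):
                    raise InvalidNetworkError("initial_state has wrong length")
            if (x0 < 0).any():
                raise InvalidNetworkError("initial_state must be non-negative")
            self.initial_state = x0

    def _species_pos(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise InvalidNetworkError(f"unknown species name {name!r}") from None

    @property
    def n_species(self) -> int:
        return len(self.species)

    def reactant_counts(self, r: int) -> np.ndarray:
        return self._vminus[r]

    def product_counts(self, r: int) -> np.ndarray:
        return self._vplus[r]

    def reaction_change(self, r: int) -> np.ndarray:
        return self._vplus[r] - self._vminus[r]

    def __repr__(self) -> str:
        return (
            f"ReactionNetwork(d={self.n_species}, "
            f"reactions={len(self.reactions)}, species={self.species})"
        )


@dataclass
class ReactionVectorSet:
    """Distinct reaction vectors, in order of first appearance, with the
    indices of the reactions sharing each vector."""

    vectors: list[np.ndarray]
    groups: list[list[int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.vectors)


def reaction_vector_set(net: ReactionNetwork) -> ReactionVectorSet:
    """Deduplicate reaction vectors and group reactions by shared vector."""
    vectors: list[np.ndarray] = []
    groups: list[list[int]] = []
    seen: dict[tuple, int] = {}
    for r in range(len(net.reactions)):
        v = net.reaction_change(r)
        key = tuple(int(x) for x in v)
        if key in seen:
            groups[seen[key]].append(r)
        else:
            seen[key] = len(vectors)
            vectors.append(v)
            groups.append([r])
    return ReactionVectorSet(vectors=vectors, groups=groups)


def stoichiometric_matrix(net: ReactionNetwork) -> np.ndarray:
    """d x n integer matrix whose columns are the distinct reaction vectors."""
    vs = reaction_vector_set(net)
    return np.stack(vs.vectors, axis=1)


def stoichiometric_rank(net: ReactionNetwork) -> int:
    """Rank of the stoichiometric matrix, exact over the rationals."""
    return _rational.rank(stoichiometric_matrix(net))


def conservation_vectors(net: ReactionNetwork) -> list[np.ndarray]:
    """Canonical integer basis of the left null space {m : m^T S = 0}.

    Each basis vector has coprime integer entries and positive leading
    coefficient; the list is empty when there is no conservation law and has
    exactly one element when the conservation vector is unique up to scale.
    """
    return _rational.left_nullspace_basis(stoichiometric_matrix(net))


def check_unit_transfer(net: ReactionNetwork) -> tuple[bool, list[np.ndarray]]:
    """Does every reaction vector have exactly one +1, one -1 and zeros else?

    Returns (flag, violating vectors). Networks with this property move one
    molecule between two species per reaction, so total copy number per
    connected block is conserved.
    """
    violators = []
    for v in reaction_vector_set(net).vectors:
        if not (np.all(np.isin(v, (-1, 0, 1)))
                and np.sum(v == 1) == 1 and np.sum(v == -1) == 1):
            violators.append(v)
    return (len(violators) == 0), violators


def mass_action_propensity(rate_constant: float, reactant_counts, state) -> float:
    """kappa times the falling-factorial product of reactant copy numbers.

    Zero whenever the state lacks the required reactant molecules.
    """
    x = np.asarray(state)
    if (x < 0).any():
        raise ValueError("state entries must be non-negative")
    out = float(rate_constant)
    for xi, vi in zip(x, np.asarray(reactant_counts, dtype=int)):
        for j in range(vi):
            out *= (int(xi) - j)
        if xi < vi:
            return 0.0
    return out


def total_propensity(net: ReactionNetwork, vector_index: int, state) -> float:
    """Summed propensity of all reactions sharing reaction vector ``vector_index``."""
    vs = reaction_vector_set(net)
    return sum(
        mass_action_propensity(
            net.reactions[r].rate_constant, net.reactant_counts(r), state
        )
        for r in vs.groups[vector_index]
    )


# -- JSON network dialect ----------------------------------------------------

def network_to_dict(net: ReactionNetwork) -> dict:
    out = {
        "species": list(net.species),
        "reactions": [
            {
                "reactants": {k: int(v) for k, v in rxn.reactants.items() if v},
                "products": {k: int(v) for k, v in rxn.products.items() if v},
                "rate_constant": float(rxn.rate_constant),
            }
            for rxn in net.reactions
        ],
    }
    if net.initial_state is not None:
        out["initial_state"] = {
            name: int(c) for name, c in zip(net.species, net.initial_state)
        }
    return out


def network_from_dict(data: dict) -> ReactionNetwork:
    try:
        species = data["species"]
        raw = data["reactions"]
    except (KeyError, TypeError) as exc:
        raise InvalidNetworkError(f"malformed network document: missing {exc}") from exc
    reactions = []
    for i, r in enumerate(raw):
        try:
            reactions.append(
                Reaction(
                    reactants=dict(r.get("reactants", {})),
                    products=dict(r.get("products", {})),
                    rate_constant=float(r["rate_constant"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise InvalidNetworkError(f"malformed reaction #{i}: {exc}") from exc
    return ReactionNetwork(species, reactions, initial_state=data.get("initial_state"))


def read_network(path: str | Path) -> ReactionNetwork:
    """Read a network from the JSON dialect used by this package."""
    with open(path) as fh:
        return network_from_dict(json.load(fh))


def write_network(net: ReactionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=2)
        fh.write("\n")
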