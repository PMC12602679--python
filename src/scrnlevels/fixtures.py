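"""Builders for the benchmark networks and a seeded random network generator.

The builders cover the worked examples used throughout the package's tests:
a three-species conversion cascade, two small multi-component networks (one
with cross-component catalysis), a histone-modification chromatin circuit, a
full chromatin circuit with DNA methylation, and a bi-parallel conversion
motif. Rate constants default to one; bimolecular constants are divided by
the reaction volume ``V`` on construction, and homodimeric reactions
additionally carry a factor 1/2 so their falling-factorial propensity
``(k/2V) x (x-1)`` matches the combinatorial pair-count rate ``(k/V) x (x-1)/2``.

The chromatin circuits are parameterized through the timescale-separation
ratio ``epsilon`` (erasure of the activating mark relative to its
autocatalytic establishment) and the relative erasure ratios ``mu`` (H3K9me3
vs activating mark) and ``mu_prime`` (DNA methylation vs activating mark);
the basal erasure constants are derived from these so that sweeping
``epsilon`` reproduces the slow-erasure regime directly.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .network_model import Reaction, ReactionNetwork

__all__ = [
    "cascade",
    "two_component",
    "coupled",
    "histone",
    "full_chromatin",
    "biparallel",
    "random_unit_transfer",
]


def _positive(**params):
    for name, val in params.items():
        if not val > 0:
            raise ConfigurationError(f"parameter {name} must be positive, got {val}")


def cascade(alpha: float = 1.0, beta: float = 1.0, n_tot: int = 2
            ) -> ReactionNetwork:
    """Irreversible two-step conversion Z -> W -> Y of a conserved pool.

    Species order (W, Y, Z); all molecules start as Z. The projected chain
    tracks (n_W, n_Y) on the triangle x1 + x2 <= n_tot.
    """
    _positive(alpha=alpha, beta=beta, n_tot=n_tot)
    return ReactionNetwork(
        species=["W", "Y", "Z"],
        reactions=[
            Reaction({"Z": 1}, {"W": 1}, alpha),
            Reaction({"W": 1}, {"Y": 1}, beta),
        ],
        initial_state={"Z": n_tot},
    )


def two_component(kappa1: float = 1.0, kappa2: float = 1.0, kappa3: float = 1.0,
                  n1: int = 2, n2: int = 2) -> ReactionNetwork:
    """Two independent subsystems: a reversible pair S1 <-> S2 and an
    irreversible conversion S3 -> S4."""
    _positive(kappa1=kappa1, kappa2=kappa2, kappa3=kappa3, n1=n1, n2=n2)
    return ReactionNetwork(
        species=["S1", "S2", "S3", "S4"],
        reactions=[
            Reaction({"S1": 1}, {"S2": 1}, kappa1),
            Reaction({"S2": 1}, {"S1": 1}, kappa2),
            Reaction({"S3": 1}, {"S4": 1}, kappa3),
        ],
        initial_state={"S1": n1, "S3": n2},
    )


def coupled(kappa1: float = 1.0, kappa2: float = 1.0, kappa3: float = 1.0,
            kappa4: float = 1.0, n1: int = 2, n2: int = 3, n3: int = 1
            ) -> ReactionNetwork:
    """Three components coupled through catalysis.

    S1 <-> S2 conversions are catalysed by S4 and S5 respectively, and
    S3 <-> S4 interconvert; S5 sits in its own component with a constant
    count. The graph components cannot be analyzed independently because
    rates cross component boundaries.
    """
    _positive(kappa1=kappa1, kappa2=kappa2, kappa3=kappa3, kappa4=kappa4,
              n1=n1, n2=n2, n3=n3)
    return ReactionNetwork(
        species=["S1", "S2", "S3", "S4", "S5"],
        reactions=[
            Reaction({"S1": 1, "S4": 1}, {"S2": 1, "S4": 1}, kappa1),
            Reaction({"S2": 1, "S5": 1}, {"S1": 1, "S5": 1}, kappa2),
            Reaction({"S3": 1}, {"S4": 1}, kappa3),
            Reaction({"S4": 1}, {"S3": 1}, kappa4),
        ],
        initial_state={"S1": n1, "S3": n2, "S5": n3},
    )


def histone(
    d_tot: int = 2,
    epsilon: float = 1.0,
    mu: float = 1.0,
    b_tilde: float = 1.0,
    k_w0_a: float = 1.0,
    k_w_a: float = 1.0,
    k_m_a: float = 1.0,
    k_e_a: float = 1.0,
    k_w0_r: float = 1.0,
    k_w_r: float = 1.0,
    k_m_r: float = 1.0,
    volume: float = 1.0,
) -> ReactionNetwork:
    """Histone-modification chromatin circuit on ``d_tot`` nucleosomes.

    Species order (D^R, D^A, D): repressed, active and unmodified
    nucleosomes. Each mark auto-catalyzes its establishment and catalyzes
    erasure of the opposite mark. Derived constants: the total erasure rate
    of the activating mark is ``delta_a = epsilon * k_m_a * d_tot / volume``,
    the repressive analogue is ``delta_r = mu * b_tilde * delta_a``, and the
    cross-catalyzed erasure of the repressive mark runs at ``mu * k_e_a``.
    """
    _positive(d_tot=d_tot, epsilon=epsilon, mu=mu, b_tilde=b_tilde,
              k_w0_a=k_w0_a, k_w_a=k_w_a, k_m_a=k_m_a, k_e_a=k_e_a,
              k_w0_r=k_w0_r, k_w_r=k_w_r, k_m_r=k_m_r, volume=volume)
    delta_a = epsilon * k_m_a * d_tot / volume
    delta_r = mu * b_tilde * delta_a
    k_e_r = mu * k_e_a
    v = volume
    return ReactionNetwork(
        species=["DR", "DA", "D"],
        reactions=[
            Reaction({"D": 1}, {"DA": 1}, k_w0_a + k_w_a),
            Reaction({"D": 1, "DA": 1}, {"DA": 2}, k_m_a / v),
            Reaction({"DA": 1}, {"D": 1}, delta_a),
            Reaction({"DA": 1, "DR": 1}, {"D": 1, "DR": 1}, k_e_a / v),
            Reaction({"D": 1}, {"DR": 1}, k_w0_r + k_w_r),
            Reaction({"D": 1, "DR": 1}, {"DR": 2}, k_m_r / v),
            Reaction({"DR": 1}, {"D": 1}, delta_r),
            Reaction({"DR": 1, "DA": 1}, {"D": 1, "DA": 1}, k_e_r / v),
        ],
        initial_state={"D": d_tot},
    )


def full_chromatin(
    d_tot: int = 2,
    epsilon: float = 1.0,
    mu: float = 1.0,
    mu_prime: float = 1.0,
    b_tilde: float = 1.0,
    beta: float = 1.0,
    k_w0_a: float = 1.0,
    k_w_a: float = 1.0,
    k_m_a: float = 1.0,
    k_e_a: float = 1.0,
    k_w0_1: float = 1.0,
    k_w_1: float = 1.0,
    k_w0_2: float = 1.0,
    k_w_2: float = 1.0,
    k_m: float = 1.0,
    k_m_bar: float = 1.0,
    k_m_prime: float = 1.0,
    volume: float = 1.0,
) -> ReactionNetwork:
    """Chromatin circuit with DNA methylation and repressive histone marks.

    Species order (D^R12, D^A, D^R1, D^R2, D): doubly repressed (methylated
    + H3K9me3), active, methylated-only, H3K9me3-only, and unmodified
    nucleosomes. Repressive marks catalyze each other's establishment,
    producing the cooperative repressed state.

    Derived constants: ``delta_a = epsilon * k_m_a * d_tot / volume`` (total
    erasure of the activating mark), ``delta_r = mu * b_tilde * delta_a``
    (basal erasure of H3K9me3), ``delta_t = beta * mu_prime * delta_a``
    (basal erasure of DNA methylation), ``k_e_r = mu * k_e_a`` and
    ``k_t_star = mu_prime * k_e_a`` (erasures catalyzed by the activating
    mark). Homodimeric establishment reactions carry the 1/2 pair-count
    factor in their constants.
    """
    _positive(d_tot=d_tot, epsilon=epsilon, mu=mu, mu_prime=mu_prime,
              b_tilde=b_tilde, beta=beta, k_w0_a=k_w0_a, k_w_a=k_w_a,
              k_m_a=k_m_a, k_e_a=k_e_a, k_w0_1=k_w0_1, k_w_1=k_w_1,
              k_w0_2=k_w0_2, k_w_2=k_w_2, k_m=k_m, k_m_bar=k_m_bar,
              k_m_prime=k_m_prime, volume=volume)
    delta_a = epsilon * k_m_a * d_tot / volume
    delta_r = mu * b_tilde * delta_a
    delta_t = beta * mu_prime * delta_a
    k_e_r = mu * k_e_a
    k_t_star = mu_prime * k_e_a
    v = volume
    # reactions grouped by net reaction vector, in the edge order used by the
    # tests: D->DA, DA->D, D->DR1, DR1->D, D->DR2, DR2->D, DR1->DR12,
    # DR12->DR1, DR2->DR12, DR12->DR2
    rxns = [
        # D -> DA: basal + autocatalytic establishment of the activating mark
        Reaction({"D": 1}, {"DA": 1}, k_w0_a + k_w_a),
        Reaction({"D": 1, "DA": 1}, {"DA": 2}, k_m_a / v),
        # DA -> D: basal erasure + erasure catalyzed by repressive marks
        # (the doubly repressed nucleosome catalyzes twice as strongly)
        Reaction({"DA": 1}, {"D": 1}, delta_a),
        Reaction({"DA": 1, "DR1": 1}, {"D": 1, "DR1": 1}, k_e_a / v),
        Reaction({"DA": 1, "DR12": 1}, {"D": 1, "DR12": 1}, 2 * k_e_a / v),
        Reaction({"DA": 1, "DR2": 1}, {"D": 1, "DR2": 1}, k_e_a / v),
        # D -> DR1: basal + methylation catalyzed by methylated nucleosomes
        Reaction({"D": 1}, {"DR1": 1}, k_w0_1 + k_w_1),
        Reaction({"D": 1, "DR2": 1}, {"DR1": 1, "DR2": 1}, k_m_prime / v),
        Reaction({"D": 1, "DR12": 1}, {"DR1": 1, "DR12": 1}, k_m_prime / v),
        # DR1 -> D: erasure of DNA methylation
        Reaction({"DR1": 1}, {"D": 1}, delta_t),
        Reaction({"DR1": 1, "DA": 1}, {"D": 1, "DA": 1}, k_t_star / v),
        # D -> DR2: basal + catalyzed establishment of H3K9me3
        Reaction({"D": 1}, {"DR2": 1}, k_w0_2 + k_w_2),
        Reaction({"D": 1, "DR2": 1}, {"DR2": 2}, k_m / v),
        Reaction({"D": 1, "DR12": 1}, {"DR2": 1, "DR12": 1}, (k_m + k_m_bar) / v),
        Reaction({"D": 1, "DR1": 1}, {"DR2": 1, "DR1": 1}, k_m_bar / v),
        # DR2 -> D: erasure of H3K9me3
        Reaction({"DR2": 1}, {"D": 1}, delta_r),
        Reaction({"DR2": 1, "DA": 1}, {"D": 1, "DA": 1}, k_e_r / v),
        # DR1 -> DR12: H3K9me3 added on a methylated nucleosome
        # (homodimeric reactions carry the 1/2 pair-count factor)
        Reaction({"DR1": 1}, {"DR12": 1}, k_w0_2),
        Reaction({"DR1": 1, "DR2": 1}, {"DR12": 1, "DR2": 1}, k_m / v),
        Reaction({"DR1": 1, "DR12": 1}, {"DR12": 2}, (k_m + k_m_bar) / v),
        Reaction({"DR1": 2}, {"DR12": 1, "DR1": 1}, k_m_bar / (2 * v)),
        # DR12 -> DR1: H3K9me3 erased from a doubly repressed nucleosome
        Reaction({"DR12": 1}, {"DR1": 1}, delta_r),
        Reaction({"DR12": 1, "DA": 1}, {"DR1": 1, "DA": 1}, k_e_r / v),
        # DR2 -> DR12: methylation added next to H3K9me3
        Reaction({"DR2": 1}, {"DR12": 1}, k_w0_1),
        Reaction({"DR2": 2}, {"DR12": 1, "DR2": 1}, k_m_prime / (2 * v)),
        Reaction({"DR2": 1, "DR12": 1}, {"DR12": 2}, k_m_prime / v),
        # DR12 -> DR2: methylation erased from a doubly repressed nucleosome
        Reaction({"DR12": 1}, {"DR2": 1}, delta_t),
        Reaction({"DR12": 1, "DA": 1}, {"DR2": 1, "DA": 1}, k_t_star / v),
    ]
    return ReactionNetwork(
        species=["DR12", "DA", "DR1", "DR2", "D"],
        reactions=rxns,
        initial_state={"D": d_tot},
    )


def biparallel(k1: float = 1.0, k2: float = 1.0, k3: float = 1.0,
               k4: float = 1.0, s_tot: int = 2) -> ReactionNetwork:
    """Two parallel conversion pathways J -> Y -> W and J -> Z -> W.

    Species order (Y, Z, W, J); all molecules start as J.
    """
    _positive(k1=k1, k2=k2, k3=k3, k4=k4, s_tot=s_tot)
    return ReactionNetwork(
        species=["Y", "Z", "W", "J"],
        reactions=[
            Reaction({"J": 1}, {"Y": 1}, k1),
            Reaction({"J": 1}, {"Z": 1}, k2),
            Reaction({"Y": 1}, {"W": 1}, k3),
            Reaction({"Z": 1}, {"W": 1}, k4),
        ],
        initial_state={"J": s_tot},
    )


def random_unit_transfer(
    d: int,
    density: float = 0.3,
    bipartite: bool = True,
    seed: int = 0,
    total: int = 2,
) -> ReactionNetwork:
    """Seeded random connected unit-transfer network on ``d`` species.

    With ``bipartite=True`` the species are split into two non-empty classes
    and every edge crosses the split, so the graph is bipartite by
    construction; otherwise edges connect arbitrary pairs and odd cycles may
    occur. A random spanning tree guarantees weak connectivity; each extra
    candidate edge is included with probability ``density``. One mass-action
    conversion reaction per edge, rate constants log-uniform in [0.1, 10].
    All molecules start on species 0 (conserved total ``total``).
    """
    if d < 2:
        raise ConfigurationError("need at least two species")
    rng = np.random.default_rng(seed)
    names = [f"X{i}" for i in range(d)]
    if bipartite:
        size_b = int(rng.integers(1, d))
        perm = rng.permutation(d)
        class_b = set(int(i) for i in perm[:size_b])
    else:
        class_b = None

    def allowed(i, j):
        if i == j:
            return False
        if class_b is None:
            return True
        return (i in class_b) != (j in class_b)

    edges: set[tuple[int, int]] = set()
    # random spanning tree: place vertices in an order that always offers a
    # cross-class partner, then connect each new vertex to a placed one
    order = [int(i) for i in rng.permutation(d)]
    if class_b is not None:
        # seed with one vertex from each class so `allowed` never starves
        first_b = next(v for v in order if v in class_b)
        first_c = next(v for v in order if v not in class_b)
        head = [first_b, first_c]
        order = head + [v for v in order if v not in head]
    placed = [order[0]]
    for v in order[1:]:
        candidates = [u for u in placed if allowed(u, v)]
        u = candidates[int(rng.integers(len(candidates)))]
        if rng.random() < 0.5:
            edges.add((v, u))
        else:
            edges.add((u, v))
        placed.append(v)
    for i in range(d):
        for j in range(d):
            if allowed(i, j) and (i, j) not in edges and rng.random() < density:
                edges.add((i, j))
    reactions = [
        Reaction({names[i]: 1}, {names[j]: 1},
                 float(10 ** rng.uniform(-1, 1)))
        for i, j in sorted(edges)
    ]
    return ReactionNetwork(
        species=names,
        reactions=reactions,
        initial_state={names[0]: total},
    )
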