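# Methods

## Model class and scope

A stochastic chemical reaction network is specified by an ordered species
list and reactions with reactant/product stoichiometries and mass-action
rate constants (volume scaling pre-folded by the caller: a bimolecular `k`
in volume `V` is supplied as `k/V`). The package analyzes *unit-transfer*
networks: every distinct reaction vector has exactly one `+1`, one `−1` and
zeros elsewhere. Reactions sharing a net vector (a plain conversion and its
catalysed variants) are grouped; their propensities sum. State spaces are
finite products of conservation simplices determined by an initial state;
countably infinite state spaces and non-mass-action kinetics are out of
scope. The full state space defaults to the entire simplex; transitions that
would leave it get rate zero.

## Exact arithmetic

The enumeration theory makes exact claims — the sign-pattern system
`Šᵀb = w` has zero or one solution and any solution is integral; rank plus
left nullity equals the species count; cycle incidence vectors lie in
`ker S` — which floating point cannot certify. All ranks, left null spaces
and sign-pattern solves therefore run over `fractions.Fraction`
(Gauss-Jordan elimination in `_rational.py`). Matrices are at most tens of
rows, so this is fast enough for the `2^(|V̂|−1)`-solve enumeration loop and
for the brute-force `2^n` oracle used in tests; the test suite additionally
cross-checks rank and null-space results against sympy. A non-integer or
non-unique solution raises an internal-consistency error rather than being
silently accepted.

Conservation vectors are reported as the reduced-row-echelon basis of the
left null space, each vector scaled to coprime integers with positive
leading entry — a deterministic canonical form for tests and reports.

## Conventions where the theory leaves freedom

* **Species order is authoritative.** Projected coordinates drop the
  highest-index species of each multi-species graph component (singleton
  components drop entirely); components are ordered by their lowest species
  index.
* **Sign canonicalization.** `L` and `−L` induce the same level structure.
  Component enumeration fixes the first reduced vector's sign to `+1`,
  iterates the remaining signs lexicographically (`+1` before `−1`), and
  canonicalizes each solution to a positive leading coefficient. Composition
  across components takes all signed sums and deduplicates under global
  negation. Output order follows the signing iteration.
* **Bipartite coloring** is deterministic: BFS from the lowest-index vertex
  of each component, root in class B; antiparallel edge pairs count once for
  coloring and connectivity but stay distinct in cycle vectors.
* **Cycle certificates.** Obstruction testing uses a cycle *basis* (spanning
  forest plus one fundamental cycle per non-tree edge, antiparallel partners
  included) rather than all weakly directed cycles. For unit-transfer
  networks the cycle space equals `ker S`, so the basis test is complete as
  well as sound; a property test verifies, pattern by pattern, that the
  certificate agrees exactly with the solver's verdict. Pruning by
  bipartiteness and by cycle obstruction is an optimization only — with
  `prune=False` the exact solver alone decides, and a test asserts both
  paths agree.

## Degenerate and boundary cases

* An intermediate empty level set makes the per-level rate extrema
  undefined; this raises a typed error rather than skipping levels.
* The bounding-chain construction requires every non-extreme state to have
  an in-space move in each direction that carries rate (`G₊(x̌)` nonempty
  off the top level when `G₊ ≠ ∅`, symmetrically below). Violations raise a
  typed feasibility error; since both bounding chains distribute both the up
  and down extremal rates, a violation in either direction invalidates the
  whole construction for that level function. The two-component benchmark
  (reversible pair plus an irreversible conversion) exercises this: none of
  its level structures admit bounds, which the tests assert as the correct
  outcome.
* A direction whose positivity precondition fails (some `λ^M_z = 0` for the
  upward passage, some `γ^m_z = 0` downward — e.g. any irreversible cascade
  downward) is reported as *undefined* with a note; the other direction is
  unaffected.

## Birth-death closed forms

The upward passage time of a birth-death chain on levels `ℓ..u` with birth
rates `λ_z` and death rates `γ_z` is evaluated as the nested sum
`Σ_i (1/λ_i)(1 + Σ_j Π γ/λ)` with running products in `O((u−ℓ)²)`;
the downward form is the same formula under level reflection
(`z ↦ ℓ+u−z`, births and deaths swapped), exposed as a tested identity.
Direct double-precision products suffice for the magnitudes exercised here
(ratios up to ~10⁵ over at most ~10 levels); a product that hits exactly
zero short-circuits. Both forms are verified to 1e−9 against first-step
linear solves of explicitly assembled tridiagonal generators, and the four
bounds are verified against exact solves of the full bounding chains
(whose level processes are birth-death by construction).

Exact MFPTs use sparse LU on the generator restricted to non-target states
(`Q_rr h = −1`); a singular restriction or non-finite solution is reported
as target unreachability, never as a silent infinity. Spaces here are at
most ~10⁴ states.

The cascade's exact passage time has an independent closed form — the mean
of the maximum of `N_tot` i.i.d. two-stage (hypoexponential) completion
times, `∫₀^∞ (1 − F(x)^{N_tot}) dx` — evaluated by adaptive quadrature at
relative tolerance 1e−11 and used as a second oracle against the linear
solve.

## Fixture networks and the random generator

The builders construct the benchmark networks with all base constants 1,
`V = 1`, and conserved totals from the initial state; every test states its
own parameters. The chromatin circuits are parameterized by the
timescale-separation ratio `ε` (activating-mark erasure relative to its
autocatalytic establishment: the basal erasure constant is
`δ_A = ε·k^A_M·D_tot/V`) and the erasure ratios `μ` (H3K9me3 vs activating)
and `μ′` (DNA methylation vs activating), with auxiliary factors `b̃`, `β`
fixing the basal/catalysed proportions. Homodimeric establishment reactions
(two identical repressive nucleosomes) carry constants halved so the
falling-factorial propensity `(k/2V)·x(x−1)` equals the pair-count rate
`(k/V)·x(x−1)/2`. Symbolic-form regression tests check every generator
entry of every fixture against the independently coded per-vector rate
functions at all states of a `D_tot = 3` space with deliberately asymmetric
rational parameters.

`random_unit_transfer` draws connected unit-transfer networks: a random
spanning tree (across a random two-coloring when a bipartite graph is
requested) plus density-controlled extra edges, one conversion reaction per
edge with log-uniform rate constants in `[0.1, 10]`, all molecules starting
on one species. It emulates the topological variety the theorems quantify
over — it does not emulate realistic kinetics, so property tests passing on
it support the combinatorial claims (existence iff bipartite, deficiency
zero, sandwich bounds), not biological realism.

## Problem sizes

Default test sizes: totals ≤ 4 on the benchmark networks, 100–200 seeded
random networks with `d ≤ 7` and small totals, brute-force oracles capped
at `n ≤ 8` edges (256 exact solves per network), and chromatin `ε`-sweeps
at `D_tot = 3` over `ε ∈ {10⁻², …, 10⁻⁵}` (35-state spaces). These sizes
already exercise every code path; the algorithms scale to `d ≲ 15` species
(enumeration is exponential only in the reduced vector count) and ~10⁴
projected states.

## A documented discrepancy

For the full chromatin circuit, the slow-chain lower bound on the
repressed-to-active passage scales as `ε⁻²`, which the package reproduces
(log-log slope 2.00). For the fast-chain *upper* bound on the same passage
the minimal downward rates are `O(ε)` on the `D_tot + 1` levels
`z = D_tot..2·D_tot`, so the dominant term of the downward closed form
carries `D_tot + 1` inverse-`ε` factors: the bound scales as
`ε^−(D_tot+1)` (measured slope 4.00 at `D_tot = 3`, `R² = 1.000`, and the
closed form agrees with an exact solve of the bounding chain to 1e−12).
An exponent of `D_tot` is sometimes quoted for this bound; the
implementation and its oracles support `D_tot + 1`, and the corresponding
acceptance assertion is left failing rather than adjusted. The bound
remains a valid (just loose) upper bound — the sandwich tests confirm it
brackets the exact passage time, whose scaling follows the `ε⁻²` side.

## Known limitations

* Enumeration cost is `2^(|V̂|−1)` exact solves per component; no heuristics
  are attempted for larger vector sets.
* Bounds address passages between the two *extreme* level sets only;
  intermediate targets and passage-time distributions are out of scope.
* Approximate level functions (`|L(v̌)| ≠ 1`) and non-mass-action kinetics
  are not supported.
* No SBML import; the JSON dialect and programmatic builders are the only
  input paths.
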