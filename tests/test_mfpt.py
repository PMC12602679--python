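"""Birth-death closed forms, exact solves, sandwich bounds, monotonicity."""

import math

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from scrnlevels import (
    BirthDeathSpec,
    birth_death_mfpt_down,
    birth_death_mfpt_up,
    bounding_generators,
    build_generator,
    cascade_hypoexp_mfpt,
    enumerate_level_functions,
    enumerate_state_space,
    exact_mfpt,
    exact_mfpt_all,
    level_bound_report,
    level_decomposition,
    level_rate_summary,
    scaling_exponent,
)
from scrnlevels import fixtures as fx
from scrnlevels.errors import (
    DegenerateSpaceError,
    EmptyLevelError,
    FeasibilityError,
    UndefinedBoundError,
)
from scrnlevels.mfpt import reflect
from conftest import pick_function


def birth_death_generator(spec: BirthDeathSpec) -> sp.csr_matrix:
    """Explicit tridiagonal generator of a birth-death chain (test oracle)."""
    m = spec.u - spec.ell + 1
    q = np.zeros((m, m))
    for i, lam in enumerate(spec.up_rates):
        q[i, i + 1] = lam
    for i, gam in enumerate(spec.down_rates):
        q[i + 1, i] = gam
    np.fill_diagonal(q, -q.sum(axis=1))
    return sp.csr_matrix(q)


class TestBirthDeathFormulas:
    def test_pure_birth_sum_of_means(self):
        spec = BirthDeathSpec(0, 5, up_rates=(2.0,) * 5, down_rates=(0.0,) * 5)
        assert birth_death_mfpt_up(spec) == pytest.approx(5 / 2.0)

    def test_three_state_chain(self):
        # independently solvable by first-step analysis: h0 = 3
        spec = BirthDeathSpec(0, 2, up_rates=(1.0, 1.0), down_rates=(1.0, 0.0))
        assert birth_death_mfpt_up(spec) == pytest.approx(3.0)

    def test_pure_death(self):
        spec = BirthDeathSpec(0, 4, up_rates=(0.0,) * 4, down_rates=(3.0,) * 4)
        assert birth_death_mfpt_down(spec) == pytest.approx(4 / 3.0)

    def test_three_state_down(self):
        spec = BirthDeathSpec(0, 2, up_rates=(0.0, 1.0), down_rates=(1.0, 1.0))
        assert birth_death_mfpt_down(spec) == pytest.approx(3.0)

    def test_zero_birth_rate_undefined(self):
        spec = BirthDeathSpec(0, 2, up_rates=(1.0, 0.0), down_rates=(1.0, 1.0))
        with pytest.raises(UndefinedBoundError):
            birth_death_mfpt_up(spec)

    @given(st.lists(st.floats(0.1, 10.0), min_size=2, max_size=8),
           st.lists(st.floats(0.1, 10.0), min_size=2, max_size=8))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_reflection_identity(self, ups, downs):
        span = min(len(ups), len(downs))
        spec = BirthDeathSpec(0, span, up_rates=tuple(ups[:span]),
                              down_rates=tuple(downs[:span]))
        assert birth_death_mfpt_down(spec) == pytest.approx(
            birth_death_mfpt_up(reflect(spec)), rel=1e-12)

    @given(st.lists(st.floats(0.05, 20.0), min_size=2, max_size=7),
           st.lists(st.floats(0.0, 20.0), min_size=2, max_size=7))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_formula_matches_linear_solve(self, ups, downs):
        """The nested-sum closed form equals first-step analysis on the
        explicit tridiagonal generator."""
        span = min(len(ups), len(downs))
        spec = BirthDeathSpec(0, span, up_rates=tuple(ups[:span]),
                              down_rates=tuple(downs[:span]))
        q = birth_death_generator(spec)
        assert birth_death_mfpt_up(spec) == pytest.approx(
            exact_mfpt(q, [span], 0), rel=1e-9)

    def test_degenerate_two_levels(self):
        spec = BirthDeathSpec(0, 1, up_rates=(2.5,), down_rates=(1.0,))
        assert birth_death_mfpt_up(spec) == pytest.approx(0.4)
        assert birth_death_mfpt_down(spec) == pytest.approx(1.0)


class TestExactMfpt:
    def test_two_state_chain(self):
        q = sp.csr_matrix(np.array([[-2.0, 2.0], [0.0, 0.0]]))
        assert exact_mfpt(q, [1], 0) == pytest.approx(0.5)

    def test_cascade_single_molecule(self):
        net = fx.cascade(alpha=2.0, beta=0.5, n_tot=1)
        space = enumerate_state_space(net)
        gen = build_generator(net, space)
        h = exact_mfpt(gen.Q, [space.index[(0, 1)]], space.index[(0, 0)])
        assert h == pytest.approx(1 / 2.0 + 1 / 0.5)

    def test_histone_symmetric_parameters(self):
        net = fx.histone(d_tot=2)  # fully symmetric defaults
        space = enumerate_state_space(net)
        gen = build_generator(net, space)
        a, r = space.index[(0, 2)], space.index[(2, 0)]
        h_ar = exact_mfpt(gen.Q, [r], a)
        h_ra = exact_mfpt(gen.Q, [a], r)
        assert h_ar == pytest.approx(h_ra, rel=1e-9)

    def test_unreachable_target(self):
        from scrnlevels.errors import UnreachableTargetError
        # absorbing two-state chain: state 1 cannot reach state 0
        q = sp.csr_matrix(np.array([[-1.0, 1.0], [0.0, 0.0]]))
        with pytest.raises(UnreachableTargetError):
            exact_mfpt(q, [0], 1)


class TestCascadeHypoexponential:
    def test_single_molecule(self):
        assert cascade_hypoexp_mfpt(2.0, 0.5, 1) == pytest.approx(2.5)
        assert cascade_hypoexp_mfpt(1.0, 1.0, 1) == pytest.approx(2.0)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("n_tot", [1, 2, 3, 4])
    def test_matches_exact_solve(self, alpha, beta, n_tot):
        net = fx.cascade(alpha=alpha, beta=beta, n_tot=n_tot)
        space = enumerate_state_space(net)
        gen = build_generator(net, space)
        start = space.index[(0, 0)]
        target = space.index[(0, n_tot)]
        exact = exact_mfpt(gen.Q, [target], start)
        assert cascade_hypoexp_mfpt(alpha, beta, n_tot) == \
            pytest.approx(exact, rel=1e-6)


class TestSandwich:
    def check(self, net, rel=1e-9):
        """Assert lower <= exact <= upper per defined direction for every
        enumerated level structure; returns the number of directions hit."""
        hits = 0
        try:
            functions = enumerate_level_functions(net)
        except DegenerateSpaceError:
            return 0
        for lf in functions:
            try:
                rep = level_bound_report(net, lf, compute_exact=True)
            except (DegenerateSpaceError, EmptyLevelError, FeasibilityError):
                continue
            if rep.up_defined:
                assert rep.lower_up <= rep.exact_up_min * (1 + rel) + 1e-12
                assert rep.exact_up_max <= rep.upper_up * (1 + rel) + 1e-12
                hits += 1
            if rep.down_defined:
                assert rep.lower_down <= rep.exact_down_min * (1 + rel) + 1e-12
                assert rep.exact_down_max <= rep.upper_down * (1 + rel) + 1e-12
                hits += 1
        return hits

    def test_fixtures(self):
        # minimum number of defined (level structure, direction) pairs per
        # fixture; the two-component network has an irreversible leg that
        # strands boundary states, so no direction is ever defined there
        builders = [
            (lambda: fx.cascade(alpha=1.3, beta=0.7, n_tot=4), 1),
            (lambda: fx.histone(d_tot=4, epsilon=0.5, mu=1.5), 2),
            (lambda: fx.full_chromatin(d_tot=3, epsilon=0.5, mu_prime=2.0), 2),
            (lambda: fx.biparallel(1.0, 2.0, 0.5, 1.5, s_tot=4), 1),
            (lambda: fx.two_component(n1=3, n2=3), 0),
            (lambda: fx.coupled(n1=3, n2=3, n3=2), 2),
        ]
        for builder, minimum in builders:
            assert self.check(builder()) >= minimum

    def test_random_bipartite_networks(self):
        total_hits = 0
        for seed in range(100):
            net = fx.random_unit_transfer(
                2 + seed % 5, seed=seed, bipartite=True,
                density=0.3, total=1 + seed % 3,
            )
            total_hits += self.check(net)
        assert total_hits >= 100

    def test_cascade_downward_undefined(self):
        net = fx.cascade(n_tot=2)
        lf = pick_function(enumerate_level_functions(net), (1, 2))
        rep = level_bound_report(net, lf)
        assert rep.up_defined and not rep.down_defined
        assert "down" in rep.notes


class TestBoundingChainConsistency:
    @pytest.mark.parametrize(
        "builder,coeffs",
        [(fx.cascade, (1, 2)), (fx.histone, (1, -1)),
         (fx.full_chromatin, (2, -1, 1, 1)), (fx.biparallel, (1, 1, 2))],
    )
    def test_formula_equals_bounding_chain_solve(self, builder, coeffs):
        """The closed-form bounds equal exact passage times of the bounding
        chains themselves (whose level processes are birth-death)."""
        net = builder()
        lf = pick_function(enumerate_level_functions(net), coeffs)
        space = enumerate_state_space(net, projection=lf.projection)
        gen = build_generator(net, space)
        dec = level_decomposition(lf, space, gen)
        summ = level_rate_summary(lf, space, gen, dec)
        fast, slow = bounding_generators(summ, space, gen)
        top = dec.level_sets[dec.u]
        bottom = dec.level_sets[dec.ell]

        def bd(up_key, down_key, fn):
            spec = BirthDeathSpec(
                dec.ell, dec.u,
                up_rates=tuple(getattr(summ, up_key)[z]
                               for z in range(dec.ell, dec.u)),
                down_rates=tuple(getattr(summ, down_key)[z]
                                 for z in range(dec.ell + 1, dec.u + 1)))
            return fn(spec)

        h_up_fast = exact_mfpt_all(fast, top)[bottom]
        assert bd("lam_max", "gam_min", birth_death_mfpt_up) == \
            pytest.approx(h_up_fast[0], rel=1e-9)
        if all(summ.gam_min[z] > 0 for z in range(dec.ell + 1, dec.u + 1)):
            h_down_fast = exact_mfpt_all(fast, bottom)[top]
            assert bd("lam_max", "gam_min", birth_death_mfpt_down) == \
                pytest.approx(h_down_fast[0], rel=1e-9)
            h_down_slow = exact_mfpt_all(slow, bottom)[top]
            assert bd("lam_min", "gam_max", birth_death_mfpt_down) == \
                pytest.approx(h_down_slow[0], rel=1e-9)


class TestMonotonicity:
    def test_cascade_bounds_and_exact_decrease_in_rates(self):
        grid = [0.5, 1.0, 1.5, 2.0, 2.5]
        n_tot = 2

        def compute(alpha, beta):
            net = fx.cascade(alpha=alpha, beta=beta, n_tot=n_tot)
            lf = pick_function(enumerate_level_functions(net), (1, 2))
            rep = level_bound_report(net, lf)
            return (rep.lower_up, rep.upper_up,
                    cascade_hypoexp_mfpt(alpha, beta, n_tot))

        table = {(a, b): compute(a, b) for a in grid for b in grid}
        for i, a in enumerate(grid[:-1]):
            for b in grid:
                for pos in range(3):  # lower, upper, exact all decrease
                    assert table[(grid[i + 1], b)][pos] < table[(a, b)][pos]
                    assert table[(b, grid[i + 1])][pos] < table[(b, a)][pos]

    def test_full_chromatin_mu_prime_monotonicity(self):
        reports = {}
        for mu_prime in (0.5, 1.0, 2.0):
            net = fx.full_chromatin(d_tot=2, mu_prime=mu_prime)
            lf = pick_function(enumerate_level_functions(net), (2, -1, 1, 1))
            reports[mu_prime] = level_bound_report(net, lf)
        for lo, hi in ((0.5, 1.0), (1.0, 2.0)):
            assert reports[hi].lower_up > reports[lo].lower_up
            assert reports[hi].upper_up > reports[lo].upper_up
            assert reports[hi].lower_down < reports[lo].lower_down
            assert reports[hi].upper_down < reports[lo].upper_down


class TestScalingExponent:
    def test_exact_powers(self):
        eps = np.array([1e-2, 1e-3, 1e-4, 1e-5])
        slope, r2 = scaling_exponent(eps, 3.0 / eps)
        assert slope == pytest.approx(1.0, abs=1e-9) and r2 == pytest.approx(1.0)
        slope, _ = scaling_exponent(eps, 0.7 / eps**2)
        assert slope == pytest.approx(2.0, abs=1e-9)

    def test_histone_bounds_scale_inversely_with_epsilon(self):
        eps_grid = [1e-2, 1e-3, 1e-4, 1e-5]
        lows, highs = [], []
        for eps in eps_grid:
            net = fx.histone(d_tot=2, epsilon=eps)
            lf = pick_function(enumerate_level_functions(net), (1, -1))
            rep = level_bound_report(net, lf)
            lows.append(rep.lower_up)
            highs.append(rep.upper_up)
        for vals in (lows, highs):
            slope, _ = scaling_exponent(eps_grid, vals)
            assert slope == pytest.approx(1.0, abs=0.1)

    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValueError):
            scaling_exponent([1e-2, 1e-3, 1e-4, 1e-5], [1.0, 2.0, 0.0, 3.0])
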