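"""Mean first passage times: closed-form birth-death bounds and exact solves.

The level process of each bounding chain is a birth-death process on the
integer levels ``ell..u``, so its hitting times have the classical nested-sum
closed form. Bracketing the true chain between the fast and slow bounding
chains gives four closed-form bounds per level structure:

* lower bound on the bottom-to-top passage: fast chain (max up, min down);
* upper bound on the bottom-to-top passage: slow chain (min up, max down);
* lower bound on the top-to-bottom passage: slow chain;
* upper bound on the top-to-bottom passage: fast chain.

Exact passage times for validation come from first-step analysis: restrict
the generator to non-target states and solve ``Q_rr h = -1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.integrate
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .coclique_enum import CocliqueLevelFunction
from .errors import UndefinedBoundError, UnreachableTargetError
from .network_model import ReactionNetwork
from .projected_chain import (
    GeneratorMatrix,
    LevelRateSummary,
    ProjectedStateSpace,
    build_generator,
    enumerate_state_space,
    level_decomposition,
    level_rate_summary,
)

__all__ = [
    "BirthDeathSpec",
    "MfptBoundReport",
    "birth_death_mfpt_up",
    "birth_death_mfpt_down",
    "reflect",
    "mfpt_bounds",
    "exact_mfpt",
    "exact_mfpt_all",
    "cascade_hypoexp_mfpt",
    "scaling_exponent",
    "level_bound_report",
]


@dataclass(frozen=True)
class BirthDeathSpec:
    """Rates of a birth-death chain on integer levels ``ell..u``.

    ``up_rates[i]`` is the birth rate at level ``ell + i`` (levels
    ``ell..u-1``); ``down_rates[i]`` the death rate at level ``ell + 1 + i``
    (levels ``ell+1..u``). Both arrays have length ``u - ell``.
    """

    ell: int
    u: int
    up_rates: tuple[float, ...]
    down_rates: tuple[float, ...]

    def __post_init__(self):
        if self.u <= self.ell:
            raise ValueError("need u > ell")
        span = self.u - self.ell
        if len(self.up_rates) != span or len(self.down_rates) != span:
            raise ValueError(f"rate arrays must have length u - ell = {span}")
        if any(r < 0 or not math.isfinite(r)
               for r in (*self.up_rates, *self.down_rates)):
            raise ValueError("rates must be finite and non-negative")


def reflect(spec: BirthDeathSpec) -> BirthDeathSpec:
    """Flip the chain upside down: level z maps to ell + u - z, so births
    become deaths and vice versa."""
    return BirthDeathSpec(
        ell=spec.ell,
        u=spec.u,
        up_rates=tuple(reversed(spec.down_rates)),
        down_rates=tuple(reversed(spec.up_rates)),
    )


def birth_death_mfpt_up(spec: BirthDeathSpec) -> float:
    """Expected time from the bottom level to the top level.

    Classical nested-sum form: sum over i of (1/lambda_i) times one plus the
    sum of cumulative products of gamma/lambda ratios above i. Requires every
    birth rate positive; death rates may vanish (pure birth collapses to the
    sum of exponential means).
    """
    lam = spec.up_rates
    gam = spec.down_rates  # gam[i] is the death rate at level ell+1+i
    span = spec.u - spec.ell
    if any(l <= 0 for l in lam):
        raise UndefinedBoundError(
            "a birth rate is zero between the levels; upward passage time "
            "is undefined (infinite)"
        )
    total = 0.0
    for i in range(span):
        inner = 1.0
        acc = 1.0
        for j in range(i + 1, span):
            acc *= gam[j - 1] / lam[j]
            inner += acc
            if acc == 0.0:
                break
        total += inner / lam[i]
    return total


def birth_death_mfpt_down(spec: BirthDeathSpec) -> float:
    """Expected time from the top level to the bottom level; the mirror of
    the upward formula under level reflection. Requires every death rate
    positive."""
    if any(g <= 0 for g in spec.down_rates):
        raise UndefinedBoundError(
            "a death rate is zero between the levels; downward passage time "
            "is undefined (infinite)"
        )
    return birth_death_mfpt_up(reflect(spec))


def _spec_from_summary(summary: LevelRateSummary, up_key: str, down_key: str
                       ) -> BirthDeathSpec:
    decomp = summary.decomposition
    ell, u = decomp.ell, decomp.u
    up = getattr(summary, up_key)
    down = getattr(summary, down_key)
    return BirthDeathSpec(
        ell=ell,
        u=u,
        up_rates=tuple(up[z] for z in range(ell, u)),
        down_rates=tuple(down[z] for z in range(ell + 1, u + 1)),
    )


@dataclass
class MfptBoundReport:
    """Four closed-form bounds, optional exact values, and validity notes."""

    ell: int
    u: int
    lower_up: float | None = None
    upper_up: float | None = None
    lower_down: float | None = None
    upper_down: float | None = None
    exact_up_min: float | None = None
    exact_up_max: float | None = None
    exact_down_min: float | None = None
    exact_down_max: float | None = None
    up_defined: bool = True
    down_defined: bool = True
    notes: dict[str, str] = field(default_factory=dict)
    level_function: CocliqueLevelFunction | None = None

    def to_dict(self) -> dict:
        out = {
            "level_range": [self.ell, self.u],
            "bounds": {
                "lower_up": self.lower_up,
                "upper_up": self.upper_up,
                "lower_down": self.lower_down,
                "upper_down": self.upper_down,
            },
            "up_defined": self.up_defined,
            "down_defined": self.down_defined,
            "notes": self.notes,
        }
        if self.exact_up_min is not None:
            out["exact_up"] = [self.exact_up_min, self.exact_up_max]
        if self.exact_down_min is not None:
            out["exact_down"] = [self.exact_down_min, self.exact_down_max]
        if self.level_function is not None:
            out["level_coefficients"] = [
                int(c) for c in self.level_function.coefficients
            ]
        return out


def mfpt_bounds(summary: LevelRateSummary) -> MfptBoundReport:
    """Evaluate the four birth-death bounds from the level-rate extrema.

    A direction whose positivity precondition fails is reported as undefined
    (note attached) rather than raising; the other direction is unaffected.
    """
    decomp = summary.decomposition
    report = MfptBoundReport(ell=decomp.ell, u=decomp.u,
                             level_function=summary.level_function)
    try:
        report.lower_up = birth_death_mfpt_up(
            _spec_from_summary(summary, "lam_max", "gam_min"))
        report.upper_up = birth_death_mfpt_up(
            _spec_from_summary(summary, "lam_min", "gam_max"))
    except UndefinedBoundError as exc:
        report.up_defined = False
        report.lower_up = report.upper_up = None
        report.notes["up"] = str(exc)
    try:
        report.lower_down = birth_death_mfpt_down(
            _spec_from_summary(summary, "lam_min", "gam_max"))
        report.upper_down = birth_death_mfpt_down(
            _spec_from_summary(summary, "lam_max", "gam_min"))
    except UndefinedBoundError as exc:
        report.down_defined = False
        report.lower_down = report.upper_down = None
        report.notes["down"] = str(exc)
    return report


def exact_mfpt_all(q: sp.spmatrix, target_states) -> np.ndarray:
    """Expected hitting time of the target set from every state.

    First-step analysis: h = 0 on targets and ``Q_rr h_r = -1`` on the rest.
    Raises UnreachableTargetError when the restricted system is singular or
    produces non-finite times.
    """
    n = q.shape[0]
    targets = np.asarray(sorted(set(int(t) for t in target_states)), dtype=int)
    if targets.size == 0 or targets.size == n:
        raise ValueError("target set must be a proper non-empty subset")
    keep = np.setdiff1d(np.arange(n), targets)
    q_rr = q.tocsr()[keep][:, keep]
    rhs = -np.ones(len(keep))
    import warnings

    try:
        with warnings.catch_warnings():
            # a singular restricted generator is diagnosed below, not a warning
            warnings.simplefilter("ignore", spla.MatrixRankWarning)
            h_r = spla.spsolve(q_rr.tocsc(), rhs)
    except RuntimeError as exc:
        raise UnreachableTargetError(str(exc)) from exc
    if not np.all(np.isfinite(h_r)) or np.any(h_r < -1e-9):
        raise UnreachableTargetError(
            "target set unreachable from part of the state space"
        )
    h = np.zeros(n)
    h[keep] = h_r
    return h


def exact_mfpt(q: sp.spmatrix, target_states, start_state: int) -> float:
    """Expected hitting time of the target set from one start state."""
    return float(exact_mfpt_all(q, target_states)[int(start_state)])


def cascade_hypoexp_mfpt(alpha: float, beta: float, n_tot: int) -> float:
    """Mean of the maximum of ``n_tot`` independent two-stage completion times.

    Each molecule converts through two sequential exponential stages with
    rates alpha and beta; the passage time of the whole pool is the maximum
    of the individual hypoexponential times, with mean
    ``integral of 1 - F(x)^n_tot``.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("rates must be positive")
    if n_tot < 1:
        raise ValueError("n_tot must be >= 1")

    if alpha == beta:
        def cdf(x):
            return 1.0 - math.exp(-alpha * x) * (1.0 + alpha * x)
    else:
        def cdf(x):
            return 1.0 - (beta * math.exp(-alpha * x)
                          - alpha * math.exp(-beta * x)) / (beta - alpha)

    val, _ = scipy.integrate.quad(
        lambda x: 1.0 - cdf(x) ** n_tot, 0.0, np.inf,
        epsabs=0.0, epsrel=1e-11, limit=200,
    )
    return float(val)


def scaling_exponent(scale_values, quantity_values) -> tuple[float, float]:
    """Least-squares slope of log(quantity) against log(1/scale).

    Returns (slope, R^2). A quantity growing like ``scale^-c`` yields slope c.
    """
    x = np.log(1.0 / np.asarray(scale_values, dtype=float))
    y = np.asarray(quantity_values, dtype=float)
    if np.any(y <= 0) or np.any(~np.isfinite(y)):
        raise ValueError("quantity values must be finite and positive")
    y = np.log(y)
    if len(x) < 4:
        raise ValueError("need at least four grid points")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2)) / float(ss_tot) if ss_tot > 0 else 1.0
    return float(slope), r2


def level_bound_report(
    net: ReactionNetwork,
    lf: CocliqueLevelFunction,
    totals: dict[int, int] | None = None,
    compute_exact: bool = False,
) -> MfptBoundReport:
    """End-to-end pipeline: state space, generator, level structure, bounds,
    and (optionally) exact passage times between the extreme levels.

    Exact values are reported as the min and max over the starting extreme
    level set, each computed by a sparse linear solve.
    """
    space = enumerate_state_space(net, totals=totals,
                                  projection=lf.projection)
    gen = build_generator(net, space)
    decomp = level_decomposition(lf, space, gen)
    summary = level_rate_summary(lf, space, gen, decomp)
    report = mfpt_bounds(summary)
    if compute_exact:
        bottom = decomp.level_sets[decomp.ell]
        top = decomp.level_sets[decomp.u]
        if report.up_defined:
            h = exact_mfpt_all(gen.Q, top)[bottom]
            report.exact_up_min, report.exact_up_max = float(h.min()), float(h.max())
        if report.down_defined:
            h = exact_mfpt_all(gen.Q, bottom)[top]
            report.exact_down_min, report.exact_down_max = float(h.min()), float(h.max())
    return report
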