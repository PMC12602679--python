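"""Exact rational linear algebra on small integer matrices.

The enumeration theory rests on exact claims: the sign-pattern system has
zero or one solution and an existing solution is integral; rank plus left
nullity equals the species count. Floating point cannot certify these, so
rank, solves and null spaces here run over `fractions.Fraction`. Matrices are
tiny (tens of rows), so simple Gauss-Jordan elimination is more than fast
enough and avoids heavier symbolic machinery in the hot enumeration loop.
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd

import numpy as np

__all__ = ["rank", "solve_unique", "left_nullspace_basis"]


def _to_rows(a) -> list[list[Fraction]]:
    return [[Fraction(int(x)) for x in row] for row in np.asarray(a)]


def _rref(rows: list[list[Fraction]]) -> tuple[list[list[Fraction]], list[int]]:
    """Reduced row echelon form in place; returns (rows, pivot columns)."""
    if not rows:
        return rows, []
    m, n = len(rows), len(rows[0])
    pivots: list[int] = []
    r = 0
    for c in range(n):
        pivot = next((i for i in range(r, m) if rows[i][c] != 0), None)
        if pivot is None:
            continue
        rows[r], rows[pivot] = rows[pivot], rows[r]
        inv = 1 / rows[r][c]
        rows[r] = [x * inv for x in rows[r]]
        for i in range(m):
            if i != r and rows[i][c] != 0:
                f = rows[i][c]
                rows[i] = [x - f * y for x, y in zip(rows[i], rows[r])]
        pivots.append(c)
        r += 1
        if r == m:
            break
    return rows, pivots


def rank(a) -> int:
    """Exact rank of an integer matrix."""
    _, pivots = _rref(_to_rows(a))
    return len(pivots)


def solve_unique(a, b) -> list[Fraction] | None:
    """Solve the (possibly overdetermined) system ``a x = b`` exactly.

    Returns the unique solution, or None if the system is inconsistent.
    Raises ValueError if the solution is not unique (column-rank deficient).
    """
    a = np.asarray(a)
    m, n = a.shape
    rows = [[Fraction(int(a[i, j])) for j in range(n)] + [Fraction(int(b[i]))]
            for i in range(m)]
    rows, pivots = _rref(rows)
    if n in pivots:  # pivot in the augmented column -> inconsistent
        return None
    if len(pivots) < n:
        raise ValueError("system is underdetermined; solution not unique")
    x: list[Fraction] = [Fraction(0)] * n
    for r, c in enumerate(pivots):
        x[c] = rows[r][n]
    return x


def _normalize_integer(vec: list[Fraction]) -> np.ndarray:
    """Scale a rational vector to coprime integers with positive leading entry."""
    denoms = [f.denominator for f in vec]
    lcm = 1
    for d in denoms:
        lcm = lcm * d // gcd(lcm, d)
    ints = [int(f * lcm) for f in vec]
    g = 0
    for x in ints:
        g = gcd(g, abs(x))
    if g > 1:
        ints = [x // g for x in ints]
    lead = next((x for x in ints if x != 0), 1)
    if lead < 0:
        ints = [-x for x in ints]
    return np.array(ints, dtype=int)


def left_nullspace_basis(s) -> list[np.ndarray]:
    """Canonical basis of {m : m^T S = 0} for an integer matrix S.

    Basis vectors are the RREF rows of the left null space, each scaled to
    coprime integer entries with positive leading coefficient, ordered by
    leading index. Empty list if the left null space is trivial.
    """
    s = np.asarray(s)
    d = s.shape[0]
    # kernel of S^T via RREF of S^T
    rows, pivots = _rref(_to_rows(s.T))
    free = [c for c in range(d) if c not in pivots]
    basis = []
    for fc in free:
        v = [Fraction(0)] * d
        v[fc] = Fraction(1)
        for r, c in enumerate(pivots):
            v[c] = -rows[r][fc]
        basis.append(v)
    if not basis:
        return []
    # canonicalize: RREF of the stacked basis, then integer-scale each row
    brows, bpiv = _rref(basis)
    return [_normalize_integer(brows[r]) for r in range(len(bpiv))]
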