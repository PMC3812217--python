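"""Exact rational linear algebra primitives.

All flux algebra in this package is exact: stoichiometric coefficients are
:class:`fractions.Fraction` (almost always integers) and every rank / nullspace
computation is done by fraction-free style Gaussian elimination over the
rationals.  No tolerance parameter exists anywhere.

Matrices are plain lists of lists of ``Fraction`` (row-major).  The functions
here are deliberately small and dependency-free because they sit in the inner
loop of the double-description step and of the brute-force oracle.
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd
from typing import Sequence

Row = list[Fraction]
Matrix = list[Row]


def _as_fraction_matrix(mat: Sequence[Sequence]) -> Matrix:
    return [[Fraction(x) for x in row] for row in mat]


def rref(mat: Sequence[Sequence]) -> tuple[Matrix, list[int]]:
    """Reduced row echelon form.

    Returns ``(R, pivots)`` where ``pivots[i]`` is the column of the leading 1
    in row ``i`` of ``R``.
    """
    m = _as_fraction_matrix(mat)
    if not m:
        return [], []
    nrows, ncols = len(m), len(m[0])
    pivots: list[int] = []
    r = 0
    for c in range(ncols):
        # partial "pivoting": any nonzero entry works over Q; take the first
        pivot_row = next((i for i in range(r, nrows) if m[i][c] != 0), None)
        if pivot_row is None:
            continue
        m[r], m[pivot_row] = m[pivot_row], m[r]
        pv = m[r][c]
        if pv != 1:
            m[r] = [x / pv for x in m[r]]
        for i in range(nrows):
            if i != r and m[i][c] != 0:
                f = m[i][c]
                m[i] = [a - f * b for a, b in zip(m[i], m[r])]
        pivots.append(c)
        r += 1
        if r == nrows:
            break
    return m, pivots


def rank(mat: Sequence[Sequence]) -> int:
    if not mat or not mat[0]:
        return 0
    return len(rref(mat)[1])


def nullspace_with_free(
    mat: Sequence[Sequence], ncols: int
) -> tuple[list[list[Fraction]], list[int]]:
    """Nullspace basis of ``mat`` plus the free-column indices.

    The basis has the conventional RREF structure: one vector per free column
    (in free-column order), with value 1 in its own free column and 0 in every
    other free column.  Vectors are scaled to coprime integers, which keeps
    the entry in the vector's own free column positive.
    """
    if ncols == 0:
        return [], []
    if not mat:
        return [integerize(unit(ncols, j)) for j in range(ncols)], list(range(ncols))
    red, pivots = rref(mat)
    free = [c for c in range(ncols) if c not in pivots]
    basis: list[list[Fraction]] = []
    for f in free:
        v = [Fraction(0)] * ncols
        v[f] = Fraction(1)
        for i, p in enumerate(pivots):
            v[p] = -red[i][f]
        basis.append(integerize(v))
    return basis, free


def nullspace_basis(mat: Sequence[Sequence], ncols: int) -> list[list[Fraction]]:
    """Basis of the right nullspace of ``mat`` (``ncols`` columns)."""
    return nullspace_with_free(mat, ncols)[0]


def unit(n: int, j: int) -> list[Fraction]:
    v = [Fraction(0)] * n
    v[j] = Fraction(1)
    return v


def integerize(v: Sequence[Fraction]) -> list[Fraction]:
    """Scale a rational vector to coprime integer entries (sign preserved)."""
    denoms = [x.denominator for x in v if x != 0]
    if not denoms:
        return [Fraction(0) for _ in v]
    from math import lcm

    scale = 1
    for d in denoms:
        scale = lcm(scale, d)
    ints = [int(x * scale) for x in v]
    g = 0
    for x in ints:
        g = gcd(g, abs(x))
    if g > 1:
        ints = [x // g for x in ints]
    return [Fraction(x) for x in ints]
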