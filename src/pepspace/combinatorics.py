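"""Closed-form counting of peptide-generation events.

For a substrate of length ``L`` and a peptide length ``N``, the number of
non-spliced, forward/reverse cis-spliced and trans-spliced peptide *events*
admits exact closed forms obtained by summing over the four splice-reactant
coordinates (i, j) and (k, n).  ``Lext`` is the minimal splice-reactant
length (default 1) and ``Imax`` caps the intervening-sequence length between
the two reactants.  Every closed form here is validated against the
brute-force tuple enumerator :func:`enumerate_splice_events`.

Conventions (shared with :mod:`pepspace.splicing`):

* forward cis: first reactant [i..j] upstream of second [k..n]; the
  intervening length k-j-1 is at least 1 (a gap of 0 would reproduce a
  contiguous non-spliced peptide);
* reverse cis: second reactant [k..n] upstream of first [i..j]; the
  intervening length i-n-1 may be 0 (adjacent reverse-order ligation is a
  genuine rearrangement);
* reactant intervals never overlap.

The Imax-restricted closed forms apply only when the cap binds, i.e. when
``Imax < L - N`` (the maximum achievable intervening length); otherwise the
unrestricted forms hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import sympy

ALPHABET_SIZE = 20
"""Number of distinct residues assumed when bounding unique sequences."""

INF = math.inf


@dataclass(frozen=True)
class SpliceCountParams:
    """Parameter bundle for the analytic splice-counting formulas.

    L, L1, L2 : substrate lengths (residues); N : peptide length;
    Lext : minimal splice-reactant length; Imax : maximum intervening
    length (``math.inf`` for no cap); M : number of splicing events used
    by :func:`expected_unique`.
    """

    L: int = 0
    L1: int = 0
    L2: int = 0
    N: int = 0
    Lext: int = 1
    Imax: float = INF
    M: int = 0

    def __post_init__(self) -> None:
        if self.Lext < 1:
            raise ValueError("Lext must be >= 1")
        for name in ("L", "L1", "L2", "N", "M"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def count_nonspliced(L: int, N: int) -> int:
    """Number of contiguous N-mers in a substrate of length L."""
    if L < N or N < 1:
        return 0
    return L - N + 1


def _cap_binds(L: int, N: int, Imax: float) -> bool:
    # Maximum achievable intervening length on a length-L substrate is L - N.
    return Imax < L - N


def count_cis_forward(L: int, N: int, Lext: int = 1, Imax: float = INF) -> int:
    """Number of forward cis-spliced peptide events (intervening >= 1)."""
    A = N - 2 * Lext + 1
    if A <= 0 or L < N:
        return 0
    if L == N:
        return 0
    if _cap_binds(L, N, Imax):
        return int(-Fraction(1, 2) * int(Imax) * A * (int(Imax) - 2 * L + 2 * N - 1))
    return int(Fraction(1, 2) * A * (L - N) * (L - N + 1))


def count_cis_reverse(L: int, N: int, Lext: int = 1, Imax: float = INF) -> int:
    """Number of reverse cis-spliced peptide events (intervening >= 0)."""
    A = N - 2 * Lext + 1
    if A <= 0 or L < N:
        return 0
    if _cap_binds(L, N, Imax):
        return int(A * (int(Imax) + 1) * (1 - Fraction(int(Imax), 2) + L - N))
    return int(Fraction(1, 2) * A * (L - N + 1) * (L - N + 2))


def count_cis_total(L: int, N: int, Lext: int = 1, Imax: float = INF) -> int:
    """Forward plus reverse cis-spliced event count."""
    return count_cis_forward(L, N, Lext, Imax) + count_cis_reverse(L, N, Lext, Imax)


def count_trans(L1: int, L2: int, N: int, Lext: int = 1) -> int:
    """Number of trans-spliced events with reactant 1 from protein 1.

    The first reactant length SR1 runs over [max(Lext, N-L2),
    min(L1, N-Lext)]; each term contributes (L1-SR1+1)(L2-N+SR1+1)
    placements.  Negative sums are clipped to zero (empty range).
    """
    sr1_min = max(Lext, N - L2)
    sr1_max = min(L1, N - Lext)
    x = sum(
        (L1 - sr1 + 1) * (L2 - N + sr1 + 1) for sr1 in range(sr1_min, sr1_max + 1)
    )
    return max(0, x)


def enumerate_splice_events(
    L: int, N: int, Lext: int = 1, Imax: float = INF, direction: str = "forward"
) -> int:
    """Brute-force count of valid (i, j, k, n) splice-reactant tuples.

    Enumerates, for every split of N into two reactant lengths (a, N-a)
    with a >= Lext and N-a >= Lext, every placement pair on a boolean grid
    and counts tuples satisfying the gap and bounds constraints.  Guarded
    to L <= 200 to keep the enumeration honest and cheap.
    """
    if L > 200:
        raise ValueError("enumeration oracle guarded to L <= 200")
    if direction not in {"forward", "reverse"}:
        raise ValueError(f"unknown direction {direction!r}")
    if L < N:
        return 0
    total = 0
    for a in range(Lext, N - Lext + 1):
        b = N - a
        # first reactant start i (1-based), second reactant start k
        i = np.arange(1, L - a + 2)[:, None]
        k = np.arange(1, L - b + 2)[None, :]
        j = i + a - 1
        n = k + b - 1
        if direction == "forward":
            gap = k - j - 1
            valid = (gap >= 1) & (n <= L)
        else:
            gap = i - n - 1
            valid = (gap >= 0) & (j <= L)
        if Imax != INF:
            valid &= gap <= Imax
        total += int(valid.sum())
    return total


def enumerate_trans_events(L1: int, L2: int, N: int, Lext: int = 1) -> int:
    """Brute-force count of trans placements (oracle for :func:`count_trans`)."""
    total = 0
    for a in range(Lext, N - Lext + 1):
        b = N - a
        if a <= L1 and b <= L2:
            total += (L1 - a + 1) * (L2 - b + 1)
    return total


def expected_unique(N: int, M: int, exact: bool = False):
    """Upper bound on unique length-N sequences after M independent events.

    Assumes every event samples uniformly with replacement from the
    20**N possible sequences:  20**N * (1 - (1 - 20**-N)**M).  Evaluated
    symbolically (the binomial term is never expanded), so M may exceed
    10**15 without loss of precision.  With ``exact=True`` the sympy
    expression is returned instead of a float.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if M < 0:
        raise ValueError("M must be >= 0")
    space = sympy.Integer(ALPHABET_SIZE) ** N
    # the power is kept unevaluated: expanding the exact rational is
    # infeasible for large M, while evalf handles it at any precision
    binom = sympy.Pow(1 - sympy.Rational(1, space), sympy.Integer(M), evaluate=False)
    expr = space * (1 - binom)
    if exact:
        return expr
    return float(expr.evalf(50))


def count_grid(
    L_values, N_values, Lext_values=(1,), Imax_values=(25,)
):
    """Tabulate analytic counts over a parameter grid.

    Returns a pandas DataFrame with one row per (L, N, Lext, Imax)
    combination and columns for non-spliced, forward/reverse/total cis
    counts; used by the CLI to chart search-space inflation.
    """
    import pandas as pd

    rows = []
    for L in L_values:
        for N in N_values:
            for Lext in Lext_values:
                for Imax in Imax_values:
                    rows.append(
                        {
                            "L": L,
                            "N": N,
                            "Lext": Lext,
                            "Imax": Imax,
                            "nonspliced": count_nonspliced(L, N),
                            "cis_forward": count_cis_forward(L, N, Lext, Imax),
                            "cis_reverse": count_cis_reverse(L, N, Lext, Imax),
                            "cis_total": count_cis_total(L, N, Lext, Imax),
                        }
                    )
    return pd.DataFrame(rows)
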