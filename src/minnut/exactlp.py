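"""Exact rational linear feasibility via phase-1 simplex.

All arithmetic is over `fractions.Fraction`; Bland's anti-cycling rule makes
termination unconditional.  The solver decides feasibility of a conjunction of
homogeneous-or-unit-right-hand-side linear constraints

    sum_j a_j x_j  {>=, =}  b        (b any rational)

over variables that are individually non-negative or sign-free, and returns an
exact witness when feasible.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

__all__ = ["LinearConstraint", "solve_feasibility", "PivotLimitExceeded"]

ZERO = Fraction(0)
ONE = Fraction(1)


class PivotLimitExceeded(Exception):
    """Raised when the pivot budget is exhausted (should not happen with
    Bland's rule; kept as a defensive guard)."""


@dataclass(frozen=True)
class LinearConstraint:
    """``coeffs · x  rel  rhs`` with rel in {">=", "="}."""

    coeffs: tuple[tuple[str, Fraction], ...]
    rel: str
    rhs: Fraction = ZERO

    def __post_init__(self) -> None:
        if self.rel not in (">=", "="):
            raise ValueError(f"unsupported relation {self.rel!r}")


def solve_feasibility(
    variables: Mapping[str, str],
    constraints: Sequence[LinearConstraint],
    max_pivots: int = 2_000_000,
) -> dict[str, Fraction] | None:
    """Return an exact witness assignment, or None if infeasible.

    ``variables`` maps variable name -> "nonneg" | "free".
    """
    var_names = list(variables)
    # Column layout: for non-negative variables one column; free variables are
    # written as the difference of two non-negative columns.
    col_of: dict[str, tuple[int, int | None]] = {}
    n_cols = 0
    for name in var_names:
        sign = variables[name]
        if sign == "nonneg":
            col_of[name] = (n_cols, None)
            n_cols += 1
        elif sign == "free":
            col_of[name] = (n_cols, n_cols + 1)
            n_cols += 2
        else:
            raise ValueError(f"unknown sign {sign!r} for variable {name!r}")

    rows: list[list[Fraction]] = []
    rhs: list[Fraction] = []
    n_slacks = sum(1 for c in constraints if c.rel == ">=")
    slack_base = n_cols
    total_cols = n_cols + n_slacks

    slack_idx = 0
    for con in constraints:
        row = [ZERO] * total_cols
        for name, coeff in con.coeffs:
            if name not in col_of:
                raise KeyError(f"constraint references unknown variable {name!r}")
            plus, minus = col_of[name]
            row[plus] += coeff
            if minus is not None:
                row[minus] -= coeff
        if con.rel == ">=":
            row[slack_base + slack_idx] = -ONE
            slack_idx += 1
        b = con.rhs
        if b < 0:
            row = [-v for v in row]
            b = -b
        rows.append(row)
        rhs.append(b)

    m = len(rows)
    if m == 0:
        return {name: ZERO for name in var_names}

    # Append artificial variables and canonicalize the phase-1 objective
    # (minimize the sum of artificials, expressed as reduced costs).
    art_base = total_cols
    for i, row in enumerate(rows):
        row.extend(ONE if k == i else ZERO for k in range(m))
    basis = [art_base + i for i in range(m)]
    obj = [ZERO] * (total_cols + m)
    obj_val = ZERO
    for i, row in enumerate(rows):
        for j in range(total_cols):
            obj[j] += row[j]
        obj_val += rhs[i]

    pivots = 0
    while True:
        # Bland: entering column = lowest-index non-artificial column with a
        # positive reduced cost.
        enter = -1
        for j in range(total_cols):
            if obj[j] > 0:
                enter = j
                break
        if enter < 0:
            break
        # Ratio test, Bland tie-break on basis index.
        leave = -1
        best = None
        for i in range(m):
            a = rows[i][enter]
            if a > 0:
                ratio = rhs[i] / a
                if best is None or ratio < best or (
                    ratio == best and basis[i] < basis[leave]
                ):
                    best = ratio
                    leave = i
        if leave < 0:
            # Unbounded improvement of a phase-1 objective cannot occur; the
            # objective is bounded below by zero.  Defensive guard only.
            raise PivotLimitExceeded("phase-1 objective unbounded (internal error)")
        pivots += 1
        if pivots > max_pivots:
            raise PivotLimitExceeded(f"exceeded {max_pivots} pivots")

        piv = rows[leave][enter]
        if piv != 1:
            rows[leave] = [v / piv if v else v for v in rows[leave]]
            rhs[leave] /= piv
        prow = rows[leave]
        pb = rhs[leave]
        # Sparse row updates: skip zero pivot-row entries.
        nonzero = [j for j, pv in enumerate(prow) if pv]
        for i in range(m):
            factor = rows[i][enter]
            if i != leave and factor != 0:
                row = rows[i]
                for j in nonzero:
                    row[j] -= factor * prow[j]
                if pb:
                    rhs[i] -= factor * pb
        factor = obj[enter]
        if factor != 0:
            for j in nonzero:
                obj[j] -= factor * prow[j]
            if pb:
                obj_val -= factor * pb
        basis[leave] = enter

    if obj_val != 0:
        return None

    values = [ZERO] * (total_cols + m)
    for i, b in enumerate(basis):
        values[b] = rhs[i]
    witness: dict[str, Fraction] = {}
    for name in var_names:
        plus, minus = col_of[name]
        witness[name] = values[plus] - (values[minus] if minus is not None else ZERO)
    return witness
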