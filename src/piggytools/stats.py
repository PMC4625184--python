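"""Exact Fisher test on 2x2 contingency tables.

The two-sided p-value follows the standard convention: with all margins
fixed, sum the hypergeometric probabilities of every table whose point
probability is at most that of the observed table.  Probabilities are
handled as exact integer binomial-coefficient weights sharing the common
denominator C(N, n), so the inclusion rule involves no floating-point
tolerance; the single final division is correctly rounded.
"""

from __future__ import annotations

from math import comb, inf


class DegenerateTableError(ValueError):
    """A row or column margin of the table is zero."""


def _cells(table) -> tuple[int, int, int, int]:
    try:
        (a, b), (c, d) = table  # nested 2x2
    except (TypeError, ValueError):
        a, b, c, d = table  # flat
    for x in (a, b, c, d):
        if int(x) != x or x < 0:
            raise ValueError("table cells must be non-negative integers")
    return int(a), int(b), int(c), int(d)


def fisher_exact(table, alternative: str = "two-sided") -> float:
    """Exact Fisher p-value for a 2x2 table.

    Parameters
    ----------
    table
        ``[[a, b], [c, d]]`` (or a flat 4-tuple) of non-negative integer
        counts; all row and column margins must be positive.
    alternative
        ``"two-sided"`` (default), ``"greater"`` or ``"less"``, referring
        to the odds ratio of the first row versus the second.
    """
    a, b, c, d = _cells(table)
    n_row1, n_row2 = a + b, c + d
    n_col1, n_col2 = a + c, b + d
    if min(n_row1, n_row2, n_col1, n_col2) == 0:
        raise DegenerateTableError("degenerate table: a margin is zero")
    n_total = a + b + c + d

    lo = max(0, n_col1 - n_row2)
    hi = min(n_row1, n_col1)
    # integer weights: w(x) = C(row1, x) * C(row2, col1 - x)
    weights = [comb(n_row1, x) * comb(n_row2, n_col1 - x) for x in range(lo, hi + 1)]
    denom = comb(n_total, n_col1)
    w_obs = weights[a - lo]

    if alternative == "two-sided":
        num = sum(w for w in weights if w <= w_obs)
    elif alternative == "greater":
        num = sum(weights[a - lo :])
    elif alternative == "less":
        num = sum(weights[: a - lo + 1])
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(num / denom, 1.0)


def odds_ratio(table) -> float:
    """Sample odds ratio (a*d)/(b*c); inf when b*c == 0."""
    a, b, c, d = _cells(table)
    if b * c == 0:
        return inf if a * d > 0 else float("nan")
    return (a * d) / (b * c)
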