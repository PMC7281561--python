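"""Exact and elementary statistics used throughout the pipeline.

The two-sided Fisher exact test uses the point-probability rule: the
p-value is the sum of hypergeometric probabilities of every table with
the observed margins whose point probability does not exceed that of the
observed table.  For the table sizes this pipeline produces, the
hypergeometric weights are computed with exact integer arithmetic
(``fractions.Fraction``) and converted to float once at the end, so the
result is bit-reproducible across platforms; very large tables fall back
to log-gamma evaluation.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, lgamma, exp
from typing import Union

from .types import Table2x2

__all__ = ["fisher_exact_two_sided", "percent_change"]

_EXACT_LIMIT = 2000  # grand total above which we switch to log-gamma


def _as_table(t, b=None, c=None, d=None) -> Table2x2:
    if isinstance(t, Table2x2):
        return t
    return Table2x2(t, b, c, d)


def fisher_exact_two_sided(table: Union[Table2x2, int], b: int = None,
                           c: int = None, d: int = None) -> float:
    """Two-sided Fisher exact test p-value for a 2x2 table.

    Accepts either a :class:`Table2x2` or four counts ``a, b, c, d``
    (rows = groups, columns = outcome yes/no).
    """
    t = _as_table(table, b, c, d)
    if t.total == 0:
        raise ValueError("table: all-zero table has no defined test")
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    n = t.total
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if lo == hi:  # a single attainable table: p = 1
        return 1.0

    if n <= _EXACT_LIMIT:
        denom = comb(n, c1)
        probs = [Fraction(comb(r1, a) * comb(r2, c1 - a), denom) for a in range(lo, hi + 1)]
        p_obs = probs[t.a - lo]
        return float(sum(p for p in probs if p <= p_obs))

    log_denom = lgamma(n + 1) - lgamma(c1 + 1) - lgamma(n - c1 + 1)

    def logp(a: int) -> float:
        return (lgamma(r1 + 1) - lgamma(a + 1) - lgamma(r1 - a + 1)
                + lgamma(r2 + 1) - lgamma(c1 - a + 1) - lgamma(r2 - c1 + a + 1)
                - log_denom)

    lp_obs = logp(t.a)
    total = 0.0
    for a in range(lo, hi + 1):
        lp = logp(a)
        if lp <= lp_obs + 1e-10:  # relative tolerance against roundoff ties
            total += exp(lp)
    return min(total, 1.0)


def percent_change(before: float, after: float) -> float:
    """Percent change 100*(after - before)/before; positive = increase."""
    if before == 0:
        raise ValueError("before: percent change is undefined for a zero reference")
    return 100.0 * (after - before) / before
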