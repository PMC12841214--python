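"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: exact rational
arithmetic instead of log-space floats, direct triple loops instead of
recursive enumeration, and an explicit restatement of the tie rule instead
of the Counter-based mode.
"""

from fractions import Fraction
from math import comb

from ifra import Stratum


def brute_force_freeman_halton(table) -> float:
    """Two-sided exact p for a 2x3 table by exact Fraction arithmetic.

    Probability of a candidate first row (t0, t1, t2) under fixed margins is
    prod_j C(c_j, t_j) / C(N, r1); the p-value sums candidates with
    probability <= the observed table's (exact comparison).
    """
    (a, b, c), (d, e, f) = table
    cols = (a + d, b + e, c + f)
    r1 = a + b + c
    n = sum(cols)

    def prob(t):
        num = comb(cols[0], t[0]) * comb(cols[1], t[1]) * comb(cols[2], t[2])
        return Fraction(num, comb(n, r1))

    p_obs = prob((a, b, c))
    total = Fraction(0)
    for t0 in range(min(r1, cols[0]) + 1):
        for t1 in range(min(r1 - t0, cols[1]) + 1):
            t2 = r1 - t0 - t1
            if t2 <= cols[2]:
                p = prob((t0, t1, t2))
                if p <= p_obs:
                    total += p
    return float(min(total, Fraction(1)))


def two_sided_hypergeometric(k: int, n1: int, n2: int, r1: int) -> float:
    """Closed-form two-sided 2x2 hypergeometric p (probability ordering).

    ``k`` successes of column 1 in row 1, column sums ``n1``/``n2``, row-1
    total ``r1``; exact Fractions throughout.
    """
    n = n1 + n2

    def pmf(x):
        return Fraction(comb(n1, x) * comb(n2, r1 - x), comb(n, r1))

    p_obs = pmf(k)
    total = sum(
        (pmf(x) for x in range(max(0, r1 - n2), min(r1, n1) + 1) if pmf(x) <= p_obs),
        Fraction(0),
    )
    return float(min(total, Fraction(1)))


def mode_highest_on_ties(strata) -> Stratum:
    """Restated combination rule: walk strata from high to low and return the
    first whose frequency equals the maximum frequency."""
    strata = list(strata)
    best_count = max(strata.count(s) for s in Stratum)
    for s in (Stratum.high, Stratum.medium, Stratum.low):
        if strata.count(s) == best_count:
            return s
    raise AssertionError("unreachable")
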