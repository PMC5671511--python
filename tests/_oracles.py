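"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the Fisher oracle
enumerates the hypergeometric distribution from the factorial definition in
exact rational arithmetic, rather than via binomial-coefficient weights.
"""

from fractions import Fraction
from functools import lru_cache
from math import factorial


@lru_cache(maxsize=None)
def _fact(n: int) -> int:
    return factorial(n)


def hypergeom_pmf_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """P of the table [[a, b], [c, d]] under fixed margins, as a Fraction."""
    n = a + b + c + d
    return Fraction(
        _fact(a + b) * _fact(c + d) * _fact(a + c) * _fact(b + d),
        _fact(n) * _fact(a) * _fact(b) * _fact(c) * _fact(d),
    )


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by enumerating all tables with fixed margins.

    Sums the probability of every table whose exact probability is <= the
    observed table's; ties are exact rational comparisons.
    """
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == r1 + r2:
        return 1.0
    observed = hypergeom_pmf_exact(a, b, c, d)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = hypergeom_pmf_exact(x, r1 - x, c1 - x, r2 - (c1 - x))
        if p <= observed:
            total += p
    return float(min(total, Fraction(1)))


def all_tables_with_margins_at_most(limit: int):
    """Yield every 2x2 table (a, b, c, d) whose four margins are all <= limit."""
    for r1 in range(limit + 1):
        for r2 in range(limit + 1):
            for c1 in range(min(limit, r1 + r2) + 1):
                if r1 + r2 - c1 > limit:
                    continue
                for a in range(max(0, c1 - r2), min(r1, c1) + 1):
                    yield a, r1 - a, c1 - a, r2 - (c1 - a)
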