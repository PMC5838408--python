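"""Independent brute-force oracles used only by the tests.

These are written against the definitions, not against the library code
they check: exact rational arithmetic over integer binomial
coefficients for the hypergeometric upper tail and the two-sided Fisher
exact test, and a one-pass counting recount for per-gene aggregation.
"""

from __future__ import annotations

from collections import Counter
from fractions import Fraction
from math import comb


def hypergeom_upper_tail_oracle(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by exact summation of the probability mass."""
    denom = comb(N, n)
    total = Fraction(0)
    for j in range(k, min(n, K) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), denom)
    return float(total)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by margin-conditional enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (exact rational
    comparison, so ties are included without floating-point slack).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return float(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs))


def recount_oracle(rows) -> dict[str, Counter]:
    """One-pass per-gene recount of classified variant rows.

    ``rows`` is an iterable of (gene, variant_class) pairs; returns
    gene -> Counter of class tallies.
    """
    out: dict[str, Counter] = {}
    for gene, cls in rows:
        out.setdefault(gene, Counter())[cls] += 1
    return out
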