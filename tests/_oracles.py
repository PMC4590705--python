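"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and scipy's
hypergeometric routines) so they can serve as dual-route checks.
"""

from fractions import Fraction
from functools import lru_cache
from itertools import combinations


@lru_cache(maxsize=None)
def enumeration_cdf_table(n: int, n_a: int, n_b: int) -> tuple[Fraction, ...]:
    """Exact P[X <= k] for k = 0..min(n_a, n_b) by subset enumeration.

    Enumerates every size-n_b subset of an n-sample universe whose first
    n_a members carry the gene-A event, counting the overlap of each
    subset with the marked block.
    """
    marked = set(range(n_a))
    kmax = min(n_a, n_b)
    counts = [0] * (kmax + 1)
    total = 0
    for subset in combinations(range(n), n_b):
        counts[len(marked.intersection(subset))] += 1
        total += 1
    cdf = []
    running = 0
    for k in range(kmax + 1):
        running += counts[k]
        cdf.append(Fraction(running, total))
    return tuple(cdf)


def enumeration_pvalue(n: int, n_a: int, n_b: int, n_ab: int) -> float:
    """Exact exclusivity p-value P[X <= n_ab] via enumeration."""
    return float(enumeration_cdf_table(n, n_a, n_b)[n_ab])


def pearson_chi2_by_hand(table) -> float:
    """Sum of (O - E)^2 / E computed with plain Python arithmetic."""
    (a, b), (c, d) = table
    total = a + b + c + d
    stat = 0.0
    for obs, rowsum, colsum in (
        (a, a + b, a + c),
        (b, a + b, b + d),
        (c, c + d, a + c),
        (d, c + d, b + d),
    ):
        expected = rowsum * colsum / total
        stat += (obs - expected) ** 2 / expected
    return stat
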