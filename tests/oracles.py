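"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exact integer arithmetic,
exhaustive enumeration, and double loops, sharing no code path with the
package.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided FET by exact integer hypergeometric enumeration.

    Sums the point probabilities of every table with the observed margins
    whose probability does not exceed the observed table's, in exact
    rational arithmetic (minimum-likelihood convention, no float ties).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return Fraction(1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = comb(r1, a) * comb(r2, c1 - a)
    num = 0
    for x in range(lo, hi + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w <= w_obs:
            num += w
    return Fraction(num, comb(n, c1))


def pascal_triangle(n_max: int) -> np.ndarray:
    """Exact binomial coefficients C[n, k] as int64 (valid to n_max <= 62)."""
    C = np.zeros((n_max + 1, n_max + 1), dtype=np.int64)
    C[:, 0] = 1
    for n in range(1, n_max + 1):
        C[n, 1:n + 1] = C[n - 1, :n] + C[n - 1, 1:n + 1]
    return C


def binom_two_sided_exact(k: int, n: int, p: Fraction) -> Fraction:
    """Two-sided binomial test by exact enumeration of point masses.

    Exact rational arithmetic: sums Binomial(n, p) masses not exceeding
    the observed one (minimum-likelihood convention).
    """
    p = Fraction(p)
    q = 1 - p
    masses = [comb(n, i) * p ** i * q ** (n - i) for i in range(n + 1)]
    obs = masses[k]
    return sum(m for m in masses if m <= obs)


def brute_force_max_independent_set(nodes, edges) -> set:
    """Largest independent set by exhaustive subset enumeration (<=16 nodes)."""
    nodes = list(nodes)
    edge_set = {frozenset(e) for e in edges}
    best: set = set()
    for r in range(len(nodes), 0, -1):
        for sub in combinations(nodes, r):
            if all(frozenset(p) not in edge_set
                   for p in combinations(sub, 2)):
                return set(sub)
    return best


def naive_carrier_recount(callset, records, model_predicate,
                          ) -> dict[str, tuple[int, int]]:
    """Per-gene (case, control) carrier counts by scanning every genotype."""
    dense = callset.genotypes.toarray()
    genes = sorted({r.gene for r in records})
    out = {}
    for gene in genes:
        cols = [j for j, r in enumerate(records)
                if r.gene == gene and model_predicate(r)]
        a = c = 0
        for i in range(callset.n_samples):
            if any(dense[i, j] in (1, 2) for j in cols):
                if callset.is_case[i]:
                    a += 1
                else:
                    c += 1
        out[gene] = (a, c)
    return out
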