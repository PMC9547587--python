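"""Independent brute-force oracles used by the test suite.

Each helper re-derives an expected value along a route deliberately
different from the implementation under test: exact rational arithmetic
for the hypergeometric tail, textbook step-up/step-down loops for the
multiple-testing corrections, nested loops and pandas merges for the
relational operations.
"""

import math
from fractions import Fraction

import pandas as pd


def exact_upper_tail(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X ~ Hypergeom(n, a+c, a+b), by exact enumeration."""
    n, succ, draws = a + b + c + d, a + c, a + b
    num = 0
    for k in range(a, min(draws, succ) + 1):
        num += math.comb(succ, k) * math.comb(n - succ, draws - k)
    return float(Fraction(num, math.comb(n, draws)))


def bonferroni_textbook(ps):
    m = len(ps)
    return [min(1.0, m * p) for p in ps]


def holm_textbook(ps):
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    out = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * ps[i])
        out[i] = min(1.0, running)
    return out


def bh_textbook(ps):
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    out = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, m * ps[i] / (rank + 1))
        out[i] = min(1.0, running)
    return out


def pandas_join(pairs_a, pairs_b):
    """Distinct (x, y) pairs of the key join, via a pandas merge."""
    if not pairs_a or not pairs_b:
        return set()
    da = pd.DataFrame(sorted(pairs_a), columns=["x", "k"])
    db = pd.DataFrame(sorted(pairs_b), columns=["k", "y"])
    j = da.merge(db, on="k")[["x", "y"]].drop_duplicates()
    return set(map(tuple, j.itertuples(index=False)))


def triple_loop_join(map_a, map_b):
    """Brute-force nested-loop join of two source→targets dicts."""
    out = {}
    for x, ks in map_a.items():
        for k in ks:
            for y in map_b.get(k, ()):  # noqa: B909 - read-only
                out.setdefault(x, set()).add(y)
    return out
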