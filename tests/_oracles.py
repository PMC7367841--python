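"""Independent brute-force oracles shared across test modules."""

import itertools
import math
from functools import lru_cache


@lru_cache(maxsize=None)
def _lg(n: int) -> float:
    return math.lgamma(n + 1)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration over tables with fixed margins
    (minimum-likelihood rule with 1+1e-7 relative slack)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = _lg(n) - _lg(c1) - _lg(n - c1)

    def lp(k):
        return (
            _lg(r1) - _lg(k) - _lg(r1 - k)
            + _lg(r2) - _lg(c1 - k) - _lg(r2 - c1 + k)
            - denom
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = math.exp(lp(a))
    total = 0.0
    for k in range(lo, hi + 1):
        pk = math.exp(lp(k))
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def mwu_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all group labelings."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)

    def u_of(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi) + 0.5 * sum(
            1 for xi in xs for yi in ys if xi == yi
        )

    dev_obs = abs(u_of(x, y) - n * m / 2)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        if abs(u_of(xs, ys) - n * m / 2) >= dev_obs - 1e-12:
            count += 1
    return count / total
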