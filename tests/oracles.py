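"""Independent exact-arithmetic oracles used by the tests.

All computations use rational arithmetic (fractions + math.comb) so they
share no code path with the scipy-backed implementations they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_sf_exact(k: int, n_pop: int, n_success: int, n_draw: int) -> Fraction:
    """P(X >= k) for a hypergeometric draw, exact."""
    total = comb(n_pop, n_draw)
    acc = Fraction(0)
    lo = max(k, 0, n_draw - (n_pop - n_success))
    hi = min(n_draw, n_success)
    for x in range(lo, hi + 1):
        acc += Fraction(comb(n_success, x) * comb(n_pop - n_success, n_draw - x), total)
    return acc


def fisher_two_sided_exact(a: int, b: int, c: int, d: int, rel_tol: float = 1e-7) -> Fraction:
    """Two-sided Fisher p: sum of tables (fixed margins) whose point
    probability is <= the observed one (within a relative tolerance)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    total = comb(n, c1)

    def point(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), total)

    obs = point(a)
    cutoff = obs * (1 + Fraction(int(rel_tol * 10**9), 10**9))
    acc = Fraction(0)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    for x in range(lo, hi + 1):
        p = point(x)
        if p <= cutoff:
            acc += p
    return acc


def binom_two_sided_exact(k: int, n: int) -> Fraction:
    """Two-sided exact binomial p against 1/2: sum of outcomes with point
    probability <= the observed one."""
    total = Fraction(1, 2**n)

    def point(x: int) -> Fraction:
        return comb(n, x) * total

    obs = point(k)
    return sum((point(x) for x in range(n + 1) if point(x) <= obs), Fraction(0))


def reciprocal_overlap_per_base(a: tuple[str, int, int], b: tuple[str, int, int]) -> float:
    """Brute-force reciprocal overlap by counting shared integer positions."""
    if a[0] != b[0]:
        return 0.0
    pa = set(range(a[1], a[2]))
    pb = set(range(b[1], b[2]))
    shared = len(pa & pb)
    if not shared:
        return 0.0
    return min(shared / len(pa), shared / len(pb))
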