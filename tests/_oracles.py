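"""Independent brute-force oracles used to check the statistical core.

Everything here is exact rational arithmetic (fractions + math.comb) or a
direct transcription of the defining formula, deliberately sharing no code
with the package implementation.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_upper_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by term-by-term summation."""
    total = comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += comb(K, j) * comb(N - K, n - j)
    return Fraction(acc, total)


def binom_lower_exact(k: int, n: int, pi: Fraction) -> Fraction:
    """P(X <= k) for X ~ Binomial(n, pi) with rational pi."""
    acc = Fraction(0)
    for j in range(0, k + 1):
        acc += comb(n, j) * pi**j * (1 - pi) ** (n - j)
    return acc


def binom_upper_exact(k: int, n: int, pi: Fraction) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, pi) with rational pi."""
    acc = Fraction(0)
    for j in range(k, n + 1):
        acc += comb(n, j) * pi**j * (1 - pi) ** (n - j)
    return acc


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, written from the definition.

    adj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, in input order.
    """
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj_sorted = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        adj_sorted[rank - 1] = min(1.0, running)
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = adj_sorted[rank]
    return out
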