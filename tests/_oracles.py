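"""Independent brute-force oracles used to freeze expected values.

Each oracle is a direct transcription of the defining formula (explicit
summation / enumeration), kept free of any code path it checks.
"""
from fractions import Fraction
from math import comb


def binomial_tail_oracle(n: int, c: int, pr: float) -> float:
    """P(X >= c), X ~ Binomial(n, pr), by explicit term-by-term summation."""
    return float(sum(comb(n, k) * pr**k * (1 - pr) ** (n - k) for k in range(c, n + 1)))


def bh_oracle(p_values):
    """Benjamini–Hochberg step-up by the textbook definition.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted order, clipped to 1,
    returned in input order.
    """
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


def hypergeom_lower_tail_oracle(n11: int, n10: int, n01: int, n00: int) -> Fraction:
    """Exact P(X <= n11) for the overlap X of two sample sets with the
    observed margins, by full hypergeometric enumeration."""
    total = n11 + n10 + n01 + n00
    a = n11 + n10
    b = n11 + n01
    denom = comb(total, b)
    lo = max(0, a + b - total)
    return Fraction(
        sum(comb(a, x) * comb(total - a, b - x) for x in range(lo, n11 + 1)), denom
    )


def fisher_two_tailed_oracle(table) -> Fraction:
    """Two-tailed Fisher exact p: sum of all hypergeometric outcomes no more
    probable than the observed table (margins fixed)."""
    (n11, n12), (n21, n22) = table
    total = n11 + n12 + n21 + n22
    r1 = n11 + n12
    c1 = n11 + n21
    denom = comb(total, c1)
    lo = max(0, r1 + c1 - total)
    hi = min(r1, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(total - r1, c1 - x), denom)
        for x in range(lo, hi + 1)
    }
    observed = probs[n11]
    return sum(p for p in probs.values() if p <= observed)


def empirical_survival(times, t) -> float:
    """Uncensored empirical survival function S(t) = #{T > t} / n."""
    times = list(times)
    return sum(1 for x in times if x > t) / len(times)
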