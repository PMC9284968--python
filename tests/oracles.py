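"""Independent brute-force oracles used to validate the fast paths.

These deliberately share no code with the package: the local-alignment
oracle is a plain-Python Gotoh DP, the binomial oracles are direct
summation / Monte-Carlo, and the amplification oracle is a dense grid
scan written against the model function only.
"""

from __future__ import annotations

import math

MATCH = 2
MISMATCH = -4
GAP_OPEN = -4  # cost of the first gapped column
GAP_EXTEND = -2  # cost of each further gapped column


def sw_affine_score(a: str, b: str) -> int:
    """Best local alignment score of a vs b under the package scoring.

    Affine convention: a gap of length L costs GAP_OPEN + (L-1)*GAP_EXTEND.
    """
    n, m = len(a), len(b)
    NEG = -(10**9)
    best = 0
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + GAP_OPEN, E[i][j - 1] + GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] + GAP_OPEN, F[i - 1][j] + GAP_EXTEND)
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def sw_affine_score_stranded(read: str, query: str) -> int:
    return max(sw_affine_score(read, query), sw_affine_score(read, revcomp(query)))


def binom_pmf(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def binom_tail_ge(c: int, n: int, p: float) -> float:
    """P(Bin(n, p) >= c) by direct summation."""
    return sum(binom_pmf(k, n, p) for k in range(max(0, c), n + 1))


def detection_power_oracle(depth, true_vaf, per_read_error, threshold):
    c = math.ceil(threshold * depth)
    sens = binom_tail_ge(c, depth, true_vaf)
    spec = 1.0 - binom_tail_ge(c, depth, per_read_error)
    return sens, spec


def detection_power_mc(depth, true_vaf, per_read_error, threshold, rng,
                       n_draws=100_000):
    c = math.ceil(threshold * depth)
    pos = rng.binomial(depth, true_vaf, size=n_draws)
    neg = rng.binomial(depth, per_read_error, size=n_draws)
    return float((pos >= c).mean()), float((neg < c).mean())


def grid_argmin_total_time(curve_amounts, curve_fractions, seq_time_fn,
                           per_unit_amp_time, fixed_overhead, n_grid=20001):
    """Dense grid-scan oracle for the optimal amplification amount."""
    import numpy as np

    lo, hi = curve_amounts[0], curve_amounts[-1]
    grid = np.linspace(lo, hi, n_grid)
    best_a, best_t = None, math.inf
    for a in grid:
        f = float(np.interp(a, curve_amounts, curve_fractions))
        t = a * per_unit_amp_time + fixed_overhead + seq_time_fn(f)
        if t < best_t:
            best_a, best_t = float(a), t
    return best_a, best_t
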