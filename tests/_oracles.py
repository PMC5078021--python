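"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately written as plain Python loops over plain
containers, sharing no code path with the package's vectorized
implementations.
"""

from __future__ import annotations

import math


def initial_scores_bf(values, threshold):
    """Per-column sum of entries strictly above the threshold (double loop)."""
    n_rows = len(values)
    n_cols = len(values[0])
    out = []
    for i in range(n_cols):
        total = 0.0
        for j in range(n_rows):
            if values[j][i] > threshold:
                total += values[j][i]
        out.append(total)
    return out


def z_scores_bf(initial_scores, m, k, a, b):
    return [(x - k * m) / (a * m**b) for x in initial_scores]


def tail_p_bf(pool, score, placeholder=True):
    """Inclusive tail fraction; counts of 0 become 0.5/N when placeholder."""
    count = sum(1 for v in pool if v >= score)
    n = len(pool)
    if count == 0 and placeholder:
        return 0.5 / n
    return count / n


def original_score_bf(z_scores, c):
    return sum(z for z in z_scores if z >= c)


def tanimoto_bf(bits_a, bits_b):
    a = len(bits_a)
    b = len(bits_b)
    c = len(set(bits_a) & set(bits_b))
    if a + b - c == 0:
        return 0.0
    return c / (a + b - c)


def edge_weight_bf(p_z):
    return 1.0 / (-math.log10(p_z))
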