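"""Independent loop-based reference implementations of the loss terms.

Deliberately naive (explicit Python loops over pixels, regions and time
points) so they share no code path with the vectorized implementations
they are used to cross-check.
"""

from __future__ import annotations

import math

import numpy as np


def rec_ref(x, g_seq, mu) -> float:
    total = 0.0
    x = np.asarray(x, dtype=float)
    for g_i, m in zip(g_seq, mu):
        g_i = np.asarray(g_i, dtype=float)
        acc = 0.0
        for idx in np.ndindex(x.shape):
            acc += (x[idx] - g_i[idx]) ** 2
        total += m * acc / x.size
    return total


def vox_ref(g_seq, a: int) -> float:
    g_seq = [np.asarray(g, dtype=float) for g in g_seq]
    n = len(g_seq)
    shape = g_seq[0].shape
    terms = []
    if a > 0:
        acc = 0.0
        for idx in np.ndindex(shape):
            lo = min(g_seq[i][idx] for i in range(a))
            acc += (g_seq[a][idx] - lo) ** 2
        terms.append(acc / g_seq[a].size)
    if a < n - 1:
        acc = 0.0
        for idx in np.ndindex(shape):
            hi = max(g_seq[i][idx] for i in range(a + 1, n))
            acc += (g_seq[a][idx] - hi) ** 2
        terms.append(acc / g_seq[a].size)
    if not terms:
        return 0.0
    return sum(terms) / len(terms) if len(terms) == 2 else terms[0]


def reg_ref(g_seq, a: int, d: int, masks, sizes, predict, bin_ages,
            eps: float = 0.1) -> float:
    """`predict(q, o_age, a_age, d)` supplies the regressor prediction."""
    g_seq = [np.asarray(g, dtype=float) for g in g_seq]
    n_time = len(g_seq)
    total = 0.0
    for q, (mask, s_q) in enumerate(zip(masks, sizes)):
        sums = []
        for g in g_seq:
            acc = 0.0
            for idx in np.ndindex(g.shape):
                if mask[idx]:
                    acc += g[idx]
            sums.append(acc + eps)
        for o in range(n_time):
            if o == a:
                continue
            if o < a:
                pred = predict(q, bin_ages[o], bin_ages[a], d)
                ratio = sums[a] / sums[o]
            else:
                pred = predict(q, bin_ages[a], bin_ages[o], d)
                ratio = sums[o] / sums[a]
            total += (pred - ratio) ** 2 * s_q
    return total / (len(masks) * (n_time - 1))


def bce_ref(probs, target: float, clip: float = 1e-7) -> float:
    acc = 0.0
    probs = np.asarray(probs, dtype=float).ravel()
    for p in probs:
        p = min(max(p, clip), 1.0 - clip)
        acc += -math.log(p if target == 1.0 else 1.0 - p)
    return acc / len(probs)
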