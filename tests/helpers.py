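"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use plain Python loops and sort-based medians so they
share no code path with the package.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np


def brute_force_features(
    signal: List[float], mappability: List[float], i: int, j: int
) -> Tuple[float, float, Optional[float], Optional[float], float]:
    """(s_bar, m_bar, rho, eta, tau) for deletion [i, j], 1-based inclusive,
    by explicit loop summation."""

    def mean(vec, a, b):
        total = 0.0
        for p in range(a, b + 1):
            total += vec[p - 1]
        return total / (b - a + 1)

    s_bar = mean(signal, i, j)
    m_bar = mean(mappability, i, j)
    left = mean(signal, 2 * i - j + 1, i - 1)
    right = mean(signal, j + 1, 2 * j - i + 1)
    rho = None if left + right == 0 else 2.0 * s_bar / (left + right)
    eta = None if left == 0 or right == 0 else min(right / left, left / right)
    tau = 0.5 * (left + right)
    return s_bar, m_bar, rho, eta, tau


def brute_force_masked_median(
    values: List[float], a: int, i: int, j: int, h: int
) -> float:
    """Median (sort, pick middle, lower-middle on even counts) of the values
    in [a-h, a+h] clamped to [1, n], excluding positions in [i, j]."""
    n = len(values)
    window = [
        values[b - 1]
        for b in range(max(1, a - h), min(n, a + h) + 1)
        if not (i <= b <= j)
    ]
    window.sort()
    return window[(len(window) - 1) // 2]


def brute_force_column_sums(matrix: np.ndarray) -> List[float]:
    n = matrix.shape[0]
    out = []
    for col in range(n):
        total = 0.0
        for row in range(n):
            total += matrix[row, col]
        out.append(total)
    return out


def random_profile_and_interval(rng, n=400, max_len=12, min_len=3):
    """A random non-negative profile pair plus an interval whose printed
    neighborhood is guaranteed in bounds."""
    signal = rng.gamma(2.0, 5.0, size=n)
    signal[rng.random(n) < 0.1] = 0.0  # zero stretches exercise UNDEFINED paths
    mapp = rng.gamma(1.5, 1.0, size=n)
    length = int(rng.integers(min_len, max_len + 1))
    # need 2i - j + 1 >= 1 and 2j - i + 1 <= n
    i = int(rng.integers(length, n - 2 * length))
    j = i + length - 1
    return signal, mapp, i, j
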