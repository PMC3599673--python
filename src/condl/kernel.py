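"""Edit-distance kernel over dependency-path token sequences.

The similarity between two paths is ``exp(-gamma * d(x, y))`` where ``d`` is
the word-level Levenshtein distance (unit-cost insert/delete/substitute over
whole tokens).  This kernel is not guaranteed positive semidefinite, so Gram
matrices built for training are repaired by clipping negative eigenvalues.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["edit_distance", "kernel", "gram_matrix", "cross_kernel"]


def edit_distance(x: Sequence[str], y: Sequence[str]) -> int:
    """Word-level Levenshtein distance between two token sequences."""
    m, n = len(x), len(y)
    if m == 0:
        return n
    if n == 0:
        return m
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        xi = x[i - 1]
        for j in range(1, n + 1):
            cost = 0 if xi == y[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[n]


def kernel(x: Sequence[str], y: Sequence[str], gamma: float = 0.25) -> float:
    """Similarity exp(-gamma * edit_distance(x, y)); symmetric, k(x, x) = 1."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    return float(np.exp(-gamma * edit_distance(x, y)))


def cross_kernel(
    xs: Sequence[Sequence[str]], ys: Sequence[Sequence[str]], gamma: float
) -> np.ndarray:
    """Raw (unrepaired) kernel matrix between two path collections."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    out = np.empty((len(xs), len(ys)))
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            out[i, j] = np.exp(-gamma * edit_distance(x, y))
    return out


def gram_matrix(
    paths: Sequence[Sequence[str]], gamma: float = 0.25, tol: float = 1e-9
) -> tuple[np.ndarray, bool]:
    """Symmetric kernel matrix over ``paths``, repaired to be PSD.

    If the smallest eigenvalue is below ``-tol``, negative eigenvalues are
    clipped to zero and the matrix reconstituted; the returned flag reports
    whether a repair was applied.
    """
    if len(paths) == 0:
        raise ValueError("gram_matrix requires at least one path")
    n = len(paths)
    gram = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            gram[i, j] = gram[j, i] = np.exp(-gamma * edit_distance(paths[i], paths[j]))
    eigvals, eigvecs = np.linalg.eigh(gram)
    repaired = bool(eigvals[0] < -tol)
    if repaired:
        clipped = np.clip(eigvals, 0.0, None)
        gram = (eigvecs * clipped) @ eigvecs.T
        gram = (gram + gram.T) / 2.0
    return gram, repaired
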