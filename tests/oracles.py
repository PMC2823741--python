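"""Independent brute-force oracles used only by the tests.

Each oracle deliberately avoids the code paths (and where practical the
library calls) used by the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def power_iteration_pc1(matrix: np.ndarray, iters: int = 20_000, tol: float = 1e-14) -> np.ndarray:
    """Leading eigenvector of a symmetric PSD matrix by plain power iteration."""
    A = np.asarray(matrix, dtype=float)
    v = np.ones(A.shape[0]) / math.sqrt(A.shape[0])
    for _ in range(iters):
        w = A @ v
        w = w / np.linalg.norm(w)
        if np.linalg.norm(w - v) < tol and np.linalg.norm(w + v) > tol:
            v = w
            break
        v = w
    return v


def align_sign(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Flip ``b`` if it points away from ``a`` (PC sign is arbitrary)."""
    return -b if float(a @ b) < 0 else b


def midranks(values) -> list[float]:
    """Average ranks by counting: rank_i = (#smaller) + (#equal + 1) / 2."""
    out = []
    for v in values:
        smaller = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        out.append(smaller + (equal + 1) / 2)
    return out


def spearman_oracle(x, y) -> float:
    """Rank correlation from first principles: midranks + explicit Pearson sums."""
    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    return sxy / math.sqrt(sxx * syy)


def allocation_oracle(budget: float, weights: dict, values: dict) -> dict:
    """Per-district allocation by explicit per-term summation.

    ``weights``: variable -> a_n; ``values``: variable -> {district: V_ni}.
    """
    districts = sorted(next(iter(values.values())).keys())
    out = {d: 0.0 for d in districts}
    for var, a_n in weights.items():
        total = sum(values[var][d] for d in districts)
        for d in districts:
            out[d] += budget * a_n * values[var][d] / total
    return out


def streaming_mean_by_group(scores, groups) -> dict:
    """One-pass running means per group (Welford-style accumulation)."""
    count: dict = {}
    mean: dict = {}
    for s, g in zip(scores, groups):
        c = count.get(g, 0) + 1
        count[g] = c
        mean[g] = mean.get(g, 0.0) + (s - mean.get(g, 0.0)) / c
    return mean
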