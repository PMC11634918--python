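"""Independent reference computations used to validate the implementation.

Everything here deliberately avoids the code paths under test: the planar
Procrustes oracle minimizes over the similarity group numerically instead of
using the SVD solution, and the permutation oracles enumerate the full
outcome space instead of sampling.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize_scalar


def planar_procrustes_oracle(X: np.ndarray, Y: np.ndarray, n_grid: int = 1441) -> float:
    """Normalized Procrustes distance of 2-D shapes by direct minimization.

    Minimizes ``||X - (b Y R + t)||^2 / ||X - mean(X)||^2`` over rotation
    angle (dense grid + bounded refinement), both reflections, non-negative
    scale (closed form given the rotation) and translation (centroid
    alignment, optimal for any rotation and scale).
    """
    X0 = X - X.mean(axis=0)
    Y0 = Y - Y.mean(axis=0)
    ss_x = float((X0**2).sum())
    ss_y = float((Y0**2).sum())

    def normalized_residual(theta: float, reflect: bool) -> float:
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s], [s, c]])
        if reflect:
            R = R @ np.diag([1.0, -1.0])
        inner = max(float((X0 * (Y0 @ R)).sum()), 0.0)  # b >= 0
        return (ss_x - inner**2 / ss_y) / ss_x

    best = np.inf
    step = 2 * np.pi / n_grid
    for reflect in (False, True):
        thetas = np.arange(n_grid) * step
        vals = [normalized_residual(t, reflect) for t in thetas]
        i = int(np.argmin(vals))
        res = minimize_scalar(
            lambda t: normalized_residual(t, reflect),
            bounds=(thetas[i] - step, thetas[i] + step),
            method="bounded",
            options={"xatol": 1e-13},
        )
        best = min(best, float(res.fun))
    return best


def swap_test_exact_p(D: np.ndarray, conf_idx, part_idx) -> float:
    """Exact swap-test p by enumerating every (block cell, participant) draw."""
    cells = [
        (conf_idx[a], conf_idx[b])
        for a in range(len(conf_idx))
        for b in range(a + 1, len(conf_idx))
    ]
    observed = np.mean([D[i, j] for i, j in cells])
    smaller = 0
    total = 0
    for i, j in cells:
        for k in part_idx:
            new_mean = observed + (D[i, k] - D[i, j]) / len(cells)
            total += 1
            if new_mean < observed:
                smaller += 1
    return smaller / total


def mantel_exact_p(D1: np.ndarray, D2: np.ndarray) -> tuple[float, float]:
    """Exact one-sided Mantel p by enumerating all n! joint relabellings.

    Returns (observed r, exact p = fraction of permutations with r >= observed,
    the identity included).
    """
    n = D1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1 = D1[iu]
    observed = float(np.corrcoef(v1, D2[iu])[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        r = float(np.corrcoef(v1, D2[np.ix_(p, p)][iu])[0, 1])
        total += 1
        if r >= observed:
            count += 1
    return observed, count / total


def icc_a1_oracle(x, y) -> float:
    """ICC(A,1) from an explicit loop-based two-way ANOVA decomposition."""
    x = list(map(float, x))
    y = list(map(float, y))
    n, k = len(x), 2
    grand = sum(x + y) / (n * k)
    row_means = [(a + b) / 2 for a, b in zip(x, y)]
    col_means = [sum(x) / n, sum(y) / n]
    ss_rows = sum(k * (m - grand) ** 2 for m in row_means)
    ss_cols = sum(n * (m - grand) ** 2 for m in col_means)
    ss_tot = sum((v - grand) ** 2 for v in x + y)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def decile_bins_oracle(values, n_bins: int) -> list[float]:
    """Loop-based decile binning straight from the edge formula."""
    n = len(values)
    out = []
    for b in range(1, n_bins + 1):
        lo = (b - 1) * n // n_bins
        hi = b * n // n_bins
        chunk = values[lo:hi]
        out.append(sum(chunk) / len(chunk))
    return out
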