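"""Ordinary Procrustes superimposition with the normalized distance.

Fits the similarity transform (translation, rotation, optional reflection,
optional isotropic scaling) of a comparison landmark matrix onto a target
matrix, minimizing the sum of squared point-wise differences. With scaling
enabled the residual is standardized by the target's centered sum of squares,
which confines the distance to [0, 1]: 0 for shapes identical up to a
similarity transform, approaching 1 for shapes whose centered configurations
are orthogonal.

The computation follows the classical SVD solution: center both matrices,
scale each to unit centered Frobenius norm, decompose the cross-product
``X0' Y0 = U S V'``, take the rotation/reflection ``T = V U'`` (with the
reflection constrained away, when requested, by flipping the axis of the
smallest singular value), and read the distance off the singular values as
``d = 1 - (sum(S))^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateShapeError",
    "ProcrustesResult",
    "procrustes_fit",
    "procrustes_distance",
]

#: centered sum-of-squares below this is treated as a degenerate shape
_DEGENERACY_TOL = 1e-24


class DegenerateShapeError(ValueError):
    """All landmarks of a matrix coincide: the shape has no extent.

    Such matrices cannot arise from real movement and are rejected rather
    than assigned a sentinel distance — they signal an upstream bug.
    """


@dataclass(frozen=True)
class ProcrustesResult:
    """Outcome of one Procrustes fit.

    ``Z = scale * comparison @ rotation + translation`` (translation applied
    row-wise) reproduces the transformed matrix from the stored components.
    """

    d: float  # normalized distance; in [0, 1] when scaling is on
    Z: np.ndarray  # transformed comparison matrix, on the target's scale
    rotation: np.ndarray  # orthogonal k x k matrix T, det = +/-1
    scale: float  # isotropic scale factor b > 0
    translation: np.ndarray  # k-vector c


def _center_and_norm(mat: np.ndarray, name: str) -> tuple[np.ndarray, np.ndarray, float]:
    mu = mat.mean(axis=0)
    centered = mat - mu
    norm = float(np.linalg.norm(centered))
    if norm * norm <= _DEGENERACY_TOL:
        raise DegenerateShapeError(
            f"{name} matrix is degenerate: all landmarks identical "
            "(zero centered sum of squares)"
        )
    return centered, mu, norm


def procrustes_fit(
    target: np.ndarray,
    comparison: np.ndarray,
    scaling: bool = True,
    reflection: bool = True,
) -> ProcrustesResult:
    """Superimpose ``comparison`` onto ``target``.

    Parameters
    ----------
    target, comparison
        n x k landmark matrices of the same shape, n >= 2, neither with all
        rows identical.
    scaling
        Fit an isotropic scale factor. With scaling on, ``d`` is the residual
        sum of squares standardized by the target's centered sum of squares
        and lies in [0, 1]; off, ``d`` is the standardized residual of the
        unscaled fit (not bounded by 1).
    reflection
        Allow ``det(rotation) = -1``. When off, the determinant is forced to
        +1 by sign-flipping the axis of the smallest singular value, which
        yields the best proper rotation.
    """
    X = np.asarray(target, dtype=float)
    Y = np.asarray(comparison, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: target {X.shape} vs comparison {Y.shape}")
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError(f"need an n x k matrix with n >= 2, got shape {X.shape}")

    X0, muX, normX = _center_and_norm(X, "target")
    Y0, muY, normY = _center_and_norm(Y, "comparison")
    X0n = X0 / normX
    Y0n = Y0 / normY

    A = X0n.T @ Y0n
    U, s, Vt = np.linalg.svd(A)
    V = Vt.T
    T = V @ U.T
    if not reflection and np.linalg.det(T) < 0:
        V = V.copy()
        V[:, -1] *= -1.0
        s = s.copy()
        s[-1] *= -1.0
        T = V @ U.T
    trace_ta = float(s.sum())

    if scaling:
        b = trace_ta * normX / normY
        d = 1.0 - trace_ta**2
        Z = normX * trace_ta * (Y0n @ T) + muX
    else:
        b = 1.0
        d = 1.0 + (normY**2 / normX**2) - 2.0 * trace_ta * normY / normX
        Z = normY * (Y0n @ T) + muX
    c = muX - b * (muY @ T)
    return ProcrustesResult(d=float(d), Z=Z, rotation=T, scale=float(b), translation=c)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized Procrustes distance in [0, 1] (scaling and reflection on).

    With scaling enabled the distance is symmetric — both directions reduce
    to ``1 - (sum of singular values of the normalized cross-product)^2`` —
    and this is asserted numerically before returning the a->b value.
    """
    d_ab = procrustes_fit(a, b).d
    d_ba = procrustes_fit(b, a).d
    if abs(d_ab - d_ba) > 1e-12:
        raise AssertionError(
            f"Procrustes distance asymmetry {abs(d_ab - d_ba):.3e} exceeds 1e-12"
        )
    return d_ab
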