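"""Statistical machinery around the motor-distance matrix.

* ``swap_test`` — empirical p-value for the hypothesis that
  confederate-confederate distances are smaller than confederate-participant
  ones, by cell-substitution permutation.
* ``mds_embed`` — two-dimensional multidimensional scaling, initialized with
  classical (principal-coordinate) scaling and refined by stress
  majorization; goodness-of-fit reported as Kruskal stress-1.
* ``icc_absolute_agreement`` — ICC(A,1), the two-way single-measurement
  absolute-agreement intraclass correlation of McGraw & Wong.
* ``robustness_subsample`` — how stable the distance matrix is when an
  increasing fraction of trials is dropped before alignment.
* ``mantel_test`` — permutation test of the correlation between two distance
  matrices under joint row/column relabelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignment import align_all_subjects
from .distance import DistanceMatrix, pairwise_distances
from .kinematics import TrialMatrix

__all__ = [
    "PermutationTestResult",
    "MDSEmbedding",
    "RobustnessCurve",
    "swap_test",
    "mds_embed",
    "kruskal_stress",
    "icc_absolute_agreement",
    "robustness_subsample",
    "mantel_test",
]


@dataclass(frozen=True)
class PermutationTestResult:
    observed_stat: float
    p_empirical: float
    n_perm: int
    seed: int | None
    kind: str  # swap_test | mantel | method_comparison

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_empirical <= 1.0:
            raise ValueError(f"p out of range: {self.p_empirical}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "observed": self.observed_stat,
            "p": self.p_empirical,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class MDSEmbedding:
    coords: np.ndarray  # n x dims, centered at the origin
    stress: float  # Kruskal stress-1
    n_steps: int
    stress_history: tuple[float, ...] = ()


@dataclass(frozen=True)
class RobustnessCurve:
    fractions_removed: tuple[float, ...]
    icc: tuple[float, ...]
    n_iter: int
    mean_matrices: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        fr = self.fractions_removed
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("fractions must be strictly increasing")
        if any(v > 1 + 1e-12 for v in self.icc):
            raise ValueError("ICC cannot exceed 1")


def swap_test(
    D: DistanceMatrix,
    confederate_tag: str = "confederate_instance",
    participant_tag: str = "participant",
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Can swapping in cross-group distances lower the within-group mean?

    The observed statistic is the mean of the confederate-confederate block
    (upper triangle). Each permutation picks a uniform random cell (i, j)
    from that block and a uniform random participant k, substitutes the
    confederate_i-participant_k distance for the cell (the first confederate
    of the couple is retained), and recomputes the block mean. The p-value is
    the fraction of permutations whose mean falls strictly below the
    observed one — ties are conservative and do not count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cells = D.block_cells(confederate_tag, confederate_tag)
    participants = D.group_indices(participant_tag)
    if len(participants) == 0:
        raise ValueError(f"group {participant_tag!r} is empty")
    block = np.array([D.values[i, j] for i, j in cells])
    observed = float(block.mean())
    n_cells = len(cells)
    rng = np.random.default_rng(seed)
    cell_draw = rng.integers(0, n_cells, size=n_perm)
    part_draw = rng.integers(0, len(participants), size=n_perm)
    smaller = 0
    for c_idx, p_idx in zip(cell_draw, part_draw):
        i, _j = cells[c_idx]
        substituted = D.values[i, participants[p_idx]]
        new_mean = observed + (substituted - block[c_idx]) / n_cells
        if new_mean < observed:
            smaller += 1
    return PermutationTestResult(
        observed_stat=observed,
        p_empirical=smaller / n_perm,
        n_perm=n_perm,
        seed=seed,
        kind="swap_test",
    )


def kruskal_stress(delta: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 over the upper triangle.

    ``sqrt(sum (delta_ij - dhat_ij)^2 / sum delta_ij^2)`` where delta are the
    input distances and dhat the embedded Euclidean distances.
    """
    iu = np.triu_indices(delta.shape[0], k=1)
    diff = coords[:, None, :] - coords[None, :, :]
    dhat = np.sqrt((diff**2).sum(axis=2))
    num = ((delta[iu] - dhat[iu]) ** 2).sum()
    den = (delta[iu] ** 2).sum()
    if den == 0:
        raise ValueError("all input distances are zero")
    return float(np.sqrt(num / den))


def _classical_scaling(delta: np.ndarray, dims: int) -> np.ndarray:
    n = delta.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (delta**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:dims]
    lam = np.clip(eigval[order], 0.0, None)
    return eigvec[:, order] * np.sqrt(lam)


def mds_embed(
    D: DistanceMatrix | np.ndarray,
    dims: int = 2,
    max_steps: int = 300,
    tol: float = 1e-6,
) -> MDSEmbedding:
    """Metric MDS: classical-scaling start, stress-majorization refinement.

    The initial configuration comes from double-centering the squared
    distances and projecting on the top eigenvectors (principal coordinate
    axes). Refinement iterates the Guttman transform, whose raw stress is
    non-increasing by construction; iteration stops when the relative drop
    in Kruskal stress-1 falls below ``tol`` or after ``max_steps``.
    """
    delta = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    n = delta.shape[0]
    if n < 3:
        raise ValueError("need at least 3 elements to embed")
    if not np.isfinite(delta).all():
        raise ValueError("non-finite distances")
    X = _classical_scaling(delta, dims)
    history = [kruskal_stress(delta, X)]
    steps = 0
    for _ in range(max_steps):
        diff = X[:, None, :] - X[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, delta / np.where(dist > 0, dist, 1.0), 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X_new = (B @ X) / n
        stress_new = kruskal_stress(delta, X_new)
        steps += 1
        prev = history[-1]
        history.append(stress_new)
        X = X_new
        if prev - stress_new < tol * max(prev, 1e-30):
            break
    X = X - X.mean(axis=0)
    return MDSEmbedding(
        coords=X, stress=history[-1], n_steps=steps, stress_history=tuple(history)
    )


def icc_absolute_agreement(x: Sequence[float], y: Sequence[float]) -> float:
    """ICC(A,1): two-way, single measurement, absolute agreement.

    Rows are the n paired observations (here: upper-triangle distance cells),
    columns the k = 2 measurement conditions (full vs reduced matrix).
    ``(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))`` from the two-way
    ANOVA mean squares: MSR between rows, MSC between columns, MSE residual.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("ICC undefined: zero variance in both vectors")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("ICC undefined: zero variance in both vectors")
    return float((msr - mse) / denom)


def robustness_subsample(
    trials: Sequence[TrialMatrix],
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    n_iter: int = 1000,
    seed: int | None = None,
    target_rule="first_available",
) -> RobustnessCurve:
    """ICC of the distance matrix under random trial removal.

    Per removal fraction f and iteration, each subject keeps
    ``max(2, round((1 - f) * t))`` of its t trials, drawn uniformly without
    replacement (original order preserved, so ``first_available`` stays
    meaningful); alignment and the pairwise distances are recomputed. The
    n_iter matrices are averaged element-wise, and ICC(A,1) compares the
    averaged matrix's upper triangle with the full-data matrix's.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(not 0.0 < f < 1.0 for f in fractions):
        raise ValueError("removal fractions must lie strictly in (0, 1)")
    by_subject: dict[str, list[TrialMatrix]] = {}
    for tm in trials:
        by_subject.setdefault(tm.subject_id, []).append(tm)
    f_max = max(fractions)
    for sid, sub in by_subject.items():
        if len(sub) < 2:
            raise ValueError(
                f"subject {sid!r} has {len(sub)} trial(s); cannot retain 2 at "
                f"removal fraction {f_max}"
            )
    full = pairwise_distances(align_all_subjects(trials, target_rule=target_rule))
    full_vec = full.upper_triangle()
    rng = np.random.default_rng(seed)
    iccs = []
    mean_mats = []
    subjects = sorted(by_subject)
    for f in fractions:
        acc = np.zeros_like(full.values)
        for _ in range(n_iter):
            kept: list[TrialMatrix] = []
            for sid in subjects:
                sub = by_subject[sid]
                t = len(sub)
                n_keep = max(2, round((1.0 - f) * t))
                idx = np.sort(rng.choice(t, size=n_keep, replace=False))
                kept.extend(sub[i] for i in idx)
            D = pairwise_distances(align_all_subjects(kept, target_rule=target_rule))
            if D.labels != full.labels:
                raise AssertionError("subject set changed under subsampling")
            acc += D.values
        mean_mat = acc / n_iter
        iu = np.triu_indices(mean_mat.shape[0], k=1)
        iccs.append(icc_absolute_agreement(full_vec, mean_mat[iu]))
        mean_mats.append(mean_mat)
    return RobustnessCurve(
        fractions_removed=fractions,
        icc=tuple(iccs),
        n_iter=n_iter,
        mean_matrices=tuple(mean_mats),
    )


def mantel_test(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_perm: int = 5000,
    seed: int | None = None,
    p_convention: str = "add_one",
) -> PermutationTestResult:
    """Mantel test of agreement between two distance matrices.

    The observed statistic is the Pearson correlation between the two upper
    triangles. Each permutation applies one random joint row-and-column
    relabelling to the second matrix and recomputes r; the one-sided p-value
    counts permuted r >= observed. ``p_convention="add_one"`` includes the
    observed statistic in numerator and denominator (p >= 1/(n_perm + 1));
    ``"pure_count"`` reports the raw fraction, which can reach 0.
    """
    if D1.labels != D2.labels:
        raise ValueError("label mismatch between the two matrices")
    n = D1.n
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if p_convention not in ("add_one", "pure_count"):
        raise ValueError(f"unknown p_convention {p_convention!r}")
    iu = np.triu_indices(n, k=1)
    v1 = D1.values[iu]
    observed = float(np.corrcoef(v1, D2.values[iu])[0, 1])
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        permuted = D2.values[np.ix_(perm, perm)]
        r = float(np.corrcoef(v1, permuted[iu])[0, 1])
        if r >= observed:
            count_ge += 1
    if p_convention == "add_one":
        p = (count_ge + 1) / (n_perm + 1)
    else:
        p = count_ge / n_perm
    return PermutationTestResult(
        observed_stat=observed,
        p_empirical=p,
        n_perm=n_perm,
        seed=seed,
        kind="mantel",
    )
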