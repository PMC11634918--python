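"""Inter-subject motor-distance matrix and the analyses built on it.

Each pair of FPT trials is compared with the normalized Procrustes distance,
producing a labelled symmetric n x n matrix covering every
confederate-confederate, participant-participant and confederate-participant
coupling. The similarity-ranking inspection (nearest / 33rd percentile /
66th percentile / farthest neighbour of a reference) and the target-trial
sensitivity analysis (how stable the matrix is under different choices of
alignment target) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

import numpy as np

from .alignment import FPTTrial, align_all_subjects
from .kinematics import TrialMatrix
from .procrustes import DegenerateShapeError, procrustes_fit

__all__ = [
    "DistanceMatrix",
    "NeighbourRanking",
    "pairwise_distances",
    "rank_neighbours",
    "target_sensitivity",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric matrix of inter-subject motor distances."""

    values: np.ndarray  # n x n, zero diagonal, off-diagonals in [0, 1]
    labels: tuple[str, ...]  # subject-instance ids
    groups: tuple[str, ...]  # group tag per label
    condition: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        n = arr.shape[0]
        if arr.shape != (n, n) or n != len(self.labels) or n != len(self.groups):
            raise ValueError("values, labels and groups have inconsistent sizes")
        if np.abs(arr - arr.T).max() > 1e-12:
            raise ValueError("distance matrix is not symmetric to 1e-12")
        if np.abs(np.diag(arr)).max() > 0:
            raise ValueError("distance matrix diagonal must be zero")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "groups", tuple(self.groups))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown subject {label!r}") from None

    def group_indices(self, tag: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == tag], dtype=int)

    def block_cells(self, tag_a: str, tag_b: str) -> list[tuple[int, int]]:
        """Index pairs of the block between two groups.

        For a same-group block these are the upper-triangle cells (each
        unordered couple once: 120 cells for 16 instances); for a cross-group
        block, every (a, b) pair (16 x 16 = 256 cells).
        """
        ia, ib = self.group_indices(tag_a), self.group_indices(tag_b)
        if len(ia) == 0 or len(ib) == 0:
            missing = tag_a if len(ia) == 0 else tag_b
            raise ValueError(f"group {missing!r} is empty")
        if tag_a == tag_b:
            return [(ia[p], ia[q]) for p in range(len(ia)) for q in range(p + 1, len(ia))]
        return [(i, j) for i in ia for j in ib]

    def block_values(self, tag_a: str, tag_b: str) -> np.ndarray:
        return np.array([self.values[i, j] for i, j in self.block_cells(tag_a, tag_b)])

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def pairwise_distances(fpts: Sequence[FPTTrial]) -> DistanceMatrix:
    """All-pairs Procrustes distances between FPT trials of one condition.

    Each unordered pair is fitted in both directions; the two distances agree
    to numerical precision (the symmetric singular-value form) and are
    averaged so the matrix invariant holds bit-exactly.
    """
    if len(fpts) < 2:
        raise ValueError("need at least 2 FPT trials")
    conditions = {f.condition for f in fpts}
    if len(conditions) > 1:
        raise ValueError(f"FPT trials span multiple conditions: {sorted(conditions)}")
    mats = []
    for f in fpts:
        try:
            mats.append(f.as_trial_matrix().values)
        except DegenerateShapeError:
            raise DegenerateShapeError(
                f"FPT trial of subject {f.subject_id!r} is degenerate"
            ) from None
    n = len(fpts)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d_ij = procrustes_fit(mats[i], mats[j]).d
            d_ji = procrustes_fit(mats[j], mats[i]).d
            if abs(d_ij - d_ji) > 1e-12:
                raise AssertionError(
                    f"asymmetry {abs(d_ij - d_ji):.3e} between "
                    f"{fpts[i].subject_id!r} and {fpts[j].subject_id!r}"
                )
            D[i, j] = D[j, i] = 0.5 * (d_ij + d_ji)
    return DistanceMatrix(
        values=D,
        labels=tuple(f.subject_id for f in fpts),
        groups=tuple(f.group for f in fpts),
        condition=fpts[0].condition,
    )


@dataclass(frozen=True)
class NeighbourRanking:
    """A reference subject's column sorted by increasing motor distance."""

    reference: str
    ordered: tuple[tuple[str, float], ...]  # (label, distance), ascending
    flags: dict = field(default_factory=dict)  # nearest/p33/p66/farthest -> label


def rank_neighbours(D: DistanceMatrix, reference: str) -> NeighbourRanking:
    """Sort a reference's distances and flag the inspection quantiles.

    Flags mark the nearest subject, the 33rd- and 66th-percentile subjects
    (1-based rank ``ceil(q * (n - 1))`` among the n-1 comparators) and the
    most dissimilar subject. Ties are broken by label order.
    """
    ref_idx = D.index_of(reference)
    entries = [
        (D.labels[i], float(D.values[ref_idx, i])) for i in range(D.n) if i != ref_idx
    ]
    entries.sort(key=lambda e: (e[1], e[0]))
    m = len(entries)
    flags = {
        "nearest": entries[0][0],
        "p33": entries[max(0, ceil(0.33 * m) - 1)][0],
        "p66": entries[max(0, ceil(0.66 * m) - 1)][0],
        "farthest": entries[-1][0],
    }
    return NeighbourRanking(reference=reference, ordered=tuple(entries), flags=flags)


def target_sensitivity(
    trials: Sequence[TrialMatrix],
    target_rules: Sequence,
    n_perm: int = 1000,
    seed: int | None = None,
):
    """Stability of the distance matrix under different alignment targets.

    Re-runs inter-trial alignment and the pairwise distance computation once
    per target rule and returns the matrix of pairwise Mantel correlations
    (with permutation p-values) between the resulting distance matrices.

    Returns
    -------
    (rules, r_matrix, p_matrix, matrices)
    """
    from .stats import mantel_test  # local import to avoid a cycle

    if not target_rules:
        raise ValueError("need at least one target rule")
    matrices = [
        pairwise_distances(align_all_subjects(trials, target_rule=rule))
        for rule in target_rules
    ]
    k = len(matrices)
    r_mat = np.eye(k)
    p_mat = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            res = mantel_test(matrices[a], matrices[b], n_perm=n_perm, seed=seed)
            r_mat[a, b] = r_mat[b, a] = res.observed_stat
            p_mat[a, b] = p_mat[b, a] = res.p_empirical
    return list(target_rules), r_mat, p_mat, matrices
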