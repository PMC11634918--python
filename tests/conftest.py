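import numpy as np
import pytest
from hypothesis import settings

from motordist import (
    align_all_subjects,
    build_trial_matrix,
    generate_dataset,
    pairwise_distances,
)
from motordist.synth import DatasetDesign

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

SMALL_DESIGN = DatasetDesign(
    n_participants=5,
    n_confederate_instances=5,
    trials_per_instance=8,
    conditions=("PG",),
)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced study design (5 + 5 subjects, 8 trials) for cheap unit tests."""
    return generate_dataset(SMALL_DESIGN, seed=7)


@pytest.fixture(scope="session")
def small_matrices(small_dataset):
    return [build_trial_matrix(t) for t in small_dataset.raw_trials]


@pytest.fixture(scope="session")
def small_fpts(small_matrices):
    return align_all_subjects(small_matrices)


@pytest.fixture(scope="session")
def small_distance(small_fpts):
    return pairwise_distances(small_fpts)


@pytest.fixture(scope="session")
def study_pg_pipeline():
    """Full study design (16 + 16 x 20 trials), PG condition, seed 1."""
    dataset = generate_dataset(DatasetDesign(conditions=("PG",)), seed=1)
    matrices = [build_trial_matrix(t) for t in dataset.raw_trials]
    fpts = align_all_subjects(matrices)
    D = pairwise_distances(fpts)
    return dataset, matrices, fpts, D


def random_shape(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """A random non-degenerate landmark matrix."""
    while True:
        mat = rng.normal(size=(n, k))
        if np.sum((mat - mat.mean(axis=0)) ** 2) > 1e-6:
            return mat


def random_rotation(rng: np.random.Generator, k: int) -> np.ndarray:
    """Haar-ish random proper rotation via QR."""
    q, r = np.linalg.qr(rng.normal(size=(k, k)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q
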