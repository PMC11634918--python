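"""Permutation tests, MDS, ICC and the robustness subsampling analysis."""

import numpy as np
import pytest

from motordist import (
    DistanceMatrix,
    icc_absolute_agreement,
    mantel_test,
    mds_embed,
    robustness_subsample,
    swap_test,
)
from motordist.stats import kruskal_stress
from oracles import icc_a1_oracle, mantel_exact_p, swap_test_exact_p

CONF = "confederate_instance"
PART = "participant"


def group_matrix(values, groups, condition="PG"):
    values = np.asarray(values, dtype=float)
    n = len(values)
    return DistanceMatrix(
        values=values,
        labels=tuple(f"s{i:02d}" for i in range(n)),
        groups=tuple(groups),
        condition=condition,
    )


def random_symmetric(rng, n, scale=1.0):
    m = rng.uniform(0.05, scale, size=(n, n))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return m


class TestSwapTest:
    def _matrix(self, conf_block, cross_value):
        # 3 confederates + 2 participants
        values = np.zeros((5, 5))
        conf = [(0, 1), (0, 2), (1, 2)]
        for (i, j), v in zip(conf, conf_block):
            values[i, j] = values[j, i] = v
        for i in range(3):
            for j in (3, 4):
                values[i, j] = values[j, i] = cross_value
        values[3, 4] = values[4, 3] = 0.5
        return group_matrix(values, [CONF] * 3 + [PART] * 2)

    def test_all_within_smaller_gives_p_zero(self):
        D = self._matrix([0.1, 0.12, 0.14], cross_value=0.9)
        res = swap_test(D, n_perm=500, seed=0)
        assert res.p_empirical == 0.0
        assert res.observed_stat == pytest.approx(0.12)

    def test_all_cross_smaller_gives_p_one(self):
        D = self._matrix([0.8, 0.85, 0.9], cross_value=0.1)
        assert swap_test(D, n_perm=500, seed=0).p_empirical == 1.0

    def test_matches_exhaustive_enumeration(self):
        """Monte-Carlo p agrees with full enumeration over every
        (cell, participant) draw within 3 binomial standard errors."""
        rng = np.random.default_rng(21)
        values = random_symmetric(rng, 5)
        D = group_matrix(values, [CONF] * 3 + [PART] * 2)
        exact = swap_test_exact_p(values, [0, 1, 2], [3, 4])
        n_perm = 4000
        mc = swap_test(D, n_perm=n_perm, seed=5).p_empirical
        se = np.sqrt(max(exact * (1 - exact), 1e-9) / n_perm)
        assert abs(mc - exact) <= 3 * se

    def test_missing_group_rejected(self):
        values = random_symmetric(np.random.default_rng(0), 4)
        D = group_matrix(values, [CONF] * 4)
        with pytest.raises(ValueError, match="empty"):
            swap_test(D)


class TestMDS:
    def test_planar_square_embeds_exactly(self):
        """Distances of a planar unit square are realizable in 2-D, so the
        embedding reaches (numerically) zero stress and recovers the square."""
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        delta = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        emb = mds_embed(delta)
        assert emb.stress <= 1e-6
        d_emb = np.sqrt(((emb.coords[:, None] - emb.coords[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(d_emb, delta, atol=1e-5)

    def test_collinear_points(self):
        pts = np.array([0.0, 1.0, 3.0])
        delta = np.abs(pts[:, None] - pts[None, :])
        assert mds_embed(delta).stress <= 1e-6

    def test_stress_monotone_nonincreasing(self, small_distance):
        emb = mds_embed(small_distance)
        hist = np.array(emb.stress_history)
        assert (np.diff(hist) <= 1e-12).all()

    def test_coords_centered(self, small_distance):
        emb = mds_embed(small_distance)
        np.testing.assert_allclose(emb.coords.mean(axis=0), 0.0, atol=1e-10)

    def test_confederates_less_scattered_than_participants(self, study_pg_pipeline):
        """The shared-style confederate instances occupy a tighter region of
        the embedding than the heterogeneous participants."""
        *_, D = study_pg_pipeline
        emb = mds_embed(D)
        conf = emb.coords[[g == CONF for g in D.groups]]
        part = emb.coords[[g == PART for g in D.groups]]

        def mean_spread(coords):
            diff = coords[:, None] - coords[None, :]
            d = np.sqrt((diff**2).sum(-1))
            iu = np.triu_indices(len(coords), k=1)
            return d[iu].mean()

        assert mean_spread(conf) < mean_spread(part)

    def test_nonfinite_rejected(self):
        delta = np.zeros((4, 4))
        delta[0, 1] = delta[1, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            mds_embed(delta)

    def test_kruskal_stress_formula(self):
        delta = np.array([[0.0, 1.0], [1.0, 0.0]])
        coords = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert kruskal_stress(delta, coords) == pytest.approx(1.0)


class TestICC:
    def test_perfect_agreement(self):
        x = np.array([0.1, 0.5, 0.3, 0.9, 0.2])
        assert icc_absolute_agreement(x, x) == pytest.approx(1.0)

    def test_offset_penalized_despite_perfect_correlation(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=30)
        y = x + 10 * x.std()
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(1.0)
        assert icc_absolute_agreement(x, y) < 0.2

    def test_toy_table_matches_anova_oracle(self):
        x = [0.12, 0.40, 0.31, 0.52, 0.09, 0.27]
        y = [0.15, 0.44, 0.28, 0.49, 0.14, 0.30]
        assert icc_absolute_agreement(x, y) == pytest.approx(icc_a1_oracle(x, y), abs=1e-12)

    def test_matches_pingouin_icc2(self):
        """Cross-check against an independent ICC implementation (two-way
        random, single rater, absolute agreement)."""
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, size=12)
        y = x + rng.normal(scale=0.08, size=12) + 0.05
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 2),
                "raters": np.tile(["full", "reduced"], 12),
                "scores": np.column_stack([x, y]).ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        expected = float(
            ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        )
        assert icc_absolute_agreement(x, y) == pytest.approx(expected, abs=1e-9)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="zero variance"):
            icc_absolute_agreement([0.2, 0.2, 0.2], [0.2, 0.2, 0.2])


class TestRobustness:
    def test_identical_trials_icc_one(self):
        from motordist import TrialMatrix

        rng = np.random.default_rng(6)
        trials = []
        for s in range(4):
            X = rng.normal(size=(10, 3))
            trials += [
                TrialMatrix(
                    values=X, subject_id=f"s{s}", group=PART,
                    condition="PG", trial_id=f"T{i}",
                )
                for i in range(5)
            ]
        curve = robustness_subsample(trials, fractions=(0.2, 0.5), n_iter=5, seed=0)
        assert curve.icc == pytest.approx((1.0, 1.0), abs=1e-9)

    def test_fraction_bounds_enforced(self, small_matrices):
        with pytest.raises(ValueError, match="strictly in"):
            robustness_subsample(small_matrices, fractions=(0.0, 0.5), n_iter=1)

    def test_icc_decreases_with_removal(self, small_matrices):
        curve = robustness_subsample(small_matrices, fractions=(0.1, 0.8), n_iter=30, seed=2)
        assert curve.icc[0] > curve.icc[1]
        assert curve.fractions_removed == (0.1, 0.8)
        assert len(curve.mean_matrices) == 2

    def test_too_few_trials_rejected(self):
        from motordist import TrialMatrix

        trials = [
            TrialMatrix(
                values=np.random.default_rng(0).normal(size=(10, 3)),
                subject_id="solo", group=PART, condition="PG", trial_id="T0",
            )
        ]
        with pytest.raises(ValueError, match="solo"):
            robustness_subsample(trials, fractions=(0.5,), n_iter=1)


class TestMantel:
    def test_identity(self):
        rng = np.random.default_rng(7)
        D1 = group_matrix(random_symmetric(rng, 6), [PART] * 6)
        res = mantel_test(D1, D1, n_perm=99, seed=0)
        assert res.observed_stat == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        values = random_symmetric(rng, 6, scale=0.4)
        scaled = 0.5 * values + 0.1
        np.fill_diagonal(scaled, 0.0)
        D1 = group_matrix(values, [PART] * 6)
        D2 = group_matrix(scaled, [PART] * 6)
        assert mantel_test(D1, D2, n_perm=99, seed=0).observed_stat == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_at_n5(self):
        rng = np.random.default_rng(9)
        v1, v2 = random_symmetric(rng, 5), random_symmetric(rng, 5)
        observed, exact_p = mantel_exact_p(v1, v2)
        D1 = group_matrix(v1, [PART] * 5)
        D2 = group_matrix(v2, [PART] * 5)
        n_perm = 4000
        res = mantel_test(D1, D2, n_perm=n_perm, seed=10, p_convention="pure_count")
        assert res.observed_stat == pytest.approx(observed, abs=1e-12)
        se = np.sqrt(exact_p * (1 - exact_p) / n_perm)
        assert abs(res.p_empirical - exact_p) <= 3 * se

    def test_matches_skbio_statistic(self):
        """Observed r agrees with an independent Mantel implementation."""
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(10)
        v1, v2 = random_symmetric(rng, 8), random_symmetric(rng, 8)
        r_ref, _, _ = skbio_mantel(
            SkbioDM(v1), SkbioDM(v2), method="pearson", permutations=0
        )
        D1 = group_matrix(v1, [PART] * 8)
        D2 = group_matrix(v2, [PART] * 8)
        res = mantel_test(D1, D2, n_perm=10, seed=0)
        assert res.observed_stat == pytest.approx(float(r_ref), abs=1e-10)

    def test_add_one_p_floor(self):
        rng = np.random.default_rng(11)
        D1 = group_matrix(random_symmetric(rng, 6), [PART] * 6)
        res = mantel_test(D1, D1, n_perm=200, seed=0)
        assert res.p_empirical >= 1 / 201

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(12)
        D1 = group_matrix(random_symmetric(rng, 5), [PART] * 5)
        D2 = DistanceMatrix(
            values=random_symmetric(rng, 5),
            labels=tuple(f"other{i}" for i in range(5)),
            groups=(PART,) * 5,
            condition="PG",
        )
        with pytest.raises(ValueError, match="label"):
            mantel_test(D1, D2)
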