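"""Identification decoding: pairwise, grid sweep, N-way, permutation null."""

import itertools

import numpy as np
import pytest

from musid import (
    IdentificationEngine,
    enumerate_folds,
    fit_encoding,
    identification_sweep,
    identify_nway,
    identify_pair,
    lomo_accuracy,
    medley_folds,
    nway_accuracy,
    permutation_null,
)
from musid.decoding import _corr_grid
from musid.encoding import VoxelRanking

from conftest import make_dataset


def _flat_corr(a, b):
    return np.corrcoef(a.ravel(), b.ravel())[0, 1]


class TestIdentifyPair:
    def test_exact_prediction_wins(self):
        rng = np.random.default_rng(0)
        meas_a = rng.standard_normal((6, 4))
        meas_b = rng.standard_normal((6, 4))
        ok_a, ok_b = identify_pair(meas_a, meas_b, meas_a, meas_b)
        assert ok_a and ok_b

    def test_swapped_predictions_fail(self):
        rng = np.random.default_rng(1)
        meas_a = rng.standard_normal((6, 4))
        meas_b = rng.standard_normal((6, 4))
        ok_a, ok_b = identify_pair(meas_a, meas_b, meas_b, meas_a)
        assert not ok_a and not ok_b

    def test_matches_hand_correlation_oracle(self):
        """Toy 3-voxel, 2-timepoint case against direct arithmetic."""
        meas_a = np.array([[1.0, 2.0, 0.5], [2.0, 1.0, 0.0]])
        meas_b = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.5]])
        pred_a = np.array([[0.9, 2.1, 0.4], [2.2, 0.8, 0.1]])
        pred_b = np.array([[0.1, 1.2, 1.9], [0.8, 0.2, 1.4]])
        expect_a = _flat_corr(meas_a, pred_a) > _flat_corr(meas_a, pred_b)
        expect_b = _flat_corr(meas_b, pred_b) > _flat_corr(meas_b, pred_a)
        assert identify_pair(meas_a, meas_b, pred_a, pred_b) == (expect_a, expect_b)

    def test_zero_variance_counts_incorrect(self):
        flat = np.ones((4, 3))
        other = np.arange(12.0).reshape(4, 3)
        ok_a, ok_b = identify_pair(flat, other, flat, other)
        assert not ok_a  # undefined correlation → conservative
        assert ok_b

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        ma, mb = rng.standard_normal((2, 5, 3))
        pa, pb = ma + 0.1 * rng.standard_normal((5, 3)), rng.standard_normal((5, 3))
        base = identify_pair(ma, mb, pa, pb)
        scaled = identify_pair(3 * ma - 1, 3 * mb - 1, 0.5 * pa + 2, 0.5 * pb + 2)
        assert base == scaled

    def test_ranking_restriction(self):
        """Only the selected top voxels and leading timepoints matter."""
        rng = np.random.default_rng(3)
        ma, mb, pa, pb = rng.standard_normal((4, 8, 5))
        ranking = VoxelRanking(np.array([4, 2, 0, 1, 3]), np.array([5.0, 4, 3, 2, 1]))
        got = identify_pair(ma, mb, pa, pb, ranking, n_voxels=2, n_timepoints=3)
        cols = [4, 2]
        expect_a = _flat_corr(ma[:3][:, cols], pa[:3][:, cols]) > _flat_corr(
            ma[:3][:, cols], pb[:3][:, cols]
        )
        expect_b = _flat_corr(mb[:3][:, cols], pb[:3][:, cols]) > _flat_corr(
            mb[:3][:, cols], pa[:3][:, cols]
        )
        assert got == (expect_a, expect_b)


class TestCorrGrid:
    def test_matches_naive_loop(self):
        rng = np.random.default_rng(4)
        meas = rng.standard_normal((7, 6))
        pred = rng.standard_normal((7, 6))
        grid = _corr_grid(meas, pred)
        for t in range(1, 8):
            for v in range(1, 7):
                got = grid[t - 1, v - 1]
                block_m = meas[:t, :v].ravel()
                block_p = pred[:t, :v].ravel()
                if t * v < 2:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(
                        np.corrcoef(block_m, block_p)[0, 1], abs=1e-10
                    )

    def test_zero_variance_cells_nan(self):
        meas = np.ones((4, 3))
        pred = np.arange(12.0).reshape(4, 3)
        grid = _corr_grid(meas, pred)
        assert np.all(np.isnan(grid))


class TestSweep:
    def test_noiseless_accuracy_100(self, design, noiseless_dataset):
        cfg, raw, feats, bold, gt = noiseless_dataset
        folds = enumerate_folds(design, 2)[:40]
        grid = identification_sweep(
            bold, feats, design, voxel_grid=(1, 2, 5, 20, 40), folds=folds
        )
        # perfect signal: exact identification wherever the flattened block
        # has ≥ 3 samples (length-2 vectors give ±1 correlations for any
        # input, so the true piece ties its competitor half the time there)
        v = np.asarray(grid.voxel_grid)[:, None]
        t = np.arange(1, grid.accuracy.shape[1] + 1)[None, :]
        informative = v * t >= 3
        assert np.all(grid.accuracy[informative] == 100.0)

    def test_denominator_counts(self, design, noiseless_dataset):
        cfg, raw, feats, bold, gt = noiseless_dataset
        folds = enumerate_folds(design, 2)[:30]
        grid = identification_sweep(bold, feats, design, folds=folds)
        assert grid.n_identifications == 60
        assert grid.per_pair_outcomes.shape == (30, 2)

    def test_full_pairwise_design_would_give_1560(self, design):
        folds = enumerate_folds(design, 2)
        assert 2 * len(folds) == 1560


class TestNway:
    def test_ranked_accuracy_endpoints_and_midpoint(self):
        # (N − rank)/(N − 1): rank 1 of 10 → 1.0; rank 10 of 10 → 0.0;
        # rank 3 of 5 → 0.5
        for n, rank, expected in [(10, 1, 1.0), (10, 10, 0.0), (5, 3, 0.5)]:
            assert (n - rank) / (n - 1) == pytest.approx(expected)

    def test_noiseless_nway_perfect(self, design, noiseless_dataset):
        cfg, raw, feats, bold, gt = noiseless_dataset
        engine = IdentificationEngine(bold, feats, design)
        res = nway_accuracy(
            bold, feats, design, n_test=5, max_folds=20, seed=0, engine=engine,
            n_voxels=40,
        )
        assert res.accuracy_pct == 100.0
        assert res.ranked_accuracy == 1.0

    def test_rank_against_bruteforce(self, design, noisy_dataset):
        """Engine ranks match a direct correlation-sorting oracle."""
        cfg, raw, feats, bold, gt = noisy_dataset
        engine = IdentificationEngine(bold, feats, design)
        fold = enumerate_folds(design, 4, max_folds=4, seed=3)[2]
        ranks, ranked_acc = identify_nway(engine, fold, n_voxels=50, n_timepoints=10)
        # oracle: refit, predict, correlate, sort
        res = fit_encoding(bold, feats, design, fold)
        ranking = res.rank_voxels()
        top = ranking.top(50)
        for i, p in enumerate(fold.test_piece_ids):
            meas = engine.measured[p][:10][:, top].ravel()
            corrs = {
                q: _flat_corr(meas, res.predict_piece(q)[:10][:, top])
                for q in fold.test_piece_ids
            }
            better = sum(1 for q, c in corrs.items() if q != p and c >= corrs[p])
            assert ranks[i] == 1 + better
        np.testing.assert_allclose(ranked_acc, (4 - ranks) / 3)

    def test_lomo_uses_medley_folds(self, design, noiseless_dataset):
        cfg, raw, feats, bold, gt = noiseless_dataset
        res = lomo_accuracy(bold, feats, design, n_voxels=40)
        assert res.ranks.shape == (4, 10)
        assert res.accuracy_pct == 100.0


class TestPermutationNull:
    def test_null_centred_at_chance_and_threshold_above(self, design, noisy_dataset):
        cfg, raw, feats, bold, gt = noisy_dataset
        engine = IdentificationEngine(bold, feats, design)
        folds = enumerate_folds(design, 2)[:80]
        null = permutation_null(
            bold, feats, design, n_perms=400, seed=9, folds=folds, engine=engine
        )
        assert null.accuracies.mean() == pytest.approx(50.0, abs=2.0)
        assert null.threshold >= null.accuracies.mean()

    def test_null_wider_than_iid_binomial(self, design, noisy_dataset):
        """Shared pieces across pairs correlate outcomes, inflating the null
        spread beyond binomial(n_id, 0.5)."""
        from scipy import stats

        cfg, raw, feats, bold, gt = noisy_dataset
        engine = IdentificationEngine(bold, feats, design)
        folds = enumerate_folds(design, 2)  # all 780 pairs share pieces
        null = permutation_null(
            bold, feats, design, n_perms=300, seed=10, folds=folds, engine=engine
        )
        n_id = 2 * len(folds)
        binom_q95 = 100.0 * stats.binom.ppf(0.95, n_id, 0.5) / n_id
        assert null.threshold > binom_q95

    def test_determinism(self, design, noisy_dataset):
        cfg, raw, feats, bold, gt = noisy_dataset
        engine = IdentificationEngine(bold, feats, design)
        folds = enumerate_folds(design, 2)[:40]
        a = permutation_null(bold, feats, design, n_perms=150, seed=5,
                             folds=folds, engine=engine)
        b = permutation_null(bold, feats, design, n_perms=150, seed=5,
                             folds=folds, engine=engine)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)

    def test_too_few_perms_rejected(self, design, noisy_dataset):
        cfg, raw, feats, bold, gt = noisy_dataset
        with pytest.raises(ValueError, match="n_perms"):
            permutation_null(bold, feats, design, n_perms=10)
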