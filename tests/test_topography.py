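"""Feature correlations, PCA, component similarity, stable matching."""

import itertools

import numpy as np
import pytest

from musid import (
    component_similarity,
    enumerate_folds,
    feature_correlations,
    pca,
    rank_voxels,
    score_overlay_export,
    stable_match,
)
from musid.topography import FeatureCorrelationMap, PcaResult


def _pca_result(loadings):
    loadings = np.asarray(loadings, float)
    k = loadings.shape[1]
    return PcaResult(
        loadings=loadings,
        scores=np.zeros((5, k)),
        explained_variance_fraction=np.linspace(0.5, 0.1, k),
    )


class TestFeatureCorrelations:
    def test_voxel_copy_of_feature_has_unit_correlation(self, design, noisy_dataset):
        cfg, raw, feats, bold, gt = noisy_dataset
        # voxel 0 ← exact copy of feature 3 inside every analysis window
        from musid.design import feature_window, piece_volume_window

        def implant(run):
            vals = run.values.copy()
            fm = feats[run.run_id]
            for p in design.pieces_of_medley(run.run_id):
                fa, fb = feature_window(design, p)
                ba, bb = piece_volume_window(design, p)
                vals[ba:bb, 0] = fm.values[fa:fb, 3]
            return type(run)(vals, run.session_id, run.run_id, run.tr_s)

        bold2 = bold.map(implant)
        fold = enumerate_folds(design, 2)[0]
        ranking = rank_voxels(bold2, feats, design, fold)
        fcm = feature_correlations(bold2, feats, design, ranking, n_voxels=30)
        row = np.flatnonzero(fcm.voxel_ids == 0)[0]
        assert fcm.values[row, 3] == pytest.approx(1.0, abs=1e-10)

    def test_noise_voxels_near_zero(self, design):
        """Pure-noise voxels correlate with every feature at null scale
        (sd ≈ 1/√n); tested on un-preprocessed data so no shared global
        component is re-introduced."""
        from conftest import make_dataset

        cfg, raw, feats, bold, gt = make_dataset(
            design, preprocess=False, savgol_window_s=242.0,
            n_voxels=60, n_responsive_voxels=20, noise_sd=1.0,
            drift_amplitude=0.0, seed=17,
        )
        fold = enumerate_folds(design, 2)[0]
        ranking = rank_voxels(bold, feats, design, fold)
        fcm = feature_correlations(bold, feats, design, ranking,
                                   n_voxels=cfg.n_voxels)
        n_total = design.n_sessions * design.n_pieces * design.vols_per_piece
        noise_rows = np.isin(fcm.voxel_ids, np.arange(cfg.n_responsive_voxels),
                             invert=True)
        assert np.abs(fcm.values[noise_rows]).max() < 6 / np.sqrt(n_total)

    def test_matches_direct_oracle_toy(self, small_design):
        from conftest import make_dataset

        cfg, raw, feats, bold, gt = make_dataset(
            small_design, preprocess=False, savgol_window_s=None,
            n_voxels=4, n_responsive_voxels=4, noise_sd=0.5, seed=5,
        )
        fold = enumerate_folds(small_design, 2)[0]
        ranking = rank_voxels(bold, feats, small_design, fold, k_inner=2)
        fcm = feature_correlations(bold, feats, small_design, ranking, n_voxels=4)
        # oracle for one (voxel, feature) entry by direct aggregation
        from musid.design import feature_window, piece_volume_window

        v = fcm.voxel_ids[0]
        xs, ys = [], []
        for s in range(small_design.n_sessions):
            for m in range(small_design.n_medleys):
                run = bold.get(s, m)
                for p in small_design.pieces_of_medley(m):
                    fa, fb = feature_window(small_design, p)
                    ba, bb = piece_volume_window(small_design, p)
                    xs.append(feats[m].values[fa:fb, 2])
                    ys.append(run.values[ba:bb, v])
        r = np.corrcoef(np.concatenate(xs), np.concatenate(ys))[0, 1]
        assert fcm.values[0, 2] == pytest.approx(r, abs=1e-12)


class TestPca:
    def test_rank_one_data_single_component(self):
        rng = np.random.default_rng(0)
        direction = rng.standard_normal(6)
        x = np.outer(rng.standard_normal(30), direction)
        x /= np.abs(x).max()
        res = pca(FeatureCorrelationMap(x, np.arange(30), tuple("abcdef")), k=3)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)
        assert res.explained_variance_fraction[1:] == pytest.approx(0.0, abs=1e-12)

    def test_loadings_orthonormal(self, design, noisy_dataset):
        cfg, raw, feats, bold, gt = noisy_dataset
        fold = enumerate_folds(design, 2)[0]
        ranking = rank_voxels(bold, feats, design, fold)
        fcm = feature_correlations(bold, feats, design, ranking, n_voxels=100)
        res = pca(fcm, k=4)
        np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(4),
                                   atol=1e-10)
        assert np.all(np.diff(res.explained_variance_fraction) <= 1e-12)
        assert res.explained_variance_fraction.sum() <= 1 + 1e-12

    def test_matches_eigendecomposition_oracle(self):
        """Toy 5-voxel × 3-feature map against a brute-force covariance
        eigendecomposition (and sklearn as an independent cross-check)."""
        x = np.array(
            [[0.1, 0.5, -0.2], [0.3, 0.1, 0.0], [-0.4, 0.2, 0.6],
             [0.0, -0.3, 0.2], [0.5, 0.4, -0.5]]
        )
        res = pca(x, k=3)
        xc = x - x.mean(0)
        evals = np.sort(np.linalg.eigvalsh(xc.T @ xc / 4))[::-1]
        np.testing.assert_allclose(
            res.explained_variance_fraction, evals / evals.sum(), atol=1e-12
        )
        from sklearn.decomposition import PCA as SkPCA

        sk = SkPCA(n_components=3).fit(x)
        np.testing.assert_allclose(
            res.explained_variance_fraction, sk.explained_variance_ratio_, atol=1e-10
        )
        np.testing.assert_allclose(
            np.abs(res.loadings), np.abs(sk.components_.T), atol=1e-8
        )

    def test_scores_reproduce_centered_data(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((20, 4)) * 0.2
        res = pca(x, k=4)
        xc = x - x.mean(0)
        np.testing.assert_allclose(res.scores @ res.loadings.T, xc, atol=1e-10)

    def test_recovers_two_orthogonal_voxel_groups(self):
        """Two voxel populations with orthogonal feature profiles emerge as
        the top two components at moderate noise."""
        rng = np.random.default_rng(2)
        u = np.zeros(8)
        u[:4] = 0.5
        v = np.zeros(8)
        v[4:] = 0.5
        rows = [u + 0.05 * rng.standard_normal(8) for _ in range(25)]
        rows += [v + 0.05 * rng.standard_normal(8) for _ in range(25)]
        res = pca(np.array(rows), k=2)
        truth = (u - np.mean([u, v], axis=0)) / np.linalg.norm(u - np.mean([u, v], axis=0))
        sim = abs(np.corrcoef(res.loadings[:, 0], truth)[0, 1])
        assert sim > 0.9


class TestComponentSimilarity:
    def test_identical_and_signflipped(self):
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.standard_normal((21, 4)))
        a = _pca_result(q)
        b = _pca_result(q * np.array([1, -1, 1, -1]))
        np.testing.assert_allclose(component_similarity(a, a), 1.0)
        np.testing.assert_allclose(component_similarity(a, b), 1.0)

    def test_random_loadings_baseline(self):
        """Independent 21-dim loading pairs: E|r| ≈ √(2/(π(n−1))) ≈ 0.178."""
        rng = np.random.default_rng(4)
        sims = []
        for _ in range(400):
            a = _pca_result(rng.standard_normal((21, 1)))
            b = _pca_result(rng.standard_normal((21, 1)))
            sims.append(component_similarity(a, b)[0])
        expected = np.sqrt(2 / (np.pi * 20))
        assert np.mean(sims) == pytest.approx(expected, rel=0.15)


class TestStableMatch:
    def test_identity_on_identical_sets(self):
        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.standard_normal((21, 4)))
        res = _pca_result(q)
        np.testing.assert_array_equal(stable_match(res, res), np.arange(4))

    def test_recovers_permutation(self):
        rng = np.random.default_rng(6)
        q, _ = np.linalg.qr(rng.standard_normal((21, 4)))
        perm = np.array([2, 0, 3, 1])
        a = _pca_result(q)
        b = _pca_result(q[:, perm])
        match = stable_match(a, b)
        # individual component i maps to the group column holding its copy
        expected = np.array([int(np.flatnonzero(perm == i)[0]) for i in range(4)])
        np.testing.assert_array_equal(match, expected)

    def test_no_blocking_pair_exhaustive(self):
        """All stable matchings of random 3–5 component problems: the
        returned matching is stable and proposer-optimal."""
        rng = np.random.default_rng(7)
        for k in (3, 4, 5):
            q, _ = np.linalg.qr(rng.standard_normal((21, 2 * k)))
            mix = q[:, :k] @ np.linalg.qr(rng.standard_normal((k, k)))[0]
            a = _pca_result(q[:, :k])
            b = _pca_result(np.clip(mix + 0.1 * rng.standard_normal((21, k)), -1, 1))
            sim = np.abs(np.corrcoef(a.loadings.T, b.loadings.T)[:k, k:])
            match = stable_match(a, b)

            def blocking(match_arr):
                inv = np.argsort(match_arr)
                for i in range(k):
                    for j in range(k):
                        if match_arr[i] == j:
                            continue
                        if sim[i, j] > sim[i, match_arr[i]] and sim[i, j] > sim[inv[j], j]:
                            return True
                return False

            assert not blocking(match)
            # proposer-optimal: every other stable matching is weakly worse
            # for every individual component
            for perm in itertools.permutations(range(k)):
                arr = np.array(perm)
                if np.array_equal(arr, match) or blocking(arr):
                    continue
                assert all(sim[i, match[i]] >= sim[i, arr[i]] - 1e-12 for i in range(k))


class TestOverlayExport:
    def test_scaling_rules(self):
        res = PcaResult(
            loadings=np.eye(3),
            scores=np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]),
            explained_variance_fraction=np.array([0.5, 0.3, 0.2]),
        )
        tc = np.array([0.0, 0.5, 1.0])
        df = score_overlay_export(res, tc, voxel_ids=np.array([10, 11, 12]))
        np.testing.assert_allclose(df["pc1_scaled_score"], [0.0, 2.0, 7.0])
        df2 = score_overlay_export(res, 2 * tc)
        np.testing.assert_allclose(
            df2["pc2_scaled_score"], 2 * df["pc2_scaled_score"]
        )
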