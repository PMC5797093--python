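"""Voxel-wise linear encoding model.

Every voxel's BOLD time series is modelled as an independent ordinary
least squares regression on the conditioned musical features:

    y_v(t) = b_v + sum_j w_vj f_j(t) + e_v(t)

The model is trained on the aggregated volumes of all sessions and all
training pieces of a fold (each repeated presentation contributes its own
rows; at the reference scale 4 sessions × 38 pieces × 23 volumes = 3,496
rows against 21 + 1 parameters, so no regularisation is needed).  Voxels
are then ranked by their mean prediction correlation over an inner
five-fold cross-validation of the training set, piece-blocked so no piece
straddles inner folds.  Test pieces never enter training or ranking.

The module follows the Model/Results convention: build an
:class:`EncodingModel` from data, call :meth:`~EncodingModel.fit`, and work
with the returned :class:`EncodingResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import CvFold, StimulusDesign, feature_window, inner_piece_blocks, piece_volume_window
from .features import FeatureMatrix
from .preprocess import BoldDataset

__all__ = [
    "EncodingModel",
    "EncodingResults",
    "VoxelRanking",
    "TrainingCache",
    "fit_encoding",
    "rank_voxels",
]


def _columnwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of two (n × k) arrays.

    Columns with zero variance yield 0 (uninformative, cannot be ranked).
    """
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    num = (a * b).sum(axis=0)
    den = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    out = np.zeros(a.shape[1])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


@dataclass(frozen=True)
class VoxelRanking:
    """Voxels ordered by mean inner-CV prediction correlation (descending,
    ties broken by ascending voxel id)."""

    voxel_ids: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("ranking scores must be non-increasing")

    def top(self, n: int) -> np.ndarray:
        return self.voxel_ids[:n]

    def __len__(self) -> int:
        return len(self.voxel_ids)


class TrainingCache:
    """Per-piece sufficient statistics shared across folds.

    For piece p let X_p (vols_per_piece × (1+k)) be the intercept-augmented
    feature block and Y_{s,p} the BOLD block of session s at the
    delay-shifted window.  The cache stores

        G_p = n_sessions · X_pᵀ X_p      (features repeat across sessions)
        H_p = X_pᵀ Σ_s Y_{s,p}
        Y_{p,s} blocks                    (for inner-CV correlations)

    so any fold's OLS fit is solve(Σ_train G_p, Σ_train H_p) and leave-out
    refits are cheap subtractions.  Feature subsets reuse the full cache by
    index slicing.
    """

    def __init__(
        self,
        bold: BoldDataset,
        features: list[FeatureMatrix],
        design: StimulusDesign,
    ) -> None:
        d = design
        if len(features) != d.n_medleys:
            raise ValueError(f"expected {d.n_medleys} feature matrices, got {len(features)}")
        self.design = d
        self.n_voxels = bold.n_voxels
        self.n_features = features[0].n_features
        self.sessions = bold.session_ids
        n_sess = len(self.sessions)
        if n_sess != d.n_sessions:
            raise ValueError(f"dataset has {n_sess} sessions, design expects {d.n_sessions}")
        vpp = d.vols_per_piece
        k1 = self.n_features + 1
        P = d.n_pieces
        self.X = np.empty((P, vpp, k1))
        self.G = np.empty((P, k1, k1))
        self.H = np.empty((P, k1, self.n_voxels))
        self.Y = np.empty((P, n_sess, vpp, self.n_voxels))
        for p in range(P):
            m, _ = d.medley_of(p)
            fa, fb = feature_window(d, p)
            xp = np.column_stack([np.ones(vpp), features[m].values[fa:fb]])
            self.X[p] = xp
            ba, bb = piece_volume_window(d, p)
            for si, s in enumerate(self.sessions):
                run = bold.get(s, m)
                if bb > run.n_volumes:
                    raise ValueError(
                        f"piece {p} window [{ba},{bb}) exceeds run length {run.n_volumes}"
                    )
                self.Y[p, si] = run.values[ba:bb]
            self.G[p] = n_sess * (xp.T @ xp)
            self.H[p] = xp.T @ self.Y[p].sum(axis=0)

    def _cols(self, feature_subset: np.ndarray | None) -> np.ndarray:
        if feature_subset is None:
            return np.arange(self.n_features + 1)
        fs = np.asarray(feature_subset, dtype=int)
        if fs.size == 0 or fs.min() < 0 or fs.max() >= self.n_features:
            raise ValueError("feature_subset indices out of range")
        if len(set(fs.tolist())) != fs.size:
            raise ValueError("feature_subset contains duplicates")
        return np.concatenate([[0], fs + 1])

    def solve(
        self, piece_ids, feature_subset: np.ndarray | None = None
    ) -> np.ndarray:
        """OLS coefficients ((1+k_sub) × voxels) on the given pieces."""
        pid = np.asarray(list(piece_ids), dtype=int)
        cols = self._cols(feature_subset)
        A = self.G[pid].sum(axis=0)[np.ix_(cols, cols)]
        B = self.H[pid].sum(axis=0)[cols]
        try:
            return np.linalg.solve(A, B)
        except np.linalg.LinAlgError as e:
            raise ValueError(f"collinear features in training design: {e}") from e

    def inner_cv_scores(
        self,
        train_ids: tuple[int, ...],
        k_inner: int = 5,
        feature_subset: np.ndarray | None = None,
    ) -> np.ndarray:
        """Mean prediction correlation per voxel over the inner folds."""
        blocks = inner_piece_blocks(train_ids, k_inner)
        cols = self._cols(feature_subset)
        train = np.asarray(sorted(train_ids), dtype=int)
        G_tot = self.G[train].sum(axis=0)[np.ix_(cols, cols)]
        H_tot = self.H[train].sum(axis=0)[cols]
        scores = np.zeros(self.n_voxels)
        n_sess = self.Y.shape[1]
        for block in blocks:
            bid = np.asarray(block, dtype=int)
            A = G_tot - self.G[bid].sum(axis=0)[np.ix_(cols, cols)]
            B = H_tot - self.H[bid].sum(axis=0)[cols]
            coef = np.linalg.solve(A, B)
            # held-out rows: every session's volumes of the block pieces
            pred_piece = self.X[bid][:, :, cols] @ coef  # (b, vpp, V)
            pred = np.repeat(pred_piece, n_sess, axis=0).reshape(-1, self.n_voxels)
            meas = self.Y[bid].reshape(-1, self.n_voxels)
            scores += _columnwise_corr(pred, meas)
        return scores / len(blocks)

    def measured_piece_mean(self, piece_id: int, trimmed: bool = True) -> np.ndarray:
        """BOLD block of a piece averaged over the repeated presentations."""
        t = self.design.transition_trim_vols if trimmed else 0
        vpp = self.design.vols_per_piece
        return self.Y[piece_id, :, t : vpp - t].mean(axis=0)

    def feature_block(
        self, piece_id: int, trimmed: bool = True,
        feature_subset: np.ndarray | None = None,
    ) -> np.ndarray:
        """Intercept-augmented feature block of a piece (trimmed window)."""
        t = self.design.transition_trim_vols if trimmed else 0
        vpp = self.design.vols_per_piece
        cols = self._cols(feature_subset)
        return self.X[piece_id, t : vpp - t][:, cols]


class EncodingModel:
    """Voxel-wise OLS encoding model for one cross-validation fold.

    Parameters
    ----------
    bold
        Preprocessed BOLD dataset (all sessions and runs).
    features
        Conditioned feature matrices, one per medley, at TR resolution.
    design
        Temporal layout; supplies the windows and the delay shift.
    fold
        Train/test piece partition.  Test pieces are never touched during
        fitting or voxel ranking.
    feature_subset
        Optional feature indices (into the 21 columns) restricting the
        regressor set; used by the sparsity sweep.
    cache
        A shared :class:`TrainingCache` may be passed to amortise the
        per-piece sufficient statistics over many folds.
    """

    def __init__(
        self,
        bold: BoldDataset | None,
        features: list[FeatureMatrix] | None,
        design: StimulusDesign,
        fold: CvFold,
        feature_subset: np.ndarray | None = None,
        cache: TrainingCache | None = None,
    ) -> None:
        if cache is None:
            if bold is None or features is None:
                raise ValueError("either bold+features or a TrainingCache is required")
            cache = TrainingCache(bold, features, design)
        self.cache = cache
        self.design = design
        self.fold = fold
        self.feature_subset = (
            None if feature_subset is None else np.asarray(feature_subset, dtype=int)
        )
        bad = set(fold.test_piece_ids) | set(fold.train_piece_ids)
        if bad - set(design.piece_ids) or len(bad) != design.n_pieces:
            raise ValueError("fold does not partition the design's piece set")

    @property
    def n_training_rows(self) -> int:
        return (
            self.design.n_sessions
            * len(self.fold.train_piece_ids)
            * self.design.vols_per_piece
        )

    def fit(self) -> "EncodingResults":
        coef = self.cache.solve(self.fold.train_piece_ids, self.feature_subset)
        return EncodingResults(self, intercepts=coef[0], weights=coef[1:].T)

    def rank_voxels(self, k_inner: int = 5) -> VoxelRanking:
        """Rank voxels by mean inner-CV prediction correlation.

        Uses only training pieces; deterministic (ties by voxel id).  For
        miniature designs with fewer training pieces than ``k_inner`` the
        split degrades gracefully to one block per piece.
        """
        k_eff = min(k_inner, len(self.fold.train_piece_ids))
        scores = self.cache.inner_cv_scores(
            self.fold.train_piece_ids, k_eff, self.feature_subset
        )
        order = np.lexsort((np.arange(len(scores)), -scores))
        return VoxelRanking(voxel_ids=order, scores=scores[order])


@dataclass
class EncodingResults:
    """Fitted encoding model: weights (voxels × k) and intercepts."""

    model: EncodingModel
    intercepts: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite encoding weights")

    @property
    def fold(self) -> CvFold:
        return self.model.fold

    @property
    def feature_subset(self) -> np.ndarray | None:
        return self.model.feature_subset

    def predict_piece(self, piece_id: int, trimmed: bool = True) -> np.ndarray:
        """Predicted BOLD block (window × voxels) for a *test* piece.

        Raises if the piece was in the training set (leakage guard).
        """
        if piece_id not in self.fold.test_piece_ids:
            raise ValueError(
                f"piece {piece_id} is not in the test set of this fold; "
                "predicting training pieces would leak"
            )
        xb = self.model.cache.feature_block(piece_id, trimmed, self.feature_subset)
        coef = np.vstack([self.intercepts, self.weights.T])
        return xb @ coef

    def rank_voxels(self, k_inner: int = 5) -> VoxelRanking:
        return self.model.rank_voxels(k_inner)

    def summary(self) -> str:
        w = self.weights
        lines = [
            "Voxel-wise encoding model (OLS)",
            "================================",
            f"training pieces : {len(self.fold.train_piece_ids)}",
            f"test pieces     : {list(self.fold.test_piece_ids)}",
            f"training rows   : {self.model.n_training_rows}",
            f"voxels          : {w.shape[0]}",
            f"features        : {w.shape[1]}"
            + ("" if self.feature_subset is None else f" (subset {self.feature_subset.tolist()})"),
            f"weight range    : [{w.min():+.4f}, {w.max():+.4f}]",
            f"mean |intercept|: {np.abs(self.intercepts).mean():.2e}",
        ]
        return "\n".join(lines)


def fit_encoding(
    bold: BoldDataset,
    features: list[FeatureMatrix],
    design: StimulusDesign,
    fold: CvFold,
    feature_subset: np.ndarray | None = None,
) -> EncodingResults:
    """Convenience wrapper: build the model and fit it."""
    return EncodingModel(bold, features, design, fold, feature_subset).fit()


def rank_voxels(
    bold: BoldDataset,
    features: list[FeatureMatrix],
    design: StimulusDesign,
    fold: CvFold,
    k_inner: int = 5,
) -> VoxelRanking:
    """Convenience wrapper for :meth:`EncodingModel.rank_voxels`."""
    return EncodingModel(bold, features, design, fold).rank_voxels(k_inner)
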