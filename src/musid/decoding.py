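"""Stimulus identification from measured BOLD.

For each cross-validation fold the fitted encoding model predicts the
BOLD block of every held-out piece from its musical features.  A measured
test block (averaged over the repeated presentations, transition volumes
trimmed) is assigned to the candidate whose predicted block correlates
best with it after concatenating the space × time block to one vector.
Binary identification compares two candidates; N-way identification ranks
up to 10, with ranked accuracy (N − rank)/(N − 1).

Accuracy is swept over the number of top-ranked voxels and the number of
time points used; the chance level of the binary task is 50% and the
significance threshold comes from a permutation null in which the piece
labels are shuffled at the decoding stage only.

Correlation ties (and undefined correlations from zero-variance vectors)
count against the decoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .design import CvFold, StimulusDesign, enumerate_folds, medley_folds
from .encoding import EncodingModel, TrainingCache, VoxelRanking
from .entropy import EntropyTable, entropy_ranking
from .features import FeatureMatrix
from .preprocess import BoldDataset

__all__ = [
    "DEFAULT_VOXEL_GRID",
    "IdentificationGrid",
    "PermutationNull",
    "NwayResult",
    "IdentificationEngine",
    "predict_piece",
    "identify_pair",
    "identification_sweep",
    "identify_nway",
    "nway_accuracy",
    "lomo_accuracy",
    "permutation_null",
    "entropy_split_accuracy",
]

log = logging.getLogger(__name__)

#: Default sweep grid over the number of top-ranked voxels.
DEFAULT_VOXEL_GRID: tuple[int, ...] = (2, 5, 10, 25, 50, 100, 200, 300, 500, 1000)


@dataclass
class IdentificationGrid:
    """Accuracy (percent) per (voxel-grid entry, time points 1..t_max)."""

    voxel_grid: np.ndarray
    accuracy: np.ndarray  # (len(voxel_grid), t_max), percent
    n_identifications: int
    #: per fold × test-piece outcome at the reference cell
    per_pair_outcomes: np.ndarray
    reference_cell: tuple[int, int]  # (n_voxels, n_timepoints) of the outcomes

    def accuracy_at(self, n_voxels: int, n_timepoints: int) -> float:
        i = int(np.flatnonzero(self.voxel_grid == n_voxels)[0])
        return float(self.accuracy[i, n_timepoints - 1])


@dataclass
class PermutationNull:
    """Empirical null of identification accuracy under label permutation."""

    n_perms: int
    accuracies: np.ndarray  # percent
    alpha: float
    threshold: float  # empirical (1 − alpha) quantile, percent


@dataclass
class NwayResult:
    """N-way identification over a set of folds."""

    n_test: int
    accuracy_pct: float
    ranked_accuracy: float
    ranks: np.ndarray  # (folds × n_test) rank of the true piece, 1 = best
    n_identifications: int


def _corr_grid(meas: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Correlation of flattened top-(t, v) sub-blocks for every (t, v).

    ``meas``/``pred`` are (t_max × v_max) with columns already in ranking
    order.  Entry [t-1, v-1] is the Pearson r between the two blocks
    restricted to the first t time points and v voxels, flattened.  Cells
    whose blocks have zero variance (or a single element) are NaN.
    Computed with 2-D prefix sums, O(t_max · v_max) total.
    """
    def cs(a):
        return a.cumsum(axis=0).cumsum(axis=1)

    sxy = cs(meas * pred)
    sx = cs(meas)
    sy = cs(pred)
    sxx = cs(meas * meas)
    syy = cs(pred * pred)
    t_max, v_max = meas.shape
    n = np.outer(np.arange(1, t_max + 1), np.arange(1, v_max + 1)).astype(float)
    cov = sxy - sx * sy / n
    vx = sxx - sx * sx / n
    vy = syy - sy * sy / n
    scale = np.maximum(sxx + syy, 1e-300)
    bad = (vx <= 1e-13 * scale) | (vy <= 1e-13 * scale) | (n < 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vx * vy)
    r[bad] = np.nan
    return r


class IdentificationEngine:
    """Shared machinery for all identification analyses.

    Builds the per-piece sufficient statistics once (via
    :class:`~musid.encoding.TrainingCache`) and evaluates folds cheaply:
    fit, rank voxels, predict test pieces, correlate against the
    presentation-averaged measured blocks.
    """

    def __init__(
        self,
        bold: BoldDataset,
        features: list[FeatureMatrix],
        design: StimulusDesign,
        feature_subset: np.ndarray | None = None,
        k_inner: int = 5,
    ) -> None:
        self.design = design
        self.cache = TrainingCache(bold, features, design)
        self.feature_subset = feature_subset
        self.k_inner = k_inner
        self.t_max = design.retained_vols_per_piece
        # presentation-averaged measured blocks, trimmed: (pieces, t_max, V)
        self.measured = np.stack(
            [self.cache.measured_piece_mean(p) for p in design.piece_ids]
        )

    @property
    def n_voxels(self) -> int:
        return self.cache.n_voxels

    def _fold_model(self, fold: CvFold) -> tuple[np.ndarray, VoxelRanking]:
        model = EncodingModel(None, None, self.design, fold,
                              self.feature_subset, cache=self.cache)
        res = model.fit()
        return res, model.rank_voxels(self.k_inner)

    def fold_prediction(self, res, piece_id: int) -> np.ndarray:
        return res.predict_piece(piece_id, trimmed=True)

    def fold_correlations(
        self,
        fold: CvFold,
        n_voxels: int,
        n_timepoints: int,
        candidates: str = "test",
    ) -> tuple[np.ndarray, np.ndarray]:
        """Correlations of each measured test block against candidate
        predictions at one (n_voxels, n_timepoints) cell.

        Returns (corr matrix |test| × |candidates|, candidate piece ids).
        ``candidates='all'`` predicts every piece of the stimulus set with
        this fold's weights (used by the permutation null).
        """
        res, ranking = self._fold_model(fold)
        v = min(n_voxels, self.n_voxels)
        top = ranking.top(v)
        cand = (
            np.asarray(fold.test_piece_ids)
            if candidates == "test"
            else np.arange(self.design.n_pieces)
        )
        t = n_timepoints
        coef = np.vstack([res.intercepts, res.weights.T])  # (1+k, V)
        corr = np.empty((len(fold.test_piece_ids), len(cand)))
        meas_vecs = [
            self.measured[a][:t][:, top].ravel() for a in fold.test_piece_ids
        ]
        for j, c in enumerate(cand):
            xb = self.cache.feature_block(int(c), True, self.feature_subset)[:t]
            pv = (xb @ coef)[:, top].ravel()
            for i, mv in enumerate(meas_vecs):
                corr[i, j] = _pearson_or_nan(mv, pv)
        return corr, cand

    def evaluate_fold_grid(
        self, fold: CvFold, voxel_grid: np.ndarray
    ) -> np.ndarray:
        """Boolean outcomes (|test| × len(grid) × t_max) for a binary fold."""
        if fold.n_test != 2:
            raise ValueError("grid evaluation is defined for pairwise folds")
        res, ranking = self._fold_model(fold)
        order = ranking.voxel_ids
        a, b = fold.test_piece_ids
        pred = {p: res.predict_piece(p, trimmed=True)[:, order] for p in (a, b)}
        grid_idx = np.minimum(voxel_grid, self.n_voxels) - 1
        out = np.empty((2, len(voxel_grid), self.t_max), dtype=bool)
        for i, (mine, other) in enumerate(((a, b), (b, a))):
            meas = self.measured[mine][:, order]
            r_true = _corr_grid(meas, pred[mine])
            r_other = _corr_grid(meas, pred[other])
            with np.errstate(invalid="ignore"):
                # undefined own correlation (or a tie) loses; an undefined
                # competitor cannot win
                correct = ~np.isnan(r_true) & (np.isnan(r_other) | (r_true > r_other))
            out[i] = correct[:, grid_idx].T
        return out

    def evaluate_fold_nway(
        self, fold: CvFold, n_voxels: int, n_timepoints: int
    ) -> np.ndarray:
        """Rank of the true piece for every measured test piece (1 = best).

        Ties give the true piece the worst tied rank (conservative).
        """
        corr, cand = self.fold_correlations(fold, n_voxels, n_timepoints, "test")
        ranks = np.empty(fold.n_test, dtype=int)
        for i, p in enumerate(fold.test_piece_ids):
            true_j = int(np.flatnonzero(cand == p)[0])
            r = corr[i]
            rt = r[true_j]
            if np.isnan(rt):
                ranks[i] = fold.n_test
                log.warning("zero-variance block for piece %d; counted worst", p)
                continue
            others = np.delete(r, true_j)
            better = np.sum(others >= rt)  # ties count against the decoder
            ranks[i] = 1 + int(better)
        return ranks


def _pearson_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    den = np.sqrt((x**2).sum() * (y**2).sum())
    if den == 0 or x.size < 2:
        return np.nan
    return float((x * y).sum() / den)


# -- spec-level operations ----------------------------------------------


def predict_piece(results, features, piece_id: int, design=None) -> np.ndarray:
    """Linear prediction (trimmed window × voxels) of a test piece.

    Thin wrapper over :meth:`EncodingResults.predict_piece`; raises if the
    piece is not held out in the results' fold.
    """
    return results.predict_piece(piece_id, trimmed=True)


def identify_pair(
    measured_a: np.ndarray,
    measured_b: np.ndarray,
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    ranking: VoxelRanking | None = None,
    n_voxels: int | None = None,
    n_timepoints: int | None = None,
) -> tuple[bool, bool]:
    """Binary identification of two measured blocks (window × voxels).

    Restricts to the top ``n_voxels`` of ``ranking`` and first
    ``n_timepoints`` volumes, concatenates each space × time block to one
    vector and compares prediction correlations.  A piece is correct iff
    its measured block correlates strictly better with its own prediction;
    ties and undefined correlations count as incorrect.
    """
    blocks = [np.asarray(m, dtype=float) for m in (measured_a, measured_b, pred_a, pred_b)]
    if ranking is not None:
        top = ranking.top(n_voxels if n_voxels is not None else len(ranking))
        blocks = [b[:, top] for b in blocks]
    if n_timepoints is not None:
        blocks = [b[:n_timepoints] for b in blocks]
    ma, mb, pa, pb = (b.ravel() for b in blocks)
    ra_own, ra_other = _pearson_or_nan(ma, pa), _pearson_or_nan(ma, pb)
    rb_own, rb_other = _pearson_or_nan(mb, pb), _pearson_or_nan(mb, pa)
    if np.isnan(ra_own) or np.isnan(rb_own):
        log.warning("zero-variance identification vector; counted incorrect")
    # undefined own correlation loses; an undefined competitor cannot win
    ok_a = (not np.isnan(ra_own)) and (np.isnan(ra_other) or ra_own > ra_other)
    ok_b = (not np.isnan(rb_own)) and (np.isnan(rb_other) or rb_own > rb_other)
    return bool(ok_a), bool(ok_b)


def identification_sweep(
    bold: BoldDataset,
    features: list[FeatureMatrix],
    design: StimulusDesign,
    voxel_grid: tuple[int, ...] | None = None,
    folds: list[CvFold] | None = None,
    reference_cell: tuple[int, int] = (100, 17),
    engine: IdentificationEngine | None = None,
) -> IdentificationGrid:
    """Binary identification accuracy over (voxels × time points).

    Accuracy(v, t) = 100 × correct / total identifications over all folds
    (2 identifications per pairwise fold).
    """
    if engine is None:
        engine = IdentificationEngine(bold, features, design)
    if folds is None:
        folds = enumerate_folds(design, n_test=2)
    grid = np.asarray(voxel_grid if voxel_grid is not None else DEFAULT_VOXEL_GRID)
    correct = np.zeros((len(grid), engine.t_max))
    ref_v, ref_t = reference_cell
    ref_t = min(ref_t, engine.t_max)
    ref_vi = int(np.argmin(np.abs(np.minimum(grid, engine.n_voxels) - ref_v)))
    outcomes = np.empty((len(folds), 2), dtype=bool)
    for fi, fold in enumerate(folds):
        out = engine.evaluate_fold_grid(fold, grid)
        correct += out.sum(axis=0)
        outcomes[fi] = out[:, ref_vi, ref_t - 1]
    n_id = 2 * len(folds)
    return IdentificationGrid(
        voxel_grid=grid,
        accuracy=100.0 * correct / n_id,
        n_identifications=n_id,
        per_pair_outcomes=outcomes,
        reference_cell=(int(grid[ref_vi]), ref_t),
    )


def identify_nway(
    engine: IdentificationEngine,
    fold: CvFold,
    n_voxels: int = 100,
    n_timepoints: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ranks of the true pieces and their ranked accuracies for one fold.

    Ranked accuracy = (N − rank)/(N − 1): 1 when the true piece wins, 0
    when it comes last.
    """
    t = n_timepoints if n_timepoints is not None else engine.t_max
    ranks = engine.evaluate_fold_nway(fold, n_voxels, t)
    n = fold.n_test
    return ranks, (n - ranks) / (n - 1)


def nway_accuracy(
    bold: BoldDataset,
    features: list[FeatureMatrix],
    design: StimulusDesign,
    n_test: int,
    folds: list[CvFold] | None = None,
    max_folds: int | None = 10_000,
    seed: int | None = 0,
    n_voxels: int = 100,
    n_timepoints: int | None = None,
    engine: IdentificationEngine | None = None,
) -> NwayResult:
    """Accuracy and ranked accuracy for identifying one piece out of N."""
    if engine is None:
        engine = IdentificationEngine(bold, features, design)
    if folds is None:
        import math

        if max_folds is not None:
            max_folds = min(max_folds, math.comb(design.n_pieces, n_test))
        folds = enumerate_folds(design, n_test, max_folds=max_folds, seed=seed)
    ranks = np.empty((len(folds), n_test), dtype=int)
    for i, fold in enumerate(folds):
        ranks[i], _ = identify_nway(engine, fold, n_voxels, n_timepoints)
    return NwayResult(
        n_test=n_test,
        accuracy_pct=100.0 * float(np.mean(ranks == 1)),
        ranked_accuracy=float(np.mean((n_test - ranks) / (n_test - 1))),
        ranks=ranks,
        n_identifications=ranks.size,
    )


def lomo_accuracy(
    bold: BoldDataset,
    features: list[FeatureMatrix],
    design: StimulusDesign,
    n_voxels: int = 100,
    n_timepoints: int | None = None,
    engine: IdentificationEngine | None = None,
) -> NwayResult:
    """Leave-one-medley-out: identify the 10 pieces of a whole held-out run."""
    if engine is None:
        engine = IdentificationEngine(bold, features, design)
    folds = medley_folds(design)
    ranks = np.empty((len(folds), design.pieces_per_medley), dtype=int)
    for i, fold in enumerate(folds):
        ranks[i], _ = identify_nway(engine, fold, n_voxels, n_timepoints)
    n = design.pieces_per_medley
    return NwayResult(
        n_test=n,
        accuracy_pct=100.0 * float(np.mean(ranks == 1)),
        ranked_accuracy=float(np.mean((n - ranks) / (n - 1))),
        ranks=ranks,
        n_identifications=ranks.size,
    )


def permutation_null(
    bold: BoldDataset,
    features: list[FeatureMatrix],
    design: StimulusDesign,
    n_perms: int = 1000,
    alpha: float = 0.05,
    seed: int | None = 0,
    n_voxels: int = 100,
    n_timepoints: int | None = None,
    folds: list[CvFold] | None = None,
    engine: IdentificationEngine | None = None,
) -> PermutationNull:
    """Null distribution of binary identification accuracy.

    The encoding stage is untouched; at the decoding stage the piece
    labels are randomly permuted over the whole stimulus set, so a
    measured block is compared against the predictions of two scrambled
    candidates.  Per-fold correlations against all candidate predictions
    are precomputed once, making each permutation a pure relabelling.
    """
    if n_perms < 100:
        raise ValueError("n_perms must be >= 100")
    if engine is None:
        engine = IdentificationEngine(bold, features, design)
    if folds is None:
        folds = enumerate_folds(design, n_test=2)
    t = n_timepoints if n_timepoints is not None else engine.t_max
    n_folds = len(folds)
    corr_all = np.empty((n_folds, 2, design.n_pieces))
    pair_ids = np.empty((n_folds, 2), dtype=int)
    for i, fold in enumerate(folds):
        corr, _ = engine.fold_correlations(fold, n_voxels, t, candidates="all")
        corr_all[i] = corr
        pair_ids[i] = fold.test_piece_ids
    rng = np.random.default_rng(seed)
    accs = np.empty(n_perms)
    rows = np.arange(n_folds)
    a_ids, b_ids = pair_ids[:, 0], pair_ids[:, 1]
    for k in range(n_perms):
        perm = rng.permutation(design.n_pieces)
        with np.errstate(invalid="ignore"):
            ok_a = corr_all[rows, 0, perm[a_ids]] > corr_all[rows, 0, perm[b_ids]]
            ok_b = corr_all[rows, 1, perm[b_ids]] > corr_all[rows, 1, perm[a_ids]]
        accs[k] = 100.0 * (ok_a.sum() + ok_b.sum()) / (2 * n_folds)
    return PermutationNull(
        n_perms=n_perms,
        accuracies=accs,
        alpha=alpha,
        threshold=float(np.quantile(accs, 1.0 - alpha)),
    )


def entropy_split_accuracy(
    bold: BoldDataset,
    features: list[FeatureMatrix],
    design: StimulusDesign,
    table: EntropyTable,
    n_voxels: int = 100,
    n_timepoints: int | None = None,
    subset_size: int = 10,
    engine: IdentificationEngine | None = None,
) -> dict[str, float]:
    """Binary accuracy within the lowest- and highest-entropy piece sets.

    Folds are restricted to the C(subset_size, 2) pairs drawn within each
    subset (45 pairs for a 10-piece subset).
    """
    if engine is None:
        engine = IdentificationEngine(bold, features, design)
    low, high = entropy_ranking(table, subset_size)
    t = n_timepoints if n_timepoints is not None else engine.t_max
    all_ids = set(design.piece_ids)

    def _acc(piece_set: tuple[int, ...]) -> float:
        import itertools

        correct = total = 0
        for pair in itertools.combinations(sorted(piece_set), 2):
            fold = CvFold(tuple(pair), tuple(sorted(all_ids - set(pair))))
            ranks = engine.evaluate_fold_nway(fold, n_voxels, t)
            correct += int(np.sum(ranks == 1))
            total += 2
        return 100.0 * correct / total

    return {
        "low_entropy_accuracy_pct": _acc(low),
        "high_entropy_accuracy_pct": _acc(high),
        "n_pairs_per_subset": len(low) * (len(low) - 1) // 2,
    }
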