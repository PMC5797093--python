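"""Per-piece Shannon-entropy information metric.

The similarity between the 21-dimensional feature vectors at every pair of
distinct time points over the *entire* stimulus set is measured by the
Pearson correlation coefficient.  The global range of these similarities
is divided into ``n_bins`` (default 10) equally spaced bins; a piece's
entropy is

    H(X) = − Σ_i p_i log2 p_i        (0 · log 0 := 0)

where p_i is the relative frequency of the piece's *within-piece* pair
similarities falling in bin i.  H is 0 when all within-piece similarities
share one bin and at most log2(n_bins) (uniform occupancy); high H marks
pieces whose feature trajectory keeps changing — rich information content.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .design import StimulusDesign, feature_window
from .features import FeatureMatrix

__all__ = [
    "EntropyTable",
    "SimilaritySet",
    "pairwise_similarity",
    "piece_entropy",
    "entropy_table",
    "entropy_ranking",
]


@dataclass
class SimilaritySet:
    """All-pair feature-vector similarities with piece labels.

    ``matrix`` is the full T × T Pearson-correlation matrix between
    time-point feature vectors; ``piece_of`` labels each time point.  Pairs
    are the strict upper triangle (unordered distinct pairs; self-pairs
    excluded).
    """

    matrix: np.ndarray
    piece_of: np.ndarray

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pairs(self) -> int:
        t = self.n_timepoints
        return t * (t - 1) // 2

    def all_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n_timepoints, k=1)
        return self.matrix[iu]

    def within_piece_values(self, piece_id: int) -> np.ndarray:
        idx = np.flatnonzero(self.piece_of == piece_id)
        if idx.size < 2:
            raise ValueError(f"piece {piece_id} has fewer than 2 retained time points")
        sub = self.matrix[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        return sub[iu]


def pairwise_similarity(
    features: list[FeatureMatrix],
    design: StimulusDesign,
    trimmed: bool = False,
) -> SimilaritySet:
    """Feature-vector similarity (Pearson r) at all distinct time-point
    pairs over the entire stimulus set.

    Rows are the per-piece windows of the conditioned features (full
    23-volume windows by default; ``trimmed`` drops the transition volumes
    instead).
    """
    rows, labels = [], []
    for fm in features:
        m = fm.medley_id
        for p in design.pieces_of_medley(m):
            a, b = feature_window(design, p, trimmed)
            rows.append(fm.values[a:b])
            labels.extend([p] * (b - a))
    x = np.concatenate(rows, axis=0)
    if x.shape[1] < 2:
        raise ValueError("similarity needs at least 2 features per time point")
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance feature vector at time point(s) {bad.tolist()}: "
            "similarity undefined"
        )
    return SimilaritySet(matrix=np.corrcoef(x), piece_of=np.asarray(labels))


def _bin_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:  # degenerate global range: widen minimally so binning works
        lo, hi = lo - 1e-12, hi + 1e-12
    return np.linspace(lo, hi, n_bins + 1)


def piece_entropy(
    similarities: SimilaritySet, piece_id: int, n_bins: int = 10,
    bin_edges: np.ndarray | None = None,
) -> float:
    """Shannon entropy (bits) of a piece's within-piece similarities.

    Bin edges span the *global* similarity range of the whole stimulus set
    (never per piece); bins are left-closed/right-open with the last bin
    closed, so the global maximum is counted.
    """
    if bin_edges is None:
        bin_edges = _bin_edges(similarities.all_values(), n_bins)
    vals = similarities.within_piece_values(piece_id)
    counts, _ = np.histogram(vals, bins=bin_edges)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


@dataclass
class EntropyTable:
    """Entropy (bits) per piece plus the global binning used."""

    h_bits: dict[int, float]
    n_bins: int
    bin_edges: np.ndarray
    n_pairs_per_piece: dict[int, int]

    def as_array(self) -> np.ndarray:
        return np.array([self.h_bits[p] for p in sorted(self.h_bits)])


def entropy_table(
    features: list[FeatureMatrix],
    design: StimulusDesign,
    n_bins: int = 10,
    trimmed: bool = False,
) -> EntropyTable:
    """Entropy of every piece under a common global binning."""
    sims = pairwise_similarity(features, design, trimmed)
    edges = _bin_edges(sims.all_values(), n_bins)
    h, npairs = {}, {}
    for p in design.piece_ids:
        h[p] = piece_entropy(sims, p, n_bins, bin_edges=edges)
        npairs[p] = sims.within_piece_values(p).size
    return EntropyTable(h_bits=h, n_bins=n_bins, bin_edges=edges,
                        n_pairs_per_piece=npairs)


def entropy_ranking(
    table: EntropyTable, n: int = 10, pieces: list[int] | None = None
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """(bottom-n, top-n) piece sets by entropy; ties break by piece id.

    ``pieces`` restricts the split to a subset (e.g. one emotional
    category).
    """
    ids = sorted(table.h_bits) if pieces is None else sorted(pieces)
    if len(ids) < 2 * n:
        raise ValueError(f"need at least {2 * n} pieces for a {n}/{n} split, have {len(ids)}")
    order = sorted(ids, key=lambda p: (table.h_bits[p], p))
    return tuple(order[:n]), tuple(order[-n:])
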