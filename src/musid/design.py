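"""Temporal layout of the music-listening experiment.

A stimulus set of ``n_pieces`` pieces of equal duration is arranged into
``n_medleys`` medleys (one medley per functional run); every medley is
presented once per session.  Each run starts with warm-up volumes and ends
with tail volumes that absorb the hemodynamic lag; neither enters any
analysis window.  All index arithmetic of the pipeline lives here: piece
windows within a run, the rigid hemodynamic-delay shift, transition
trimming, and the cross-validation fold constructions.

Volume indices are 0-based, half-open ranges throughout the package.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DesignError",
    "StimulusDesign",
    "CvFold",
    "piece_volume_window",
    "feature_window",
    "enumerate_folds",
    "medley_folds",
    "inner_piece_blocks",
]


class DesignError(ValueError):
    """Structural inconsistency in the stimulus design or an index request."""


@dataclass(frozen=True)
class CvFold:
    """One cross-validation fold: a partition of the pieces.

    ``test_piece_ids`` are held out of encoding-model training and later
    identified during decoding; ``train_piece_ids`` are the rest.
    """

    test_piece_ids: tuple[int, ...]
    train_piece_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        overlap = set(self.test_piece_ids) & set(self.train_piece_ids)
        if overlap:
            raise DesignError(f"fold test/train sets overlap: {sorted(overlap)}")

    @property
    def n_test(self) -> int:
        return len(self.test_piece_ids)


@dataclass(frozen=True)
class StimulusDesign:
    """Pieces, medleys, runs and sessions, plus the windowing conventions.

    Defaults describe the reference experiment: 40 pieces of 46 s at
    TR = 2 s, ten pieces per medley, four medleys, four sessions (each
    medley heard once per session, hence four presentations per piece).

    Parameters
    ----------
    hemodynamic_delay_vols
        Rigid forward shift (in volumes) applied to a piece's BOLD window
        to account for the hemodynamic lag; the feature window is not
        lagged.
    transition_trim_vols
        Volumes dropped at each end of a piece window (after the delay
        shift) to exclude the fade cross-over between adjacent pieces.
    warmup_vols, tail_vols
        Run padding; stored for run-length bookkeeping, excluded from all
        analysis windows.
    """

    n_pieces: int = 40
    piece_duration_s: float = 46.0
    tr_s: float = 2.0
    pieces_per_medley: int = 10
    n_medleys: int = 4
    n_sessions: int = 4
    hemodynamic_delay_vols: int = 3
    transition_trim_vols: int = 3
    warmup_vols: int = 10
    tail_vols: int = 5

    def __post_init__(self) -> None:
        if self.n_pieces != self.pieces_per_medley * self.n_medleys:
            raise DesignError(
                f"n_pieces={self.n_pieces} != pieces_per_medley×n_medleys="
                f"{self.pieces_per_medley * self.n_medleys}"
            )
        if self.tr_s <= 0:
            raise DesignError("tr_s must be positive")
        ratio = self.piece_duration_s / self.tr_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise DesignError(
                f"piece_duration_s={self.piece_duration_s} not divisible by tr_s={self.tr_s}"
            )
        if self.retained_vols_per_piece < 1:
            raise DesignError("transition_trim_vols leaves no retained volumes")
        for name in ("n_sessions", "n_medleys", "pieces_per_medley"):
            if getattr(self, name) < 1:
                raise DesignError(f"{name} must be >= 1")
        for name in ("hemodynamic_delay_vols", "transition_trim_vols", "warmup_vols", "tail_vols"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if self.hemodynamic_delay_vols > self.tail_vols:
            raise DesignError(
                "hemodynamic_delay_vols exceeds tail_vols: the shifted window of "
                "the last piece would run past the end of the run"
            )

    # -- derived sizes -------------------------------------------------
    @property
    def vols_per_piece(self) -> int:
        return int(round(self.piece_duration_s / self.tr_s))

    @property
    def retained_vols_per_piece(self) -> int:
        return self.vols_per_piece - 2 * self.transition_trim_vols

    @property
    def medley_vols(self) -> int:
        """Stimulus volumes per run (pieces only, no padding)."""
        return self.pieces_per_medley * self.vols_per_piece

    @property
    def vols_per_run(self) -> int:
        return self.warmup_vols + self.medley_vols + self.tail_vols

    @property
    def piece_ids(self) -> range:
        return range(self.n_pieces)

    # -- piece ↔ medley arithmetic ------------------------------------
    def medley_of(self, piece_id: int) -> tuple[int, int]:
        """Return (medley_id, position-within-medley) of a piece."""
        if not 0 <= piece_id < self.n_pieces:
            raise DesignError(f"piece_id {piece_id} out of range [0, {self.n_pieces})")
        return divmod(piece_id, self.pieces_per_medley)

    def pieces_of_medley(self, medley_id: int) -> tuple[int, ...]:
        if not 0 <= medley_id < self.n_medleys:
            raise DesignError(f"medley_id {medley_id} out of range [0, {self.n_medleys})")
        start = medley_id * self.pieces_per_medley
        return tuple(range(start, start + self.pieces_per_medley))

    @property
    def medley_assignment(self) -> dict[int, tuple[int, int]]:
        """Mapping piece_id → (medley_id, position)."""
        return {p: self.medley_of(p) for p in self.piece_ids}

    def to_dict(self) -> dict:
        return {
            "n_pieces": self.n_pieces,
            "piece_duration_s": self.piece_duration_s,
            "tr_s": self.tr_s,
            "pieces_per_medley": self.pieces_per_medley,
            "n_medleys": self.n_medleys,
            "n_sessions": self.n_sessions,
            "hemodynamic_delay_vols": self.hemodynamic_delay_vols,
            "transition_trim_vols": self.transition_trim_vols,
            "warmup_vols": self.warmup_vols,
            "tail_vols": self.tail_vols,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusDesign":
        return cls(**d)


def piece_volume_window(
    design: StimulusDesign, piece_id: int, trimmed: bool = False
) -> tuple[int, int]:
    """Half-open BOLD volume index range of a piece within its run.

    The window is shifted forward by ``hemodynamic_delay_vols`` (the BOLD
    response lags the stimulus); if ``trimmed``, ``transition_trim_vols``
    volumes are additionally dropped at each end to avoid the fade
    cross-over between adjacent pieces.
    """
    _, position = design.medley_of(piece_id)
    start = design.warmup_vols + position * design.vols_per_piece + design.hemodynamic_delay_vols
    stop = start + design.vols_per_piece
    if trimmed:
        start += design.transition_trim_vols
        stop -= design.transition_trim_vols
    if stop > design.vols_per_run:
        medley_id, _ = design.medley_of(piece_id)
        raise DesignError(
            f"window [{start}, {stop}) of piece {piece_id} exceeds run length "
            f"{design.vols_per_run} in run (medley) {medley_id}"
        )
    return start, stop


def feature_window(
    design: StimulusDesign, piece_id: int, trimmed: bool = False
) -> tuple[int, int]:
    """Half-open row range of a piece within its medley's feature matrix.

    Feature matrices contain stimulus samples only (no warm-up/tail) and
    are not lagged: BOLD volume ``warmup + i + delay`` is modelled by
    feature row ``i``.
    """
    _, position = design.medley_of(piece_id)
    start = position * design.vols_per_piece
    stop = start + design.vols_per_piece
    if trimmed:
        start += design.transition_trim_vols
        stop -= design.transition_trim_vols
    return start, stop


def enumerate_folds(
    design: StimulusDesign,
    n_test: int,
    max_folds: int | None = None,
    seed: int | None = None,
) -> list[CvFold]:
    """Leave-``n_test``-pieces-out folds.

    Exhaustive (all ``C(n_pieces, n_test)`` combinations, lexicographic
    order) when ``max_folds`` is None or ``n_test <= 3`` or ``max_folds``
    covers the total; otherwise ``max_folds`` distinct folds sampled
    uniformly without replacement using ``seed``.
    """
    n = design.n_pieces
    if not 2 <= n_test <= n - 1:
        raise DesignError(f"n_test={n_test} outside [2, {n - 1}]")
    total = math.comb(n, n_test)
    if max_folds is not None:
        if max_folds > total:
            raise DesignError(f"max_folds={max_folds} exceeds total folds {total}")
        if max_folds < 1:
            raise DesignError("max_folds must be >= 1")

    all_ids = set(range(n))

    def _fold(test: tuple[int, ...]) -> CvFold:
        return CvFold(test, tuple(sorted(all_ids - set(test))))

    exhaustive = max_folds is None or n_test <= 3 or max_folds >= total
    if exhaustive:
        return [_fold(c) for c in itertools.combinations(range(n), n_test)]

    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, ...]] = set()
    while len(chosen) < max_folds:
        chosen.add(tuple(sorted(rng.choice(n, size=n_test, replace=False).tolist())))
    return [_fold(c) for c in sorted(chosen)]


def medley_folds(design: StimulusDesign) -> list[CvFold]:
    """Leave-one-medley-out folds: each fold holds out a complete run."""
    all_ids = set(design.piece_ids)
    folds = []
    for m in range(design.n_medleys):
        test = design.pieces_of_medley(m)
        folds.append(CvFold(test, tuple(sorted(all_ids - set(test)))))
    return folds


def inner_piece_blocks(train_piece_ids: tuple[int, ...], k: int = 5) -> list[tuple[int, ...]]:
    """Split training pieces into ``k`` contiguous blocks for inner CV.

    Blocks respect piece boundaries so no piece straddles inner folds;
    remainders go to the earliest blocks.
    """
    ids = sorted(train_piece_ids)
    if len(ids) < k:
        raise DesignError(f"cannot split {len(ids)} training pieces into {k} blocks")
    base, extra = divmod(len(ids), k)
    blocks, i = [], 0
    for b in range(k):
        size = base + (1 if b < extra else 0)
        blocks.append(tuple(ids[i : i + size]))
        i += size
    return blocks
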