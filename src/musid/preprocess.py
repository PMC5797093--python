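"""BOLD run conditioning.

Each functional run (one medley presentation) is a volumes × voxels
matrix.  Preprocessing follows a fixed order:

1. Savitzky–Golay detrending per voxel (242-s window, order 3),
2. nuisance regression against an arbitrary regressor set,
3. global-signal correction,
4. temporal Gaussian smoothing (5-s width, read as FWHM),
5. per-run z-normalisation of every voxel.

All stages are deterministic and operate run by run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .features import savgol_detrend

__all__ = [
    "BoldRun",
    "BoldDataset",
    "NuisanceSet",
    "regress_out",
    "global_signal_correct",
    "gaussian_smooth",
    "normalize_run",
    "preprocess_run",
    "preprocess_dataset",
]

log = logging.getLogger(__name__)


@dataclass
class BoldRun:
    """One functional run: ``values`` is volumes × voxels."""

    values: np.ndarray
    session_id: int
    run_id: int  # medley index
    tr_s: float = 2.0
    voxel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("BOLD values must be 2-D (volumes × voxels)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD run contains non-finite values")
        if self.voxel_ids is None:
            self.voxel_ids = np.arange(self.values.shape[1])
        else:
            self.voxel_ids = np.asarray(self.voxel_ids, dtype=int)
            if self.voxel_ids.shape != (self.values.shape[1],):
                raise ValueError("voxel_ids length must match voxel count")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class BoldDataset:
    """All runs of one subject, indexed by (session_id, run_id)."""

    runs: list[BoldRun]

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("empty BOLD dataset")
        n_vox = {r.n_voxels for r in self.runs}
        if len(n_vox) != 1:
            raise ValueError(f"inconsistent voxel counts across runs: {sorted(n_vox)}")
        keys = [(r.session_id, r.run_id) for r in self.runs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (session_id, run_id) pairs")
        self._index = {k: r for k, r in zip(keys, self.runs)}

    def get(self, session_id: int, run_id: int) -> BoldRun:
        try:
            return self._index[(session_id, run_id)]
        except KeyError:
            raise KeyError(f"no run for session {session_id}, medley {run_id}") from None

    @property
    def n_voxels(self) -> int:
        return self.runs[0].n_voxels

    @property
    def session_ids(self) -> list[int]:
        return sorted({r.session_id for r in self.runs})

    def map(self, fn) -> "BoldDataset":
        return BoldDataset([fn(r) for r in self.runs])


@dataclass
class NuisanceSet:
    """Confound regressors for one run (volumes × k)."""

    regressors: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be 2-D")
        if self.labels is not None and len(self.labels) != self.regressors.shape[1]:
            raise ValueError("labels length must match regressor count")

    @property
    def k(self) -> int:
        return self.regressors.shape[1]


def _drop_dependent_columns(design: np.ndarray) -> np.ndarray:
    """Remove linearly dependent columns (keep earliest), warn if any."""
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1.0)
    if not keep.all():
        log.warning("dropping %d linearly dependent nuisance column(s)", (~keep).sum())
        return design[:, keep]
    return design


def regress_out(run: BoldRun, nuis: NuisanceSet | None) -> BoldRun:
    """Residualise every voxel on [intercept | nuisance regressors]."""
    if nuis is None or nuis.k == 0:
        return replace(run, values=run.values - run.values.mean(axis=0))
    if nuis.regressors.shape[0] != run.n_volumes:
        raise ValueError(
            f"nuisance rows ({nuis.regressors.shape[0]}) != run volumes ({run.n_volumes})"
        )
    design = np.column_stack([np.ones(run.n_volumes), nuis.regressors])
    design = _drop_dependent_columns(design)
    coef, *_ = np.linalg.lstsq(design, run.values, rcond=None)
    return replace(run, values=run.values - design @ coef)


def global_signal_correct(run: BoldRun, mode: str = "regress") -> BoldRun:
    """Remove the global signal (across-voxel mean per volume).

    ``regress`` (default) removes each voxel's OLS fit on the global
    signal; ``subtract`` subtracts the global signal directly.
    """
    if run.n_voxels < 2:
        raise ValueError("global signal correction needs at least 2 voxels")
    g = run.values.mean(axis=1)
    if mode == "subtract":
        return replace(run, values=run.values - g[:, None])
    if mode != "regress":
        raise ValueError(f"unknown mode {mode!r}; use 'regress' or 'subtract'")
    design = np.column_stack([np.ones(run.n_volumes), g])
    coef, *_ = np.linalg.lstsq(design, run.values, rcond=None)
    return replace(run, values=run.values - design @ coef)


def gaussian_smooth(run: BoldRun, fwhm_s: float = 5.0) -> BoldRun:
    """Temporal Gaussian smoothing.

    The width is interpreted as FWHM (σ = FWHM / √(8 ln 2)); the kernel is
    truncated at ±4σ and edges are renormalised so a constant series passes
    through unchanged.
    """
    if fwhm_s <= 0:
        raise ValueError("fwhm_s must be positive")
    sigma = fwhm_s / np.sqrt(8.0 * np.log(2.0)) / run.tr_s  # in samples
    half = max(1, int(np.ceil(4.0 * sigma)))
    t = np.arange(-half, half + 1)
    w = np.exp(-0.5 * (t / sigma) ** 2)
    w /= w.sum()
    n = run.n_volumes
    out = np.empty_like(run.values)
    # edge renormalisation: divide by the convolved all-ones series
    norm = np.convolve(np.ones(n), w, mode="same")
    for j in range(run.n_voxels):
        out[:, j] = np.convolve(run.values[:, j], w, mode="same") / norm
    return replace(run, values=out)


def normalize_run(run: BoldRun) -> BoldRun:
    """Z-score each voxel within the run (population variance)."""
    mean = run.values.mean(axis=0)
    sd = run.values.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance voxel(s): {run.voxel_ids[bad].tolist()}")
    return replace(run, values=(run.values - mean) / sd)


def preprocess_run(
    run: BoldRun,
    nuis: NuisanceSet | None = None,
    savgol_window_s: float | None = 242.0,
    savgol_order: int = 3,
    gsr_mode: str = "regress",
    fwhm_s: float = 5.0,
) -> BoldRun:
    """Apply the full fixed-order conditioning to one run.

    ``savgol_window_s=None`` skips detrending (short test runs).
    """
    out = run
    if savgol_window_s is not None:
        out = replace(out, values=savgol_detrend(out.values, savgol_window_s,
                                                 savgol_order, run.tr_s))
    out = regress_out(out, nuis)
    out = global_signal_correct(out, gsr_mode)
    out = gaussian_smooth(out, fwhm_s)
    return normalize_run(out)


def preprocess_dataset(
    bold: BoldDataset,
    nuisance: dict[tuple[int, int], NuisanceSet] | None = None,
    **kwargs,
) -> BoldDataset:
    """Preprocess every run; ``nuisance`` maps (session, run) → NuisanceSet."""
    nuisance = nuisance or {}
    return bold.map(
        lambda r: preprocess_run(r, nuisance.get((r.session_id, r.run_id)), **kwargs)
    )
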