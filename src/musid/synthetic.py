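"""Synthetic stimulus features and BOLD responses with known ground truth.

The generator emulates the structure of the reference experiment — 40
pieces × 46 s at TR = 2 s in 4 medleys, 4 sessions of repeated
presentation, 21 correlated feature channels — so every downstream stage
can be tested end-to-end without external data.

Features are stationary Gaussian AR(1) channels with a configurable
cross-feature covariance (marginal covariance equals ``feature_cov``
exactly).  Voxel responses are a linear mixture of the *conditioned*
features plus a per-run cubic drift and AR(1) Gaussian noise; only the
first ``n_responsive_voxels`` rows of the weight matrix are nonzero,
mirroring the sparse set of music-responsive voxels.  Everything is
reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import StimulusDesign, feature_window
from .features import FEATURE_NAMES, FeatureMatrix
from .preprocess import BoldDataset, BoldRun

__all__ = ["SyntheticConfig", "GroundTruth", "generate_features", "generate_bold",
           "default_true_weights", "entropy_contrast_config"]


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the reference study conditions."""

    design: StimulusDesign = field(default_factory=StimulusDesign)
    n_voxels: int = 150
    n_responsive_voxels: int = 100
    true_weights: np.ndarray | None = None  # built from seed when None
    feature_ar_coeff: float = 0.85
    feature_cov: np.ndarray | None = None  # identity when None
    noise_sd: float = 0.5
    noise_ar_coeff: float = 0.3
    drift_amplitude: float = 1.0
    seed: int = 0
    #: optional per-piece multiplier on feature fluctuations — pieces with a
    #: larger scale have richer feature dynamics (used for entropy studies)
    piece_feature_scale: np.ndarray | None = None
    #: sd of a per-piece constant feature offset; combined with a small
    #: fluctuation scale this yields pieces whose feature vectors barely
    #: change over time (similarities pile into one bin → low entropy)
    piece_offset_sd: float = 0.0
    #: optional per-piece AR(1) coefficient overriding feature_ar_coeff —
    #: slow pieces (coefficient near 1) keep their variance through the
    #: hemodynamic low-pass and end up with rich conditioned dynamics,
    #: fast pieces are attenuated towards near-constant trajectories
    piece_ar_coeff: np.ndarray | None = None
    n_features: int = len(FEATURE_NAMES)

    def __post_init__(self) -> None:
        if not 0 <= self.n_responsive_voxels <= self.n_voxels:
            raise ValueError("need 0 <= n_responsive_voxels <= n_voxels")
        if not 0.0 <= self.feature_ar_coeff < 1.0:
            raise ValueError("feature_ar_coeff must lie in [0, 1)")
        if not 0.0 <= self.noise_ar_coeff < 1.0:
            raise ValueError("noise_ar_coeff must lie in [0, 1)")
        if self.noise_sd < 0 or self.drift_amplitude < 0 or self.piece_offset_sd < 0:
            raise ValueError("noise_sd, drift_amplitude and piece_offset_sd must be >= 0")
        if self.feature_cov is not None:
            c = np.asarray(self.feature_cov, dtype=float)
            if c.shape != (self.n_features, self.n_features):
                raise ValueError(f"feature_cov must be {self.n_features}×{self.n_features}")
            if not np.allclose(c, c.T):
                raise ValueError("feature_cov must be symmetric")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValueError("feature_cov must be positive semidefinite")
            self.feature_cov = c
        if self.true_weights is not None:
            w = np.asarray(self.true_weights, dtype=float)
            if w.shape != (self.n_voxels, self.n_features):
                raise ValueError(f"true_weights must be {self.n_voxels}×{self.n_features}")
            if self.n_responsive_voxels < self.n_voxels and np.any(
                w[self.n_responsive_voxels:] != 0
            ):
                raise ValueError("weight rows of non-responsive voxels must be all-zero")
            self.true_weights = w
        if self.piece_feature_scale is not None:
            s = np.asarray(self.piece_feature_scale, dtype=float)
            if s.shape != (self.design.n_pieces,):
                raise ValueError("piece_feature_scale must have one entry per piece")
            self.piece_feature_scale = s
        if self.piece_ar_coeff is not None:
            a = np.asarray(self.piece_ar_coeff, dtype=float)
            if a.shape != (self.design.n_pieces,):
                raise ValueError("piece_ar_coeff must have one entry per piece")
            if np.any(a < 0) or np.any(a >= 1):
                raise ValueError("piece_ar_coeff values must lie in [0, 1)")
            self.piece_ar_coeff = a


@dataclass
class GroundTruth:
    """What the generator knows: weights, responsive voxels, seed trail."""

    true_weights: np.ndarray
    responsive_voxel_ids: np.ndarray
    seed: int
    child_seeds: dict[str, int]
    #: noise- and drift-free signal per (session_id, run_id), volumes × voxels
    signal: dict[tuple[int, int], np.ndarray]


def default_true_weights(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Sparse weight rows: responsive voxels N(0, 1/n_features), rest zero."""
    w = np.zeros((cfg.n_voxels, cfg.n_features))
    w[: cfg.n_responsive_voxels] = rng.standard_normal(
        (cfg.n_responsive_voxels, cfg.n_features)
    ) / np.sqrt(cfg.n_features)
    return w


def _chol(cov: np.ndarray) -> np.ndarray:
    # tolerate PSD matrices that are singular to rounding error
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))


def _ar1_series(n: int, k: int, ar: float, chol: np.ndarray | None,
                rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) rows with marginal covariance chol @ chol.T
    (identity covariance when ``chol`` is None)."""
    innov = rng.standard_normal((n, k))
    if chol is not None:
        innov = innov @ chol.T
    x = np.empty((n, k))
    x[0] = innov[0]
    scale = np.sqrt(1.0 - ar**2)
    for t in range(1, n):
        x[t] = ar * x[t - 1] + scale * innov[t]
    return x


def generate_features(cfg: SyntheticConfig) -> list[FeatureMatrix]:
    """One TR-resolution FeatureMatrix per medley (pre-conditioning).

    Channels are jointly AR(1) with lag-1 autocorrelation
    ``feature_ar_coeff`` and marginal covariance ``feature_cov``; the
    optional per-piece scale multiplies each piece's rows.
    """
    d = cfg.design
    cov = cfg.feature_cov if cfg.feature_cov is not None else np.eye(cfg.n_features)
    chol = _chol(cov)
    ss = np.random.SeedSequence(cfg.seed)
    offset_child, *children = ss.spawn(d.n_medleys + 1)
    offsets = np.zeros((d.n_pieces, cfg.n_features))
    if cfg.piece_offset_sd > 0:
        offsets = cfg.piece_offset_sd * np.random.default_rng(
            offset_child
        ).standard_normal((d.n_pieces, cfg.n_features))
    out = []
    for m in range(d.n_medleys):
        rng = np.random.default_rng(children[m])
        if cfg.piece_ar_coeff is None:
            x = _ar1_series(d.medley_vols, cfg.n_features, cfg.feature_ar_coeff, chol, rng)
        else:
            # independent stationary AR(1) per piece at its own coefficient
            x = np.empty((d.medley_vols, cfg.n_features))
            for p in d.pieces_of_medley(m):
                a, b = feature_window(d, p)
                x[a:b] = _ar1_series(b - a, cfg.n_features,
                                     float(cfg.piece_ar_coeff[p]), chol, rng)
        labels = np.repeat(d.pieces_of_medley(m), d.vols_per_piece)
        for p in d.pieces_of_medley(m):
            a, b = feature_window(d, p)
            if cfg.piece_feature_scale is not None:
                x[a:b] *= cfg.piece_feature_scale[p]
            x[a:b] += offsets[p]
        names = tuple(FEATURE_NAMES[: cfg.n_features]) if cfg.n_features <= len(
            FEATURE_NAMES
        ) else tuple(f"f{i}" for i in range(cfg.n_features))
        out.append(
            FeatureMatrix(x, feature_names=names, medley_id=m, piece_labels=labels,
                          sample_rate_hz=1.0 / d.tr_s, per_tr=True)
        )
    return out


def generate_bold(
    cfg: SyntheticConfig, features_conditioned: list[FeatureMatrix]
) -> tuple[BoldDataset, GroundTruth]:
    """Voxel responses as a linear mixture of the conditioned features.

    Per run: ``signal + drift + noise`` where the signal at BOLD volume
    ``warmup + delay + i`` is ``F[i] @ W.T`` (the design's rigid
    hemodynamic shift), the drift is a per-voxel random cubic polynomial of
    amplitude ``drift_amplitude``, and the noise is AR(1) Gaussian with
    marginal sd ``noise_sd``.  Each of the ``n_sessions`` presentations of
    a medley gets an independent noise/drift realisation.
    """
    d = cfg.design
    if len(features_conditioned) != d.n_medleys:
        raise ValueError(f"expected {d.n_medleys} feature matrices, got {len(features_conditioned)}")
    for fm in features_conditioned:
        if fm.n_samples != d.medley_vols:
            raise ValueError(
                f"medley {fm.medley_id}: {fm.n_samples} feature rows, design expects {d.medley_vols}"
            )
        if fm.n_features != cfg.n_features:
            raise ValueError(
                f"feature count {fm.n_features} does not match weights ({cfg.n_features})"
            )

    ss = np.random.SeedSequence((cfg.seed, 1))
    w_child, *run_children = ss.spawn(1 + d.n_sessions * d.n_medleys)
    if cfg.true_weights is not None:
        weights = cfg.true_weights
    else:
        weights = default_true_weights(cfg, np.random.default_rng(w_child))

    basis = np.polynomial.polynomial.polyvander(
        np.linspace(-1.0, 1.0, d.vols_per_run), 3
    )  # vols × 4, constant..cubic
    a = d.warmup_vols + d.hemodynamic_delay_vols
    runs, signal_store, child_seeds = [], {}, {}
    i = 0
    for s in range(d.n_sessions):
        for m in range(d.n_medleys):
            rng = np.random.default_rng(run_children[i])
            child_seeds[f"session{s}_medley{m}"] = int(
                run_children[i].generate_state(1)[0]
            ) % (2**31)
            i += 1
            signal = np.zeros((d.vols_per_run, cfg.n_voxels))
            signal[a : a + d.medley_vols] = features_conditioned[m].values @ weights.T
            drift = np.zeros_like(signal)
            if cfg.drift_amplitude > 0:
                coef = rng.standard_normal((4, cfg.n_voxels)) * cfg.drift_amplitude
                drift = basis @ coef
            noise = np.zeros_like(signal)
            if cfg.noise_sd > 0:
                noise = cfg.noise_sd * _ar1_series(
                    d.vols_per_run, cfg.n_voxels, cfg.noise_ar_coeff, None, rng
                )
            runs.append(
                BoldRun(signal + drift + noise, session_id=s, run_id=m, tr_s=d.tr_s)
            )
            signal_store[(s, m)] = signal
    gt = GroundTruth(
        true_weights=weights,
        responsive_voxel_ids=np.arange(cfg.n_responsive_voxels),
        seed=cfg.seed,
        child_seeds=child_seeds,
        signal=signal_store,
    )
    return BoldDataset(runs), gt


def entropy_contrast_config(seed: int = 0, design: StimulusDesign | None = None) -> SyntheticConfig:
    """Ensemble with an information-content contrast between medleys.

    The first half of the pieces (two medleys) have nearly constant feature
    trajectories (fluctuation scale 0.05 around a small per-piece offset),
    the second half rich dynamics (scale 1.2).  Rich pieces spread their
    within-piece feature similarities over many bins (high entropy) and
    carry more temporal signal into the BOLD mixture; impoverished pieces
    concentrate near-unity similarities (low entropy) and must be told
    apart almost purely spatially.  Noise is set high enough (sd 8) that
    identification is well off ceiling.
    """
    design = design if design is not None else StimulusDesign()
    half = design.n_pieces // 2
    scale = np.where(np.arange(design.n_pieces) < half, 0.05, 1.2)
    return SyntheticConfig(
        design=design,
        n_voxels=80,
        n_responsive_voxels=40,
        noise_sd=8.0,
        piece_feature_scale=scale,
        piece_offset_sd=0.1,
        seed=seed,
    )
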