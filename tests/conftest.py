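import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from musid import (
    HrfSpec,
    StimulusDesign,
    SyntheticConfig,
    condition_features,
    generate_bold,
    generate_features,
)
from musid.preprocess import preprocess_dataset


@pytest.fixture(scope="session")
def design():
    """Reference layout: 40 pieces × 46 s, TR 2 s, 4 medleys × 4 sessions."""
    return StimulusDesign()


@pytest.fixture(scope="session")
def small_design():
    """Miniature layout for fast structural tests: 6 pieces × 20 s."""
    return StimulusDesign(
        n_pieces=6,
        piece_duration_s=20.0,
        tr_s=2.0,
        pieces_per_medley=3,
        n_medleys=2,
        n_sessions=2,
        hemodynamic_delay_vols=2,
        transition_trim_vols=2,
        warmup_vols=4,
        tail_vols=3,
    )


def make_dataset(design, preprocess=True, savgol_window_s=242.0, **cfg_kwargs):
    """Generate conditioned features + (optionally preprocessed) BOLD."""
    cfg = SyntheticConfig(design=design, **cfg_kwargs)
    raw = generate_features(cfg)
    feats = condition_features(
        raw, HrfSpec(), decimation=1, dt_s=design.tr_s,
        savgol_window_s=savgol_window_s, tr_s=design.tr_s,
    )
    bold, gt = generate_bold(cfg, feats)
    if preprocess:
        bold = preprocess_dataset(bold, savgol_window_s=savgol_window_s)
    return cfg, raw, feats, bold, gt


@pytest.fixture(scope="session")
def noiseless_dataset(design):
    """Drift- and noise-free data at the reference scale (exact OLS regime).

    Left unpreprocessed: with zero noise, non-responsive voxels are
    constant and per-run z-scoring is undefined for them.
    """
    return make_dataset(
        design, preprocess=False, savgol_window_s=242.0,
        n_voxels=60, n_responsive_voxels=40, noise_sd=0.0, drift_amplitude=0.0,
        seed=101,
    )


@pytest.fixture(scope="session")
def noisy_dataset(design):
    """Moderate-noise preprocessed data at the reference scale."""
    return make_dataset(
        design, preprocess=True,
        n_voxels=150, n_responsive_voxels=100, noise_sd=0.5, seed=202,
    )
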