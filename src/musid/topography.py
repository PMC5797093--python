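"""Feature topography across music-responsive voxels.

To avoid collinearity bias, each musical feature is correlated
*separately* (univariate, no joint regression) with the BOLD time series
of the best-ranked voxels.  A principal-component analysis of the
resulting voxels × 21 correlation map reveals the dominant feature
gradients across the auditory cortex; individual-subject components are
matched to group components with the Gale–Shapley stable-marriage
algorithm, using descending absolute loading correlation as preferences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import StimulusDesign, feature_window, piece_volume_window
from .encoding import VoxelRanking, _columnwise_corr
from .features import FeatureMatrix
from .preprocess import BoldDataset

__all__ = [
    "FeatureCorrelationMap",
    "PcaResult",
    "feature_correlations",
    "pca",
    "component_similarity",
    "stable_match",
    "score_overlay_export",
]


@dataclass
class FeatureCorrelationMap:
    """Voxels × features matrix of univariate temporal correlations."""

    values: np.ndarray
    voxel_ids: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.nanmax(np.abs(self.values)) > 1.0 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class PcaResult:
    """Loadings (features × k), scores (voxels × k), explained fractions."""

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_fraction: np.ndarray
    feature_names: tuple[str, ...] | None = None

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def feature_correlations(
    bold: BoldDataset,
    features: list[FeatureMatrix],
    design: StimulusDesign,
    ranking: VoxelRanking,
    n_voxels: int = 300,
) -> FeatureCorrelationMap:
    """Univariate correlation of every (voxel, feature) pair.

    Computed over all analysis volumes: the full piece windows of every
    run and session, BOLD delay-shifted as everywhere else.
    """
    if n_voxels > len(ranking):
        raise ValueError(f"requested {n_voxels} voxels, ranking has {len(ranking)}")
    top = ranking.top(n_voxels)
    f_rows, y_rows = [], []
    for s in sorted({r.session_id for r in bold.runs}):
        for fm in features:
            m = fm.medley_id
            run = bold.get(s, m)
            for p in design.pieces_of_medley(m):
                fa, fb = feature_window(design, p)
                ba, bb = piece_volume_window(design, p)
                f_rows.append(fm.values[fa:fb])
                y_rows.append(run.values[ba:bb][:, top])
    F = np.concatenate(f_rows, axis=0)
    Y = np.concatenate(y_rows, axis=0)
    if np.any(F.std(axis=0) == 0) or np.any(Y.std(axis=0) == 0):
        raise ValueError("zero-variance feature or voxel series")
    Fc = F - F.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    num = Yc.T @ Fc
    den = np.outer(
        np.sqrt((Yc**2).sum(axis=0)), np.sqrt((Fc**2).sum(axis=0))
    )
    return FeatureCorrelationMap(
        values=num / den, voxel_ids=top, feature_names=features[0].feature_names
    )


def pca(fcm: FeatureCorrelationMap | np.ndarray, k: int = 4) -> PcaResult:
    """Principal components of the correlation map.

    Features are the variables, voxels the observations; the map is
    mean-centred per feature (not re-scaled — correlations already share a
    scale) and the covariance eigendecomposed.  Deterministic sign
    convention: each component's largest-magnitude loading is positive.
    """
    x = fcm.values if isinstance(fcm, FeatureCorrelationMap) else np.asarray(fcm, float)
    n, p = x.shape
    if n < k:
        raise ValueError(f"need at least k={k} observations, got {n}")
    xc = x - x.mean(axis=0)
    cov = (xc.T @ xc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    loadings = evecs[:, :k]
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    total = evals.sum()
    frac = evals[:k] / total if total > 0 else np.zeros(k)
    names = fcm.feature_names if isinstance(fcm, FeatureCorrelationMap) else None
    return PcaResult(
        loadings=loadings,
        scores=xc @ loadings,
        explained_variance_fraction=frac,
        feature_names=names,
    )


def component_similarity(a: PcaResult, b: PcaResult) -> np.ndarray:
    """|Pearson r| between matching loading vectors (sign-invariant)."""
    k = min(a.k, b.k)
    return np.abs(_columnwise_corr(a.loadings[:, :k], b.loadings[:, :k]))


def _preferences(sim: np.ndarray) -> list[list[int]]:
    """Descending-similarity preference lists, ties broken by index."""
    return [
        sorted(range(sim.shape[1]), key=lambda j: (-sim[i, j], j))
        for i in range(sim.shape[0])
    ]


def stable_match(individual: PcaResult, group: PcaResult, k: int | None = None) -> np.ndarray:
    """Gale–Shapley matching of individual to group components.

    Preferences on both sides are descending absolute loading correlation;
    individual components propose, so the result is proposer-optimal among
    all stable matchings.  Returns ``match`` with ``match[i]`` the group
    component assigned to individual component i.
    """
    k = k if k is not None else min(individual.k, group.k)
    sim = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            sim[i, j] = abs(
                np.corrcoef(individual.loadings[:, i], group.loadings[:, j])[0, 1]
            )
    prop_pref = _preferences(sim)
    # group side ranks proposers by its own (transposed) similarities
    acc_rank = np.empty((k, k), dtype=int)
    for j, pref in enumerate(_preferences(sim.T)):
        for rank, i in enumerate(pref):
            acc_rank[j, i] = rank
    match_of_group = [-1] * k
    next_choice = [0] * k
    free = list(range(k - 1, -1, -1))
    while free:
        i = free.pop()
        j = prop_pref[i][next_choice[i]]
        next_choice[i] += 1
        cur = match_of_group[j]
        if cur == -1:
            match_of_group[j] = i
        elif acc_rank[j, i] < acc_rank[j, cur]:
            match_of_group[j] = i
            free.append(cur)
        else:
            free.append(i)
    match = np.empty(k, dtype=int)
    for j, i in enumerate(match_of_group):
        match[i] = j
    return match


def score_overlay_export(
    pca_result: PcaResult,
    training_correlations: np.ndarray,
    voxel_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-voxel component scores scaled by the encoding training
    correlations, emphasising music-responsive voxels in overlays."""
    tc = np.asarray(training_correlations, dtype=float)
    if tc.shape[0] != pca_result.scores.shape[0]:
        raise ValueError("one training correlation per voxel required")
    scaled = pca_result.scores * tc[:, None]
    if voxel_ids is None:
        voxel_ids = np.arange(scaled.shape[0])
    df = pd.DataFrame(scaled, columns=[f"pc{j + 1}_scaled_score" for j in range(pca_result.k)])
    df.insert(0, "voxel_id", np.asarray(voxel_ids, dtype=int))
    df.insert(1, "training_correlation", tc)
    return df
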