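"""End-to-end orchestration and reports.

``run_full_analysis`` drives design → synthetic data (or loaded inputs) →
feature conditioning → BOLD preprocessing → encoding/decoding sweep →
permutation null → entropy → topography → sparsity, emitting TSV tables, a
human-readable summary and a JSON run manifest.  All randomness derives
from one master seed, so two runs with the same configuration produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decoding import (
    DEFAULT_VOXEL_GRID,
    IdentificationEngine,
    entropy_split_accuracy,
    identification_sweep,
    lomo_accuracy,
    nway_accuracy,
    permutation_null,
)
from .design import StimulusDesign, enumerate_folds
from .entropy import entropy_table
from .features import HrfSpec, condition_features
from .io import write_bold_dataset, write_design, write_features, write_ground_truth
from .preprocess import preprocess_dataset
from .sparsity import fit_accuracy_curve, sparsity_sweep
from .synthetic import SyntheticConfig, generate_bold, generate_features
from .topography import feature_correlations, pca, score_overlay_export

__all__ = ["RunConfig", "RunManifest", "run_full_analysis", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One-file configuration of a full analysis (YAML-serialisable)."""

    design: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)
    hrf: dict = field(default_factory=dict)
    master_seed: int = 0
    n_voxels_anchor: int = 100
    n_voxels_pca: int = 300
    voxel_grid: tuple[int, ...] = DEFAULT_VOXEL_GRID
    n_perms: int = 1000
    alpha: float = 0.05
    max_pair_folds: int | None = None  # None = all pairs
    sparsity_folds: int | None = 100
    savgol_window_s: float | None = 242.0
    entropy_bins: int = 10
    pca_components: int = 4

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown configuration keys: {sorted(extra)}")
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    version: str
    output_digests: dict
    timings_s: dict


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(
    config: RunConfig | dict | str | Path,
    out_dir: str | Path,
    write_inputs: bool = False,
) -> RunManifest:
    """Execute every stage on synthetic data and write the report bundle.

    Returns the manifest (also written as ``manifest.json``).
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t_all = time.perf_counter()

    def stage(name):
        log.info("stage: %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    ss = np.random.SeedSequence(config.master_seed)
    seed_synth, seed_folds, seed_perm, seed_nway = (
        int(s.generate_state(1)[0]) % (2**31) for s in ss.spawn(4)
    )

    s = stage("design")
    design = StimulusDesign(**config.design)
    write_design(design, out / "design.yaml")
    done(s)

    s = stage("synthetic")
    cfg = SyntheticConfig(design=design, seed=seed_synth, **config.synthetic)
    raw_features = generate_features(cfg)
    done(s)

    s = stage("features")
    hrf = HrfSpec(**config.hrf)
    feats = condition_features(
        raw_features, hrf, decimation=1, dt_s=design.tr_s,
        savgol_window_s=config.savgol_window_s, tr_s=design.tr_s,
    )
    done(s)

    s = stage("bold")
    bold_raw, gt = generate_bold(cfg, feats)
    done(s)

    s = stage("preprocess")
    bold = preprocess_dataset(bold_raw, savgol_window_s=config.savgol_window_s)
    done(s)

    if write_inputs:
        for fm in raw_features:
            write_features(fm, out / f"features_raw_medley-{fm.medley_id}.tsv")
        write_bold_dataset(bold_raw, out / "bold_raw")
        write_ground_truth(gt, out / "ground_truth")

    s = stage("decode_sweep")
    engine = IdentificationEngine(bold, feats, design)
    max_pairs = config.max_pair_folds
    pair_folds = enumerate_folds(design, 2)
    if max_pairs is not None and max_pairs < len(pair_folds):
        rng = np.random.default_rng(seed_folds)
        pair_folds = [pair_folds[i] for i in sorted(
            rng.choice(len(pair_folds), size=max_pairs, replace=False))]
    grid = identification_sweep(
        bold, feats, design, voxel_grid=config.voxel_grid, folds=pair_folds,
        reference_cell=(config.n_voxels_anchor, design.retained_vols_per_piece),
        engine=engine,
    )
    grid_df = pd.DataFrame(
        [
            (int(v), t + 1, grid.accuracy[i, t])
            for i, v in enumerate(grid.voxel_grid)
            for t in range(grid.accuracy.shape[1])
        ],
        columns=["n_voxels", "n_timepoints", "accuracy_pct"],
    )
    grid_df.to_csv(out / "identification_grid.tsv", sep="\t", index=False,
                   float_format="%.6g")
    done(s)

    s = stage("permutation")
    null = permutation_null(
        bold, feats, design, n_perms=config.n_perms, alpha=config.alpha,
        seed=seed_perm, n_voxels=config.n_voxels_anchor, folds=pair_folds,
        engine=engine,
    )
    done(s)

    s = stage("entropy")
    etable = entropy_table(feats, design, n_bins=config.entropy_bins)
    pd.DataFrame(
        {
            "piece_id": sorted(etable.h_bits),
            "H_bits": [etable.h_bits[p] for p in sorted(etable.h_bits)],
            "n_pairs": [etable.n_pairs_per_piece[p] for p in sorted(etable.h_bits)],
        }
    ).to_csv(out / "entropy.tsv", sep="\t", index=False, float_format="%.6g")
    esplit = entropy_split_accuracy(
        bold, feats, design, etable,
        n_voxels=config.n_voxels_anchor,
        subset_size=min(10, design.n_pieces // 2),
        engine=engine,
    )
    done(s)

    s = stage("nway")
    # N-way depth matches the medley size so it stays comparable with the
    # leave-one-medley-out variant and leaves ample training pieces
    n_max = min(10, design.pieces_per_medley)
    nway = nway_accuracy(
        bold, feats, design, n_test=n_max, max_folds=None if n_max <= 3 else 200,
        seed=seed_nway, n_voxels=config.n_voxels_anchor, engine=engine,
    )
    lomo = lomo_accuracy(bold, feats, design, n_voxels=config.n_voxels_anchor,
                         engine=engine)
    done(s)

    s = stage("topography")
    full_fold = pair_folds[0]
    from .encoding import EncodingModel

    ranking = EncodingModel(None, None, design, full_fold, cache=engine.cache).rank_voxels()
    n_pca_vox = min(config.n_voxels_pca, engine.n_voxels)
    fcm = feature_correlations(bold, feats, design, ranking, n_voxels=n_pca_vox)
    pres = pca(fcm, k=min(config.pca_components, fcm.values.shape[1]))
    loadings = pd.DataFrame(
        pres.loadings, columns=[f"pc{j + 1}" for j in range(pres.k)]
    )
    loadings.insert(0, "feature", list(fcm.feature_names))
    loadings.to_csv(out / "pca_loadings.tsv", sep="\t", index=False, float_format="%.6g")
    train_corr = ranking.scores[np.argsort(ranking.voxel_ids)][fcm.voxel_ids]
    score_overlay_export(pres, train_corr, fcm.voxel_ids).to_csv(
        out / "pca_scores_scaled.tsv", sep="\t", index=False, float_format="%.6g"
    )
    done(s)

    s = stage("sparsity")
    sp_folds = pair_folds
    if config.sparsity_folds is not None and config.sparsity_folds < len(pair_folds):
        rng = np.random.default_rng(seed_folds + 1)
        sp_folds = [pair_folds[i] for i in sorted(
            rng.choice(len(pair_folds), size=config.sparsity_folds, replace=False))]
    curve = sparsity_sweep(bold, feats, design, folds=sp_folds,
                           n_voxels=config.n_voxels_anchor)
    fits = fit_accuracy_curve(curve)
    curve.table.to_csv(out / "sparsity.tsv", sep="\t", index=False, float_format="%.6g")
    done(s)

    anchor_acc = grid.accuracy_at(grid.reference_cell[0], grid.reference_cell[1])
    summary = [
        f"musid {__version__} full analysis",
        f"design: {design.n_pieces} pieces × {design.piece_duration_s:g}s, "
        f"TR {design.tr_s:g}s, {design.n_medleys} medleys × {design.n_sessions} sessions",
        f"pairwise folds: {len(pair_folds)} ({grid.n_identifications} identifications)",
        f"accuracy at {grid.reference_cell[0]} voxels, full length: {anchor_acc:.1f}%",
        f"permutation null: mean {null.accuracies.mean():.1f}%, "
        f"{100 * (1 - null.alpha):.0f}th pct {null.threshold:.1f}% ({null.n_perms} perms)",
        f"entropy split: high {esplit['high_entropy_accuracy_pct']:.1f}% vs "
        f"low {esplit['low_entropy_accuracy_pct']:.1f}% "
        f"({esplit['n_pairs_per_subset']} pairs each)",
        f"N={nway.n_test}-way: {nway.accuracy_pct:.1f}% (ranked {nway.ranked_accuracy:.3f}); "
        f"LOMO: {lomo.accuracy_pct:.1f}% (ranked {lomo.ranked_accuracy:.3f})",
        f"PCA explained variance: "
        + " + ".join(f"{100 * f:.0f}%" for f in pres.explained_variance_fraction),
        f"sparsity fit: {fits.better} wins "
        f"(RSS exp {fits.exponential_rss:.3g} vs log {fits.logarithmic_rss:.3g})",
    ]
    (out / "summary.txt").write_text("\n".join(summary) + "\n")

    timings["total"] = round(time.perf_counter() - t_all, 3)
    digests = {p.name: _digest(p) for p in sorted(out.glob("*.tsv"))}
    digests["summary.txt"] = _digest(out / "summary.txt")
    manifest = RunManifest(
        config=asdict(config),
        seeds={
            "master": config.master_seed,
            "synthetic": seed_synth,
            "fold_subsample": seed_folds,
            "permutation": seed_perm,
            "nway": seed_nway,
        },
        version=__version__,
        output_digests=digests,
        timings_s=timings,
    )
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2, default=str))
    return manifest
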