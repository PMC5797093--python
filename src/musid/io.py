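"""Plain-text I/O: feature TSV, BOLD TSV with JSON sidecar, design YAML.

All artifacts are human-readable delimited text so a pipeline run can be
inspected and versioned without binary tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import StimulusDesign
from .features import FeatureMatrix
from .preprocess import BoldDataset, BoldRun

__all__ = [
    "write_design",
    "read_design",
    "write_features",
    "read_features",
    "write_bold_run",
    "read_bold_run",
    "write_bold_dataset",
    "read_bold_dataset",
    "write_ground_truth",
]


def write_design(design: StimulusDesign, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(design.to_dict(), sort_keys=False))


def read_design(path: str | Path) -> StimulusDesign:
    return StimulusDesign.from_dict(yaml.safe_load(Path(path).read_text()))


def write_features(fm: FeatureMatrix, path: str | Path) -> None:
    """TSV with a piece_id label column followed by the feature columns."""
    df = pd.DataFrame(fm.values, columns=list(fm.feature_names))
    labels = fm.piece_labels if fm.piece_labels is not None else np.full(fm.n_samples, -1)
    df.insert(0, "piece_id", labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_features(path: str | Path, medley_id: int = 0, tr_s: float | None = 2.0) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t")
    if "piece_id" not in df.columns:
        raise ValueError(f"{path}: missing piece_id column")
    labels = df.pop("piece_id").to_numpy(dtype=int)
    return FeatureMatrix(
        df.to_numpy(dtype=float),
        feature_names=tuple(df.columns),
        medley_id=medley_id,
        piece_labels=labels,
        sample_rate_hz=None if tr_s is None else 1.0 / tr_s,
        per_tr=True,
    )


def write_bold_run(run: BoldRun, prefix: str | Path) -> None:
    """``<prefix>.tsv`` (volumes × voxels) plus ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".tsv"), run.values, delimiter="\t", fmt="%.10g")
    sidecar = {
        "session_id": run.session_id,
        "run_id": run.run_id,
        "tr_s": run.tr_s,
        "voxel_ids": run.voxel_ids.tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def read_bold_run(prefix: str | Path) -> BoldRun:
    prefix = Path(prefix)
    values = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    return BoldRun(
        values,
        session_id=sidecar["session_id"],
        run_id=sidecar["run_id"],
        tr_s=sidecar["tr_s"],
        voxel_ids=np.asarray(sidecar["voxel_ids"]),
    )


def write_bold_dataset(bold: BoldDataset, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for run in bold.runs:
        prefix = out_dir / f"bold_ses-{run.session_id}_run-{run.run_id}"
        write_bold_run(run, prefix)
        paths.append(prefix.with_suffix(".tsv"))
    return paths


def read_bold_dataset(in_dir: str | Path) -> BoldDataset:
    in_dir = Path(in_dir)
    prefixes = sorted(p.with_suffix("") for p in in_dir.glob("bold_ses-*_run-*.tsv"))
    if not prefixes:
        raise FileNotFoundError(f"no bold_ses-*_run-*.tsv files under {in_dir}")
    return BoldDataset([read_bold_run(p) for p in prefixes])


def write_ground_truth(gt, out_dir: str | Path) -> None:
    """Ground-truth sidecar: weights TSV + JSON metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "true_weights.tsv", gt.true_weights, delimiter="\t", fmt="%.10g")
    meta = {
        "responsive_voxel_ids": gt.responsive_voxel_ids.tolist(),
        "seed": gt.seed,
        "child_seeds": gt.child_seeds,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(meta))
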