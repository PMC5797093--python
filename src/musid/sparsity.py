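"""Model-sparsity assessment.

Identification accuracy is measured as a function of the number of
features in the encoding model, from 1 to the full set.  Features have no
intrinsic order, so the sweep runs twice — in ascending and in descending
order of the variance inflation factor — and the per-m accuracy is the
mean over the two orders.  The resulting curve is compared between a
saturating-exponential and a logarithmic least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .design import CvFold, StimulusDesign, enumerate_folds
from .decoding import IdentificationEngine
from .features import FeatureMatrix, vif_order
from .preprocess import BoldDataset

__all__ = ["SparsityCurve", "CurveFitComparison", "sparsity_sweep", "fit_accuracy_curve"]


@dataclass
class SparsityCurve:
    """Accuracy per feature count, for both VIF orders and their mean."""

    table: pd.DataFrame  # columns: n_features, acc_ascending, acc_descending, acc_mean
    ascending_order: np.ndarray
    descending_order: np.ndarray
    n_voxels: int
    n_timepoints: int

    @property
    def n_features(self) -> np.ndarray:
        return self.table["n_features"].to_numpy()

    @property
    def accuracy(self) -> np.ndarray:
        return self.table["acc_mean"].to_numpy()


@dataclass
class CurveFitComparison:
    exponential_params: np.ndarray  # a, b, c of a(1 − e^{−bm}) + c
    exponential_rss: float
    logarithmic_params: np.ndarray  # a, b of a ln(m) + b
    logarithmic_rss: float
    better: str  # 'exponential' | 'logarithmic'
    exponential_converged: bool


def _binary_accuracy(engine: IdentificationEngine, folds: list[CvFold],
                     n_voxels: int, n_timepoints: int) -> float:
    correct = total = 0
    for fold in folds:
        ranks = engine.evaluate_fold_nway(fold, n_voxels, n_timepoints)
        correct += int(np.sum(ranks == 1))
        total += ranks.size
    return 100.0 * correct / total


def sparsity_sweep(
    bold: BoldDataset,
    features: list[FeatureMatrix],
    design: StimulusDesign,
    folds: list[CvFold] | None = None,
    n_voxels: int = 100,
    n_timepoints: int | None = None,
) -> SparsityCurve:
    """Rerun encoding + binary identification with the first m features of
    each VIF order, m = 1..n_features; accuracy per m is the mean over the
    two orders (accuracy taken at ``n_voxels`` top voxels and, by default,
    the full trimmed piece length)."""
    asc, desc = vif_order(features)
    if folds is None:
        folds = enumerate_folds(design, n_test=2)
    p = features[0].n_features
    t = n_timepoints if n_timepoints is not None else design.retained_vols_per_piece
    acc = {"ascending": np.empty(p), "descending": np.empty(p)}
    for name, order in (("ascending", asc), ("descending", desc)):
        for m in range(1, p + 1):
            engine = IdentificationEngine(bold, features, design,
                                          feature_subset=order[:m])
            acc[name][m - 1] = _binary_accuracy(engine, folds, n_voxels, t)
    table = pd.DataFrame(
        {
            "n_features": np.arange(1, p + 1),
            "acc_ascending": acc["ascending"],
            "acc_descending": acc["descending"],
            "acc_mean": (acc["ascending"] + acc["descending"]) / 2.0,
        }
    )
    return SparsityCurve(table=table, ascending_order=asc, descending_order=desc,
                         n_voxels=n_voxels, n_timepoints=t)


def _exp_form(m, a, b, c):
    # clipped exponent keeps optimizer excursions finite
    return a * (1.0 - np.exp(-np.clip(b * m, -700.0, 700.0))) + c


def fit_accuracy_curve(curve: SparsityCurve | tuple[np.ndarray, np.ndarray]) -> CurveFitComparison:
    """Least-squares fits of the accuracy curve.

    Saturating exponential a·(1 − e^{−b·m}) + c (initialised at
    a = max − min, b = 0.2, c = min, with a grid restart over b on
    non-convergence) versus logarithmic a·ln(m) + b (closed form).
    Reports the residual sum of squares of each and which is lower.
    """
    if isinstance(curve, SparsityCurve):
        m, y = curve.n_features.astype(float), curve.accuracy
    else:
        m, y = np.asarray(curve[0], float), np.asarray(curve[1], float)
    if m.size < 4:
        raise ValueError("need at least 4 points to compare curve fits")

    # logarithmic fit is linear in parameters
    X = np.column_stack([np.log(m), np.ones_like(m)])
    log_params, *_ = np.linalg.lstsq(X, y, rcond=None)
    log_rss = float(np.sum((y - X @ log_params) ** 2))

    p0 = (y.max() - y.min(), 0.2, y.min())
    exp_params, converged = None, False
    for b0 in (p0[1], 0.05, 0.5, 1.0, 2.0):
        try:
            popt, _ = curve_fit(_exp_form, m, y, p0=(p0[0], b0, p0[2]), maxfev=20_000)
            resid = float(np.sum((y - _exp_form(m, *popt)) ** 2))
            if exp_params is None or resid < exp_rss:
                exp_params, exp_rss = popt, resid
            converged = True
        except RuntimeError:
            continue
    if exp_params is None:  # flagged fallback: report the initial guess
        exp_params = np.asarray(p0)
        exp_rss = float(np.sum((y - _exp_form(m, *exp_params)) ** 2))

    return CurveFitComparison(
        exponential_params=np.asarray(exp_params),
        exponential_rss=exp_rss,
        logarithmic_params=log_params,
        logarithmic_rss=log_rss,
        better="exponential" if exp_rss < log_rss else "logarithmic",
        exponential_converged=converged,
    )
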