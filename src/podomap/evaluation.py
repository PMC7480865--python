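"""Evaluation metrics, threshold optimisation, and spatial-block CV.

AUC is the weighted probability that a random presence outscores a random
absence (ties count one half); TSS = sensitivity + specificity - 1; PCC is the
proportion correctly classified. The occurrence threshold is the cut-off
giving the best trade-off between sensitivity, specificity and accuracy:
we maximise sensitivity + specificity (equivalently TSS) over all candidate
thresholds, breaking ties by higher accuracy and then by lower threshold.

Spatial-block cross-validation tiles the study extent with square blocks
(2,000 km in the continental design, configurable) and assigns blocks to k
fold labels, balanced and shuffled, so test points are geographically
separated from training points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .grid import GridRaster, GridSpec

logger = logging.getLogger("podomap")


class EvaluationError(ValueError):
    pass


def _as_arrays(labels, scores, weights=None):
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if weights is None:
        weights = np.ones_like(scores)
    weights = np.asarray(weights, dtype=float)
    if not (labels.shape == scores.shape == weights.shape):
        raise EvaluationError("labels, scores and weights must have equal length")
    return labels, scores, weights


def roc_auc(labels, scores, weights=None) -> float:
    """Weighted ROC AUC (Mann-Whitney form, ties counted one half)."""
    labels, scores, weights = _as_arrays(labels, scores, weights)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("AUC undefined with a single class")
    return float(roc_auc_score(labels, scores, sample_weight=weights))


def tss(sensitivity: float, specificity: float) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


@dataclass
class ConfusionSummary:
    tp: float
    fp: float
    tn: float
    fn: float

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else np.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) > 0 else np.nan

    @property
    def pcc(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total > 0 else np.nan


def confusion_at(labels, scores, weights=None, threshold: float = 0.5) -> ConfusionSummary:
    """Weighted confusion summary; prediction is positive iff score >= threshold."""
    labels, scores, weights = _as_arrays(labels, scores, weights)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionSummary(
        tp=float(weights[pred & pos].sum()),
        fp=float(weights[pred & ~pos].sum()),
        tn=float(weights[~pred & ~pos].sum()),
        fn=float(weights[~pred & pos].sum()),
    )


@dataclass
class ThresholdResult:
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float

    @property
    def tss(self) -> float:
        return tss(self.sensitivity, self.specificity)


def _threshold_candidates(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.empty(0)
    return np.unique(np.concatenate([uniq, mids]))


def optimal_threshold(labels, scores, weights=None) -> ThresholdResult:
    """Best sensitivity/specificity trade-off over candidate thresholds.

    Candidates are all distinct scores plus midpoints between consecutive
    distinct scores. The maximiser of sensitivity + specificity wins; ties are
    broken by higher accuracy, then by lower threshold.
    """
    labels, scores, weights = _as_arrays(labels, scores, weights)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("threshold optimisation requires both classes")
    best = None
    for t in _threshold_candidates(scores):
        cm = confusion_at(labels, scores, weights, threshold=t)
        key = (cm.sensitivity + cm.specificity, cm.pcc, -t)
        if best is None or key > best[0]:
            best = (key, t, cm)
    _, t, cm = best
    return ThresholdResult(
        threshold=float(t),
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        accuracy=cm.pcc,
        auc=roc_auc(labels, scores, weights),
    )


# ---------------------------------------------------------------------------
# Spatial blocks


@dataclass
class FoldAssignment:
    """Block-to-fold map over a tiling of the extent by square blocks."""

    block_size_km: float
    n_block_rows: int
    n_block_cols: int
    fold_of_block: dict[int, int]  # flat block index -> fold label 1..k
    fold_of_point: np.ndarray = field(default=None)  # type: ignore[assignment]

    def block_of_points(self, spec: GridSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        bx = np.floor((np.asarray(x, float) - spec.x_min) / self.block_size_km).astype(int)
        by = np.floor((np.asarray(y, float) - spec.y_min) / self.block_size_km).astype(int)
        bx = np.clip(bx, 0, self.n_block_cols - 1)
        by = np.clip(by, 0, self.n_block_rows - 1)
        return by * self.n_block_cols + bx


def make_spatial_blocks(
    spec: GridSpec,
    points: np.ndarray,
    block_km: float = 2000.0,
    k: int = 5,
    rng_seed: int = 0,
) -> FoldAssignment:
    """Tile the extent with block_km squares anchored at (x_min, y_min) and
    assign each block a fold label 1..k, balanced across blocks and shuffled.

    Points (n x 2 array of x, y) inherit their block's fold. Fails if any fold
    ends up with no points.
    """
    if block_km <= 0:
        raise EvaluationError("block_km must be positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n_bc = int(np.ceil((spec.x_max - spec.x_min) / block_km))
    n_br = int(np.ceil((spec.y_max - spec.y_min) / block_km))
    n_blocks = n_bc * n_br
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n_blocks)
    labels = np.tile(np.arange(1, k + 1), int(np.ceil(n_blocks / k)))[:n_blocks]
    fold_of_block = {int(b): int(l) for b, l in zip(order, labels)}
    fa = FoldAssignment(block_km, n_br, n_bc, fold_of_block)
    blocks = fa.block_of_points(spec, pts[:, 0], pts[:, 1])
    fa.fold_of_point = np.array([fold_of_block[int(b)] for b in blocks])
    present = set(fa.fold_of_point.tolist())
    missing = [f for f in range(1, k + 1) if f not in present]
    if missing:
        raise EvaluationError(
            f"folds {missing} contain no points; use a larger k or smaller blocks"
        )
    return fa


def block_cv(frame, specs, folds: FoldAssignment, gates=None):
    """Spatial-block cross-validation: for each fold, fit every learner on the
    other folds and score it on the held-out fold.

    Returns a list of ModelRun (one per fold x learner spec) whose metrics are
    computed on the spatially held-out fold; folds whose test set has a single
    class are skipped with a log message.
    """
    from .ensemble import ModelRun, _evaluate  # local import to avoid cycle
    from .learners import fit_learner

    fold_labels = np.unique(folds.fold_of_point)
    if len(fold_labels) < 2:
        raise EvaluationError("block CV requires at least 2 non-empty folds")
    runs = []
    for f in fold_labels:
        test_idx = folds.fold_of_point == f
        train_idx = ~test_idx
        y_test = frame.labels[test_idx]
        if len(np.unique(y_test)) < 2 or len(np.unique(frame.labels[train_idx])) < 2:
            logger.warning("block_cv: fold %d has a single class, skipped", f)
            continue
        train = frame.subset(train_idx)
        test = frame.subset(test_idx)
        for spec in specs:
            fitted = fit_learner(spec, train)
            auc, t, p = _evaluate(fitted, test)
            runs.append(
                ModelRun(
                    algorithm=spec.algorithm,
                    replicate_index=int(f),
                    split_seed=spec.rng_seed,
                    fitted=fitted,
                    auc=auc,
                    tss=t,
                    pcc=p,
                )
            )
    if not runs:
        raise EvaluationError("block CV produced no usable folds")
    return runs


def compare_predictions_pearson(a: GridRaster, b: GridRaster) -> float:
    """Pearson correlation between two aligned rasters over jointly valid cells."""
    if not a.spec.aligned(b.spec):
        raise EvaluationError("rasters are not aligned")
    both = a.valid_mask & b.valid_mask
    if both.sum() < 2:
        raise EvaluationError("need at least 2 jointly valid cells")
    va, vb = a.values[both], b.values[both]
    if np.std(va) == 0 or np.std(vb) == 0:
        raise EvaluationError("zero variance input")
    return float(np.corrcoef(va, vb)[0, 1])
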