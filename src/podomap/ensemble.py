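"""Replicate-evaluate-gate-combine ensemble engine.

Each learner is refitted on 50 (configurable) stratified 80/20 random splits;
every replicate is scored on its held-out 20% by AUC, TSS and PCC (TSS and
PCC at the held-out TSS-maximising threshold, the convention of ensemble
platforms in this field). Replicates failing the quality gates
(AUC >= 0.8 and TSS >= 0.7 by default) are disregarded; the surviving runs
are combined into a per-cell AUC-weighted mean suitability surface with
equal-tail 2.5%/97.5% quantile bounds across members.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import EvaluationError, confusion_at, optimal_threshold, roc_auc
from .grid import CovariateStack, GridRaster
from .learners import FittedLearner, LearnerSpec, fit_learner
from .survey import ModelFrame

logger = logging.getLogger("podomap")


class EnsembleError(ValueError):
    pass


@dataclass
class ModelRun:
    """One fitted learner replicate with its held-out scores."""

    algorithm: str
    replicate_index: int
    split_seed: int
    fitted: FittedLearner
    auc: float
    tss: float
    pcc: float

    def to_record(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "replicate_index": self.replicate_index,
            "split_seed": self.split_seed,
            "auc": self.auc,
            "tss": self.tss,
            "pcc": self.pcc,
        }


def derive_seed(global_seed: int, algorithm: str, replicate: int) -> int:
    """Deterministic per-run seed from (global seed, algorithm, replicate)."""
    algo_code = zlib.crc32(algorithm.encode()) % (2**31)
    ss = np.random.SeedSequence([global_seed, algo_code, replicate])
    return int(ss.generate_state(1)[0] % (2**31))


def _stratified_split(labels, train_fraction, rng):
    idx = np.arange(len(labels))
    train = []
    for cls in np.unique(labels):
        cls_idx = idx[labels == cls]
        perm = rng.permutation(cls_idx)
        n_train = max(1, int(round(train_fraction * len(cls_idx))))
        n_train = min(n_train, len(cls_idx) - 1) if len(cls_idx) > 1 else n_train
        train.append(perm[:n_train])
    train = np.concatenate(train)
    mask = np.zeros(len(labels), dtype=bool)
    mask[train] = True
    return mask


def _evaluate(fitted: FittedLearner, test: ModelFrame) -> tuple[float, float, float]:
    """Held-out AUC, TSS and PCC (the latter two at the TSS-optimal cut-off)."""
    scores = fitted.predict_prob(test.X)
    auc = roc_auc(test.labels, scores, test.weights)
    opt = optimal_threshold(test.labels, scores, test.weights)
    cm = confusion_at(test.labels, scores, test.weights, opt.threshold)
    return auc, opt.tss, cm.pcc


def run_replicates(
    frame: ModelFrame,
    specs: list[LearnerSpec],
    n_reps: int = 50,
    train_fraction: float = 0.8,
    rng_seed: int = 0,
    max_resplits: int = 10,
) -> list[ModelRun]:
    """Fit n_reps stratified 80/20 replicates of every learner spec.

    Splits are stratified by label so each test set holds both classes; a
    degenerate split is redrawn with a derived seed (bounded retries).
    """
    if n_reps < 1:
        raise EnsembleError("n_reps must be >= 1")
    runs: list[ModelRun] = []
    for spec in specs:
        for rep in range(1, n_reps + 1):
            seed = derive_seed(rng_seed, spec.algorithm, rep)
            for attempt in range(max_resplits):
                rng = np.random.default_rng(seed + attempt)
                train_mask = _stratified_split(frame.labels, train_fraction, rng)
                test_labels = frame.labels[~train_mask]
                if len(np.unique(test_labels)) == 2:
                    break
                logger.warning("replicate %s/%d: single-class test split, redrawing",
                               spec.algorithm, rep)
            else:
                raise EnsembleError("could not obtain a two-class test split")
            run_spec = LearnerSpec(spec.algorithm, spec.hyperparameters, rng_seed=seed)
            fitted = fit_learner(run_spec, frame.subset(train_mask))
            auc, tss_val, pcc = _evaluate(fitted, frame.subset(~train_mask))
            runs.append(
                ModelRun(
                    algorithm=spec.algorithm,
                    replicate_index=rep,
                    split_seed=seed,
                    fitted=fitted,
                    auc=auc,
                    tss=tss_val,
                    pcc=pcc,
                )
            )
    return runs


def select_runs(runs: list[ModelRun], auc_min: float = 0.8, tss_min: float = 0.7) -> list[ModelRun]:
    """Keep exactly the runs with AUC >= auc_min and TSS >= tss_min."""
    if not runs:
        raise EnsembleError("no runs to select from")
    selected = [r for r in runs if r.auc >= auc_min and r.tss >= tss_min]
    if not selected:
        raise EnsembleError(
            f"no run passed the quality gates (AUC >= {auc_min}, TSS >= {tss_min}); "
            "consider relaxing the gates"
        )
    return selected


@dataclass
class EnsemblePrediction:
    """Per-cell weighted-mean suitability with quantile bounds and members."""

    mean: GridRaster
    lower: GridRaster
    upper: GridRaster
    member_predictions: list[tuple[str, GridRaster]]
    weights: dict[str, float] = field(default_factory=dict)


def predict_run_raster(run: ModelRun, stack: CovariateStack) -> GridRaster:
    """One member's suitability surface over all stack-valid cells."""
    mask = stack.valid_mask()
    table = stack.table()
    probs = run.fitted.predict_prob(table[run.fitted.covariate_names])
    out = np.full(stack.spec.shape, np.nan)
    out[mask] = probs
    return GridRaster(stack.spec, out, ~mask)


def ensemble_predict(
    selected: list[ModelRun],
    stack: CovariateStack,
    quantiles: tuple[float, float] = (0.025, 0.975),
) -> EnsemblePrediction:
    """AUC-weighted mean of member suitability surfaces per grid cell.

    mean = sum(w_i p_i) / sum(w_i) with w_i the member's held-out AUC; the
    lower/upper surfaces are the equal-tail quantiles of the member
    predictions per cell. Cells invalid in the stack stay masked.
    """
    if not selected:
        raise EnsembleError("ensemble requires at least one selected run")
    missing = [
        c for r in selected for c in r.fitted.covariate_names if c not in stack.names
    ]
    if missing:
        raise EnsembleError(f"stack lacks covariates required by members: {sorted(set(missing))}")
    mask = stack.valid_mask()
    table = stack.table()
    preds = np.empty((len(selected), int(mask.sum())))
    weights = np.empty(len(selected))
    members = []
    for i, run in enumerate(selected):
        preds[i] = run.fitted.predict_prob(table[run.fitted.covariate_names])
        weights[i] = run.auc
        out = np.full(stack.spec.shape, np.nan)
        out[mask] = preds[i]
        members.append(
            (f"{run.algorithm}_{run.replicate_index}", GridRaster(stack.spec, out, ~mask))
        )
    wmean = (weights[:, None] * preds).sum(axis=0) / weights.sum()
    lo = np.quantile(preds, quantiles[0], axis=0)
    hi = np.quantile(preds, quantiles[1], axis=0)

    def to_raster(flat):
        out = np.full(stack.spec.shape, np.nan)
        out[mask] = flat
        return GridRaster(stack.spec, out, ~mask)

    return EnsemblePrediction(
        mean=to_raster(wmean),
        lower=to_raster(lo),
        upper=to_raster(hi),
        member_predictions=members,
        weights={m[0]: float(w) for m, w in zip(members, weights)},
    )
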