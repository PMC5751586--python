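"""Evaluation protocol: negative controls, 5-fold CV, ACC/TPR/FPR, ROC/AUC.

Negative controls pair each positive with a shuffled same-length window
drawn from a background pool (e.g. unrelated ncRNAs).  Cross-validation
stratifies by class, trains on k-1 folds and scores the held-out fold;
ROC curves are traced over the pooled held-out confidences and AUC is
computed by the trapezoidal rule (reported both as a fraction and x100).
A parameter-sweep harness grids dataset size x N_th x Z_th, recording
per-cell CV accuracy and mean family counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from . import calibration as calib
from .clustering import ClusteringParams
from .features import SvmConfig, ZeroFamiliesError, train_detector
from .kmer import KmerLogOdds
from .sequence_io import NucleotideSequence, SequenceSet, decode
from .simulate import FixtureSpec, generate_fixture

logger = logging.getLogger(__name__)

#: trainer signature: (train_pos, train_neg, seed) -> scorer(seqs) -> scores
Trainer = Callable[[SequenceSet, SequenceSet, int], Callable[[SequenceSet], np.ndarray]]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(ACC, TPR, FPR) from confusion counts.

    ACC = (TP+TN)/(TP+TN+FP+FN), TPR = TP/(TP+FN), FPR = FP/(TN+FP).
    """
    total = counts.tp + counts.tn + counts.fp + counts.fn
    if total == 0:
        raise ZeroDivisionError("ACC undefined: no samples")
    if counts.tp + counts.fn == 0:
        raise ZeroDivisionError("TPR undefined: no positives")
    if counts.tn + counts.fp == 0:
        raise ZeroDivisionError("FPR undefined: no negatives")
    acc = (counts.tp + counts.tn) / total
    tpr = counts.tp / (counts.tp + counts.fn)
    fpr = counts.fp / (counts.tn + counts.fp)
    return acc, tpr, fpr


def make_negatives(pos: SequenceSet, background: SequenceSet,
                   rng_seed: int) -> SequenceSet:
    """One shuffled background window per positive, length-matched.

    For each positive a background record at least as long is drawn
    uniformly, a window of the positive's length is cut at a uniform
    offset, and the window is mononucleotide-shuffled.
    """
    rng = np.random.default_rng(rng_seed)
    bg_codes = [rec.encoded() for rec in background]
    bg_lengths = np.array([c.size for c in bg_codes])
    negatives = []
    for rec in pos:
        eligible = np.nonzero(bg_lengths >= rec.length)[0]
        if eligible.size == 0:
            raise ValueError(
                f"no background sequence of length >= {rec.length} "
                f"for positive {rec.id!r}"
            )
        src = bg_codes[int(rng.choice(eligible))]
        start = int(rng.integers(0, src.size - rec.length + 1))
        window = rng.permutation(src[start:start + rec.length])
        negatives.append(NucleotideSequence(f"neg_{rec.id}", decode(window)))
    return SequenceSet(negatives)


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) arrays over the score-threshold sweep."""
    fpr, tpr, _ = _roc_curve(y_true, scores)
    return fpr, tpr


def auc_trapezoid(y_true: np.ndarray, scores: np.ndarray) -> float:
    fpr, tpr = roc_points(np.asarray(y_true), np.asarray(scores))
    return float(_trapezoid_auc(fpr, tpr))


@dataclass
class EvalReport:
    """Results of one cross-validation experiment."""

    fold_counts: list[ConfusionCounts]
    fold_metrics: list[tuple[float, float, float]]  # (ACC, TPR, FPR) per fold
    acc: float
    tpr: float
    fpr: float
    roc: list[tuple[float, float]]  # pooled (FPR, TPR) points
    auc: float
    config: dict = field(default_factory=dict)

    @property
    def auc_pct(self) -> float:
        """AUC on the x100 scale used for reporting."""
        return 100.0 * self.auc

    def to_dict(self) -> dict:
        return {
            "fold_counts": [vars(c) for c in self.fold_counts],
            "fold_metrics": [list(m) for m in self.fold_metrics],
            "acc": self.acc, "tpr": self.tpr, "fpr": self.fpr,
            "auc": self.auc, "auc_pct": self.auc_pct,
            "roc": [list(p) for p in self.roc],
            "config": self.config,
        }


def _stratified_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def crossvalidate(pos: SequenceSet, neg: SequenceSet, k: int = 5,
                  trainer: Trainer | None = None, rng_seed: int = 0,
                  decision_threshold: float = 0.5,
                  config: dict | None = None) -> EvalReport:
    """Stratified k-fold cross-validation of a detector-training recipe.

    ``trainer(train_pos, train_neg, fold_seed)`` must return a scorer
    mapping a SequenceSet to per-sequence confidences/scores; calls are
    positive when the score reaches ``decision_threshold``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(pos) < k or len(neg) < k:
        raise ValueError("each class needs at least k sequences")
    if trainer is None:
        trainer = ngm_trainer()
    rng = np.random.default_rng(rng_seed)
    pos_folds = _stratified_folds(len(pos), k, rng)
    neg_folds = _stratified_folds(len(neg), k, rng)
    fold_counts: list[ConfusionCounts] = []
    fold_metrics: list[tuple[float, float, float]] = []
    pooled_scores: list[np.ndarray] = []
    pooled_truth: list[np.ndarray] = []
    for fold in range(k):
        test_pos = SequenceSet(pos[int(i)] for i in sorted(pos_folds[fold]))
        test_neg = SequenceSet(neg[int(i)] for i in sorted(neg_folds[fold]))
        train_pos = SequenceSet(
            pos[int(i)] for f in range(k) if f != fold for i in sorted(pos_folds[f]))
        train_neg = SequenceSet(
            neg[int(i)] for f in range(k) if f != fold for i in sorted(neg_folds[f]))
        scorer = trainer(train_pos, train_neg, rng_seed * 1000 + fold)
        s_pos = np.asarray(scorer(test_pos), dtype=float)
        s_neg = np.asarray(scorer(test_neg), dtype=float)
        counts = ConfusionCounts(
            tp=int((s_pos >= decision_threshold).sum()),
            fn=int((s_pos < decision_threshold).sum()),
            fp=int((s_neg >= decision_threshold).sum()),
            tn=int((s_neg < decision_threshold).sum()),
        )
        fold_counts.append(counts)
        fold_metrics.append(metrics(counts))
        pooled_scores.append(np.concatenate([s_pos, s_neg]))
        pooled_truth.append(np.concatenate([np.ones(len(test_pos)),
                                            np.zeros(len(test_neg))]))
    scores = np.concatenate(pooled_scores)
    truth = np.concatenate(pooled_truth)
    fpr_pts, tpr_pts = roc_points(truth, scores)
    mean = np.mean(fold_metrics, axis=0)
    return EvalReport(
        fold_counts=fold_counts,
        fold_metrics=fold_metrics,
        acc=float(mean[0]), tpr=float(mean[1]), fpr=float(mean[2]),
        roc=list(zip(fpr_pts.tolist(), tpr_pts.tolist())),
        auc=float(_trapezoid_auc(fpr_pts, tpr_pts)),
        config={"k": k, "rng_seed": rng_seed,
                "decision_threshold": decision_threshold, **(config or {})},
    )


# ------------------------------------------------------------- trainers

def ngm_trainer(params: ClusteringParams | None = None,
                svm_config: SvmConfig | None = None,
                anchor_lengths=calib.DEFAULT_ANCHOR_LENGTHS,
                detection_ensemble_size: int = 2000,
                family_counts: list[int] | None = None) -> Trainer:
    """Trainer adapter for the NGM+SVM detector.

    ``family_counts``, if given, records the number of families each
    trained fold found (used by the sweep harness).
    """
    base = params or ClusteringParams()

    def train(train_pos: SequenceSet, train_neg: SequenceSet, seed: int):
        det = train_detector(
            train_pos, train_neg, replace(base, rng_seed=seed),
            svm_config=svm_config, anchor_lengths=anchor_lengths,
            detection_ensemble_size=detection_ensemble_size)
        if family_counts is not None:
            family_counts.append(len(det.families))
        return det.confidences

    return train


def kmer_trainer() -> Trainer:
    """Trainer adapter for the k-mer log-odds baseline."""

    def train(train_pos: SequenceSet, train_neg: SequenceSet, seed: int):
        scorer = KmerLogOdds(train_pos, train_neg)
        return scorer.scores

    return train


# ------------------------------------------------------- parameter sweep

def parameter_sweep(sizes: Sequence[int], n_th_values: Sequence[int],
                    z_th_values: Sequence[float],
                    fixture_spec: FixtureSpec | None = None,
                    data: tuple[SequenceSet, SequenceSet] | None = None,
                    rng_seed: int = 0, k: int = 5,
                    clustering_ensemble_size: int = 1000,
                    detection_ensemble_size: int = 1000) -> pd.DataFrame:
    """Grid of CV accuracy and mean family count over (size, N_th, Z_th).

    Either a fixture spec (data are generated per size, negatives built
    from the fixture background) or an explicit (pos, neg) pair (sub-
    sampled per size) must be supplied.  Cells whose clustering finds no
    family get accuracy NaN and family count 0.
    """
    if (fixture_spec is None) == (data is None):
        raise ValueError("supply exactly one of fixture_spec or data")
    rows = []
    for size in sizes:
        if fixture_spec is not None:
            spec = replace(fixture_spec,
                           family_size=max(1, size // max(1, fixture_spec.num_families)),
                           background_size=size, rng_seed=rng_seed)
            pos, background, _ = generate_fixture(spec)
            neg = make_negatives(pos, background, rng_seed + 1)
        else:
            full_pos, full_neg = data
            rng = np.random.default_rng(rng_seed)
            pos = SequenceSet(full_pos[int(i)] for i in
                              sorted(rng.choice(len(full_pos), min(size, len(full_pos)),
                                                replace=False)))
            neg = SequenceSet(full_neg[int(i)] for i in
                              sorted(rng.choice(len(full_neg), min(size, len(full_neg)),
                                                replace=False)))
        for n_th in n_th_values:
            for z_th in z_th_values:
                params = ClusteringParams(
                    n_th=int(n_th), z_th=float(z_th),
                    ensemble_size=clustering_ensemble_size)
                counts: list[int] = []
                trainer = ngm_trainer(
                    params, detection_ensemble_size=detection_ensemble_size,
                    family_counts=counts)
                try:
                    report = crossvalidate(pos, neg, k=k, trainer=trainer,
                                           rng_seed=rng_seed)
                    acc = report.acc
                except ZeroFamiliesError:
                    acc = float("nan")
                mean_families = float(np.mean(counts)) if counts else 0.0
                rows.append({"size": int(size), "n_th": int(n_th),
                             "z_th": float(z_th), "acc": acc,
                             "mean_families": mean_families})
                logger.info("sweep cell size=%d n_th=%d z_th=%.2f: "
                            "acc=%.3f families=%.1f", size, n_th, z_th,
                            acc, mean_families)
    return pd.DataFrame(rows)
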