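"""NGM feature extraction and the SVM piRNA detector.

Each classified family contributes one feature: the Z-score of a
sequence's similarity against that family's n-gram model, standardized
by the family's detection-stage calibration (multi-length shuffled
ensemble + length regression).  The feature vectors — typically well
under 50 dimensions — feed a C-support-vector classifier with RBF kernel
whose Platt-scaled probability is reported as the detection confidence.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from . import calibration as calib
from .calibration import ZCalibration, calibrate, zscores
from .clustering import ClusteringParams, SequenceFamily, cluster_all, write_families
from .ngm import NGramModel
from .sequence_io import (LABEL_NEGATIVE, LABEL_POSITIVE, NucleotideSequence,
                          SequenceSet)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureVector:
    """Per-sequence Z-scores, one per family (discovery order)."""

    sequence_id: str
    values: tuple[float, ...]


@dataclass(frozen=True)
class SvmConfig:
    """RBF c-SVC settings; grid search is off by default."""

    C: float = 1.0
    gamma: str | float = "scale"
    grid_search: bool = False
    grid_C: tuple[float, ...] = (0.1, 1.0, 10.0)
    grid_gamma: tuple[float, ...] = (0.01, 0.1, 1.0)
    cv_folds: int = 3


class ZeroFamiliesError(ValueError):
    """Raised when clustering yields no family to extract features from."""


def feature_matrix(families: list[SequenceFamily], seqs: SequenceSet,
                   L_score: int) -> np.ndarray:
    """(n_sequences, n_families) matrix of Z-score features.

    The scan window for each sequence is capped at its length; shorter-
    than-window sequences are therefore fine, but sequences shorter than
    the gram size are not scoreable.
    """
    if not families:
        raise ZeroFamiliesError("no families: no features to extract")
    cols = [zscores(fam.calibration, fam.model, seqs, L_score)
            for fam in families]
    return np.column_stack(cols)


def featurize(families: list[SequenceFamily], seqs: SequenceSet,
              L_score: int) -> list[FeatureVector]:
    """Feature vectors in the input sequence order."""
    mat = feature_matrix(families, seqs, L_score)
    return [FeatureVector(rec.id, tuple(row)) for rec, row in zip(seqs, mat)]


@dataclass
class DetectorModel:
    """A trained piRNA detector: families, calibrations and the SVM."""

    families: list[SequenceFamily]
    svm: CalibratedClassifierCV
    L_score: int
    params: ClusteringParams
    training_meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.params.n

    def confidences(self, seqs: SequenceSet) -> np.ndarray:
        """P(piRNA) for every sequence (all must have length >= n)."""
        mat = feature_matrix(self.families, seqs, self.L_score)
        positive_col = int(np.nonzero(self.svm.classes_ == 1)[0][0])
        return self.svm.predict_proba(mat)[:, positive_col]

    def predict(self, seqs: SequenceSet,
                threshold: float = 0.5) -> list[tuple[str, str, float]]:
        """(id, label, confidence) triples; label is piRNA iff conf >= threshold.

        Sequences shorter than the gram size cannot be scored; they are
        skipped with a warning and the rest are still processed.
        """
        scoreable, skipped = [], []
        for rec in seqs:
            (scoreable if rec.length >= self.n else skipped).append(rec)
        for rec in skipped:
            warnings.warn(
                f"sequence {rec.id!r} shorter than n={self.n}; skipped")
        if not scoreable:
            return []
        conf = self.confidences(SequenceSet(scoreable))
        return [
            (rec.id, LABEL_POSITIVE if c >= threshold else LABEL_NEGATIVE, float(c))
            for rec, c in zip(scoreable, conf)
        ]

    # ---------------------------------------------------------- persistence

    def save(self, directory: str | Path) -> None:
        """Write the model bundle (manifest, families, models, SVM state)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_families(self.families, directory / "families.tsv")
        fam_docs = []
        for fam in self.families:
            fam_docs.append({
                "family_id": fam.family_id,
                "seed_id": fam.seed_id,
                "member_ids": fam.member_ids,
                "model": fam.model.to_dict(),
                "calibration": fam.calibration.to_dict(),
            })
        (directory / "families.json").write_text(json.dumps(fam_docs))
        joblib.dump(self.svm, directory / "svm.joblib")
        manifest = {
            "L_score": self.L_score,
            "params": {
                "n": self.params.n, "z_th": self.params.z_th,
                "n_th": self.params.n_th,
                "pseudo_count": self.params.pseudo_count,
                "L": self.params.L,
                "ensemble_size": self.params.ensemble_size,
                "rng_seed": self.params.rng_seed,
                "seed_criterion": self.params.seed_criterion,
            },
            "training_meta": self.training_meta,
            "num_families": len(self.families),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "DetectorModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        fam_docs = json.loads((directory / "families.json").read_text())
        families = [
            SequenceFamily(
                family_id=doc["family_id"], seed_id=doc["seed_id"],
                member_ids=list(doc["member_ids"]),
                model=NGramModel.from_dict(doc["model"]),
                calibration=ZCalibration.from_dict(doc["calibration"]),
            )
            for doc in fam_docs
        ]
        svm = joblib.load(directory / "svm.joblib")
        params = ClusteringParams(**manifest["params"])
        return cls(families=families, svm=svm, L_score=manifest["L_score"],
                   params=params, training_meta=manifest.get("training_meta", {}))


def train_detector(pos: SequenceSet, neg: SequenceSet,
                   params: ClusteringParams | None = None,
                   svm_config: SvmConfig | None = None,
                   anchor_lengths=calib.DEFAULT_ANCHOR_LENGTHS,
                   detection_ensemble_size: int = calib.DEFAULT_ENSEMBLE_SIZE,
                   ) -> DetectorModel:
    """Train the full detector: cluster, calibrate, featurize, fit the SVM.

    The detection-stage calibration shuffles the positive training set
    itself as the null source; anchor lengths without any long-enough
    source sequence are dropped with a warning.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("positive and negative training sets must be non-empty")
    params = params or ClusteringParams()
    svm_config = svm_config or SvmConfig()
    families, residual = cluster_all(pos, params)
    if not families:
        raise ZeroFamiliesError(
            "clustering found no family; the dataset may be too small to "
            "build n-gram models — try a smaller n_th or more sequences"
        )
    L_score = params.L if params.L is not None else pos.min_length
    max_len = int(pos.lengths().max())
    anchors = [a for a in anchor_lengths if a <= max_len]
    dropped = sorted(set(anchor_lengths) - set(anchors))
    if dropped:
        warnings.warn(f"anchor lengths {dropped} exceed the longest training "
                      "sequence; dropped")
    if not anchors:
        raise ValueError("no usable anchor length for calibration")
    for i, fam in enumerate(families):
        fam.calibration = calibrate(
            fam.model, pos, L_score, anchor_lengths=anchors,
            ensemble_size=detection_ensemble_size,
            rng_seed=params.rng_seed + 1 + i,
            model_id=f"family:{fam.seed_id}",
        )
    x_pos = feature_matrix(families, pos, L_score)
    x_neg = feature_matrix(families, neg, L_score)
    x = np.vstack([x_pos, x_neg])
    y = np.concatenate([np.ones(len(pos), dtype=int),
                        np.zeros(len(neg), dtype=int)])
    base = SVC(kernel="rbf", C=svm_config.C, gamma=svm_config.gamma,
               random_state=params.rng_seed % (2 ** 31))
    if svm_config.grid_search:
        grid = GridSearchCV(
            base, {"C": list(svm_config.grid_C), "gamma": list(svm_config.grid_gamma)},
            cv=svm_config.cv_folds, scoring="accuracy", n_jobs=1)
        grid.fit(x, y)
        base = grid.best_estimator_
    # Platt-style sigmoid mapping of the decision value to a probability
    svm = CalibratedClassifierCV(base, method="sigmoid",
                                 cv=svm_config.cv_folds, ensemble=False)
    svm.fit(x, y)
    meta = {
        "n_pos": len(pos), "n_neg": len(neg),
        "n_families": len(families),
        "n_residual": len(residual),
        "anchor_lengths": anchors,
        "detection_ensemble_size": detection_ensemble_size,
        "rng_seed": params.rng_seed,
    }
    logger.info("trained detector: %d families, %d features", len(families),
                len(families))
    return DetectorModel(families=families, svm=svm, L_score=L_score,
                         params=params, training_meta=meta)


def predict(model: DetectorModel, seqs: SequenceSet,
            threshold: float = 0.5) -> list[tuple[str, str, float]]:
    """Functional alias of :meth:`DetectorModel.predict`."""
    return model.predict(seqs, threshold=threshold)
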