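"""Z-score calibration of n-gram similarity scores.

Raw similarities S(b) depend strongly on sequence length and on the
model's training composition, so they are standardized against a null
ensemble of shuffled sequences:

    Z(b) = (S(b) - mu) / sigma,

where mu and sigma are the mean and standard deviation of S over the
ensemble.  Two calibration modes are used:

* clustering stage — one ensemble at a single fixed length (the dataset
  minimum), giving scalar mu/sigma;
* detection stage — ensembles at anchor lengths 21, 26, 31, 36 (18,000
  shuffled sequences each by default), with mu(length) and sigma(length)
  interpolated between anchors by epsilon-SVR regression (RBF kernel) and
  clamped to the nearest anchor outside the anchor range.

The ensemble is built by drawing random same-length windows of the
source sequences and applying a mononucleotide shuffle, so n-gram
structure is destroyed while base composition is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVR

from .ngm import NGramModel
from .sequence_io import NucleotideSequence, SequenceSet, decode


DEFAULT_ANCHOR_LENGTHS = (21, 26, 31, 36)
DEFAULT_ENSEMBLE_SIZE = 18_000


class AnchorRegressor:
    """Smooth interpolator through (length, value) anchor points.

    Fits an epsilon-SVR with RBF kernel on standardized inputs and
    targets.  C defaults to 100 so the four anchor points are
    near-interpolated (small C shrinks predictions toward the target
    mean, which would defeat the calibration).  Outside the anchor range
    the prediction is clamped to the nearest anchor's.
    """

    def __init__(self, lengths: Sequence[int], values: Sequence[float],
                 C: float = 100.0, epsilon: float = 0.01,
                 gamma: str | float = "scale") -> None:
        order = np.argsort(lengths)
        self.lengths = np.asarray(lengths, dtype=float)[order]
        self.values = np.asarray(values, dtype=float)[order]
        self.lo = float(self.lengths[0])
        self.hi = float(self.lengths[-1])
        self._y_mean = float(self.values.mean())
        self._y_std = float(self.values.std())
        self._x_mean = float(self.lengths.mean())
        self._x_std = float(self.lengths.std()) or 1.0
        if self.lengths.size < 2 or self._y_std < 1e-12:
            self._svr = None  # constant function
        else:
            x = (self.lengths[:, None] - self._x_mean) / self._x_std
            y = (self.values - self._y_mean) / self._y_std
            self._svr = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma=gamma)
            self._svr.fit(x, y)

    def __call__(self, length: float | np.ndarray) -> float | np.ndarray:
        arr = np.atleast_1d(np.asarray(length, dtype=float))
        arr = np.clip(arr, self.lo, self.hi)
        if self._svr is None:
            out = np.full(arr.shape, self._y_mean)
        else:
            x = (arr[:, None] - self._x_mean) / self._x_std
            out = self._svr.predict(x) * self._y_std + self._y_mean
        return float(out[0]) if np.isscalar(length) or np.ndim(length) == 0 else out


@dataclass
class ZCalibration:
    """Length-dependent null statistics of S for one n-gram model."""

    model_id: str
    anchor_lengths: list[int]
    mu_at: dict[int, float]
    sigma_at: dict[int, float]
    ensemble_size: int
    rng_seed: int
    L_score: int
    regression: dict = field(default_factory=lambda: {"C": 100.0, "epsilon": 0.01})
    _mu_reg: AnchorRegressor = field(init=False, repr=False, compare=False)
    _sigma_reg: AnchorRegressor = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        anchors = list(self.anchor_lengths)
        mu = [self.mu_at[a] for a in anchors]
        sigma = [self.sigma_at[a] for a in anchors]
        self._mu_reg = AnchorRegressor(anchors, mu, **self.regression)
        self._sigma_reg = AnchorRegressor(anchors, sigma, **self.regression)

    def mu_predict(self, length: float | np.ndarray):
        return self._mu_reg(length)

    def sigma_predict(self, length: float | np.ndarray):
        return self._sigma_reg(length)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "anchor_lengths": list(self.anchor_lengths),
            "mu_at": {str(k): v for k, v in self.mu_at.items()},
            "sigma_at": {str(k): v for k, v in self.sigma_at.items()},
            "ensemble_size": self.ensemble_size,
            "rng_seed": self.rng_seed,
            "L_score": self.L_score,
            "regression": self.regression,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ZCalibration":
        # The regressors are refitted from the stored anchors; the fit is
        # deterministic, so predictions round-trip exactly.
        return cls(
            model_id=doc["model_id"],
            anchor_lengths=list(doc["anchor_lengths"]),
            mu_at={int(k): v for k, v in doc["mu_at"].items()},
            sigma_at={int(k): v for k, v in doc["sigma_at"].items()},
            ensemble_size=doc["ensemble_size"],
            rng_seed=doc["rng_seed"],
            L_score=doc["L_score"],
            regression=doc.get("regression", {"C": 100.0, "epsilon": 0.01}),
        )


def build_ensemble_matrix(source: SequenceSet, length: int, size: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Encoded (size, length) matrix of shuffled source windows."""
    if size < 2:
        raise ValueError("ensemble size must be >= 2")
    if len(source) == 0:
        raise ValueError("ensemble source is empty")
    eligible = [rec for rec in source if rec.length >= length]
    if not eligible:
        raise ValueError(
            f"no source sequence of length >= {length} to build the ensemble"
        )
    codes = [rec.encoded() for rec in eligible]
    out = np.empty((size, length), dtype=np.int64)
    for row in range(size):
        src = codes[int(rng.integers(0, len(codes)))]
        start = int(rng.integers(0, src.size - length + 1))
        out[row] = rng.permutation(src[start:start + length])
    return out


def build_ensemble(source: SequenceSet, length: int, size: int,
                   rng_seed: int | np.random.Generator) -> SequenceSet:
    """Shuffled-window null ensemble as a :class:`SequenceSet`.

    Each member is a random length-``length`` window of a random source
    sequence (uniform over the sequences long enough), mononucleotide-
    shuffled; fully reproducible from ``rng_seed``.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    mat = build_ensemble_matrix(source, length, size, rng)
    return SequenceSet(
        NucleotideSequence(f"shuf{i:05d}", decode(mat[i])) for i in range(mat.shape[0])
    )


def calibrate(model: NGramModel, source: SequenceSet, L_score: int,
              anchor_lengths: Sequence[int] = DEFAULT_ANCHOR_LENGTHS,
              ensemble_size: int = DEFAULT_ENSEMBLE_SIZE,
              rng_seed: int = 0, model_id: str = "model",
              regression: dict | None = None) -> ZCalibration:
    """Estimate mu/sigma at each anchor length and fit the regressions.

    Each anchor's ensemble is scored with ``scan`` windows of
    ``min(L_score, anchor)``.  A near-zero sigma (< 1e-12) indicates a
    degenerate model/ensemble (e.g. the uniform model, whose score is a
    deterministic function of length) and raises a ValueError.
    """
    anchors = sorted(int(a) for a in anchor_lengths)
    if not anchors:
        raise ValueError("need at least one anchor length")
    for a in anchors:
        if a < model.n:
            raise ValueError(f"anchor length {a} < model n={model.n}")
    rng = np.random.default_rng(rng_seed)
    mu_at: dict[int, float] = {}
    sigma_at: dict[int, float] = {}
    for a in anchors:
        mat = build_ensemble_matrix(source, a, ensemble_size, rng)
        scores = model.scan_batch(mat, min(L_score, a))
        mu_at[a] = float(scores.mean())
        sigma = float(scores.std(ddof=1))
        if sigma < 1e-12:
            raise ValueError(
                f"degenerate null at length {a}: sigma={sigma:g} "
                "(the model gives the same score to every shuffled sequence)"
            )
        sigma_at[a] = sigma
    return ZCalibration(
        model_id=model_id,
        anchor_lengths=anchors,
        mu_at=mu_at,
        sigma_at=sigma_at,
        ensemble_size=int(ensemble_size),
        rng_seed=int(rng_seed),
        L_score=int(L_score),
        regression=regression or {"C": 100.0, "epsilon": 0.01},
    )


def zscore(calibration: ZCalibration, model: NGramModel,
           seq: NucleotideSequence, L_score: int) -> float:
    """Z(b) = (S(b) - mu(len)) / sigma(len) for a single sequence."""
    if seq.length < L_score:
        raise ValueError(
            f"sequence {seq.id!r} shorter ({seq.length}) than window {L_score}"
        )
    s = model.scan(seq, L_score).value
    sigma = calibration.sigma_predict(seq.length)
    if sigma <= 0:
        raise ValueError(f"non-positive predicted sigma at length {seq.length}")
    return (s - calibration.mu_predict(seq.length)) / sigma


def zscores(calibration: ZCalibration, model: NGramModel,
            seqs: SequenceSet, L_score: int) -> np.ndarray:
    """Vectorized :func:`zscore` over a set; windows are capped per sequence."""
    lengths = seqs.lengths()
    out = np.empty(len(seqs))
    by_length: dict[int, list[int]] = {}
    for pos, rec in enumerate(seqs):
        by_length.setdefault(rec.length, []).append(pos)
    for length, positions in by_length.items():
        mat = np.stack([seqs[p].encoded() for p in positions])
        s = model.scan_batch(mat, min(L_score, length))
        mu = calibration.mu_predict(float(length))
        sigma = calibration.sigma_predict(float(length))
        if sigma <= 0:
            raise ValueError(f"non-positive predicted sigma at length {length}")
        out[positions] = (s - mu) / sigma
    assert lengths.size == out.size
    return out
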