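"""n-gram Markov models (NGMs) over the DNA alphabet.

An n-gram model is an (n-1)th-order Markov chain: the probability of each
base depends on the preceding n-1 bases.  A model is summarized by

* ``state_prob`` — the marginal probability of every (n-1)-gram, and
* ``trans_prob`` — the probability of each base given its (n-1)-gram
  context,

both estimated from windowed counts over the training sequences with an
additive pseudo-count ``alpha`` that keeps every probability strictly
positive (mutation tolerance).

The homology score of a length-``L`` window starting at offset ``k`` of a
sequence ``b`` is the log-likelihood

    R(b, k) = log P(g_k) + sum_{i=k+n-1}^{k+L-1} log P(b_i | context_i)

(natural logarithm; 0-based offsets; ``g_k`` is the (n-1)-gram starting at
``k``), and the sequence-level similarity ``S(b)`` is the maximum of
``R(b, k)`` over all offsets.  The scan is computed with a constant-work-
per-shift prefix-sum update and agrees with per-window recomputation to
floating-point accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .sequence_io import NucleotideSequence, SequenceSet, encode

__all__ = [
    "NGramModel",
    "SimilarityScore",
    "fit_ngm",
    "uniform_model",
    "loglik_window",
    "scan_max_similarity",
]


def gram_indices(codes: np.ndarray, m: int) -> np.ndarray:
    """Base-4 indices of every length-``m`` gram of an encoded sequence.

    Returns an array of length ``len(codes) - m + 1`` (empty if the
    sequence is shorter than ``m``); works on a 2-D batch along axis 1.
    """
    length = codes.shape[-1]
    if length < m:
        shape = codes.shape[:-1] + (0,)
        return np.empty(shape, dtype=np.int64)
    out = np.zeros(codes.shape[:-1] + (length - m + 1,), dtype=np.int64)
    for j in range(m):  # Horner evaluation of the base-4 digits
        out = out * 4 + codes[..., j:length - m + 1 + j]
    return out


@dataclass(frozen=True)
class SimilarityScore:
    """Maximum windowed log-likelihood and where it was achieved."""

    value: float
    offset: int
    window_length: int


class NGramModel:
    """An (n-1)th-order Markov chain over {A, C, G, T} with pseudo-counts.

    Attributes
    ----------
    n : int
        Gram size (n >= 2); the default throughout the package is the
        tetragram, n = 4.
    pseudo_count : float
        Additive smoothing constant alpha > 0.
    state_prob : ndarray, shape (4**(n-1),)
        Marginal (n-1)-gram probabilities; sums to 1.
    trans_prob : ndarray, shape (4**(n-1), 4)
        Conditional base probabilities per context; each row sums to 1.
    trained_on : int
        Number of training sequences behind the counts (0 for the
        uniform model).
    """

    def __init__(self, n: int, pseudo_count: float, state_prob: np.ndarray,
                 trans_prob: np.ndarray, trained_on: int = 0) -> None:
        if n < 2:
            raise ValueError(f"gram size n must be >= 2, got {n}")
        if pseudo_count <= 0:
            raise ValueError("pseudo_count must be positive")
        m = n - 1
        state_prob = np.asarray(state_prob, dtype=np.float64)
        trans_prob = np.asarray(trans_prob, dtype=np.float64)
        if state_prob.shape != (4 ** m,):
            raise ValueError(f"state_prob must have shape ({4 ** m},)")
        if trans_prob.shape != (4 ** m, 4):
            raise ValueError(f"trans_prob must have shape ({4 ** m}, 4)")
        self.n = int(n)
        self.pseudo_count = float(pseudo_count)
        self.state_prob = state_prob
        self.trans_prob = trans_prob
        self.trained_on = int(trained_on)
        self._state_logp = np.log(state_prob)
        self._trans_logp = np.log(trans_prob)

    # ------------------------------------------------------------------ fit

    @classmethod
    def fit(cls, training: SequenceSet | Iterable[NucleotideSequence],
            n: int = 4, pseudo_count: float = 1.0) -> "NGramModel":
        """Estimate the model from training sequences.

        State probabilities count every (n-1)-gram window of every
        sequence; transition probabilities count every n-gram.  Both get
        ``pseudo_count`` added per cell and are normalized.
        """
        records = list(training)
        if not records:
            raise ValueError("cannot fit an n-gram model on an empty training set")
        if n < 2:
            raise ValueError(f"gram size n must be >= 2, got {n}")
        m = n - 1
        for rec in records:
            if rec.length < n:
                raise ValueError(
                    f"training sequence {rec.id!r} is shorter than n={n}"
                )
        state_counts = np.zeros(4 ** m, dtype=np.int64)
        ngram_counts = np.zeros(4 ** m * 4, dtype=np.int64)
        for rec in records:
            codes = rec.encoded()
            grams = gram_indices(codes, m)
            state_counts += np.bincount(grams, minlength=4 ** m)
            full = grams[:-1] * 4 + codes[m:]
            ngram_counts += np.bincount(full, minlength=4 ** m * 4)
        alpha = float(pseudo_count)
        state_prob = (state_counts + alpha) / (state_counts.sum() + alpha * 4 ** m)
        ngram_counts = ngram_counts.reshape(4 ** m, 4)
        context_counts = ngram_counts.sum(axis=1)
        trans_prob = (ngram_counts + alpha) / (context_counts + 4 * alpha)[:, None]
        return cls(n, alpha, state_prob, trans_prob, trained_on=len(records))

    @classmethod
    def uniform(cls, n: int = 4, pseudo_count: float = 1.0) -> "NGramModel":
        """The pure pseudo-count model: uniform states and transitions."""
        m = n - 1
        state_prob = np.full(4 ** m, 1.0 / 4 ** m)
        trans_prob = np.full((4 ** m, 4), 0.25)
        return cls(n, pseudo_count, state_prob, trans_prob, trained_on=0)

    # ---------------------------------------------------------------- score

    def loglik_window(self, seq: NucleotideSequence | np.ndarray,
                      k: int, L: int) -> float:
        """Log-likelihood R(b, k) of the length-``L`` window at offset ``k``.

        Plain term-by-term summation; :meth:`scan` is the fast path.
        """
        codes = seq if isinstance(seq, np.ndarray) else seq.encoded()
        m = self.n - 1
        if L < self.n:
            raise ValueError(f"window length {L} < n={self.n}")
        if k < 0 or k + L > codes.shape[0]:
            raise ValueError(
                f"window [{k}, {k + L}) out of bounds for length {codes.shape[0]}"
            )
        gram = 0
        for j in range(m):
            gram = gram * 4 + int(codes[k + j])
        total = float(self._state_logp[gram])
        for i in range(k + m, k + L):
            ctx = 0
            for j in range(i - m, i):
                ctx = ctx * 4 + int(codes[j])
            total += float(self._trans_logp[ctx, int(codes[i])])
        return total

    def window_scores(self, codes: np.ndarray, L: int) -> np.ndarray:
        """R(b, k) for every offset k, via the incremental prefix-sum scan.

        ``codes`` may be 1-D (one sequence) or 2-D (a batch of equal-length
        sequences); scores are returned along the last axis.
        """
        m = self.n - 1
        length = codes.shape[-1]
        if L < self.n:
            raise ValueError(f"window length {L} < n={self.n}")
        if length < L:
            raise ValueError(f"sequence length {length} < window length {L}")
        grams = gram_indices(codes, m)
        state = self._state_logp[grams]
        trans = self._trans_logp[grams[..., :-1], codes[..., m:]]
        zero = np.zeros(codes.shape[:-1] + (1,))
        prefix = np.concatenate([zero, np.cumsum(trans, axis=-1)], axis=-1)
        n_windows = length - L + 1
        return (state[..., :n_windows]
                + prefix[..., L - m:L - m + n_windows]
                - prefix[..., :n_windows])

    def scan(self, seq: NucleotideSequence | np.ndarray, L: int) -> SimilarityScore:
        """Similarity S(b): the best length-``L`` window (ties: smallest offset)."""
        codes = seq if isinstance(seq, np.ndarray) else seq.encoded()
        scores = self.window_scores(codes, L)
        offset = int(np.argmax(scores))
        return SimilarityScore(value=float(scores[offset]), offset=offset,
                               window_length=L)

    def scan_batch(self, codes: np.ndarray, L: int) -> np.ndarray:
        """S(b) for a 2-D batch of equal-length encoded sequences."""
        return self.window_scores(codes, L).max(axis=-1)

    # ------------------------------------------------------------ serialize

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pseudo_count": self.pseudo_count,
            "trained_on": self.trained_on,
            "state_prob": self.state_prob.tolist(),
            "trans_prob": self.trans_prob.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "NGramModel":
        return cls(doc["n"], doc["pseudo_count"], np.array(doc["state_prob"]),
                   np.array(doc["trans_prob"]), trained_on=doc.get("trained_on", 0))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "NGramModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def __repr__(self) -> str:  # pragma: no cover
        return (f"NGramModel(n={self.n}, alpha={self.pseudo_count}, "
                f"trained_on={self.trained_on})")


# Functional aliases for the class methods above.

def fit_ngm(training: SequenceSet, n: int = 4, pseudo_count: float = 1.0) -> NGramModel:
    return NGramModel.fit(training, n=n, pseudo_count=pseudo_count)


def uniform_model(n: int = 4, pseudo_count: float = 1.0) -> NGramModel:
    return NGramModel.uniform(n=n, pseudo_count=pseudo_count)


def loglik_window(model: NGramModel, seq: NucleotideSequence, k: int, L: int) -> float:
    return model.loglik_window(seq, k, L)


def scan_max_similarity(model: NGramModel, seq: NucleotideSequence,
                        L: int) -> SimilarityScore:
    return model.scan(seq, L)


def scan_scores(model: NGramModel, seqs: SequenceSet, L_score: int) -> np.ndarray:
    """S(b) for every sequence of a (possibly mixed-length) set.

    The window length used for each sequence is ``min(L_score, length)``;
    sequences are grouped by length so each group is scanned as one batch.
    Returns scores aligned with the input order.
    """
    out = np.empty(len(seqs))
    by_length: dict[int, list[int]] = {}
    for pos, rec in enumerate(seqs):
        by_length.setdefault(rec.length, []).append(pos)
    for length, positions in by_length.items():
        mat = np.stack([seqs[p].encoded() for p in positions])
        L_eff = min(L_score, length)
        out[positions] = model.scan_batch(mat, L_eff)
    return out
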