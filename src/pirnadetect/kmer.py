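"""K-mer count baseline: 1,364 features (all 1-mers through 5-mers).

The decision rule scores a sequence by the length-normalized log-odds of
its k-mer counts under class-conditional frequency tables estimated from
the positive/negative training sets, thresholded at a cutoff ``t``
(default 1.2).  The published scheme this emulates defines only the
interface (k-mer frequencies + a cutoff); the log-odds form here is this
package's stand-in for its unpublished internals.  An SVM back-end on
the raw 1,364-dimensional count vectors is available for an
apples-to-apples feature comparison with the NGM detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .ngm import gram_indices
from .sequence_io import NucleotideSequence, SequenceSet

MAX_K = 5
#: offsets[k-1] is where the length-k block starts in the feature vector
OFFSETS = np.concatenate([[0], np.cumsum([4 ** k for k in range(1, MAX_K + 1)])])
NUM_FEATURES = int(OFFSETS[-1])  # 4 + 16 + 64 + 256 + 1024 = 1364


@dataclass(frozen=True)
class KmerFeatureVector:
    sequence_id: str
    counts: np.ndarray  # length 1364, k ascending then lexicographic

    def block(self, k: int) -> np.ndarray:
        """Counts of all length-k k-mers."""
        return self.counts[OFFSETS[k - 1]:OFFSETS[k]]


def kmer_counts(seq: NucleotideSequence) -> np.ndarray:
    """Overlapping occurrence counts of every k-mer, k = 1..5."""
    codes = seq.encoded()
    out = np.zeros(NUM_FEATURES, dtype=np.int64)
    for k in range(1, MAX_K + 1):
        grams = gram_indices(codes, k)
        if grams.size:
            out[OFFSETS[k - 1]:OFFSETS[k]] = np.bincount(grams, minlength=4 ** k)
    return out


def kmer_features(seq: NucleotideSequence) -> KmerFeatureVector:
    return KmerFeatureVector(seq.id, kmer_counts(seq))


def count_matrix(seqs: SequenceSet) -> np.ndarray:
    return np.stack([kmer_counts(rec) for rec in seqs])


class KmerLogOdds:
    """Class-conditional k-mer log-odds scorer with additive smoothing."""

    def __init__(self, train_pos: SequenceSet, train_neg: SequenceSet,
                 alpha: float = 1.0) -> None:
        if len(train_pos) == 0 or len(train_neg) == 0:
            raise ValueError("both training classes must be non-empty")
        self.log_odds = np.empty(NUM_FEATURES)
        pos_tot = count_matrix(train_pos).sum(axis=0)
        neg_tot = count_matrix(train_neg).sum(axis=0)
        for k in range(1, MAX_K + 1):
            sl = slice(int(OFFSETS[k - 1]), int(OFFSETS[k]))
            f_pos = (pos_tot[sl] + alpha) / (pos_tot[sl].sum() + alpha * 4 ** k)
            f_neg = (neg_tot[sl] + alpha) / (neg_tot[sl].sum() + alpha * 4 ** k)
            self.log_odds[sl] = np.log(f_pos) - np.log(f_neg)

    def scores(self, seqs: SequenceSet) -> np.ndarray:
        """Per-sequence score: sum(count * log-odds) / length."""
        counts = count_matrix(seqs)
        lengths = seqs.lengths().astype(float)
        return counts @ self.log_odds / lengths


def kmer_classify(train_pos: SequenceSet, train_neg: SequenceSet,
                  test: SequenceSet, cutoff: float = 1.2,
                  backend: str = "logodds", rng_seed: int = 0,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Scores and boolean piRNA calls for the test set.

    backend "logodds": thresholds the log-odds score at ``cutoff``;
    backend "svm": RBF c-SVC on the 1,364 counts, thresholding the
    predicted probability at 0.5 (``cutoff`` is ignored).
    """
    if backend == "logodds":
        scorer = KmerLogOdds(train_pos, train_neg)
        scores = scorer.scores(test)
        return scores, scores >= cutoff
    if backend == "svm":
        x = np.vstack([count_matrix(train_pos), count_matrix(train_neg)])
        y = np.concatenate([np.ones(len(train_pos), dtype=int),
                            np.zeros(len(train_neg), dtype=int)])
        svm = CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=rng_seed % (2 ** 31)),
            method="sigmoid", cv=3, ensemble=False)
        svm.fit(x, y)
        positive_col = int(np.nonzero(svm.classes_ == 1)[0][0])
        scores = svm.predict_proba(count_matrix(test))[:, positive_col]
        return scores, scores >= 0.5
    raise ValueError(f"unknown backend {backend!r}")
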