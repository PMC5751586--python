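"""Shared fixtures: small seeded synthetic datasets and a trained detector."""

import warnings

import numpy as np
import pytest

from pirnadetect.clustering import ClusteringParams
from pirnadetect.evaluation import make_negatives
from pirnadetect.features import train_detector
from pirnadetect.sequence_io import NucleotideSequence, SequenceSet
from pirnadetect.simulate import FixtureSpec, generate_fixture

# sklearn's internal deprecation chatter is irrelevant to the assertions here
warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


@pytest.fixture(scope="session")
def two_family_data():
    """Two planted motif families (150 members each) plus background."""
    spec = FixtureSpec(num_families=2, family_size=150, background_size=300,
                       rng_seed=1)
    pos, background, truth = generate_fixture(spec)
    return pos, background, truth


@pytest.fixture(scope="session")
def small_detector(two_family_data):
    """A detector trained on the small two-family dataset (seeded)."""
    pos, background, _ = two_family_data
    neg = make_negatives(pos, background, rng_seed=2)
    params = ClusteringParams(n_th=80, z_th=1.5, ensemble_size=800, rng_seed=3)
    det = train_detector(pos, neg, params, detection_ensemble_size=1000)
    return det, pos, neg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequences(rng, count, length_range=(26, 36), prefix="s"):
    lo, hi = length_range
    out = []
    for i in range(count):
        length = int(rng.integers(lo, hi + 1))
        bases = "".join("ACGT"[c] for c in rng.integers(0, 4, length))
        out.append(NucleotideSequence(f"{prefix}{i}", bases))
    return SequenceSet(out)


@pytest.fixture
def random_pool(rng):
    return random_sequences(rng, 30)
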