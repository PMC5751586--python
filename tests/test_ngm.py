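"""n-gram model estimation and windowed log-likelihood scoring.

The brute-force oracle here recomputes Eq.-style window scores term by
term straight from the probability tables, independently of the model's
own scoring code paths.
"""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirnadetect.ngm import NGramModel, fit_ngm, uniform_model
from pirnadetect.sequence_io import BASE_ORDER, NucleotideSequence, SequenceSet


def seq(bases, sid="s"):
    return NucleotideSequence(sid, bases)


def gram_index(bases: str) -> int:
    idx = 0
    for c in bases:
        idx = idx * 4 + BASE_ORDER.index(c)
    return idx


def bruteforce_window(model, bases, k, L):
    """Independent term-by-term resummation from the probability tables."""
    m = model.n - 1
    total = math.log(model.state_prob[gram_index(bases[k:k + m])])
    for i in range(k + m, k + L):
        ctx = gram_index(bases[i - m:i])
        total += math.log(model.trans_prob[ctx, BASE_ORDER.index(bases[i])])
    return total


def random_model(rng, n=4):
    m = n - 1
    state = rng.dirichlet(np.ones(4 ** m))
    trans = rng.dirichlet(np.ones(4), size=4 ** m)
    return NGramModel(n, 1.0, state, trans)


def random_bases(rng, length):
    return "".join(BASE_ORDER[c] for c in rng.integers(0, 4, length))


class TestFit:
    def test_uniform_model_is_pure_pseudocounts(self):
        model = uniform_model(4)
        assert np.allclose(model.state_prob, 1 / 64)
        assert np.allclose(model.trans_prob, 1 / 4)

    def test_homopolymer_counts(self):
        # 10 A's: seven AAAA n-grams -> trans(AAA->A) = (7+1)/(7+4)
        model = fit_ngm(SequenceSet([seq("A" * 10)]), n=4, pseudo_count=1.0)
        assert model.trans_prob[gram_index("AAA"), 0] == pytest.approx(8 / 11)
        # eight AAA windows among 64 trigram cells
        assert model.state_prob[gram_index("AAA")] == pytest.approx(9 / 72)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit_ngm(SequenceSet([]), n=4)

    def test_short_sequence_rejected_by_name(self):
        with pytest.raises(ValueError, match="tiny"):
            fit_ngm(SequenceSet([seq("ACGTACGT"), seq("ACG", "tiny")]), n=4)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 12))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_normalization_invariants(self, seed, count):
        """State probs sum to 1 and every context's transitions sum to 1."""
        rng = np.random.default_rng(seed)
        training = SequenceSet(
            seq(random_bases(rng, int(rng.integers(8, 40))), f"t{i}")
            for i in range(count))
        model = fit_ngm(training, n=4, pseudo_count=0.5)
        assert model.state_prob.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(model.trans_prob.sum(axis=1), 1.0, atol=1e-9)
        assert (model.state_prob > 0).all() and (model.trans_prob > 0).all()


class TestLoglikWindow:
    def test_uniform_model_closed_form(self):
        model = uniform_model(4)
        rng = np.random.default_rng(0)
        value = model.loglik_window(seq(random_bases(rng, 20)), 0, 10)
        assert value == pytest.approx(-20 * math.log(2), abs=1e-9)

    def test_degenerate_certain_model_scores_zero(self):
        # all probabilities along the scored path equal to 1 -> log terms vanish
        eps = 1e-300
        state = np.full(64, eps)
        state[gram_index("AAA")] = 1 - 63 * eps
        trans = np.full((64, 4), 1 / 4.0)
        trans[gram_index("AAA")] = [1 - 3 * eps, eps, eps, eps]
        model = NGramModel(4, 1.0, state, trans)
        assert model.loglik_window(seq("A" * 10), 0, 10) == pytest.approx(0, abs=1e-9)

    def test_fit_and_score_matches_bruteforce(self):
        model = fit_ngm(SequenceSet([seq("A" * 10)]), n=4)
        got = model.loglik_window(seq("A" * 10), 0, 10)
        assert got == pytest.approx(bruteforce_window(model, "A" * 10, 0, 10),
                                    abs=1e-9)

    def test_window_bounds_checked(self):
        model = uniform_model(4)
        s = seq("ACGTACGTACGT")
        with pytest.raises(ValueError):
            model.loglik_window(s, 5, 10)
        with pytest.raises(ValueError):
            model.loglik_window(s, 0, 3)


class TestScan:
    def test_single_window_equals_loglik(self, rng):
        model = random_model(rng)
        bases = random_bases(rng, 26)
        res = model.scan(seq(bases), 26)
        assert res.offset == 0
        assert res.value == pytest.approx(model.loglik_window(seq(bases), 0, 26))

    def test_scan_dominates_every_offset(self, rng):
        model = random_model(rng)
        bases = random_bases(rng, 40)
        best = model.scan(seq(bases), 20)
        for k in range(0, 21):
            assert best.value >= model.loglik_window(seq(bases), k, 20) - 1e-9

    def test_incremental_equals_bruteforce_recomputation(self, rng):
        """Prefix-sum scan equals per-window term-by-term resummation."""
        for _ in range(50):
            model = random_model(rng)
            bases = random_bases(rng, 50)
            got = model.scan(seq(bases), 26)
            expected = max(
                (bruteforce_window(model, bases, k, 26), -k)
                for k in range(0, 50 - 26 + 1))
            assert got.value == pytest.approx(expected[0], abs=1e-9)
            assert got.offset == -expected[1]

    def test_extension_never_decreases_max(self, rng):
        """Adding windows (sequence extension) can only raise the maximum."""
        model = random_model(rng)
        bases = random_bases(rng, 30)
        base_val = model.scan(seq(bases), 26).value
        extended = random_bases(rng, 5) + bases + random_bases(rng, 5)
        assert model.scan(seq(extended), 26).value >= base_val - 1e-12

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            uniform_model(4).scan(seq("ACGTACGT"), 10)


class TestSerialization:
    def test_round_trip_exact(self, tmp_path, rng):
        model = fit_ngm(
            SequenceSet(seq(random_bases(rng, 30), f"t{i}") for i in range(5)),
            n=4, pseudo_count=0.7)
        path = tmp_path / "model.json"
        model.save(path)
        back = NGramModel.load(path)
        assert back.n == model.n
        assert back.pseudo_count == model.pseudo_count
        assert (back.state_prob == model.state_prob).all()
        assert (back.trans_prob == model.trans_prob).all()
        # the document is self-describing JSON
        doc = json.loads(path.read_text())
        assert set(doc) >= {"n", "pseudo_count", "state_prob", "trans_prob"}
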