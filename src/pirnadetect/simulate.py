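"""Synthetic motif-family fixtures with ground-truth labels.

The generator emulates the structure the detector assumes: families of
short RNA-like sequences (26-36 nt, the piRNA size range) that share a
degenerate motif — a fixed template embedded at a random offset with
independent per-base substitutions — plus a background pool of unrelated
sequences drawn i.i.d. from a base-composition model.  Embedding (rather
than whole-sequence homology) makes the max-over-windows scan do real
work.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_io import NucleotideSequence, SequenceSet, decode


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset draw.

    Defaults describe the standard test condition: two families of 300
    members each, a 12-nt motif mutated at 10% per base, sequence lengths
    uniform on [26, 36], and a uniform-composition background.
    """

    num_families: int = 2
    family_size: int = 300
    motif_length: int = 12
    length_range: tuple[int, int] = (26, 36)
    mutation_rate: float = 0.10
    background_size: int = 300
    background_composition: tuple[float, float, float, float] = (0.25,) * 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad length range {self.length_range}")
        if self.motif_length > lo:
            raise ValueError(
                f"motif_length {self.motif_length} exceeds minimum sequence length {lo}"
            )
        if not (0.0 <= self.mutation_rate <= 0.5):
            raise ValueError("mutation_rate must lie in [0, 0.5]")
        if min(self.num_families, self.family_size, self.background_size) < 0:
            raise ValueError("sizes must be non-negative")
        comp = np.asarray(self.background_composition, dtype=float)
        if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
            raise ValueError("background_composition must be 4 probabilities summing to 1")


def _mutate(motif: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``rate`` by a different base."""
    out = motif.copy()
    hits = np.nonzero(rng.random(motif.size) < rate)[0]
    for i in hits:
        out[i] = (out[i] + rng.integers(1, 4)) % 4
    return out


def generate_fixture(spec: FixtureSpec) -> tuple[SequenceSet, SequenceSet, dict[str, str]]:
    """Draw one labeled dataset.

    Returns
    -------
    positives : SequenceSet
        All family members, ids ``fam<f>_m<i>``.
    background : SequenceSet
        Unrelated sequences, ids ``bg<i>``.
    truth : dict
        id -> family label (``"fam<f>"``) or ``"background"``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    comp = np.asarray(spec.background_composition, dtype=float)
    lo, hi = spec.length_range
    positives: list[NucleotideSequence] = []
    truth: dict[str, str] = {}
    for f in range(spec.num_families):
        motif = rng.integers(0, 4, size=spec.motif_length)
        for i in range(spec.family_size):
            length = int(rng.integers(lo, hi + 1))
            flank = rng.choice(4, size=length, p=comp)
            offset = int(rng.integers(0, length - spec.motif_length + 1))
            seq = flank.copy()
            seq[offset:offset + spec.motif_length] = _mutate(
                motif, spec.mutation_rate, rng)
            seq_id = f"fam{f}_m{i}"
            positives.append(NucleotideSequence(seq_id, decode(seq)))
            truth[seq_id] = f"fam{f}"
    background: list[NucleotideSequence] = []
    for i in range(spec.background_size):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(4, size=length, p=comp)
        seq_id = f"bg{i}"
        background.append(NucleotideSequence(seq_id, decode(seq)))
        truth[seq_id] = "background"
    return SequenceSet(positives), SequenceSet(background), truth


def write_truth(truth: dict[str, str], path: str | Path) -> None:
    """Ground-truth map as a two-column TSV (id, label)."""
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for seq_id, label in truth.items():
            fh.write(f"{seq_id}\t{label}\n")


def read_truth(path: str | Path) -> dict[str, str]:
    truth: dict[str, str] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            seq_id, label = line.rstrip("\n").split("\t")
            truth[seq_id] = label
    return truth
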