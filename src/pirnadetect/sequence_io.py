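"""Reading, writing and validation of nucleotide sequences.

Everything downstream assumes a canonical DNA alphabet: sequences are
strings over ``{A, C, G, T}``, with ``U`` mapped to ``T`` on input (piRNA
databases mix RNA and DNA conventions).  A :class:`SequenceSet` is an
ordered collection with unique identifiers; its minimum sequence length
supplies the scan-window length ``L`` used throughout the scoring stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical base order; index arithmetic everywhere assumes A=0, C=1, G=2, T=3.
BASE_ORDER = "ACGT"

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASE_ORDER):
    _CODE[ord(_b)] = _i

ALPHABET_POLICIES = ("strict", "map-u", "drop-ambiguous")

LABEL_POSITIVE = "piRNA"
LABEL_NEGATIVE = "non-piRNA"


def encode(bases: str) -> np.ndarray:
    """Encode an A/C/G/T string as an int array (A=0, C=1, G=2, T=3)."""
    raw = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if codes.size and codes.min() < 0:
        bad = bases[int(np.argmax(codes < 0))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes.astype(np.int64)


def decode(codes: Sequence[int]) -> str:
    """Inverse of :func:`encode`."""
    return "".join(BASE_ORDER[int(c)] for c in codes)


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over the canonical alphabet.

    Parameters
    ----------
    id : str
        Unique identifier (FASTA header up to the first whitespace).
    bases : str
        Uppercase string over ``{A, C, G, T}``; ``U`` must already have
        been mapped to ``T``.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        encode(self.bases)  # validates the alphabet

    @property
    def length(self) -> int:
        return len(self.bases)

    def encoded(self) -> np.ndarray:
        return encode(self.bases)


class SequenceSet:
    """Ordered collection of :class:`NucleotideSequence` with unique ids."""

    def __init__(self, records: Iterable[NucleotideSequence]) -> None:
        self.records: list[NucleotideSequence] = list(records)
        self._index: dict[str, int] = {}
        for pos, rec in enumerate(self.records):
            if rec.id in self._index:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            self._index[rec.id] = pos

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[NucleotideSequence]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> NucleotideSequence:
        if isinstance(key, str):
            return self.records[self._index[key]]
        return self.records[key]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def lengths(self) -> np.ndarray:
        return np.array([r.length for r in self.records], dtype=np.int64)

    @property
    def min_length(self) -> int:
        """Minimum sequence length in the set (undefined when empty)."""
        if not self.records:
            raise ValueError("min_length is undefined for an empty SequenceSet")
        return int(self.lengths().min())

    def subset(self, ids: Iterable[str]) -> "SequenceSet":
        """Records with the given ids, in this set's order."""
        wanted = set(ids)
        return SequenceSet(r for r in self.records if r.id in wanted)

    def without(self, ids: Iterable[str]) -> "SequenceSet":
        dropped = set(ids)
        return SequenceSet(r for r in self.records if r.id not in dropped)


def _normalize(record_id: str, raw: str, policy: str) -> str | None:
    """Apply the alphabet policy; return normalized bases or None to drop."""
    bases = raw.upper().replace("U", "T")
    ok = all(c in BASE_ORDER for c in bases)
    if ok:
        return bases
    if policy == "drop-ambiguous":
        return None
    bad = next(c for c in bases if c not in BASE_ORDER)
    raise ValueError(
        f"record {record_id!r} contains non-ACGTU character {bad!r} "
        f"(alphabet policy {policy!r})"
    )


def read_fasta(path: str | Path, alphabet_policy: str = "drop-ambiguous") -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Parameters
    ----------
    path : path-like
        FASTA file; wrapped lines are fine, descriptions after the first
        whitespace are ignored for identity.
    alphabet_policy : {"strict", "map-u", "drop-ambiguous"}
        ``U`` is always mapped to ``T``.  Under ``drop-ambiguous`` (the
        default) records containing any other non-ACGT character are
        dropped with a logged count; the other two policies raise a
        :class:`ValueError` naming the offending record.
    """
    if alphabet_policy not in ALPHABET_POLICIES:
        raise ValueError(f"unknown alphabet policy {alphabet_policy!r}")
    path = Path(path)
    records: list[NucleotideSequence] = []
    dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        bases = _normalize(rec.id, str(rec.seq), alphabet_policy)
        if bases is None:
            dropped += 1
            continue
        records.append(NucleotideSequence(id=rec.id, bases=bases))
    if dropped:
        logger.warning("read_fasta(%s): dropped %d ambiguous record(s)", path, dropped)
    if not records and not dropped:
        logger.warning("read_fasta(%s): no records found", path)
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet | Iterable[NucleotideSequence], path: str | Path,
                width: int = 70) -> None:
    """Write sequences as FASTA (fixed line width)."""
    with open(path, "w") as fh:
        for rec in seqs:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i:i + width] + "\n")


def write_predictions(records: Iterable[tuple[str, str, float]],
                      path: str | Path) -> None:
    """Write (id, label, confidence) triples as a headered TSV.

    Labels are ``piRNA`` / ``non-piRNA``; confidences must lie in [0, 1]
    and are printed with 6 decimal digits.
    """
    rows = list(records)
    for seq_id, label, conf in rows:
        if not (0.0 <= conf <= 1.0):
            raise ValueError(f"confidence for {seq_id!r} outside [0, 1]: {conf}")
        if label not in (LABEL_POSITIVE, LABEL_NEGATIVE):
            raise ValueError(f"unknown label {label!r} for {seq_id!r}")
    with open(path, "w") as fh:
        fh.write("id\tlabel\tconfidence\n")
        for seq_id, label, conf in rows:
            fh.write(f"{seq_id}\t{label}\t{conf:.6f}\n")


def read_predictions(path: str | Path) -> list[tuple[str, str, float]]:
    """Parse a predictions TSV back into (id, label, confidence) triples."""
    out: list[tuple[str, str, float]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError(f"{path}: not a predictions TSV")
        for line in fh:
            seq_id, label, conf = line.rstrip("\n").split("\t")
            out.append((seq_id, label, float(conf)))
    return out
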