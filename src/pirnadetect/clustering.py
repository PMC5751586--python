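"""Seed-and-collect clustering of sequences into motif-sharing families.

The loop: pick the sequence containing the globally most frequent
(n-1)-gram as a seed, fit an n-gram model on the seed alone, standardize
every pool sequence's similarity against a shuffled-pool null, and
collect all sequences with Z >= Z_th.  If at least N_th sequences are
collected, they form a family — the model is refitted on all members and
its calibration rebuilt — and are removed from the pool; otherwise the
seed is retired (it can still join a later family) and the next seed is
tried.  The loop ends when every remaining sequence has been tried as a
seed.

The window length L is fixed once, from the minimum sequence length of
the full dataset, so all families score on one scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .calibration import ZCalibration, build_ensemble_matrix, zscores
from .ngm import NGramModel, gram_indices
from .sequence_io import SequenceSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusteringParams:
    """Tunables of the clustering stage.

    ``n_th=200`` and ``z_th=1.5`` are the standard operating point
    balancing accuracy against the number of models built; the tetragram
    (n=4) is the standard gram size for piRNA-scale sequences.
    """

    n: int = 4
    z_th: float = 1.5
    n_th: int = 200
    pseudo_count: float = 1.0
    L: int | None = None  # scan window; resolved to the dataset minimum length
    ensemble_size: int = 2000
    rng_seed: int = 0
    #: "pool-max-gram": seed contains the pool-wide most frequent (n-1)-gram;
    #: "self-total": seed with the largest summed pool-frequency of its own grams.
    seed_criterion: str = "pool-max-gram"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.n_th < 1:
            raise ValueError("n_th must be >= 1")
        if self.seed_criterion not in ("pool-max-gram", "self-total"):
            raise ValueError(f"unknown seed criterion {self.seed_criterion!r}")


@dataclass
class SequenceFamily:
    """A collected homologous family with its refitted model."""

    family_id: int
    seed_id: str
    member_ids: list[str]
    model: NGramModel
    calibration: ZCalibration

    def __len__(self) -> int:
        return len(self.member_ids)


def pick_seed(pool: SequenceSet, n: int, criterion: str = "pool-max-gram",
              eligible: Iterable[str] | None = None) -> str:
    """Choose the seed sequence by (n-1)-gram frequency.

    Under the default criterion the pool-wide occurrence count of every
    (n-1)-gram is tallied and each sequence is scored by the largest
    count among the grams it contains; ties go to the sequence with more
    own occurrences of that gram, then to input order.  ``eligible``
    restricts the candidates (used to skip retired seeds) while counts
    are still taken over the whole pool.
    """
    if len(pool) == 0:
        raise ValueError("cannot pick a seed from an empty pool")
    m = n - 1
    for rec in pool:
        if rec.length < m:
            raise ValueError(f"sequence {rec.id!r} shorter than n-1={m}")
    per_seq_grams = {rec.id: gram_indices(rec.encoded(), m) for rec in pool}
    totals = np.zeros(4 ** m, dtype=np.int64)
    for grams in per_seq_grams.values():
        totals += np.bincount(grams, minlength=4 ** m)
    candidates = set(eligible) if eligible is not None else None
    best: tuple[int, int, int] | None = None
    best_id: str | None = None
    for pos, rec in enumerate(pool):
        if candidates is not None and rec.id not in candidates:
            continue
        grams = per_seq_grams[rec.id]
        own = np.bincount(grams, minlength=4 ** m)
        if criterion == "pool-max-gram":
            pool_count = int(totals[grams].max())
            tied = grams[totals[grams] == pool_count]
            own_count = int(own[tied].max())
            key = (pool_count, own_count, -pos)
        else:  # self-total
            key = (int(totals[grams].sum()), 0, -pos)
        if best is None or key > best:
            best, best_id = key, rec.id
    if best_id is None:
        raise ValueError("no eligible seed candidate")
    return best_id


def _single_anchor_calibration(scores: np.ndarray, L: int, ensemble_size: int,
                               rng_seed: int, model_id: str) -> ZCalibration:
    mu = float(scores.mean())
    sigma = float(scores.std(ddof=1))
    if sigma < 1e-12:
        raise ValueError(f"degenerate clustering null: sigma={sigma:g}")
    return ZCalibration(model_id=model_id, anchor_lengths=[L], mu_at={L: mu},
                        sigma_at={L: sigma}, ensemble_size=ensemble_size,
                        rng_seed=rng_seed, L_score=L)


def collect_family(pool: SequenceSet, seed_id: str, params: ClusteringParams,
                   null_matrix: np.ndarray | None = None) -> SequenceFamily | None:
    """Try to grow a family around ``seed_id``.

    Returns the family (model refitted on all members, calibration
    rebuilt for the refit model) when at least ``n_th`` pool sequences
    reach ``z_th``, else None.  ``null_matrix`` is an optional
    precomputed shuffled-pool ensemble (encoded, one row per sequence of
    length L) reused across seed attempts.
    """
    if seed_id not in pool:
        raise ValueError(f"seed {seed_id!r} not in pool")
    L = params.L if params.L is not None else pool.min_length
    if L < params.n:
        raise ValueError(f"window length {L} < n={params.n}")
    if null_matrix is None:
        rng = np.random.default_rng(params.rng_seed)
        null_matrix = build_ensemble_matrix(pool, L, params.ensemble_size, rng)
    seed_model = NGramModel.fit([pool[seed_id]], n=params.n,
                                pseudo_count=params.pseudo_count)
    cal = _single_anchor_calibration(seed_model.scan_batch(null_matrix, L), L,
                                     null_matrix.shape[0], params.rng_seed,
                                     f"seed:{seed_id}")
    z = zscores(cal, seed_model, pool, L)
    member_ids = [rec.id for rec, zi in zip(pool, z)
                  if zi >= params.z_th or rec.id == seed_id]
    if len(member_ids) < params.n_th:
        return None
    members = pool.subset(member_ids)
    family_model = NGramModel.fit(members, n=params.n,
                                  pseudo_count=params.pseudo_count)
    family_cal = _single_anchor_calibration(
        family_model.scan_batch(null_matrix, L), L, null_matrix.shape[0],
        params.rng_seed, f"family:{seed_id}")
    return SequenceFamily(family_id=-1, seed_id=seed_id, member_ids=member_ids,
                          model=family_model, calibration=family_cal)


def cluster_all(dataset: SequenceSet,
                params: ClusteringParams) -> tuple[list[SequenceFamily], SequenceSet]:
    """Partition a dataset into families plus an unclassified residual.

    Families are returned in discovery order with sequential ids; the
    residual holds every sequence that joined no family.  Termination is
    guaranteed: each iteration either removes >= n_th sequences or
    permanently retires one seed candidate.
    """
    if len(dataset) == 0:
        raise ValueError("cannot cluster an empty dataset")
    L = params.L if params.L is not None else dataset.min_length
    params = replace(params, L=L)
    rng = np.random.default_rng(params.rng_seed)
    null_matrix = build_ensemble_matrix(dataset, L, params.ensemble_size, rng)
    pool = dataset
    tried: set[str] = set()
    families: list[SequenceFamily] = []
    iterations = 0
    max_iterations = 2 * len(dataset)
    while True:
        iterations += 1
        if iterations > max_iterations:  # termination guard; unreachable
            raise RuntimeError("clustering failed to terminate")
        eligible = [sid for sid in pool.ids if sid not in tried]
        if not eligible:
            break
        seed_id = pick_seed(pool, params.n, params.seed_criterion, eligible)
        family = collect_family(pool, seed_id, params, null_matrix=null_matrix)
        if family is None:
            tried.add(seed_id)
            continue
        family.family_id = len(families)
        families.append(family)
        pool = pool.without(family.member_ids)
        logger.info("family %d: seed %s, %d members, %d sequences left",
                    family.family_id, seed_id, len(family), len(pool))
    return families, pool


def write_families(families: Iterable[SequenceFamily], path: str | Path) -> None:
    """Family membership as a TSV (family_id, seed_id, member_id)."""
    with open(path, "w") as fh:
        fh.write("family_id\tseed_id\tmember_id\n")
        for fam in families:
            for member in fam.member_ids:
                fh.write(f"{fam.family_id}\t{fam.seed_id}\t{member}\n")
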