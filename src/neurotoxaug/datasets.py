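"""Dataset assembly and one-hot encoding for the classification benchmark.

Four dataset types are built from the known and augmented peptides:

* ``unaug_train`` (one per fold): known neurotoxic peptides from k-1 folds
  plus an equal number of known non-neurotoxic peptides;
* ``test`` (one per fold): the held-out fold of known neurotoxic peptides,
  again balanced with negatives;
* ``aug_train``: the augmented neurotoxic peptides (minus the simulation
  share) balanced with negatives;
* ``simulation``: augmented neurotoxic peptides held out from aug_train,
  balanced with negatives — a large evaluation set measuring how well a
  model generalizes to unseen family variants.

Every dataset is class-balanced; negatives are drawn without replacement
and kept disjoint between a fold's train and test splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .pepcore import CANONICAL_AA, Label, PeptideRecord

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


@dataclass
class DatasetBundle:
    """The four dataset types, per fold where applicable."""

    unaug_train: list[list[PeptideRecord]]
    test: list[list[PeptideRecord]]
    aug_train: list[PeptideRecord]
    simulation: list[PeptideRecord]
    n_folds: int = 5


@dataclass
class EncodedBatch:
    """One-hot encoded peptides: ``tensor`` is N x L_max x 20 in {0, 1},
    left-aligned with all-zero padding past each sequence's length."""

    tensor: np.ndarray
    lengths: np.ndarray
    labels: np.ndarray
    L_max: int
    ids: list[str] | None = None


def make_folds(
    records: list[PeptideRecord], k: int, seed: int
) -> list[np.ndarray]:
    """Randomly partition record indices into ``k`` near-equal disjoint
    sets (sizes differ by at most 1).  Deterministic for a fixed seed."""
    n = len(records)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def assemble(
    known_pos: list[PeptideRecord],
    known_neg: list[PeptideRecord],
    augmented: list[PeptideRecord],
    k: int = 5,
    sim_fraction: float = 0.25,
    seed: int = 0,
) -> DatasetBundle:
    """Build the four balanced dataset types.

    Known positives are split into ``k`` folds (train = k-1 folds, test =
    held-out fold).  Augmented positives are split into aug_train
    (1 - sim_fraction) and simulation (sim_fraction).  Each dataset is
    padded with an equal number of negatives sampled without replacement
    from ``known_neg``; a fold's train and test negatives are disjoint,
    and simulation negatives are kept disjoint from aug_train negatives
    when the supply allows (otherwise they are resampled from the full
    negative pool with a warning).
    """
    if not known_pos or not known_neg or not augmented:
        raise ValueError("known_pos, known_neg and augmented must be non-empty")
    if not (0.0 < sim_fraction < 1.0):
        raise ValueError("sim_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    folds = make_folds(known_pos, k, int(rng.integers(2**31)))

    def draw_negs(count: int, pool: np.ndarray) -> tuple[list[PeptideRecord], np.ndarray]:
        if count > len(pool):
            raise ValueError(
                f"insufficient negatives: need {count}, have {len(pool)}"
            )
        take = pool[:count]
        return [known_neg[j] for j in take], pool[count:]

    unaug_train: list[list[PeptideRecord]] = []
    test: list[list[PeptideRecord]] = []
    for i in range(k):
        test_pos = [known_pos[j] for j in folds[i]]
        train_pos = [
            known_pos[j]
            for f in range(k)
            if f != i
            for j in folds[f]
        ]
        pool = rng.permutation(len(known_neg))
        train_neg, pool = draw_negs(len(train_pos), pool)
        test_neg, pool = draw_negs(len(test_pos), pool)
        unaug_train.append(train_pos + train_neg)
        test.append(test_pos + test_neg)

    n_sim = int(round(len(augmented) * sim_fraction))
    n_sim = min(max(n_sim, 1), len(augmented) - 1)
    aug_perm = rng.permutation(len(augmented))
    sim_pos = [augmented[j] for j in aug_perm[:n_sim]]
    aug_pos = [augmented[j] for j in aug_perm[n_sim:]]

    pool = rng.permutation(len(known_neg))
    if len(aug_pos) + len(sim_pos) <= len(known_neg):
        aug_neg, pool = draw_negs(len(aug_pos), pool)
        sim_neg, pool = draw_negs(len(sim_pos), pool)
    else:
        logger.warning(
            "negative pool (%d) too small for disjoint aug-train/simulation "
            "draws (%d + %d); sampling each independently",
            len(known_neg), len(aug_pos), len(sim_pos),
        )
        aug_neg, _ = draw_negs(len(aug_pos), rng.permutation(len(known_neg)))
        sim_neg, _ = draw_negs(len(sim_pos), rng.permutation(len(known_neg)))

    return DatasetBundle(
        unaug_train=unaug_train,
        test=test,
        aug_train=aug_pos + aug_neg,
        simulation=sim_pos + sim_neg,
        n_folds=k,
    )


def one_hot_encode(
    records: list[PeptideRecord], L_max: int = 300
) -> EncodedBatch:
    """Encode peptides as an N x L_max x 20 binary tensor.

    Channel order is alphabetical by one-letter code (ACDEFGHIKLMNPQRSTVWY);
    sequences are left-aligned from position 0 and zero-padded on the
    right.  Labels map neurotoxic -> 1, anything else -> 0.
    """
    n = len(records)
    tensor = np.zeros((n, L_max, 20), dtype=np.float32)
    lengths = np.zeros(n, dtype=np.int64)
    labels = np.zeros(n, dtype=np.int64)
    for i, rec in enumerate(records):
        if len(rec) > L_max:
            raise ValueError(
                f"record {rec.id!r} has length {len(rec)} > L_max={L_max}"
            )
        idx = [_AA_INDEX[aa] for aa in rec.sequence]
        tensor[i, np.arange(len(idx)), idx] = 1.0
        lengths[i] = len(idx)
        labels[i] = 1 if rec.label is Label.NEUROTOXIC else 0
    return EncodedBatch(
        tensor=tensor,
        lengths=lengths,
        labels=labels,
        L_max=L_max,
        ids=[r.id for r in records],
    )


def decode(batch: EncodedBatch) -> list[str]:
    """Invert :func:`one_hot_encode` back to sequence strings."""
    out = []
    for i in range(batch.tensor.shape[0]):
        L = int(batch.lengths[i])
        idx = batch.tensor[i, :L].argmax(axis=1)
        out.append("".join(CANONICAL_AA[j] for j in idx))
    return out
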