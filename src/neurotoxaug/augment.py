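"""Stochastic peptide augmentation with homology-based acceptance.

New neurotoxin-like training sequences are generated from known neurotoxic
peptides by two independent per-position edits:

* substitution: each residue is replaced with probability ``p_sub``
  (default 0.5).  The replacement is drawn from the residue's own
  physicochemical side-chain class with probability ``p_similar`` (default
  0.6, excluding the original letter) and from outside that class
  otherwise.  A replacement never equals the original residue — an edit
  that preserved the letter would be unobservable.
* insertion: after each position, with probability ``p_ins`` (default 0.1)
  one residue drawn uniformly from all 20 letters is inserted.

A variant is accepted only if it still looks like a neurotoxin: its best
local-alignment E-value against the known neurotoxic reference set must
fall below ``evalue_cutoff`` (default 1e-5), and its length must stay
within the 50-300 residue window used for the real datasets.  Accepted
variants are deduplicated by exact sequence against the seeds and against
each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .homology import ScoringScheme, best_hit
from .pepcore import (
    CANONICAL_AA,
    Label,
    PeptideRecord,
    PhyschemGroups,
    Provenance,
)

#: Length window enforced on accepted augmented sequences, matching the
#: 50-300 residue selection applied to the database peptides.
LENGTH_BOUNDS = (50, 300)


@dataclass(frozen=True)
class AugmentationParams:
    """Sampler probabilities and acceptance settings.

    ``target_count`` is the number of accepted augmented sequences
    requested; the attempt budget is ``target_count * max_attempts_per_accept``.
    """

    p_sub: float = 0.5
    p_similar: float = 0.6
    p_ins: float = 0.1
    evalue_cutoff: float = 1e-5
    target_count: int = 1
    max_attempts_per_accept: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_similar", "p_ins"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if self.target_count < 1:
            raise ValueError("target_count must be >= 1")
        if self.max_attempts_per_accept < 1:
            raise ValueError("max_attempts_per_accept must be >= 1")


@dataclass
class AugmentationReport:
    """Outcome of one augmentation run."""

    accepted: list[PeptideRecord]
    attempts: int
    acceptance_rate: float
    per_seed_counts: Mapping[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class VariantTrace:
    """Per-position edit record of one sampled variant.

    ``substituted[i]`` is True when seed position ``i`` was replaced;
    ``same_class[i]`` is True when that replacement stayed in the seed
    residue's physicochemical class (False wherever ``substituted[i]`` is
    False); ``inserted_after[i]`` counts residues inserted directly after
    seed position ``i`` (0 or 1 per draw).
    """

    substituted: tuple[bool, ...]
    same_class: tuple[bool, ...]
    inserted_after: tuple[int, ...]


class AugmentationStarvedError(RuntimeError):
    """Raised when the attempt budget is exhausted with no acceptances."""

    def __init__(self, attempts: int, accepted: int):
        rate = accepted / attempts if attempts else 0.0
        super().__init__(
            f"augmentation starved: {accepted} accepted in {attempts} "
            f"attempts (acceptance rate {rate:.4f}); the seeds may be too "
            f"short or too diverged from the reference set"
        )
        self.acceptance_rate = rate


def generate_variant(
    seed_peptide: PeptideRecord,
    params: AugmentationParams,
    groups: PhyschemGroups,
    rng: np.random.Generator,
    variant_id: str | None = None,
    return_trace: bool = False,
) -> PeptideRecord | tuple[PeptideRecord, VariantTrace]:
    """Sample one unfiltered variant of ``seed_peptide``.

    Deterministic for a fixed ``rng`` state.  If a residue's class is a
    singleton (no same-class alternative exists) the similar branch falls
    back to a dissimilar draw.  With ``return_trace=True`` the per-position
    :class:`VariantTrace` is returned alongside the record.
    """
    if not seed_peptide.sequence:
        raise ValueError("seed sequence must be non-empty")
    alphabet = CANONICAL_AA
    out: list[str] = []
    subbed: list[bool] = []
    same_cls: list[bool] = []
    ins_after: list[int] = []
    for aa in seed_peptide.sequence:
        if rng.random() < params.p_sub:
            cls = groups.class_of(aa)
            same = sorted(groups.members(cls) - {aa})
            other = sorted(set(alphabet) - groups.members(cls))
            if same and rng.random() < params.p_similar:
                out.append(same[rng.integers(len(same))])
                subbed.append(True)
                same_cls.append(True)
            else:
                out.append(other[rng.integers(len(other))])
                subbed.append(True)
                same_cls.append(False)
        else:
            out.append(aa)
            subbed.append(False)
            same_cls.append(False)
        if rng.random() < params.p_ins:
            out.append(alphabet[rng.integers(len(alphabet))])
            ins_after.append(1)
        else:
            ins_after.append(0)
    record = PeptideRecord(
        id=variant_id or f"{seed_peptide.id}|aug",
        sequence="".join(out),
        label=Label.NEUROTOXIC,
        provenance=Provenance.AUGMENTED,
        source_id=seed_peptide.id,
    )
    if return_trace:
        trace = VariantTrace(
            substituted=tuple(subbed),
            same_class=tuple(same_cls),
            inserted_after=tuple(ins_after),
        )
        return record, trace
    return record


def augment_dataset(
    seeds: list[PeptideRecord],
    reference: list[PeptideRecord],
    params: AugmentationParams,
    scheme: ScoringScheme | None = None,
    groups: PhyschemGroups | None = None,
) -> AugmentationReport:
    """Generate ``params.target_count`` accepted augmented peptides.

    Seeds are cycled round-robin; each attempt samples one variant, checks
    the length window, and accepts it if its best hit against ``reference``
    has ``evalue < params.evalue_cutoff`` and its sequence is new (distinct
    from every seed and every previously accepted variant).  Stops when the
    target is reached or the attempt budget
    ``target_count * max_attempts_per_accept`` is exhausted; a run that
    accepts nothing raises :class:`AugmentationStarvedError`.
    """
    if not seeds:
        raise ValueError("seeds must be non-empty")
    if any(s.label is not Label.NEUROTOXIC for s in seeds):
        raise ValueError("all seeds must be labelled neurotoxic")
    if not reference:
        raise ValueError("reference set must be non-empty")
    scheme = scheme or ScoringScheme()
    groups = groups or PhyschemGroups()
    rng = np.random.default_rng(params.seed)
    db_residues = sum(len(r) for r in reference)
    min_len, max_len = LENGTH_BOUNDS

    seen: set[str] = {s.sequence for s in seeds}
    accepted: list[PeptideRecord] = []
    per_seed: dict[str, int] = {s.id: 0 for s in seeds}
    budget = params.target_count * params.max_attempts_per_accept
    attempts = 0
    i = 0
    while len(accepted) < params.target_count and attempts < budget:
        seed = seeds[i % len(seeds)]
        i += 1
        attempts += 1
        variant = generate_variant(
            seed, params, groups, rng,
            variant_id=f"{seed.id}|aug{attempts}",
        )
        if not (min_len <= len(variant) <= max_len):
            continue
        if variant.sequence in seen:
            continue
        hit = best_hit(variant, reference, scheme, db_residues=db_residues)
        if hit.evalue < params.evalue_cutoff:
            accepted.append(variant)
            seen.add(variant.sequence)
            per_seed[seed.id] += 1
    if not accepted:
        raise AugmentationStarvedError(attempts, 0)
    return AugmentationReport(
        accepted=accepted,
        attempts=attempts,
        acceptance_rate=len(accepted) / attempts,
        per_seed_counts=per_seed,
    )
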