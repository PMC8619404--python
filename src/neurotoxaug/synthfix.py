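"""Synthetic neurotoxin-like peptide families and background negatives.

Real neurotoxic venom peptides are short, cysteine-rich sequences whose
disulfide frameworks (e.g. inhibitor-cystine-knot C1-C4/C2-C5/C3-C6
patterns) are far better conserved than the intervening residues.  The
generator emulates exactly that structure: each positive family grows from
a random ancestor with cysteines pinned at fixed scaffold offsets, and
members diverge by per-position substitution while the scaffold stays
immutable.  Negatives are uniform-random peptides, so cysteine occurs at
the background rate of 1/20 and no scaffold exists.

This gives every pipeline stage — homology filtering, augmentation, CNN
training, screening — a self-contained benchmark with a known family
signal, without any database download.  What it does *not* emulate:
signal/propeptide architecture, real amino-acid composition biases, or
homology between negatives and positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pepcore import CANONICAL_AA, Label, PeptideRecord, Provenance

#: Six-cysteine scaffold offsets (0-based) reminiscent of knottin spacing.
DEFAULT_SCAFFOLD = (2, 9, 16, 24, 33, 44)

_NON_CYS = [a for a in CANONICAL_AA if a != "C"]


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic benchmark.

    ``scaffold`` lists fixed 0-based cysteine positions shared by every
    member of every positive family; it must fit within the minimum
    length.  ``mutation_rate`` is the per-position substitution
    probability applied (outside the scaffold) when deriving a member from
    its family ancestor.
    """

    n_families: int = 5
    members_per_family: int = 40
    scaffold: tuple[int, ...] = DEFAULT_SCAFFOLD
    length_range: tuple[int, int] = (55, 90)
    mutation_rate: float = 0.1
    neg_count: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (50 <= lo <= hi <= 300):
            raise ValueError("length_range must lie within [50, 300]")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate outside [0, 1]")
        if self.n_families < 1 or self.members_per_family < 1:
            raise ValueError("need at least one family with one member")
        if max(self.scaffold) >= lo:
            raise ValueError(
                f"scaffold position {max(self.scaffold)} does not fit the "
                f"minimum length {lo}"
            )
        if len(set(self.scaffold)) != len(self.scaffold):
            raise ValueError("scaffold positions must be distinct")


def make_benchmark(
    spec: FamilySpec,
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Generate ``(positives, negatives)`` for one benchmark run.

    Each family draws an ancestor of random length in ``length_range``
    with cysteines only at the scaffold positions; members substitute
    non-scaffold positions independently at ``mutation_rate`` with
    non-cysteine letters (so the scaffold's cysteine count is exact by
    construction).  Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    scaffold = set(spec.scaffold)
    positives: list[PeptideRecord] = []
    for fam in range(spec.n_families):
        length = int(rng.integers(lo, hi + 1))
        ancestor = [
            "C" if i in scaffold else _NON_CYS[rng.integers(len(_NON_CYS))]
            for i in range(length)
        ]
        for m in range(spec.members_per_family):
            member = list(ancestor)
            for i in range(length):
                if i in scaffold:
                    continue
                if rng.random() < spec.mutation_rate:
                    choices = [a for a in _NON_CYS if a != member[i]]
                    member[i] = choices[rng.integers(len(choices))]
            positives.append(
                PeptideRecord(
                    id=f"fam{fam}_m{m}",
                    sequence="".join(member),
                    label=Label.NEUROTOXIC,
                    provenance=Provenance.KNOWN,
                )
            )
    negatives: list[PeptideRecord] = []
    letters = list(CANONICAL_AA)
    for n in range(spec.neg_count):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(letters[j] for j in rng.integers(0, 20, size=length))
        negatives.append(
            PeptideRecord(
                id=f"neg{n}",
                sequence=seq,
                label=Label.NON_NEUROTOXIC,
                provenance=Provenance.KNOWN,
            )
        )
    return positives, negatives


#: Mature-region sequences of the four experimentally assayed candidate
#: peptides (synthesized regions with predicted disulfide frameworks),
#: packaged as small fixed fixtures for tests and examples.
_ASSAYED_CANDIDATES = (
    ("c62771", "SCIRRSASCDHRPSDCCFNSSCRCNLWGTNCRCQRAGLFQKWGK"),
    ("c136163", "KCRLEGCKSRTRVCVKCQMYLCIMKNNCF"),
    ("c43972", "WCSCGLSKKQPFCDGSHINHPKKLQPVRFNPPKDGRFLLCRCKQTNNRPYCD"),
    ("c68875", "GRRGRRQRCSSLLRNWERCDRRNQCPCGAGL"),
)


def table4_fixtures() -> list[PeptideRecord]:
    """The four assayed candidate mature-region peptides as records
    (ids c62771, c136163, c43972, c68875; lengths 44, 29, 52, 31)."""
    records = [
        PeptideRecord(
            id=pid,
            sequence=seq,
            label=Label.UNKNOWN,
            provenance=Provenance.CANDIDATE,
        )
        for pid, seq in _ASSAYED_CANDIDATES
    ]
    return records
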