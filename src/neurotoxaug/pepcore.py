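"""Core peptide domain types, FASTA I/O, and sequence filters.

The package works exclusively with the 20 canonical amino acids: peptides
are later one-hot encoded into a 20-channel representation, so records
carrying ambiguity codes (X, B, Z, U, O, J) cannot be used downstream and
are dropped on read (or rejected, in strict mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetical by one-letter code.  This
#: ordering is also the channel order of the one-hot encoding.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: Ambiguity / non-standard letters that may appear in real FASTA files.
NON_CANONICAL_AA = frozenset("XBZUOJ")


class Label(str, Enum):
    """Functional class of a peptide."""

    NEUROTOXIC = "neurotoxic"
    NON_NEUROTOXIC = "non_neurotoxic"
    UNKNOWN = "unknown"


class Provenance(str, Enum):
    """Where a record came from: a database, the augmentation sampler, or
    a screening candidate pool."""

    KNOWN = "known"
    AUGMENTED = "augmented"
    CANDIDATE = "candidate"


@dataclass(frozen=True)
class PeptideRecord:
    """An identified amino-acid sequence with label and provenance.

    Parameters
    ----------
    id
        Sequence identifier (FASTA header up to the first whitespace).
    sequence
        Upper-case string over the 20 canonical amino-acid letters.
    label
        Functional class; defaults to unknown.
    provenance
        Origin of the record; augmented records must carry ``source_id``,
        the id of the seed peptide they were generated from.
    """

    id: str
    sequence: str
    label: Label = Label.UNKNOWN
    provenance: Provenance = Provenance.KNOWN
    source_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _CANONICAL_SET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-canonical letters {sorted(bad)}"
            )
        if self.provenance is Provenance.AUGMENTED and self.source_id is None:
            raise ValueError(
                f"record {self.id!r}: augmented records require source_id"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_label(self, label: Label) -> "PeptideRecord":
        return replace(self, label=label)


#: Standard textbook side-chain classes.  The augmentation sampler's
#: "similar residue" draw is uniform within the original residue's class.
DEFAULT_GROUPS: Mapping[str, frozenset[str]] = {
    "aliphatic_nonpolar": frozenset("GAVLIPM"),
    "aromatic": frozenset("FWY"),
    "polar_uncharged": frozenset("STCNQ"),
    "basic": frozenset("KRH"),
    "acidic": frozenset("DE"),
}


@dataclass(frozen=True)
class PhyschemGroups:
    """A partition of the 20 amino-acid letters into named side-chain
    classes (disjoint, jointly exhaustive)."""

    groups: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, members in self.groups.items():
            if seen & members:
                raise ValueError(f"class {name!r} overlaps another class")
            seen |= members
        if seen != _CANONICAL_SET:
            missing = _CANONICAL_SET - seen
            extra = seen - _CANONICAL_SET
            raise ValueError(
                f"classes must partition the 20 letters "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )
        object.__setattr__(
            self,
            "_lookup",
            {aa: name for name, members in self.groups.items() for aa in members},
        )

    def class_of(self, residue: str) -> str:
        """Name of the class containing ``residue``."""
        return group_of(residue, self)

    def members(self, name: str) -> frozenset[str]:
        return self.groups[name]


def group_of(residue: str, groups: PhyschemGroups) -> str:
    """Return the name of the physicochemical class of ``residue``.

    Raises ``ValueError`` for non-canonical letters.
    """
    try:
        return groups._lookup[residue]  # type: ignore[attr-defined]
    except KeyError:
        raise ValueError(f"non-canonical residue {residue!r}") from None


def read_fasta(
    path: str | Path,
    *,
    label: Label = Label.UNKNOWN,
    provenance: Provenance = Provenance.KNOWN,
    strict: bool = False,
) -> list[PeptideRecord]:
    """Read a peptide FASTA file into a list of :class:`PeptideRecord`.

    Sequences are upper-cased on read.  Records containing non-canonical
    letters are dropped with a warning; with ``strict=True`` they raise
    instead.  ``label`` and ``provenance`` are applied to every record.
    """
    path = Path(path)
    records: list[PeptideRecord] = []
    n_dropped = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not seq:
            raise ValueError(f"{path}: entry {entry.id!r} has an empty sequence")
        bad = set(seq) - _CANONICAL_SET
        if bad:
            if strict:
                raise ValueError(
                    f"{path}: entry {entry.id!r} contains non-canonical "
                    f"letters {sorted(bad)}"
                )
            logger.warning(
                "dropping %s: non-canonical letters %s", entry.id, sorted(bad)
            )
            n_dropped += 1
            continue
        records.append(
            PeptideRecord(
                id=entry.id, sequence=seq, label=label, provenance=provenance
            )
        )
    if n_dropped:
        logger.warning("%s: dropped %d non-canonical record(s)", path, n_dropped)
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA. ``read_fasta`` inverts it."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)


def filter_by_length(
    records: Iterable[PeptideRecord], min_len: int, max_len: int
) -> list[PeptideRecord]:
    """Keep records with ``min_len <= len <= max_len`` (inclusive bounds),
    preserving order.  The screening pipeline uses 50-300 residues."""
    if not (1 <= min_len <= max_len):
        raise ValueError(f"invalid length bounds ({min_len}, {max_len})")
    return [r for r in records if min_len <= len(r) <= max_len]
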