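"""Local-alignment homology scoring with Karlin-Altschul E-values.

Serves two roles: accepting augmented peptides (a variant must remain
homologous to the known neurotoxin set) and providing the classical
homology-search baseline during transcriptome screening.

The built-in engine is Smith-Waterman with affine gaps (Biopython's
C-accelerated ``PairwiseAligner``) scored with BLOSUM62 and converted to
E-values via the Karlin-Altschul formula ``E = K * m * n * exp(-lambda*S)``
with fixed gapped-BLOSUM62 parameters.  This reproduces BLAST's cutoff
semantics without finite-size (edge-effect) corrections, so decisions very
close to the cutoff may differ from a real blastp run; an adapter to an
external ``blastp`` binary is available for exact parity.

Gap costs follow the BLAST convention: a gap of length ``g`` costs
``gap_open + g * gap_extend``.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .pepcore import PeptideRecord

logger = logging.getLogger(__name__)


def _default_matrix():
    return substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin-Altschul
    parameters for one search configuration.

    Defaults are the standard gapped BLOSUM62 / 11 / 1 scheme with
    lambda = 0.267, K = 0.041.
    """

    substitution_matrix: object = field(default_factory=_default_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        m = np.asarray(self.substitution_matrix)
        if not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.substitution_matrix
        # PairwiseAligner charges open_gap_score for the first gap position;
        # BLAST charges open + extend for a length-1 gap.
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of a query against one subject.

    Spans are 0-based half-open intervals on the respective sequences.
    """

    query_id: str
    subject_id: str
    score: int
    evalue: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("local alignment score must be non-negative")
        if self.evalue <= 0:
            raise ValueError("E-value must be positive")

    @property
    def bitscore(self) -> float:
        """Normalized score in bits: (lambda*S - ln K) / ln 2 under the
        default scheme (provided for report parity with BLAST output)."""
        scheme = ScoringScheme()
        return (scheme.lam * self.score - math.log(scheme.K)) / math.log(2)


def local_align(
    query: PeptideRecord, subject: PeptideRecord, scheme: ScoringScheme
) -> AlignmentHit:
    """Maximal Smith-Waterman score of ``query`` vs ``subject`` under the
    scheme's matrix and affine gap penalties, with one optimal span.

    Deterministic: among equal-scoring alignments the aligner's first
    enumerated alignment is reported.  The E-value uses the subject length
    as database size; for searches against a set use
    :func:`homology_filter`, which scales by the total residue count.
    """
    if not query.sequence or not subject.sequence:
        raise ValueError("cannot align an empty sequence")
    aligner = scheme.make_aligner()
    alignments = aligner.align(query.sequence, subject.sequence)
    best = alignments[0]
    score = int(round(best.score))
    qa, sa = best.aligned
    q_span = (int(qa[0][0]), int(qa[-1][1]))
    s_span = (int(sa[0][0]), int(sa[-1][1]))
    ev = evalue_of(score, len(query), len(subject), scheme)
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        score=score,
        evalue=ev,
        query_span=q_span,
        subject_span=s_span,
    )


def evalue_of(
    score: int, query_len: int, db_residues: int, scheme: ScoringScheme
) -> float:
    """Karlin-Altschul expect value ``E = K * m * n * exp(-lambda * S)``.

    ``m`` is the query length and ``n`` the total residue count of the
    database searched.  Strictly decreasing in ``score``.
    """
    if score < 0:
        raise ValueError("score must be non-negative")
    if query_len < 1 or db_residues < 1:
        raise ValueError("lengths must be positive")
    return scheme.K * query_len * db_residues * math.exp(-scheme.lam * score)


def best_hit(
    candidate: PeptideRecord,
    reference: list[PeptideRecord],
    scheme: ScoringScheme,
    db_residues: int | None = None,
) -> AlignmentHit:
    """Best-scoring hit of ``candidate`` over all reference sequences.

    The E-value is computed against ``db_residues`` (default: total residue
    count of the reference set, matching BLAST's search-space scaling).
    Only the winning pair is traced back for spans; the scan itself is
    score-only for speed.
    """
    if not reference:
        raise ValueError("reference set must be non-empty")
    if db_residues is None:
        db_residues = sum(len(r) for r in reference)
    aligner = scheme.make_aligner()
    scores = [aligner.score(candidate.sequence, r.sequence) for r in reference]
    i_best = int(np.argmax(scores))
    hit = local_align(candidate, reference[i_best], scheme)
    ev = evalue_of(hit.score, len(candidate), db_residues, scheme)
    return AlignmentHit(
        query_id=hit.query_id,
        subject_id=hit.subject_id,
        score=hit.score,
        evalue=ev,
        query_span=hit.query_span,
        subject_span=hit.subject_span,
    )


def homology_filter(
    candidates: list[PeptideRecord],
    reference: list[PeptideRecord],
    cutoff: float,
    scheme: ScoringScheme | None = None,
) -> list[tuple[PeptideRecord, AlignmentHit]]:
    """Keep candidates whose best E-value against the reference set is
    strictly below ``cutoff`` (the screening default is 1e-5).

    Returns ``(record, best_hit)`` pairs in input order.  The database size
    for every E-value is the total residue count of the reference set.
    """
    if not reference:
        raise ValueError("reference set must be non-empty")
    scheme = scheme or ScoringScheme()
    db_residues = sum(len(r) for r in reference)
    kept: list[tuple[PeptideRecord, AlignmentHit]] = []
    for cand in candidates:
        hit = best_hit(cand, reference, scheme, db_residues=db_residues)
        if hit.evalue < cutoff:
            kept.append((cand, hit))
    return kept


def external_blastp_adapter(
    candidates_path: str | Path,
    reference_path: str | Path,
    cutoff: float,
) -> list[AlignmentHit]:
    """Run ``makeblastdb`` + ``blastp`` (tabular output) and parse hits
    passing the E-value cutoff.

    Requires the NCBI BLAST+ binaries on PATH; raises ``RuntimeError`` if
    they are missing (never a silent fallback to the built-in engine).
    Returns the best hit per query, matching :func:`homology_filter`'s
    hit/no-hit contract.
    """
    for tool in ("makeblastdb", "blastp"):
        if shutil.which(tool) is None:
            raise RuntimeError(
                f"external tool unavailable: {tool!r} not found on PATH"
            )
    with tempfile.TemporaryDirectory() as tmp:
        db = str(Path(tmp) / "refdb")
        subprocess.run(
            ["makeblastdb", "-in", str(reference_path), "-dbtype", "prot",
             "-out", db],
            check=True, capture_output=True,
        )
        out = Path(tmp) / "hits.tsv"
        subprocess.run(
            ["blastp", "-query", str(candidates_path), "-db", db,
             "-outfmt", "6 qseqid sseqid pident length qstart qend sstart send evalue bitscore",
             "-evalue", str(cutoff), "-out", str(out)],
            check=True, capture_output=True,
        )
        hits = parse_blast_tabular(out)
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        if h.query_id not in best or h.evalue < best[h.query_id].evalue:
            best[h.query_id] = h
    return [h for h in best.values() if h.evalue < cutoff]


def parse_blast_tabular(path: str | Path) -> list[AlignmentHit]:
    """Parse BLAST outfmt-6 lines (qseqid sseqid pident length qstart qend
    sstart send evalue bitscore) into :class:`AlignmentHit` objects.

    BLAST coordinates are 1-based inclusive; spans are converted to 0-based
    half-open.  The bitscore is stored as the (rounded) raw score slot is
    not available in tabular output, so ``score`` carries the rounded
    bitscore here.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            qid, sid = f[0], f[1]
            qstart, qend, sstart, send = (int(f[4]), int(f[5]), int(f[6]), int(f[7]))
            evalue = float(f[8])
            bitscore = float(f[9])
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    score=int(round(bitscore)),
                    evalue=max(evalue, 5e-324),
                    query_span=(qstart - 1, qend),
                    subject_span=(sstart - 1, send),
                )
            )
    return hits
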