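"""Screen candidate peptides with a trained model against a homology baseline.

Given translated transcriptome peptides, a trained classifier and a
reference set of known neurotoxins, the screen reports which candidates
the model calls neurotoxic, which have a significant local-alignment hit
(the classical way such peptides would be found), the overlap between the
two, and the model's *novel* calls — candidates predicted neurotoxic that
no homology search would have surfaced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .cnnbench import TrainedModel
from .datasets import one_hot_encode
from .homology import AlignmentHit, ScoringScheme, best_hit
from .pepcore import PeptideRecord

logger = logging.getLogger(__name__)


@dataclass
class ScreenReport:
    """Model calls vs homology hits over one candidate set.

    ``novel`` is ``model_hits`` minus the homology-positive ids;
    ``homology_hits`` is sorted by ascending E-value.
    """

    model_hits: set[str]
    homology_hits: list[AlignmentHit]
    overlap: set[str]
    novel: set[str]
    n_skipped: int = 0
    probabilities: dict[str, float] = field(default_factory=dict)


def screen_candidates(
    candidates: list[PeptideRecord],
    model: TrainedModel,
    reference: list[PeptideRecord],
    cutoff: float = 1e-5,
    scheme: ScoringScheme | None = None,
    L_max: int = 300,
) -> ScreenReport:
    """Run the model and the homology baseline over the candidates.

    Candidates longer than ``L_max`` are skipped (never truncated —
    truncation would fabricate sequence) and counted in ``n_skipped``.
    The model verdict is the argmax class; the per-candidate neurotoxic
    probability is kept for downstream re-thresholding.  An empty
    candidate list yields an empty report.
    """
    if not reference:
        raise ValueError("reference set must be non-empty")
    scheme = scheme or ScoringScheme()
    usable = [c for c in candidates if len(c) <= L_max]
    n_skipped = len(candidates) - len(usable)
    if n_skipped:
        logger.warning("skipped %d over-length candidate(s)", n_skipped)
    if not usable:
        return ScreenReport(model_hits=set(), homology_hits=[],
                            overlap=set(), novel=set(), n_skipped=n_skipped)

    proba = model.predict_proba(one_hot_encode(usable, L_max))
    model_hits = {c.id for c, p in zip(usable, proba) if p[1] > p[0]}
    probabilities = {c.id: float(p[1]) for c, p in zip(usable, proba)}

    db_residues = sum(len(r) for r in reference)
    homology_hits = []
    for cand in usable:
        hit = best_hit(cand, reference, scheme, db_residues=db_residues)
        if hit.evalue < cutoff:
            homology_hits.append(hit)
    homology_hits.sort(key=lambda h: h.evalue)
    homologous_ids = {h.query_id for h in homology_hits}
    overlap = model_hits & homologous_ids
    novel = model_hits - homologous_ids
    return ScreenReport(
        model_hits=model_hits, homology_hits=homology_hits,
        overlap=overlap, novel=novel, n_skipped=n_skipped,
        probabilities=probabilities,
    )


def write_overlap_table(report: ScreenReport, path: str | Path) -> None:
    """Write homology hits with the model verdict as a TSV, sorted by
    ascending E-value."""
    header = ["candidate_id", "subject_id", "evalue", "bitscore",
              "model_verdict", "model_probability"]
    rows = []
    for h in sorted(report.homology_hits, key=lambda h: h.evalue):
        verdict = "neurotoxic" if h.query_id in report.model_hits else "-"
        prob = report.probabilities.get(h.query_id, float("nan"))
        rows.append([h.query_id, h.subject_id, f"{h.evalue:.3e}",
                     f"{h.bitscore:.2f}", verdict, f"{prob:.4f}"])
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_report_json(report: ScreenReport, path: str | Path) -> None:
    """Serialize the screen summary (counts and id sets) as JSON."""
    payload = {
        "n_model_hits": len(report.model_hits),
        "n_homology_hits": len(report.homology_hits),
        "n_overlap": len(report.overlap),
        "n_novel": len(report.novel),
        "n_skipped": report.n_skipped,
        "model_hits": sorted(report.model_hits),
        "overlap": sorted(report.overlap),
        "novel": sorted(report.novel),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
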