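"""Screen a candidate peptide pool with a trained model vs homology search.

Trains a small CNN on augmented positives + random negatives, then screens
a candidate pool containing 10 true family homologs hidden among 40
background peptides.  The report cross-tabulates the model's neurotoxic
calls against the classical homology baseline (best local-alignment
E-value < 1e-5): candidates called by the model but invisible to homology
search are the "novel" set — the reason to train a model at all.
"""

import neurotoxaug as na
from neurotoxaug import cnnbench
from neurotoxaug.cnnbench import _split_train_val
from neurotoxaug.datasets import one_hot_encode
from neurotoxaug.pepcore import Provenance

seed = 3
pos, neg = na.make_benchmark(na.FamilySpec(seed=seed))
report = na.augment_dataset(
    pos, pos, na.AugmentationParams(target_count=1000, seed=seed))

# train on augmented positives + negatives
train_records = report.accepted + neg[: len(report.accepted)]
batch = one_hot_encode(train_records, L_max=130)
spec = cnnbench.ModelSpec(block_type="conv_pool", n_blocks=2,
                          filters=(8, 16), train_source="aug")
tr, va = _split_train_val(batch, 0.2, seed)
model = cnnbench.train(cnnbench.build_model(spec, 130, seed=seed),
                       tr, va, spec, seed=seed, max_epochs=40, patience=6)

# candidate pool: 10 held-back family members (two per family) + 40
# background peptides; the held-back members are excluded from the
# reference database so their detection is a genuine search, not a lookup
held_back = pos[::20][:10]
held_ids = {p.id for p in held_back}
homologs = [na.PeptideRecord(id=f"cand_h{i}", sequence=p.sequence,
                             provenance=Provenance.CANDIDATE)
            for i, p in enumerate(held_back)]
decoys = [na.PeptideRecord(id=f"cand_d{i}", sequence=n.sequence,
                           provenance=Provenance.CANDIDATE)
          for i, n in enumerate(neg[-40:])]
reference = [p for p in pos if p.id not in held_ids]

screen = na.screen_candidates(homologs + decoys, model, reference,
                              cutoff=1e-5, L_max=130)
print(f"candidates screened: {len(homologs) + len(decoys)}")
print(f"model neurotoxic calls: {len(screen.model_hits)}")
print(f"homology hits (E < 1e-5): {len(screen.homology_hits)}")
print(f"overlap (found by both): {len(screen.overlap)}")
print(f"novel (model-only calls): {len(screen.novel)}")
for h in screen.homology_hits[:3]:
    print(f"  best hits: {h.query_id} -> {h.subject_id} "
          f"E={h.evalue:.2e} bits={h.bitscore:.1f}")
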