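# Methods

This note documents the models, the defaults and the judgement calls in
`neurotoxaug`, in the package's own terms.

## The augmentation sampler

For each seed-position the sampler makes two independent draws:

1. with probability `p_sub` (default 0.5) the residue is substituted.
   Conditional on substitution, with probability `p_similar` (default
   0.6) the replacement is uniform over the residue's own physicochemical
   class *excluding the original letter*; otherwise it is uniform over
   the letters *outside* the class. The two branches draw from disjoint
   sets, which makes `p_similar` empirically recoverable: a same-class
   replacement can only have come from the similar branch. A replacement
   never equals the original residue — a "substitution" preserving the
   letter would be unobservable and would silently deflate the effective
   edit rate.
2. with probability `p_ins` (default 0.1) one residue, uniform over all
   20 letters, is inserted directly after the position. Insertion is
   per-position, not per-sequence, mirroring the per-residue substitution
   semantics; insertions before the first residue do not occur (a
   documented asymmetry of the edit model, irrelevant at these rates).

If a residue's class is a singleton the similar branch has no legal
outcome and falls back to the dissimilar branch.

**Physicochemical classes.** The default partition is the textbook
side-chain grouping: aliphatic/nonpolar {G,A,V,L,I,P,M}, aromatic
{F,W,Y}, polar uncharged {S,T,C,N,Q}, basic {K,R,H}, acidic {D,E}. Any
disjoint, exhaustive partition of the 20 letters can be supplied instead;
the invariants are enforced at construction.

**Acceptance.** A variant is accepted iff its best local-alignment
E-value against the full known-neurotoxic reference set (not merely its
own seed) is strictly below `evalue_cutoff` (default 1e-5), its length
lies in the 50–300 window applied to the database peptides, and its exact
sequence is new. Deduplication is by exact string match only; near
duplicates are legitimate family members and the homology filter already
bounds their divergence. One seeded `numpy` generator is threaded through
an entire augmentation run; runs are byte-reproducible.

The augmentation run cycles seeds round-robin with an attempt budget of
`target_count * max_attempts_per_accept` (default 50×); exhausting the
budget with zero acceptances raises an explicit starvation error carrying
the observed acceptance rate, rather than looping forever on seeds that
cannot pass the filter.

## Homology scoring

Local alignment is Smith–Waterman with affine gaps, computed by
Biopython's C `PairwiseAligner` with BLOSUM62. Gap costs follow the
BLAST convention (a gap of length *g* costs `gap_open + g*gap_extend`,
default 11/1), so the aligner's open score is set to −12 and its extend
score to −1. Raw scores are converted to expect values with the
Karlin–Altschul formula `E = K·m·n·exp(−λS)` using fixed gapped-BLOSUM62
parameters λ = 0.267, K = 0.041 and database size *n* = total residue
count of the reference set. Two deliberate approximations relative to a
real blastp run:

* λ and K are constants of the scoring scheme, not estimated per search;
* no finite-size/edge-effect length corrections are applied.

Decisions far from the cutoff (exact family members: E ≈ 1e-40;
unrelated 50-mers: E ≈ 1) are unaffected; decisions within an order of
magnitude of 1e-5 may differ from BLAST. For exact parity an adapter runs
external `makeblastdb`/`blastp` and parses tabular output; it raises if
the binaries are absent rather than silently substituting the built-in
engine. The cutoff comparison is strict (`E < cutoff`) everywhere.

Tie-breaking among equal-scoring spans follows the aligner's enumeration
order (first optimal alignment); only the score and one optimal span are
contractual.

## Datasets

Known positives are split into k = 5 near-equal random folds; fold *i*'s
training set is the other k−1 folds. Augmented positives are split
`1−sim_fraction` / `sim_fraction` (default 0.25) into AUG-train and
simulation. Every dataset is balanced by drawing an equal number of
negatives without replacement; train/test negative draws are disjoint
within a fold, and simulation negatives are disjoint from AUG-train
negatives whenever the pool suffices (otherwise independent draws with a
logged warning). The simulation set contains real negatives because
precision and recall are undefined on a single-class set. Splits are
random, not sequence-identity-aware — family members can land on both
sides of a fold boundary, which flatters the unAUG test-fold numbers but
affects both model groups equally.

One-hot encoding uses the fixed channel order ACDEFGHIKLMNPQRSTVWY,
left-aligned sequences and all-zero right padding, with `L_max = 300` by
default (the upper length bound); benchmarks on shorter synthetic
peptides pass a smaller `L_max` to cut convolution cost.

## The CNN family and training

No deep-learning framework is part of the package's dependency set; the
network engine (`_nn.py`) implements exactly what the benchmark needs in
numpy: valid-mode 1-D convolution via im2col, ReLU, width-2 max pooling,
dense layers, a 2-way softmax head with cross-entropy, He initialization
and Adam. At these model sizes (10³–10⁵ parameters, ≤2000 training
sequences) vectorized numpy is fast enough that a framework would buy
nothing but a dependency.

An architecture is `block_type ∈ {conv-pool, conv-conv-pool}` ×
`n_blocks ∈ 1..4` × base filter width ∈ {8, 16, 32} (filters double per
block), kernel size 5, dense width 32 — 24 architectures. The full grid
crosses these with 2 learning rates (0.005, 0.0001), 6 training sources
(5 unAUG folds + AUG) and 3 repeats: 864 cells. The desk-scale grid used
by the tests keeps depth-2 blocks, one learning rate and one repeat: 12
cells. Networks whose spatial dimension would collapse below the kernel
size (deep stacks on short `L_max`) fail at build time with a
configuration error rather than at the first forward pass.

Training defaults: up to 200 epochs (the benchmark uses 40), batch 32,
early stopping on validation F1 with patience 20 (benchmark 6), best
checkpoint restored, stratified 80/20 train/validation split. Every cell
derives its own seed from `SeedSequence([base_seed, cell_index])`, so
results are independent of grid ordering and a resumed run (cells are
streamed to a TSV log and skipped on re-run) is idempotent.

Metrics use the standard confusion-matrix definitions with neurotoxic as
the positive class; a metric whose denominator is zero is reported as
undefined, never as 0. Selection is arg-max of F1 on the simulation set,
ties broken by fewer parameters, then lower learning rate, then lower
repeat index. unAUG-trained models are tested on their own fold's test
set; AUG-trained models (which see no known positives in training) on
all test folds pooled. The paired t-test pairs metric values at matched
architecture cells and uses Student's t with n−1 degrees of freedom,
two-sided; zero-variance differences are a degenerate-input error.

## The synthetic benchmark

`synthfix` emulates the one structural fact that makes neurotoxin
families learnable: a conserved cysteine scaffold on a diverging
background. Each family grows from a random ancestor with cysteines
pinned at fixed offsets (default six positions within the first 45
residues); members substitute non-scaffold positions at `mutation_rate`
(default 0.1) with non-cysteine letters, so the scaffold is exact by
construction. Negatives are uniform-random peptides (cysteine at the
1/20 background rate). Default sizes — 5 families × 40 members, lengths
55–90, 2000 negatives — keep the full suite in minutes on one CPU.

What passing benchmarks do and do not show: the generator reproduces the
*geometry* of the problem (small conserved families, homology-acceptable
variants, unrelated background) but not real venom-peptide composition,
signal/propeptide architecture, or hard negatives homologous to
positives. The AUG-vs-unAUG direction measured here is therefore evidence
about the augmentation mechanism, not a performance forecast for any
real database snapshot; absolute F1 values on real data will differ.

The benchmark asserted by the acceptance test uses 5 families × 20
members (100 known positives), augmentation to 1000 accepted variants,
`sim_fraction` 0.25, `L_max` 120, the 12-cell grid, three seeds — sized
so one seed completes in well under a minute on a single CPU. Under
these conditions the unAUG models, near-perfect on their own test folds,
lose most of their recall on the simulation variants (50% of positions
substituted, 40% of those out-of-class), while AUG models trained on the
same distribution keep F1 above 0.85 — the strict inequality holds with
a wide margin in every seed tried.

## Screening

Candidates longer than `L_max` are skipped and counted, never truncated
— truncation would fabricate sequence. The model verdict is the argmax
class (probability threshold 0.5); per-candidate probabilities are kept
in the report for downstream re-thresholding. The homology baseline uses
the same filter as augmentation acceptance; hits are sorted by ascending
E-value in the overlap table. By construction `|overlap| + |novel| =
|model_hits|`.

## Known limitations

* Karlin–Altschul parameters are scheme constants; near-cutoff
  acceptance may differ from blastp (see above).
* The packaged architecture family is a faithful shape (block types,
  depths, widths, two learning rates), not a replica of any specific
  published hyperparameter table.
* Random (not identity-clustered) splits overstate test-fold performance
  on families; simulation-set comparisons are unaffected.
* Negatives in the synthetic benchmark are easy; real "non-neurotoxic"
  sets contain cysteine-rich non-toxins the benchmark does not model.
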