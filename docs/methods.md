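# Methods

## Problem and model

`vqrefine` refines small-variant callsets after calling: given a VCF
from any caller and a truth set used only for labeling, it learns to
separate true variants from technical artifacts using nothing but the
per-record quality evidence, then rewrites the FILTER column. The
package follows a model/results design: `SentenceClassifier` is built
from a labeled sentence corpus and a vocabulary, `fit()` returns a
`ClassifierResults` holding the weights, the per-epoch training log,
`summary()`, prediction and checkpointing.

### Labeling

A query record is labeled PASS iff its (CHROM, POS) pair occurs in the
truth VCF. The match key includes CHROM because a bare position would
collide across chromosomes; contig names are normalized by stripping a
leading `chr` (configurable) so `chr1`/`1` callsets compare. Alleles
and genotypes are not compared — the label means "a high-confidence
variant exists at this site", and the identical convention is used for
training and evaluation, so reported metrics are internally consistent
filtering metrics, not representation-aware benchmarking figures.
Representation-aware matchers can be plugged in through the `matcher`
hook on `label_by_position`.

### Sentence encoding

Locus columns (CHROM, POS, REF, ALT, and also ID, which carries no
quality signal) are dropped; QUAL, the INFO map in source order, and —
for single-sample files — the FORMAT fields are serialized as one
`KEY=value` token each. Whole-pair tokens (rather than splitting key
and value) keep sentences short and make the vocabulary the natural
carrier of caller-specific features: adapting to a new caller dialect
means appending its tokens (`extend_vocabulary`), which never renumbers
existing ids, so a trained embedding stays valid.

Float values are rounded to `numeric_precision` decimals before
tokenization. The default is 2; the training-based tests and the
acceptance script use 0 (integer binning), because with unbinned
continuous values nearly every token is unique, the vocabulary explodes
and held-out sentences become all-unknown. Precision is an encoding
parameter bound into the model checkpoint, so train and inference can
never disagree silently (a vocabulary SHA-256 fingerprint is checked on
every prediction and on checkpoint load).

Special tokens are `[PAD]`, `[UNK]`, `[START]`, `[SEP]` with fixed ids
0–3. Token sequences open with `[START]` (whose final-layer state is
the pooled representation), are truncated to `max_sequence_length`
(default 64; 16 in the desk-scale tests, which comfortably covers both
dialects' sentences) and padded; the attention mask excludes padding
keys in every layer.

### Encoder

Pre-norm transformer encoder, implemented in numpy (float64, CPU):

- token embedding + learned positional embedding;
- per block: `x + MHSA(LN(x))` then `x + FFN(LN(x))`, FFN = GELU MLP;
- final LayerNorm, first-token pooling, 2-way linear head, softmax.

Training is fixed-epoch (no early stopping) cross-entropy with AdamW
(decoupled weight decay 0.01 applied to matrices only). Gradients are
hand-derived; the test suite checks them against central finite
differences at every parameter tensor. The attention mask uses an
additive bias of −10⁴, large enough that masked keys underflow to zero
weight while keeping float64 headroom for numerically stable
gradients. Per-epoch validation accuracy and ROC AUC are logged.

Desk-scale default: 2 layers, 2 heads, hidden 64, feed-forward 128,
batch 64, learning rate 1e-4, 10 epochs. The published full-scale
settings (6–12 layers and heads, batch 600–1,300, learning rate
5e-5–1e-4, 21 epochs) are expressible through the same `ModelConfig`;
`epochs=0` is allowed and denotes an untrained (random-init) baseline,
useful as a grid-search control. `grid_search` retrains every candidate
under one seed policy and selects by final validation ROC AUC, breaking
ties toward fewer parameters then candidate order.

Reproducibility: a fixed (corpus, config, seed) gives an identical
training log; inference is batching-invariant up to float round-off
(BLAS reduction order may differ across batch shapes).

### FILTER contract

`update_filter` puts the decision first; pre-existing caller
annotations other than PASS/FAIL/`.` are preserved after it; a prior
lone PASS (or a prior model decision) is replaced, never duplicated —
so refinement is idempotent and every refined record carries exactly
one of {PASS, FAIL}, first. A `##FILTER=<ID=FAIL,...>` header line is
injected when absent. The PASS probability is written to the
`PASS_PROB` INFO tag (declared in the header, configurable, excludable)
and stripped before encoding, so re-refining a refined VCF is a no-op
on decisions.

VCF I/O is text-level and round-trip faithful: INFO values are kept as
raw ordered strings and `write(read(x))` is byte-identical on data
lines. This is a deliberate design constraint — downstream tools must
see caller annotations exactly as emitted — and is why records are not
routed through a typed VCF library (pysam serves as an independent
parsing oracle in the tests instead).

### Metrics

Computed closed-form from confusion counts with PASS positive.
Weighted precision/recall/F1 use true-class supports (the
scikit-learn `average="weighted"` convention; for two classes weighted
recall ≡ accuracy). The published per-sample tables reproduce under
exactly this convention, which pins it. MCC multiplies the square
roots of the four denominator factors separately so ~10⁷-scale counts
cannot overflow, and returns 0 when any factor vanishes. ROC AUC is the
midrank Mann–Whitney statistic (ties count ½), verified against
exhaustive pair enumeration. Zero-denominator metrics are defined as 0
with a warning. Batched evaluation sums confusion counts across
batches before deriving global metrics (metrics of sums, never means
of metrics).

### Hard-filter baselines

GATK4: the six printed defaults with strict inequalities, so a record
sitting exactly on every threshold passes; missing annotations do not
fire (RankSum annotations are undefined at homozygous sites).
BCFTools: `QUAL >= 20`, inclusive; a missing QUAL fails, since a
quality floor cannot be met by an absent value.

## Synthetic data

The generator emulates the study conditions without downloads. Each
record is planted true with probability `truth_overlap_fraction`
(default 0.8, mirroring the ~82/18 PASS/FAIL imbalance of the real
merged training callset); true records' positions form the truth VCF.
Quality features are drawn from a two-component Gaussian model — a
"true variant" component (e.g. QD≈20, FS≈2, MQ≈60, high QUAL) and a
"technical artifact" component placed inside the firing region of
every GATK4 default filter (QD≈1, FS≈90, MQ≈28, SOR≈5.5,
MQRankSum≈−14, ReadPosRankSum≈−9.5, low QUAL). `SignalModel.noise_rate`
swaps a record's feature component with that probability, setting the
Bayes accuracy floor at 1 − noise for separated components;
`separation` scales both the mean gap and the sd contrast, so 0 yields
literally identical components (no signal, Bayes accuracy =
max(overlap, 1 − overlap)). `feature_separability` estimates the Bayes
accuracy by Monte Carlo with the exact posterior under the unclipped
Gaussian densities (clipping and integer rounding of emitted values
are ignored there; the induced error is well below the 0.01 tolerance
the tests use).

What the generator does **not** emulate: linkage and allele-frequency
structure, indel representation quirks, multi-allelic sites, regional
coverage autocorrelation, and truth sets containing positions absent
from the query. Passing tests therefore demonstrate the pipeline's
correctness and the classifier's capacity to learn feature-based
PASS/FAIL structure — not field accuracy on real sequencing data.

## Problem sizes and numerical choices

Unit fixtures use 1,000-record callsets; learnability checks use
5,000-sentence corpora with a 60/40 split (the split fraction of the
original study), 10 epochs for the clean-rule condition and 5 for the
shuffled/noisy conditions, sizes chosen so the whole suite runs in
minutes on one CPU. The label-shuffled null is asserted inside
AUC ∈ [0.45, 0.55]; with ~2,000 validation records the null standard
error is ≈0.016, so the band is ≈3σ. Probability→decision uses
`p >= threshold` (boundary passes). Seeds: every stochastic component
(simulation, splitting, initialization, shuffling) takes an explicit
seed; derived seeds are small fixed offsets of the user seed.

## Known limitations

- Position-only labeling cannot distinguish allele mismatches at a
  truth position; that is a property of the method being implemented,
  not a bug.
- The numpy encoder is desk-scale: fine for ~10⁴–10⁵ sentences, not a
  GPU trainer for 2×10⁶-record corpora, although `ModelConfig` accepts
  the full-scale settings.
- Symbolic-ALT (structural) records pass through refinement untouched
  only in the sense that nothing prevents classifying them; their
  INFO dialects were not considered.
- BCF binary output and tabix indexing are out of scope; bgzip is
  supported on read, plain text on write.
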