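# vqrefine

Self-attention refinement of variant calls, directly on VCF files.

Small-variant callers (GATK4 HaplotypeCaller, BCFTools, ...) emit raw
callsets that mix true variants with technical artifacts, and the stock
remedy — hard thresholds on quality annotations such as `QD < 2.0` or
`QUAL >= 20` — is brittle, especially on low-coverage data. `vqrefine`
treats post-calling refinement as sequence classification: each variant
record's quality evidence (QUAL, the INFO annotations, FORMAT fields)
is flattened into a token "sentence", a small self-attention encoder
predicts whether the record is a true variant (PASS) or an artifact
(FAIL), and the decision is written back into the FILTER column while
every pre-existing caller annotation is preserved after it. The package
is for bioinformaticians who want a trainable, caller-agnostic filter
that drops into standard VCF pipelines.

## The model

Training labels come from a truth set by **position matching**: a query
record is labeled PASS iff its (CHROM, POS) occurs in the truth VCF,
otherwise FAIL — alleles are deliberately not compared, so the same
labeling convention serves training and evaluation.

Each labeled record becomes a sentence of key=value tokens with all
locus information (CHROM, POS, ID, REF, ALT) removed, e.g.

    QUAL=143.2 QD=21.4 FS=1.2 MQ=60.0 SOR=0.9 MQRankSum=0.3 ReadPosRankSum=-0.2 DP=12 GT=0/1 DP=12

The classifier is a pre-norm transformer encoder: token embedding +
learned positional embedding, `L` blocks of multi-head self-attention
and a GELU feed-forward sublayer with residual connections, first-token
pooling, and a 2-way softmax head, trained with cross-entropy under
AdamW for a fixed number of epochs. For a sentence `x` with PASS
probability `p(x)`, the decision is `PASS iff p(x) >= t` (default
`t = 0.5`).

Evaluation uses the full two-class battery with PASS positive:
accuracy `(TP+TN)/N`, support-weighted precision/recall/F1 (weights =
true class supports; weighted recall ≡ accuracy), the Matthews
correlation coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

and ROC AUC computed as the Mann–Whitney statistic with midrank ties.

Hard-filter baselines are built in: the six GATK4 defaults
(`QD < 2.0`, `FS > 60.0`, `MQ < 40.0`, `SOR > 4.0`,
`MQRankSum < −12.5`, `ReadPosRankSum < −8.0`; any firing rule fails the
record) and the BCFTools floor `QUAL >= 20`.

A synthetic-data module generates GATK4- and BCFTools-dialect callsets
with paired truth sets and a planted two-component feature model of
known Bayes accuracy, so the whole pipeline is testable without any
download.

## Worked example

```bash
# 1. a 5,000-record GATK4-dialect callset with an 80% truth overlap
vqrefine --seed 7 simulate --dialect gatk4 --n 5000 --out-prefix fix/

# 2. label + train (60/40 split, desk-scale encoder) in one step;
#    16 tokens comfortably cover a GATK4-dialect sentence
printf 'max_sequence_length = 16\n' > fix/cfg.toml
vqrefine --seed 7 train --train-vcf fix/query.vcf --truth-vcf fix/truth.vcf \
         --config fix/cfg.toml --numeric-precision 0 --out fix/model.ckpt.npz

# 3. refine the callset and evaluate it
vqrefine refine --vcf fix/query.vcf --model fix/model.ckpt.npz --out fix/refined.vcf
vqrefine evaluate --refined fix/refined.vcf --truth fix/truth.vcf --out fix/report.json
```

The training step prints a per-epoch fit table (output of
`ClassifierResults.summary()`); the run shown here ends with

```
epoch   train loss   val acc   val AUC
    ...
   10       0.0120    1.0000    1.0000
```

meaning the encoder fully recovers the planted PASS/FAIL rule on the
held-out 40% (the synthetic rule is noise-free, so Bayes accuracy is
1.0). The refine step prints `refined 5000 records: 3967 PASS / 1033
FAIL -> fix/refined.vcf` — exactly the 3,967 planted truth positions —
and the global block of `report.json` reads

```
accuracy 1.0   roc_auc 1.0   mcc 1.0   tp 3967  fp 0  fn 0  tn 1033
```

Each record in `fix/refined.vcf` carries its PASS probability in the
`PASS_PROB` INFO tag with the model decision first in FILTER.

The same objects are available as a library:

```python
from vqrefine import (SimulationConfig, simulate_callset, build_vocabulary,
                      record_to_sentence, EncodingConfig, ModelConfig,
                      SentenceClassifier, make_split, SplitSpec)

sim = simulate_callset(SimulationConfig(n_records=5000, seed=7))
enc = EncodingConfig(max_sequence_length=16, numeric_precision=0)
corpus = [record_to_sentence(r, enc, label=l)
          for r, l in zip(sim.query_records, sim.labels)]
train_set, val_set = make_split(corpus, SplitSpec(seed=1))
vocab = build_vocabulary(train_set)
model = SentenceClassifier(train_set, val_set, vocab,
                           ModelConfig(max_sequence_length=16, seed=1), enc)
results = model.fit()
print(results.summary())
probs = results.predict_proba(val_set, vocab)
```

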