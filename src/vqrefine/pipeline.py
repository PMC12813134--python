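"""End-to-end orchestration: VCF in -> sentences -> probabilities ->
decisions -> FILTER-updated VCF out, plus training-corpus assembly.

Refinement streams records in batches, so memory is bounded by the
batch tensor, not the callset. Every output record carries exactly one
model decision first in FILTER (caller annotations preserved after it)
and, by default, the PASS probability as an INFO tag so downstream ROC
analysis can run without re-running the model. A JSON run manifest is
written alongside every output VCF.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .classifier import ClassifierResults, decide
from .encoding import EncodingConfig, Sentence, Vocabulary, record_to_sentence
from .vcf_io import (
    FAIL,
    FAIL_FILTER_META,
    PASS,
    VariantRecord,
    VcfHeader,
    read_vcf,
    update_filter,
    write_vcf,
)

DEFAULT_PROB_TAG = "PASS_PROB"
DEFAULT_BATCH_SIZE = 10_000


def _prob_tag_meta(tag: str) -> str:
    return (
        f'##INFO=<ID={tag},Number=1,Type=Float,'
        f'Description="Refinement model PASS probability">'
    )


@dataclass
class RunManifest:
    """Provenance sidecar for one refinement run."""

    input_vcf: str
    output_vcf: str
    vocab_fingerprint: str
    model_config: dict
    threshold: float
    batch_size: int
    prob_tag: str | None
    records_in: int = 0
    records_out: int = 0
    n_pass: int = 0
    n_fail: int = 0
    started_utc: str = ""
    finished_utc: str = ""

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def _batched(
    records: Iterable[VariantRecord], size: int
) -> Iterator[list[VariantRecord]]:
    batch: list[VariantRecord] = []
    for rec in records:
        batch.append(rec)
        if len(batch) >= size:
            yield batch
            batch = []
    if batch:
        yield batch


def refine(
    vcf_in: str | Path,
    results: ClassifierResults,
    vocab: Vocabulary,
    vcf_out: str | Path,
    threshold: float = 0.5,
    batch_size: int = DEFAULT_BATCH_SIZE,
    prob_tag: str | None = DEFAULT_PROB_TAG,
    manifest_path: str | Path | None = None,
) -> RunManifest:
    """Refine a callset: classify each record and rewrite its FILTER.

    The probability tag (when enabled) is excluded from sentence
    encoding, so refining an already-refined VCF reproduces the same
    decisions. Record count is conserved and checked in the manifest.
    """
    results._check_vocab(vocab)
    encoding = results.encoding
    if prob_tag is not None and prob_tag not in encoding.drop_info_keys:
        encoding = EncodingConfig(
            max_sequence_length=encoding.max_sequence_length,
            numeric_precision=encoding.numeric_precision,
            fields_included=encoding.fields_included,
            drop_info_keys=encoding.drop_info_keys | {prob_tag},
        )
    manifest = RunManifest(
        input_vcf=str(vcf_in),
        output_vcf=str(vcf_out),
        vocab_fingerprint=results.vocab_fingerprint,
        model_config=asdict(results.config),
        threshold=threshold,
        batch_size=batch_size,
        prob_tag=prob_tag,
        started_utc=datetime.now(timezone.utc).isoformat(),
    )

    header, records = read_vcf(vcf_in)
    out_header = header.with_filter_declared(FAIL, FAIL_FILTER_META)
    if prob_tag is not None:
        out_header = out_header.with_info_declared(prob_tag, _prob_tag_meta(prob_tag))

    def _refined() -> Iterator[VariantRecord]:
        for batch in _batched(records, batch_size):
            manifest.records_in += len(batch)
            sentences = [record_to_sentence(r, encoding) for r in batch]
            probs = results.predict_proba(sentences, vocab, batch_size=batch_size)
            for rec, p in zip(batch, probs):
                decision = decide(float(p), threshold)
                if decision == PASS:
                    manifest.n_pass += 1
                else:
                    manifest.n_fail += 1
                rec = update_filter(rec, decision)
                if prob_tag is not None:
                    rec.info[prob_tag] = f"{p:.6f}"
                yield rec

    manifest.records_out = write_vcf(out_header, _refined(), vcf_out)
    manifest.finished_utc = datetime.now(timezone.utc).isoformat()
    if manifest.records_out != manifest.records_in:
        raise RuntimeError(
            f"record count not conserved: {manifest.records_in} in, "
            f"{manifest.records_out} out"
        )
    if manifest_path is None:
        manifest_path = str(vcf_out) + ".manifest.json"
    manifest.write(manifest_path)
    return manifest


def build_training_corpus(
    labeled_vcfs: Sequence[str | Path],
    subsample_size: int | None = None,
    seed: int = 0,
    encoding: EncodingConfig = EncodingConfig(),
) -> list[Sentence]:
    """Merge labeled callsets into one sentence corpus.

    Files are concatenated in argument order (each record's label read
    from the first FILTER entry), then optionally subsampled uniformly
    without replacement with the given seed. Mirrors the merge-then-
    subsample construction of the published training set (2M records
    drawn from the merged GATK4 + BCFTools callsets).
    """
    if not labeled_vcfs:
        raise ValueError("at least one labeled VCF is required")
    corpus: list[Sentence] = []
    for path in labeled_vcfs:
        _, records = read_vcf(path)
        for i, rec in enumerate(records):
            if not rec.filters or rec.filters[0] not in (PASS, FAIL):
                raise ValueError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks a PASS/FAIL "
                    "label in FILTER; run labeling first"
                )
            corpus.append(
                record_to_sentence(rec, encoding, label=rec.filters[0], source_index=i)
            )
    if subsample_size is not None and subsample_size < len(corpus):
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(corpus), size=subsample_size, replace=False))
        corpus = [corpus[i] for i in keep]
    return corpus


def corpus_label_counts(corpus: Sequence[Sentence]) -> tuple[int, int]:
    n_pass = sum(1 for s in corpus if s.label == PASS)
    return n_pass, len(corpus) - n_pass
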