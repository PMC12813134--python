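"""Evaluate a refined callset against a truth set.

Predictions are read from the first FILTER entry of the refined VCF,
reference labels come from position-based truth matching, and the
optional probability INFO tag feeds ROC AUC. Records are processed in
batches (default 10,000) and per-batch reports are returned alongside
the global one; the global confusion is the sum of batch confusions,
never an average of batch metrics.
"""

from __future__ import annotations

from pathlib import Path

from .metrics import ConfusionCounts, MetricsReport, confusion, roc_auc, weighted_metrics
from .pipeline import DEFAULT_BATCH_SIZE, DEFAULT_PROB_TAG, _batched
from .truth_labeling import TruthIndex, build_truth_index, position_matcher
from .vcf_io import FAIL, PASS, read_vcf


def evaluate_vcf(
    refined_vcf: str | Path,
    truth: str | Path | TruthIndex,
    batch_size: int = DEFAULT_BATCH_SIZE,
    prob_tag: str | None = DEFAULT_PROB_TAG,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """(global report, per-batch reports) for one refined callset.

    ROC AUC appears in the global report only when every record carries
    a numeric probability under ``prob_tag``.
    """
    index = truth if isinstance(truth, TruthIndex) else build_truth_index(truth)
    _, records = read_vcf(refined_vcf)

    batch_reports: list[MetricsReport] = []
    total = ConfusionCounts(0, 0, 0, 0)
    all_labels: list[str] = []
    all_probs: list[float] = []
    probs_complete = True
    for batch in _batched(records, batch_size):
        labels = [
            PASS if position_matcher(rec, index) else FAIL for rec in batch
        ]
        preds = [
            PASS if (rec.filters and rec.filters[0] == PASS) else FAIL
            for rec in batch
        ]
        counts = confusion(labels, preds)
        total = total + counts
        batch_auc = None
        if probs_complete and prob_tag is not None:
            probs = [rec.info_float(prob_tag) for rec in batch]
            if any(p is None for p in probs):
                probs_complete = False
            else:
                all_labels.extend(labels)
                all_probs.extend(probs)  # type: ignore[arg-type]
                if len(set(labels)) == 2:
                    batch_auc = roc_auc(labels, probs)  # type: ignore[arg-type]
        batch_reports.append(weighted_metrics(counts, roc_auc_value=batch_auc))

    global_auc = None
    if prob_tag is not None and probs_complete and all_probs and len(set(all_labels)) == 2:
        global_auc = roc_auc(all_labels, all_probs)
    return weighted_metrics(total, roc_auc_value=global_auc), batch_reports
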