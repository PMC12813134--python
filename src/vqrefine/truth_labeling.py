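"""Position-based PASS/FAIL labeling against a truth-set VCF.

A query record is labeled PASS when its (contig, position) pair occurs
anywhere in the truth set, FAIL otherwise. Alleles and genotypes are
deliberately not compared: the label says "a high-confidence variant
exists at this site", which is the consistent convention used for both
training labels and evaluation in this framework. Representation-aware
matching (hap.py / vcfeval style) is a pluggable alternative via the
``matcher`` hook.

Match keys use CHROM + POS; POS alone would collide across chromosomes.
Contig names are normalized (default: strip a leading "chr") so that
GRCh38 "chr1" and "1" callsets can be compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

from .vcf_io import FAIL, PASS, VariantRecord, read_vcf, update_filter


def normalize_contig(name: str, strip_chr: bool = True) -> str:
    if strip_chr and name.lower().startswith("chr"):
        return name[3:]
    return name


@dataclass
class TruthIndex:
    """Set of normalized (contig, 1-based pos) pairs from a truth VCF."""

    positions: set[tuple[str, int]] = field(default_factory=set)
    n_records: int = 0
    strip_chr: bool = True

    def add(self, chrom: str, pos: int) -> None:
        self.positions.add((normalize_contig(chrom, self.strip_chr), pos))
        self.n_records += 1

    def __contains__(self, key: tuple[str, int]) -> bool:
        chrom, pos = key
        return (normalize_contig(chrom, self.strip_chr), pos) in self.positions

    def __len__(self) -> int:
        return len(self.positions)


def build_truth_index(
    truth_vcf: str | Path, strip_chr: bool = True
) -> TruthIndex:
    """Index every (contig, pos) of the truth set.

    Multi-allelic splits (duplicate positions) collapse in the position
    set but still count in ``n_records``. An empty truth VCF yields a
    valid empty index with a warning.
    """
    index = TruthIndex(strip_chr=strip_chr)
    _, records = read_vcf(truth_vcf)
    for rec in records:
        index.add(rec.chrom, rec.pos)
    if index.n_records == 0:
        warnings.warn(f"truth VCF {truth_vcf} contains no records; all query "
                      "records will be labeled FAIL", stacklevel=2)
    return index


Matcher = Callable[[VariantRecord, TruthIndex], bool]


def position_matcher(record: VariantRecord, index: TruthIndex) -> bool:
    return (record.chrom, record.pos) in index


def label_by_position(
    query: Iterable[VariantRecord],
    index: TruthIndex,
    matcher: Matcher = position_matcher,
) -> Iterator[tuple[VariantRecord, str]]:
    """Yield (record-with-updated-FILTER, label) pairs.

    Deterministic and order-independent: each record's label depends only
    on its own coordinates and the index.
    """
    for rec in query:
        label = PASS if matcher(rec, index) else FAIL
        yield update_filter(rec, label), label


def count_labels(labeled: Iterable[tuple[VariantRecord, str]]) -> tuple[int, int]:
    """(n_pass, n_fail) over a labeled stream; sums to the record count."""
    n_pass = n_fail = 0
    for _, label in labeled:
        if label == PASS:
            n_pass += 1
        else:
            n_fail += 1
    return n_pass, n_fail
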