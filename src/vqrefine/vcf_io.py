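"""Text-level VCF reading and writing with round-trip fidelity.

Variant records are kept as raw, ordered strings: INFO values are never
re-typed or re-formatted, so write(read(x)) reproduces the source data
lines byte for byte. This fidelity is a hard contract — downstream tools
must see the caller's annotations exactly as emitted, with only the
FILTER column rewritten by :func:`update_filter`.

Coordinates are 1-based throughout, as in the VCF text itself. Plain
text and bgzip/gzip compressed files are both readable; plain text is
written by default.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator

MISSING = "."

PASS = "PASS"
FAIL = "FAIL"

#: header line injected when a refined VCF lacks a FAIL filter declaration
FAIL_FILTER_META = '##FILTER=<ID=FAIL,Description="Record classified as artifact by the refinement model">'

FIXED_COLUMNS = ("#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO")


class VcfFormatError(ValueError):
    """Malformed VCF structure (missing #CHROM line, short data line...)."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass
class VariantRecord:
    """One VCF data line.

    ``info`` preserves source key order; flag keys map to ``None``.
    ``qual`` is kept as the raw string so "60" and "60.00" round-trip
    distinctly; use :meth:`qual_value` for the numeric view.
    """

    chrom: str
    pos: int
    id: str = MISSING
    ref: str = "N"
    alts: list[str] = field(default_factory=lambda: ["."])
    qual: str = MISSING
    filters: list[str] = field(default_factory=list)
    info: dict[str, str | None] = field(default_factory=dict)
    format_keys: list[str] = field(default_factory=list)
    samples: list[dict[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"POS must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("REF must be non-empty")

    def qual_value(self) -> float | None:
        """QUAL as float, or None when missing ('.')."""
        if self.qual == MISSING or self.qual == "":
            return None
        try:
            return float(self.qual)
        except ValueError:
            return None

    def info_float(self, key: str) -> float | None:
        """Numeric view of one INFO value; None if absent or non-numeric."""
        raw = self.info.get(key)
        if raw is None:
            return None
        try:
            return float(raw)
        except ValueError:
            return None

    def to_line(self) -> str:
        """Serialize back to a VCF data line (tab-joined)."""
        info_str = (
            ";".join(k if v is None else f"{k}={v}" for k, v in self.info.items())
            if self.info
            else MISSING
        )
        filt_str = ";".join(self.filters) if self.filters else MISSING
        cols = [
            self.chrom,
            str(self.pos),
            self.id,
            self.ref,
            ",".join(self.alts) if self.alts else MISSING,
            self.qual,
            filt_str,
            info_str,
        ]
        if self.format_keys:
            cols.append(":".join(self.format_keys))
            for sample in self.samples:
                cols.append(":".join(sample.get(k, MISSING) for k in self.format_keys))
        return "\t".join(cols)


@dataclass
class VcfHeader:
    """Meta lines (##...) plus the sample-name tail of the #CHROM line."""

    meta_lines: list[str] = field(default_factory=list)
    sample_names: list[str] = field(default_factory=list)

    @property
    def filter_ids(self) -> set[str]:
        ids = set()
        for line in self.meta_lines:
            if line.startswith("##FILTER=<ID="):
                ids.add(line[len("##FILTER=<ID=") :].split(",", 1)[0].rstrip(">"))
        return ids

    def column_line(self) -> str:
        cols = list(FIXED_COLUMNS)
        if self.sample_names:
            cols.append("FORMAT")
            cols.extend(self.sample_names)
        return "\t".join(cols)

    def with_filter_declared(self, filter_id: str, meta_line: str) -> "VcfHeader":
        """Copy of the header guaranteed to declare ``filter_id``."""
        if filter_id in self.filter_ids:
            return self
        return VcfHeader(self.meta_lines + [meta_line], list(self.sample_names))

    def with_info_declared(self, info_id: str, meta_line: str) -> "VcfHeader":
        declared = any(
            line.startswith(f"##INFO=<ID={info_id},") for line in self.meta_lines
        )
        if declared:
            return self
        return VcfHeader(self.meta_lines + [meta_line], list(self.sample_names))


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":  # gzip/bgzip
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_data_line(line: str, line_number: int | None = None) -> VariantRecord:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 8:
        raise VcfFormatError(
            f"data line has {len(cols)} columns, expected >= 8", line_number
        )
    chrom, pos_s, rid, ref, alt_s, qual, filt_s, info_s = cols[:8]
    try:
        pos = int(pos_s)
    except ValueError:
        raise VcfFormatError(f"non-integer POS {pos_s!r}", line_number) from None
    filters = [] if filt_s in (MISSING, "") else filt_s.split(";")
    info: dict[str, str | None] = {}
    if info_s not in (MISSING, ""):
        for item in info_s.split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                info[k] = v
            else:
                info[item] = None  # flag
    format_keys: list[str] = []
    samples: list[dict[str, str]] = []
    if len(cols) > 8:
        format_keys = cols[8].split(":")
        for sample_col in cols[9:]:
            values = sample_col.split(":")
            samples.append(dict(zip(format_keys, values)))
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        id=rid,
        ref=ref,
        alts=alt_s.split(",") if alt_s else [MISSING],
        qual=qual,
        filters=filters,
        info=info,
        format_keys=format_keys,
        samples=samples,
    )


def read_vcf(path: str | Path) -> tuple[VcfHeader, Iterator[VariantRecord]]:
    """Parse a VCF file into a header and a record iterator.

    The header is consumed eagerly (up to and including the #CHROM line);
    records stream lazily in file order. Raises :class:`VcfFormatError`
    when the #CHROM line is missing or a data line is short.
    """
    fh = _open_text(path)
    meta_lines: list[str] = []
    sample_names: list[str] = []
    header_seen = False
    line_number = 0
    for line in fh:
        line_number += 1
        line = line.rstrip("\n")
        if line.startswith("##"):
            meta_lines.append(line)
        elif line.startswith("#CHROM"):
            cols = line.split("\t")
            if len(cols) > 9:
                sample_names = cols[9:]
            header_seen = True
            break
        else:
            fh.close()
            raise VcfFormatError(
                "encountered data before #CHROM header line", line_number
            )
    if not header_seen:
        fh.close()
        raise VcfFormatError("no #CHROM header line found")
    header = VcfHeader(meta_lines=meta_lines, sample_names=sample_names)

    def _records() -> Iterator[VariantRecord]:
        n = line_number
        with fh:
            for raw in fh:
                n += 1
                if not raw.strip():
                    continue
                yield parse_data_line(raw, n)

    return header, _records()


def write_vcf(
    header: VcfHeader,
    records: Iterable[VariantRecord],
    path: str | Path,
    bgzip: bool = False,
) -> int:
    """Write a VCF; returns the number of data lines written.

    Raises ValueError when a record's sample count disagrees with the
    header's sample names.
    """
    n_samples = len(header.sample_names)
    opener = gzip.open if bgzip else open
    n = 0
    with opener(path, "wt") as out:
        for line in header.meta_lines:
            out.write(line + "\n")
        out.write(header.column_line() + "\n")
        for rec in records:
            if rec.samples and len(rec.samples) != n_samples:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} has {len(rec.samples)} sample "
                    f"columns but header declares {n_samples}"
                )
            out.write(rec.to_line() + "\n")
            n += 1
    return n


def update_filter(record: VariantRecord, decision: str) -> VariantRecord:
    """Write a PASS/FAIL decision into FILTER, preserving caller annotations.

    The decision becomes the first FILTER entry. Pre-existing entries other
    than PASS, FAIL and '.' are kept after it; a prior lone PASS (or '.')
    carries no information to preserve and is replaced. PASS never
    co-occurs with another PASS, and re-applying the same decision is a
    no-op, so refinement is idempotent.
    """
    if decision not in (PASS, FAIL):
        raise ValueError(f"decision must be PASS or FAIL, got {decision!r}")
    preserved = [f for f in record.filters if f not in (PASS, FAIL, MISSING)]
    return replace(record, filters=[decision] + preserved)
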