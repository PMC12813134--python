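"""Variant-record "sentence" encoding and the domain vocabulary.

Each variant record is flattened into a whitespace-separated token
string — the sentence the classifier consumes. Locus identity (CHROM,
POS, ID, REF, ALT) is excluded by construction: two records differing
only in where they sit on the genome produce identical sentences. What
remains is the evidence the caller attached to the call — QUAL, the
INFO annotations, and (for single-sample files) the FORMAT fields.

Tokens are whole key=value pairs ("DP=10", "MQ=60.0"), one per
annotation. Float values are canonicalized to a fixed decimal precision
before tokenization so the vocabulary stays bounded; integers and
non-numeric strings pass through verbatim. INFO flags become bare-key
tokens.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .vcf_io import MISSING, VariantRecord

PAD_TOKEN = "[PAD]"
UNK_TOKEN = "[UNK]"
START_TOKEN = "[START]"
SEP_TOKEN = "[SEP]"
SPECIAL_TOKENS = (PAD_TOKEN, UNK_TOKEN, START_TOKEN, SEP_TOKEN)

MISSING_VALUE_TOKEN = "<MISSING>"

QUAL_FIELD = "QUAL"
INFO_FIELD = "INFO"
FORMAT_FIELD = "FORMAT"


@dataclass(frozen=True)
class EncodingConfig:
    """Controls which record fields become tokens and how values are shaped.

    max_sequence_length caps the token-id sequence (sequence-start token
    included); numeric_precision is the decimal places kept for float
    values; fields_included is the ordered field groups serialized;
    drop_info_keys removes bookkeeping tags (e.g. a probability tag
    written by a previous refinement pass) before encoding.
    """

    max_sequence_length: int = 64
    numeric_precision: int = 2
    fields_included: tuple[str, ...] = (QUAL_FIELD, INFO_FIELD, FORMAT_FIELD)
    drop_info_keys: frozenset[str] = frozenset({"PASS_PROB"})

    def __post_init__(self) -> None:
        if self.max_sequence_length < 8:
            raise ValueError("max_sequence_length must be >= 8")
        if self.numeric_precision < 0:
            raise ValueError("numeric_precision must be >= 0")
        unknown = set(self.fields_included) - {QUAL_FIELD, INFO_FIELD, FORMAT_FIELD}
        if unknown:
            raise ValueError(f"unknown field groups: {sorted(unknown)}")


@dataclass
class Sentence:
    """Tokenized text form of one record plus its (optional) label."""

    text: str
    label: str | None = None
    source_index: int = 0

    @property
    def tokens(self) -> list[str]:
        return self.text.split()


def canonical_value(raw: str, precision: int) -> str:
    """Canonicalize one value string: ints verbatim, floats rounded."""
    if raw == "" or raw == MISSING:
        return MISSING_VALUE_TOKEN
    try:
        int(raw)
        return raw
    except ValueError:
        pass
    try:
        return str(round(float(raw), precision))
    except (ValueError, OverflowError):
        return raw


def record_to_sentence(
    record: VariantRecord,
    cfg: EncodingConfig = EncodingConfig(),
    label: str | None = None,
    source_index: int = 0,
) -> Sentence:
    """Flatten a record into its sentence.

    Field order is fixed (QUAL, then INFO in source order, then
    FORMAT/sample values), so identical inputs give identical sentences.
    A missing QUAL yields the dedicated missing-value token.
    """
    tokens: list[str] = []
    for group in cfg.fields_included:
        if group == QUAL_FIELD:
            tokens.append(f"QUAL={canonical_value(record.qual, cfg.numeric_precision)}")
        elif group == INFO_FIELD:
            for key, value in record.info.items():
                if key in cfg.drop_info_keys:
                    continue
                if value is None:  # flag
                    tokens.append(key)
                else:
                    tokens.append(f"{key}={canonical_value(value, cfg.numeric_precision)}")
        elif group == FORMAT_FIELD:
            for sample in record.samples:
                for key in record.format_keys:
                    value = sample.get(key, MISSING)
                    tokens.append(f"{key}={canonical_value(value, cfg.numeric_precision)}")
    return Sentence(text=" ".join(tokens), label=label, source_index=source_index)


class Vocabulary:
    """Token <-> id map with fixed special tokens.

    Ids 0..3 are PAD, UNK, START, SEP in that order; corpus tokens
    follow. Once frozen, out-of-vocabulary tokens map to UNK (they do in
    any case at tokenization time — freezing only documents intent and
    blocks accidental in-place growth).
    """

    def __init__(self, tokens: Sequence[str] = (), frozen: bool = False):
        self._id_to_token: list[str] = list(SPECIAL_TOKENS)
        self._token_to_id: dict[str, int] = {
            t: i for i, t in enumerate(self._id_to_token)
        }
        for tok in tokens:
            self._append(tok)
        self.frozen = frozen

    def _append(self, token: str) -> None:
        if token not in self._token_to_id:
            self._token_to_id[token] = len(self._id_to_token)
            self._id_to_token.append(token)

    def __len__(self) -> int:
        return len(self._id_to_token)

    def __contains__(self, token: str) -> bool:
        return token in self._token_to_id

    @property
    def pad_id(self) -> int:
        return self._token_to_id[PAD_TOKEN]

    @property
    def unk_id(self) -> int:
        return self._token_to_id[UNK_TOKEN]

    @property
    def start_id(self) -> int:
        return self._token_to_id[START_TOKEN]

    @property
    def sep_id(self) -> int:
        return self._token_to_id[SEP_TOKEN]

    def id_of(self, token: str) -> int:
        return self._token_to_id.get(token, self.unk_id)

    def token_of(self, idx: int) -> str:
        return self._id_to_token[idx]

    @property
    def token_to_id(self) -> dict[str, int]:
        return dict(self._token_to_id)

    def fingerprint(self) -> str:
        """Stable checksum binding trained models to this vocabulary."""
        digest = hashlib.sha256("\n".join(self._id_to_token).encode()).hexdigest()
        return digest[:16]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#vqrefine-vocabulary\tv1\n")
            fh.write("#specials\t" + "\t".join(SPECIAL_TOKENS) + "\n")
            for token in self._id_to_token:
                fh.write(token + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        with open(path) as fh:
            magic = fh.readline()
            if not magic.startswith("#vqrefine-vocabulary"):
                raise ValueError(f"{path} is not a vocabulary file")
            fh.readline()  # specials line, fixed by format version
            tokens = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
        if tokens[: len(SPECIAL_TOKENS)] != list(SPECIAL_TOKENS):
            raise ValueError("vocabulary file missing special-token prefix")
        return cls(tokens[len(SPECIAL_TOKENS) :], frozen=True)


def _ordered_by_frequency(counts: Counter) -> list[str]:
    # frequency descending, then lexicographic: deterministic across runs
    return sorted(counts, key=lambda t: (-counts[t], t))


def build_vocabulary(
    sentences: Iterable[Sentence], min_count: int = 1
) -> Vocabulary:
    """Build the vocabulary from a sentence corpus.

    Contains the special tokens plus every corpus token with frequency
    >= min_count, ordered by descending frequency then lexicographically.
    Raises on an empty corpus.
    """
    counts: Counter = Counter()
    n = 0
    for sent in sentences:
        n += 1
        counts.update(sent.tokens)
    if n == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    kept = Counter({t: c for t, c in counts.items() if c >= min_count})
    return Vocabulary(_ordered_by_frequency(kept))


def extend_vocabulary(
    vocab: Vocabulary, new_sentences: Iterable[Sentence], min_count: int = 1
) -> Vocabulary:
    """New vocabulary with unseen tokens appended; existing ids unchanged.

    This is the cross-caller adaptation hook: a model trained on one
    caller dialect keeps its token ids while the new dialect's INFO
    tokens get fresh ids at the end.
    """
    counts: Counter = Counter()
    for sent in new_sentences:
        counts.update(t for t in sent.tokens if t not in vocab)
    kept = Counter({t: c for t, c in counts.items() if c >= min_count})
    extended = Vocabulary(vocab._id_to_token[len(SPECIAL_TOKENS) :])
    for token in _ordered_by_frequency(kept):
        extended._append(token)
    return extended


def tokenize(
    sentence: Sentence,
    vocab: Vocabulary,
    cfg: EncodingConfig = EncodingConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Token-id sequence and attention mask for one sentence.

    The sequence-start id comes first; token ids follow (UNK for
    out-of-vocabulary); the result is truncated then padded to
    max_sequence_length. The mask is 1 on real tokens, 0 on padding.
    """
    ids = [vocab.start_id] + [vocab.id_of(t) for t in sentence.tokens]
    ids = ids[: cfg.max_sequence_length]
    mask = [1] * len(ids)
    while len(ids) < cfg.max_sequence_length:
        ids.append(vocab.pad_id)
        mask.append(0)
    return np.asarray(ids, dtype=np.int64), np.asarray(mask, dtype=np.int64)


def detokenize(ids: Sequence[int], vocab: Vocabulary) -> str:
    """Inverse of tokenize modulo padding: the token string."""
    tokens = []
    for idx in ids:
        tok = vocab.token_of(int(idx))
        if tok in (PAD_TOKEN, START_TOKEN):
            continue
        tokens.append(tok)
    return " ".join(tokens)


def encode_corpus(
    sentences: Sequence[Sentence],
    vocab: Vocabulary,
    cfg: EncodingConfig = EncodingConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Stack (ids, mask) over a corpus: arrays of shape (n, max_len)."""
    if not sentences:
        empty = np.empty((0, cfg.max_sequence_length), dtype=np.int64)
        return empty, empty.copy()
    ids = np.empty((len(sentences), cfg.max_sequence_length), dtype=np.int64)
    mask = np.empty_like(ids)
    for i, sent in enumerate(sentences):
        ids[i], mask[i] = tokenize(sent, vocab, cfg)
    return ids, mask
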