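"""Self-attention PASS/FAIL sequence classifier: model, results, selection.

The central object is :class:`SentenceClassifier`, a model built from a
labeled sentence corpus plus its vocabulary, in the model/results idiom:
``fit()`` runs fixed-epoch AdamW training and returns a
:class:`ClassifierResults` carrying the learned weights, the per-epoch
training log (train loss, validation accuracy and ROC AUC), and
prediction/serialization methods. ``summary()`` prints the fit like a
regression table.

The encoder honors a fixed contract — token embedding + learned
positional embedding, pre-norm multi-head self-attention blocks,
first-token pooling, 2-way softmax head — and is deliberately
backbone-minimal: the published full-scale configuration (12-layer
class, batch 1,300, 21 epochs) and the desk-scale default (2 layers, 2
heads, hidden 64) are both just :class:`ModelConfig` instances.

Module-level :func:`train`, :func:`predict_proba` and
:func:`grid_search` are thin functional wrappers over the same objects.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _transformer as T
from .encoding import EncodingConfig, Sentence, Vocabulary, encode_corpus
from .metrics import roc_auc
from .vcf_io import FAIL, PASS

CHECKPOINT_VERSION = 1


class VocabularyMismatchError(RuntimeError):
    """A trained model was handed a vocabulary it was not trained with."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the encoder and its training loop.

    Defaults are the desk-scale configuration; the full-scale published
    settings (learning rate 5e-5..1e-4, batch 600-1,300, 6-12 heads,
    6-12 layers, 21 epochs) are expressible with the same fields.
    """

    hidden_size: int = 64
    num_layers: int = 2
    num_heads: int = 2
    feedforward_size: int = 128
    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 10
    seed: int = 0
    max_sequence_length: int = 64
    weight_decay: float = 0.01
    class_weighted: bool = False

    def __post_init__(self) -> None:
        if self.hidden_size % self.num_heads != 0:
            raise ValueError(
                f"hidden_size ({self.hidden_size}) must be divisible by "
                f"num_heads ({self.num_heads})"
            )
        for name in ("hidden_size", "num_layers", "num_heads", "feedforward_size",
                     "batch_size", "max_sequence_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 0:  # 0 = untrained baseline (random init)
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation split policy: fraction, optional subsample, seed."""

    train_fraction: float = 0.60
    subsample_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def make_split(
    sentences: Sequence[Sentence], spec: SplitSpec
) -> tuple[list[Sentence], list[Sentence]]:
    """Disjoint, exhaustive train/validation split of the (optionally
    subsampled) corpus; train size is floor(fraction * n)."""
    n = len(sentences)
    if n < 2:
        raise ValueError(f"corpus of {n} sentences is too small to split")
    rng = np.random.default_rng(spec.seed)
    idx = np.arange(n)
    if spec.subsample_size is not None and spec.subsample_size < n:
        idx = rng.choice(idx, size=spec.subsample_size, replace=False)
    perm = rng.permutation(idx)
    n_train = int(np.floor(spec.train_fraction * len(perm)))
    train = [sentences[i] for i in perm[:n_train]]
    val = [sentences[i] for i in perm[n_train:]]
    return train, val


def _labels_to_array(sentences: Sequence[Sentence]) -> np.ndarray:
    labels = np.empty(len(sentences), dtype=np.int64)
    for i, s in enumerate(sentences):
        if s.label not in (PASS, FAIL):
            raise ValueError(f"sentence {i} has no PASS/FAIL label")
        labels[i] = 1 if s.label == PASS else 0
    return labels


class SentenceClassifier:
    """Model object: a labeled corpus, its vocabulary, and a config.

    ``fit()`` trains for the configured fixed number of epochs (no early
    stopping) and returns :class:`ClassifierResults`. Training is
    reproducible: same corpus, config and seed give an identical log.
    """

    def __init__(
        self,
        train_sentences: Sequence[Sentence],
        val_sentences: Sequence[Sentence],
        vocab: Vocabulary,
        config: ModelConfig = ModelConfig(),
        encoding: EncodingConfig | None = None,
    ):
        self.config = config
        self.vocab = vocab
        self.encoding = encoding or EncodingConfig(
            max_sequence_length=config.max_sequence_length
        )
        if self.encoding.max_sequence_length != config.max_sequence_length:
            raise ValueError("encoding and model max_sequence_length disagree")
        self.train_ids, self.train_mask = encode_corpus(
            train_sentences, vocab, self.encoding
        )
        self.val_ids, self.val_mask = encode_corpus(val_sentences, vocab, self.encoding)
        self.train_labels = _labels_to_array(train_sentences)
        self.val_labels = _labels_to_array(val_sentences)
        if self.train_ids.max(initial=0) >= len(vocab):
            raise ValueError("token id exceeds vocabulary size")

    def fit(self, verbose: bool = False) -> "ClassifierResults":
        cfg = self.config
        params = T.init_params(
            vocab_size=len(self.vocab),
            max_len=cfg.max_sequence_length,
            hidden=cfg.hidden_size,
            layers=cfg.num_layers,
            heads=cfg.num_heads,
            ff=cfg.feedforward_size,
            seed=cfg.seed,
        )
        opt = T.AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        rng = np.random.default_rng(cfg.seed + 1)
        class_weights = None
        if cfg.class_weighted:
            n = len(self.train_labels)
            n_pos = max(int(self.train_labels.sum()), 1)
            n_neg = max(n - n_pos, 1)
            class_weights = np.array([n / (2.0 * n_neg), n / (2.0 * n_pos)])

        def _validate(entry: dict) -> dict:
            if len(self.val_labels):
                probs = _predict_ids(params, cfg, self.val_ids, self.val_mask)
                preds = probs >= 0.5
                entry["val_accuracy"] = float((preds == self.val_labels).mean())
                str_labels = [PASS if y else FAIL for y in self.val_labels]
                entry["val_roc_auc"] = roc_auc(str_labels, probs)
            return entry

        log: list[dict] = []
        n = self.train_ids.shape[0]
        if cfg.epochs == 0:  # untrained baseline: log the random-init state
            log.append(_validate({"epoch": 0, "train_loss": float("nan")}))
        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                loss, grads = T.loss_and_grads(
                    params,
                    self.train_ids[sel],
                    self.train_mask[sel],
                    self.train_labels[sel],
                    cfg.num_layers,
                    cfg.num_heads,
                    class_weights=class_weights,
                )
                opt.step(params, grads)
                losses.append(loss)
            entry = _validate({"epoch": epoch, "train_loss": float(np.mean(losses))})
            log.append(entry)
            if verbose:
                print(
                    "epoch {epoch}: loss={train_loss:.4f}".format(**entry)
                    + (
                        " val_acc={val_accuracy:.4f} val_auc={val_roc_auc:.4f}".format(**entry)
                        if "val_accuracy" in entry
                        else ""
                    )
                )
        return ClassifierResults(
            params=params,
            config=cfg,
            encoding=self.encoding,
            vocab_fingerprint=self.vocab.fingerprint(),
            training_log=log,
        )


def _predict_ids(
    params: dict[str, np.ndarray],
    cfg: ModelConfig,
    ids: np.ndarray,
    mask: np.ndarray,
    batch_size: int = 10_000,
) -> np.ndarray:
    """PASS probabilities for pre-encoded id/mask arrays, batched.

    batch_size is the caller-facing partition; the forward pass always
    runs in small internal chunks because attention scores scale as
    O(batch * heads * length^2) and would dominate memory otherwise.
    Each record's forward pass is independent, so chunking never
    changes the probabilities beyond float round-off.
    """
    chunk = min(batch_size, 256)
    out = np.empty(ids.shape[0])
    for start in range(0, ids.shape[0], chunk):
        sl = slice(start, start + chunk)
        logits = T.forward(params, ids[sl], mask[sl], cfg.num_layers, cfg.num_heads)
        out[sl] = T.softmax(logits, axis=-1)[:, 1]
    return out


@dataclass
class ClassifierResults:
    """Fitted classifier: weights, config, log, and prediction methods."""

    params: dict[str, np.ndarray]
    config: ModelConfig
    encoding: EncodingConfig
    vocab_fingerprint: str
    training_log: list[dict] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return T.n_params(self.params)

    @property
    def final_val_auc(self) -> float:
        if not self.training_log or "val_roc_auc" not in self.training_log[-1]:
            return float("nan")
        return self.training_log[-1]["val_roc_auc"]

    def _check_vocab(self, vocab: Vocabulary) -> None:
        if vocab.fingerprint() != self.vocab_fingerprint:
            raise VocabularyMismatchError(
                f"model was trained with vocabulary {self.vocab_fingerprint}, "
                f"got {vocab.fingerprint()}"
            )

    def predict_proba(
        self,
        sentences: Sequence[Sentence],
        vocab: Vocabulary,
        batch_size: int = 10_000,
    ) -> np.ndarray:
        """Per-record PASS probability, order-preserving, batched.

        Fails fast when the supplied vocabulary does not match the one
        the model was trained with. The batch partition never changes
        the result beyond floating-point round-off.
        """
        self._check_vocab(vocab)
        ids, mask = encode_corpus(sentences, vocab, self.encoding)
        return _predict_ids(self.params, self.config, ids, mask, batch_size)

    def decide_labels(
        self,
        sentences: Sequence[Sentence],
        vocab: Vocabulary,
        threshold: float = 0.5,
        batch_size: int = 10_000,
    ) -> list[str]:
        probs = self.predict_proba(sentences, vocab, batch_size)
        return [decide(p, threshold) for p in probs]

    def summary(self) -> str:
        cfg = self.config
        buf = io.StringIO()
        w = buf.write
        w("Self-attention PASS/FAIL classifier — fit summary\n")
        w("=" * 52 + "\n")
        w(f"{'encoder layers':<28}{cfg.num_layers}\n")
        w(f"{'attention heads':<28}{cfg.num_heads}\n")
        w(f"{'hidden size':<28}{cfg.hidden_size}\n")
        w(f"{'feed-forward size':<28}{cfg.feedforward_size}\n")
        w(f"{'parameters':<28}{self.n_params:,}\n")
        w(f"{'optimizer':<28}AdamW (lr={cfg.learning_rate}, wd={cfg.weight_decay})\n")
        w(f"{'batch size':<28}{cfg.batch_size}\n")
        w(f"{'epochs':<28}{cfg.epochs}\n")
        w(f"{'seed':<28}{cfg.seed}\n")
        w(f"{'vocabulary fingerprint':<28}{self.vocab_fingerprint}\n")
        w("-" * 52 + "\n")
        w(f"{'epoch':>5} {'train loss':>12} {'val acc':>9} {'val AUC':>9}\n")
        for e in self.training_log:
            acc = e.get("val_accuracy")
            auc = e.get("val_roc_auc")
            w(
                f"{e['epoch']:>5} {e['train_loss']:>12.4f} "
                f"{acc if acc is not None else float('nan'):>9.4f} "
                f"{auc if auc is not None else float('nan'):>9.4f}\n"
            )
        return buf.getvalue()

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: weights + config + vocab fingerprint."""
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "encoding": {
                "max_sequence_length": self.encoding.max_sequence_length,
                "numeric_precision": self.encoding.numeric_precision,
                "fields_included": list(self.encoding.fields_included),
                "drop_info_keys": sorted(self.encoding.drop_info_keys),
            },
            "vocab_fingerprint": self.vocab_fingerprint,
            "training_log": self.training_log,
        }
        arrays = {f"param::{k}": v for k, v in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(
        cls, path: str | Path, vocab: Vocabulary | None = None
    ) -> "ClassifierResults":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            params = {
                k[len("param::") :]: npz[k] for k in npz.files if k.startswith("param::")
            }
        enc = meta["encoding"]
        results = cls(
            params=params,
            config=ModelConfig(**meta["config"]),
            encoding=EncodingConfig(
                max_sequence_length=enc["max_sequence_length"],
                numeric_precision=enc["numeric_precision"],
                fields_included=tuple(enc["fields_included"]),
                drop_info_keys=frozenset(enc["drop_info_keys"]),
            ),
            vocab_fingerprint=meta["vocab_fingerprint"],
            training_log=meta["training_log"],
        )
        if vocab is not None:
            results._check_vocab(vocab)
        return results


def decide(probability: float, threshold: float = 0.5) -> str:
    """PASS iff probability >= threshold (boundary counts as PASS)."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"probability {probability} outside [0, 1]")
    return PASS if probability >= threshold else FAIL


def train(
    train_sentences: Sequence[Sentence],
    val_sentences: Sequence[Sentence],
    vocab: Vocabulary,
    config: ModelConfig = ModelConfig(),
    encoding: EncodingConfig | None = None,
    verbose: bool = False,
) -> ClassifierResults:
    """Functional wrapper: build the model object and fit it."""
    model = SentenceClassifier(train_sentences, val_sentences, vocab, config, encoding)
    return model.fit(verbose=verbose)


def predict_proba(
    results: ClassifierResults,
    sentences: Sequence[Sentence],
    vocab: Vocabulary,
    batch_size: int = 10_000,
) -> np.ndarray:
    return results.predict_proba(sentences, vocab, batch_size)


def grid_search(
    train_sentences: Sequence[Sentence],
    val_sentences: Sequence[Sentence],
    vocab: Vocabulary,
    candidates: Sequence[ModelConfig],
    encoding: EncodingConfig | None = None,
    seed: int | None = None,
    verbose: bool = False,
) -> tuple[ModelConfig, list[dict]]:
    """Train every candidate under an identical seed policy and pick the
    one with the highest final validation ROC AUC.

    Ties break toward fewer parameters, then candidate order. Returns
    (best config, leaderboard) where the leaderboard has one entry per
    candidate with its AUC, accuracy and parameter count.
    """
    if not candidates:
        raise ValueError("grid_search needs at least one candidate config")
    leaderboard: list[dict] = []
    for i, cand in enumerate(candidates):
        cfg = cand if seed is None else replace(cand, seed=seed)
        results = train(train_sentences, val_sentences, vocab, cfg, encoding)
        last = results.training_log[-1] if results.training_log else {}
        leaderboard.append(
            {
                "index": i,
                "config": cfg,
                "val_roc_auc": last.get("val_roc_auc", float("nan")),
                "val_accuracy": last.get("val_accuracy", float("nan")),
                "n_params": results.n_params,
            }
        )
        if verbose:
            print(f"candidate {i}: AUC={leaderboard[-1]['val_roc_auc']:.4f}")
    best = max(
        leaderboard, key=lambda e: (e["val_roc_auc"], -e["n_params"], -e["index"])
    )
    return best["config"], leaderboard
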