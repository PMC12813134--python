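"""Synthetic caller-dialect callsets with planted, learnable PASS/FAIL structure.

The generator emulates the two reference caller dialects — a GATK4-style
callset (INFO keys QD, FS, MQ, SOR, MQRankSum, ReadPosRankSum, DP) and a
BCFTools-style one (DP, MQ, with QUAL carrying most of the signal) — and
the paired truth set used for position-based labeling.

The planted structure is a two-component feature model: each record is
planted true with probability ``truth_overlap_fraction`` (true records'
positions go into the truth VCF), and its quality annotations are drawn
from a "true variant" distribution or a "technical artifact"
distribution. Label noise swaps the feature component with a fixed
probability, so the best achievable (Bayes) accuracy of any classifier
that sees only the features is 1 - noise_rate when the components are
well separated; :func:`feature_separability` estimates it for any
setting by Monte Carlo on the generative densities.

The artifact component deliberately sits inside the firing region of
the GATK4 default hard filters, so heuristic baselines behave sensibly
on generated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .vcf_io import MISSING, VariantRecord, VcfHeader, write_vcf

#: per-dialect feature model: key -> (true_mean, true_sd, artifact_mean,
#: artifact_sd, integer-valued?)
_GATK4_FEATURES: dict[str, tuple[float, float, float, float, bool]] = {
    "QD": (20.0, 3.0, 1.0, 0.5, False),
    "FS": (2.0, 1.0, 90.0, 15.0, False),
    "MQ": (60.0, 1.5, 28.0, 5.0, False),
    "SOR": (1.0, 0.3, 5.5, 0.8, False),
    "MQRankSum": (0.0, 1.0, -14.0, 1.5, False),
    "ReadPosRankSum": (0.0, 1.0, -9.5, 1.0, False),
    "DP": (12.0, 3.0, 5.0, 2.0, True),
}
_BCFTOOLS_FEATURES: dict[str, tuple[float, float, float, float, bool]] = {
    "DP": (12.0, 3.0, 5.0, 2.0, True),
    "MQ": (59.0, 2.0, 30.0, 6.0, False),
}
#: QUAL per dialect (true_mean, true_sd, artifact_mean, artifact_sd)
_QUAL_MODEL: dict[str, tuple[float, float, float, float]] = {
    "gatk4": (150.0, 40.0, 10.0, 6.0),
    "bcftools": (140.0, 35.0, 8.0, 4.0),
}

_INFO_META = {
    "QD": '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant confidence by depth">',
    "FS": '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (phred)">',
    "MQ": '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    "SOR": '##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric odds ratio strand bias">',
    "MQRankSum": '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">',
    "ReadPosRankSum": '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
    "DP": '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SignalModel:
    """Planted rule parameters: how separable the two components are.

    noise_rate is the probability that a record's features are drawn
    from the opposite component (the label stays tied to truth-set
    membership), so it is the irreducible error floor. separation
    linearly scales the distance between component means (1.0 = the
    defaults above; 0.0 = identical components, no learnable signal).
    """

    noise_rate: float = 0.0
    separation: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    n_records: int = 1000
    dialect: str = "gatk4"
    truth_overlap_fraction: float = 0.8
    signal_model: SignalModel = SignalModel()
    seed: int = 0
    contigs: tuple[tuple[str, int], ...] = (("chr1", 10_000_000),)

    def __post_init__(self) -> None:
        if self.dialect not in ("gatk4", "bcftools"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if not 0.0 <= self.truth_overlap_fraction <= 1.0:
            raise ValueError("truth_overlap_fraction must be in [0, 1]")
        if self.n_records < 0:
            raise ValueError("n_records must be >= 0")

    @property
    def feature_model(self) -> dict[str, tuple[float, float, float, float, bool]]:
        return _GATK4_FEATURES if self.dialect == "gatk4" else _BCFTOOLS_FEATURES


def _component_params(
    cfg: SimulationConfig,
) -> list[tuple[str, float, float, float, float, bool]]:
    """(name, mean_true, sd, mean_artifact, sd, is_int) with separation
    applied by shrinking both means toward their midpoint."""
    out = []
    entries = [(k, *v) for k, v in cfg.feature_model.items()]
    qt_m, qt_s, qa_m, qa_s = _QUAL_MODEL[cfg.dialect]
    entries.append(("QUAL", qt_m, qt_s, qa_m, qa_s, False))
    # separation scales both the mean gap and the sd contrast, so s=0
    # gives literally identical components (no learnable signal)
    s = cfg.signal_model.separation
    for name, mt, st, ma, sa, is_int in entries:
        mid = 0.5 * (mt + ma)
        mid_sd = 0.5 * (st + sa)
        out.append(
            (name,
             mid + s * (mt - mid), mid_sd + s * (st - mid_sd),
             mid + s * (ma - mid), mid_sd + s * (sa - mid_sd),
             is_int)
        )
    return out


@dataclass
class SimulatedCallset:
    """In-memory query/truth pair plus the planted labels ("PASS"/"FAIL")."""

    query_header: VcfHeader
    query_records: list[VariantRecord]
    truth_header: VcfHeader
    truth_records: list[VariantRecord]
    labels: list[str]
    config: SimulationConfig

    @property
    def n_planted_true(self) -> int:
        return sum(1 for l in self.labels if l == "PASS")

    def write(
        self,
        query_path: str | Path,
        truth_path: str | Path,
        labels_path: str | Path | None = None,
    ) -> None:
        write_vcf(self.query_header, self.query_records, query_path)
        write_vcf(self.truth_header, self.truth_records, truth_path)
        if labels_path is not None:
            with open(labels_path, "w") as fh:
                fh.write("chrom\tpos\tlabel\n")
                for rec, label in zip(self.query_records, self.labels):
                    fh.write(f"{rec.chrom}\t{rec.pos}\t{label}\n")


def _header(cfg: SimulationConfig, truth: bool) -> VcfHeader:
    meta = ["##fileformat=VCFv4.2", f"##source=vqrefine-simulate-{cfg.dialect}"]
    meta += [f"##contig=<ID={name},length={length}>" for name, length in cfg.contigs]
    if not truth:
        meta += [_INFO_META[k] for k in cfg.feature_model]
        meta += [
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Sample depth">',
        ]
        return VcfHeader(meta_lines=meta, sample_names=["SAMPLE"])
    return VcfHeader(meta_lines=meta, sample_names=[])


def simulate_callset(cfg: SimulationConfig) -> SimulatedCallset:
    """Generate the query/truth pair; deterministic for a fixed config."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_records

    # distinct sorted positions per contig, allocated proportionally
    lengths = np.array([l for _, l in cfg.contigs], dtype=float)
    counts = rng.multinomial(n, lengths / lengths.sum()) if n else np.zeros(
        len(cfg.contigs), dtype=int
    )
    for (name, length), k in zip(cfg.contigs, counts):
        if k > length:
            raise ValueError(
                f"contig {name} (length {length}) cannot host {k} distinct positions"
            )
    sites: list[tuple[str, int]] = []
    for (name, length), k in zip(cfg.contigs, counts):
        pos = np.sort(rng.choice(length, size=int(k), replace=False)) + 1
        sites.extend((name, int(p)) for p in pos)

    planted_true = rng.random(n) < cfg.truth_overlap_fraction
    flip = rng.random(n) < cfg.signal_model.noise_rate
    feature_component = planted_true ^ flip  # True -> "true variant" features

    features = _component_params(cfg)
    values: dict[str, np.ndarray] = {}
    for name, mt, st, ma, sa, is_int in features:
        mean = np.where(feature_component, mt, ma)
        sd = np.where(feature_component, st, sa)
        draw = rng.normal(mean, sd)
        if name in ("FS", "SOR", "QUAL"):
            draw = np.clip(draw, 0.0, None)
        if name == "DP" or is_int:
            draw = np.clip(np.rint(draw), 1, None)
        values[name] = draw

    ref = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    gt = np.where(rng.random(n) < 0.6, "0/1", "1/1")

    info_keys = list(cfg.feature_model)
    records: list[VariantRecord] = []
    labels: list[str] = []
    truth_records: list[VariantRecord] = []
    for i, (chrom, pos) in enumerate(sites):
        info: dict[str, str | None] = {}
        for key in info_keys:
            v = values[key][i]
            info[key] = str(int(v)) if cfg.feature_model[key][4] else f"{v:.2f}"
        dp_str = info.get("DP", str(int(values["DP"][i])) if "DP" in values else "10")
        rec = VariantRecord(
            chrom=chrom,
            pos=pos,
            id=MISSING,
            ref=str(_BASES[ref[i]]),
            alts=[str(_BASES[(ref[i] + alt_shift[i]) % 4])],
            qual=f"{values['QUAL'][i]:.2f}",
            filters=[],
            info=info,
            format_keys=["GT", "DP"],
            samples=[{"GT": str(gt[i]), "DP": dp_str}],
        )
        records.append(rec)
        label = "PASS" if planted_true[i] else "FAIL"
        labels.append(label)
        if planted_true[i]:
            truth_records.append(
                VariantRecord(
                    chrom=chrom, pos=pos, id=MISSING, ref=rec.ref,
                    alts=list(rec.alts), qual=MISSING, filters=["PASS"], info={},
                )
            )
    return SimulatedCallset(
        query_header=_header(cfg, truth=False),
        query_records=records,
        truth_header=_header(cfg, truth=True),
        truth_records=truth_records,
        labels=labels,
        config=cfg,
    )


def feature_separability(
    cfg: SimulationConfig, n_mc: int = 50_000, seed: int | None = None
) -> float:
    """Monte-Carlo estimate of the planted rule's Bayes accuracy.

    Draws synthetic records from the generative model and scores them
    with the exact posterior P(true | features) under the unclipped
    Gaussian densities; the achievable accuracy is the hit rate of the
    posterior-argmax decision. For well-separated components this
    approaches 1 - noise_rate; for separation 0 it collapses to
    max(overlap, 1 - overlap).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pi = cfg.truth_overlap_fraction
    rho = cfg.signal_model.noise_rate
    features = _component_params(cfg)

    z = rng.random(n_mc) < pi
    flip = rng.random(n_mc) < rho
    comp = z ^ flip
    log_true = np.zeros(n_mc)
    log_art = np.zeros(n_mc)
    for name, mt, st, ma, sa, _ in features:
        x = rng.normal(np.where(comp, mt, ma), np.where(comp, st, sa))
        log_true += norm.logpdf(x, mt, st)
        log_art += norm.logpdf(x, ma, sa)
    # p(x|z=1) = (1-rho) p_true(x) + rho p_art(x); symmetric for z=0
    m = np.maximum(log_true, log_art)
    p_t = np.exp(log_true - m)
    p_a = np.exp(log_art - m)
    post_1 = pi * ((1 - rho) * p_t + rho * p_a)
    post_0 = (1 - pi) * ((1 - rho) * p_a + rho * p_t)
    predict_true = post_1 >= post_0
    return float((predict_true == z).mean())
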