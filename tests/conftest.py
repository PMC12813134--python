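"""Shared fixtures: synthetic callsets and a small trained model.

Everything is generated programmatically at collection time; the
session-scoped trained model amortizes the one genuinely expensive
setup across the end-to-end and acceptance tests.
"""

from __future__ import annotations

import pytest

from vqrefine.classifier import ModelConfig, SplitSpec, make_split, train
from vqrefine.encoding import EncodingConfig, build_vocabulary, record_to_sentence
from vqrefine.synthetic import SimulationConfig, simulate_callset

#: encoding used for all training-based tests: integer binning keeps the
#: token space small enough that validation tokens are in-vocabulary
DESK_ENCODING = EncodingConfig(max_sequence_length=16, numeric_precision=0)
DESK_CONFIG = ModelConfig(max_sequence_length=16, seed=1)


@pytest.fixture(scope="session")
def gatk_sim():
    """1,000-record GATK4-dialect callset with 80% truth overlap."""
    return simulate_callset(
        SimulationConfig(n_records=1000, dialect="gatk4",
                         truth_overlap_fraction=0.8, seed=7)
    )


@pytest.fixture(scope="session")
def bcf_sim():
    """400-record BCFTools-dialect callset."""
    return simulate_callset(
        SimulationConfig(n_records=400, dialect="bcftools",
                         truth_overlap_fraction=0.8, seed=11)
    )


@pytest.fixture(scope="session")
def gatk_vcf_paths(gatk_sim, tmp_path_factory):
    d = tmp_path_factory.mktemp("gatk_fixture")
    query, truth = d / "query.vcf", d / "truth.vcf"
    gatk_sim.write(query, truth)
    return query, truth


@pytest.fixture(scope="session")
def labeled_corpus(gatk_sim):
    return [
        record_to_sentence(rec, DESK_ENCODING, label=label, source_index=i)
        for i, (rec, label) in enumerate(zip(gatk_sim.query_records, gatk_sim.labels))
    ]


@pytest.fixture(scope="session")
def tiny_fit(labeled_corpus):
    """(results, vocab, train, val): a 3-epoch fit on the 1,000-record fixture."""
    train_set, val_set = make_split(labeled_corpus, SplitSpec(seed=1))
    vocab = build_vocabulary(train_set)
    cfg = ModelConfig(max_sequence_length=16, seed=1, epochs=3)
    results = train(train_set, val_set, vocab, cfg, DESK_ENCODING)
    return results, vocab, train_set, val_set
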