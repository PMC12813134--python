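"""Default hard-filter baselines for GATK4 and BCFTools callsets.

These are the rule sets the refinement model is compared against. A
record FAILs when any rule fires. Boundary semantics follow the printed
thresholds exactly: the six GATK4 rules are strict inequalities (a
record sitting exactly on a threshold does not fire), the BCFTools
quality floor is inclusive (QUAL = 20 passes).

Missing annotations do not fire a rule — the GATK convention, since
RankSum annotations are undefined at homozygous sites — except for the
BCFTools QUAL floor, where a missing quality cannot satisfy a minimum
and therefore fails.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .vcf_io import FAIL, PASS, VariantRecord

QUAL_SELECTOR = "QUAL"

_COMPARATORS: dict[str, Callable[[float, float], bool]] = {
    "<": operator.lt,
    ">": operator.gt,
    "<=": operator.le,
    ">=": operator.ge,
}


@dataclass(frozen=True)
class FilterRule:
    """One threshold rule; ``fires`` == record fails this rule.

    selector is an INFO key or the QUAL pseudo-selector; comparator and
    threshold define the *failing* condition (e.g. "QD", "<", 2.0 fails
    records with QD below 2). fail_on_missing controls the action when
    the selected value is absent or non-numeric.
    """

    selector: str
    comparator: str
    threshold: float
    fail_on_missing: bool = False

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if not (self.threshold == self.threshold and abs(self.threshold) != float("inf")):
            raise ValueError("threshold must be finite")

    def value_of(self, record: VariantRecord) -> float | None:
        if self.selector == QUAL_SELECTOR:
            return record.qual_value()
        return record.info_float(self.selector)

    def fires(self, record: VariantRecord) -> bool:
        value = self.value_of(record)
        if value is None:
            return self.fail_on_missing
        return _COMPARATORS[self.comparator](value, self.threshold)


def gatk4_default_rules() -> list[FilterRule]:
    """The six GATK4 default hard filters: QD < 2.0, FS > 60.0,
    MQ < 40.0, SOR > 4.0, MQRankSum < -12.5, ReadPosRankSum < -8.0."""
    return [
        FilterRule("QD", "<", 2.0),
        FilterRule("FS", ">", 60.0),
        FilterRule("MQ", "<", 40.0),
        FilterRule("SOR", ">", 4.0),
        FilterRule("MQRankSum", "<", -12.5),
        FilterRule("ReadPosRankSum", "<", -8.0),
    ]


def bcftools_default_rule() -> FilterRule:
    """The BCFTools quality floor: PASS iff QUAL >= 20 (inclusive).

    Expressed as the failing condition QUAL < 20; a missing QUAL fails.
    """
    return FilterRule(QUAL_SELECTOR, "<", 20.0, fail_on_missing=True)


def rules_for_dialect(dialect: str) -> list[FilterRule]:
    if dialect == "gatk4":
        return gatk4_default_rules()
    if dialect == "bcftools":
        return [bcftools_default_rule()]
    raise ValueError(f"unknown dialect {dialect!r}; expected gatk4 or bcftools")


def apply_rules(record: VariantRecord, rules: Sequence[FilterRule]) -> str:
    """FAIL iff any rule fires; deterministic in record and rules."""
    if not rules:
        raise ValueError("apply_rules requires at least one rule")
    return FAIL if any(rule.fires(record) for rule in rules) else PASS
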