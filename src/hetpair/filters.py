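"""Post hoc filtering of consensus somatic variants.

Six rules are applied in a fixed order, each a pure predicate, with a
per-variant audit trail recording the first rule a variant fails:

1. multiallelic    — remove multiallelic sites
2. common_variant  — remove population allele frequency > 1% (missing AF
                     treated as 0, i.e. kept)
3. low_vaf         — remove tumour allele frequency < 0.01
4. low_depth       — require read depth >= 10 (by default in BOTH the
                     tumour and the matched normal; ``depth_rule="either"``
                     relaxes this to at least one sample)
5. alt_read_support— keep tumour alt reads >= 5 AND normal alt reads <= 2
                     (both bounds inclusive)
6. synonymous      — remove synonymous coding variants (non-coding classes
                     are not touched by this rule, so promoter/intronic
                     variants survive)

Because every rule is a pure predicate, the surviving *set* does not
depend on rule order — only the audit attribution does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .variants import ConsensusVariant

FILTER_ORDER = (
    "multiallelic",
    "common_variant",
    "low_vaf",
    "low_depth",
    "alt_read_support",
    "synonymous",
)


@dataclass
class FilterThresholds:
    """Filter-chain thresholds; defaults are the conventional values for
    high-confidence somatic calls from a tumour/normal pair."""

    pop_af_max: float = 0.01  # strictly greater is removed
    vaf_min: float = 0.01  # strictly lower is removed
    min_depth: int = 10
    depth_rule: str = "both"  # require both samples >= min_depth, or either
    min_tumour_alt: int = 5  # inclusive
    max_normal_alt: int = 2  # inclusive
    drop_synonymous: bool = True

    def __post_init__(self):
        if self.depth_rule not in ("both", "either"):
            raise ValueError("depth_rule must be 'both' or 'either'")


@dataclass
class FilterReport:
    """Counts removed per rule plus each variant's first failed rule."""

    input_count: int
    removed: dict[str, int] = field(default_factory=dict)
    first_failed: dict[tuple, str] = field(default_factory=dict)

    @property
    def pass_count(self) -> int:
        return sum(1 for r in self.first_failed.values() if r == "pass")

    def check_conservation(self) -> None:
        if sum(self.removed.values()) + self.pass_count != self.input_count:
            raise AssertionError("filter audit does not conserve variant count")


def _fails(v: ConsensusVariant, rule: str, t: FilterThresholds) -> bool:
    if rule == "multiallelic":
        return v.multiallelic
    if rule == "common_variant":
        return v.pop_af is not None and v.pop_af > t.pop_af_max
    if rule == "low_vaf":
        return v.resolved_vaf < t.vaf_min
    if rule == "low_depth":
        tum_ok = v.tumour_depth >= t.min_depth
        nor_ok = v.normal_depth >= t.min_depth
        return not (tum_ok and nor_ok) if t.depth_rule == "both" else not (tum_ok or nor_ok)
    if rule == "alt_read_support":
        return not (v.tumour_alt >= t.min_tumour_alt and v.normal_alt <= t.max_normal_alt)
    if rule == "synonymous":
        return t.drop_synonymous and v.func_class == "synonymous"
    raise ValueError(f"unknown filter rule {rule!r}")


def apply_post_hoc_filters(
    variants: list[ConsensusVariant],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[ConsensusVariant], FilterReport]:
    """Run the six-rule chain; returns survivors and the audit report."""
    t = thresholds or FilterThresholds()
    report = FilterReport(input_count=len(variants))
    report.removed = {name: 0 for name in FILTER_ORDER}
    survivors = []
    for v in variants:
        for rule in FILTER_ORDER:
            if rule == "low_vaf" and v.resolved_vaf is None:
                raise ValueError(f"variant {v.key} lacks a resolved VAF")
            if _fails(v, rule, t):
                report.removed[rule] += 1
                report.first_failed[v.key] = rule
                break
        else:
            report.first_failed[v.key] = "pass"
            survivors.append(v)
    report.check_conservation()
    return survivors, report
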