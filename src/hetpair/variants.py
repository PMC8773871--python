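"""Somatic variant model, per-caller VCF parsing and multi-caller consensus.

Three callers are modelled, mirroring a Mutect2/Strelka2/MuSE-style trio:
``callerA`` and ``callerB`` call both SNVs and indels, ``callerC`` calls
SNVs only. High-confidence SNVs are those called by at least 2 of the 3
callers; high-confidence indels are those shared by the two indel-capable
callers. VAF is resolved by caller precedence (callerA when available,
else callerB, else recomputed from alt/depth).

Cross-caller matching requires one canonical representation per variant:
keys are (chrom, pos, ref, alt) after left-alignment and parsimony
trimming of indels.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

from .reference import Reference

#: Caller labels, positional: first two call indels, all three call SNVs.
CALLERS = ("callerA", "callerB", "callerC")
SNV_CALLERS = ("callerA", "callerB", "callerC")
INDEL_CALLERS = ("callerA", "callerB")
VAF_PRECEDENCE = ("callerA", "callerB")

COMPONENTS = ("Neg", "Abr")

#: Functional classes treated as non-genic for recurrence counting.
NONGENIC_CLASSES = frozenset({"intergenic", "upstream", "downstream"})


@dataclass
class VariantCall:
    """One caller's record for one ALT allele at one site."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    caller: str
    tumour_depth: int
    normal_depth: int
    tumour_alt: int
    normal_alt: int
    vaf: float | None = None
    pop_af: float | None = None
    func_class: str | None = None
    gene: str | None = None
    multiallelic: bool = False

    def __post_init__(self):
        if self.tumour_alt > self.tumour_depth:
            raise ValueError(
                f"{self.chrom}:{self.pos} tumour_alt {self.tumour_alt} exceeds "
                f"depth {self.tumour_depth}"
            )
        if self.normal_alt > self.normal_depth:
            raise ValueError(
                f"{self.chrom}:{self.pos} normal_alt {self.normal_alt} exceeds "
                f"depth {self.normal_depth}"
            )
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"{self.chrom}:{self.pos} VAF {self.vaf} outside [0,1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_class(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"


@dataclass
class ConsensusVariant:
    """A normalized variant key with its supporting-caller set and resolved
    evidence, ready for the post hoc filter chain."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    supporting_callers: frozenset
    resolved_vaf: float
    tumour_depth: int
    normal_depth: int
    tumour_alt: int
    normal_alt: int
    pop_af: float | None = None
    func_class: str | None = None
    gene: str | None = None
    multiallelic: bool = False
    evidence: list = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ComponentCallset:
    """All consensus variants of one dissected tumour component."""

    tumour_id: str
    component: str  # "Neg" (E-cadherin negative) or "Abr" (aberrant/positive)
    variants: list[ConsensusVariant] = field(default_factory=list)

    def __post_init__(self):
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate variant keys within a component callset")

    def keys(self, variant_class: str | None = None) -> set:
        return {
            v.key
            for v in self.variants
            if variant_class is None or v.variant_class == variant_class
        }

    def of_class(self, variant_class: str) -> list[ConsensusVariant]:
        return [v for v in self.variants if v.variant_class == variant_class]


def read_caller_vcf(
    path: str,
    caller: str,
    tumour_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
    pass_only: bool = True,
) -> list[VariantCall]:
    """Parse one caller's somatic VCF into VariantCalls.

    One call is emitted per ALT allele per record; records with more than
    one ALT are flagged multiallelic. Only FILTER=PASS records are kept by
    default. FORMAT must carry AD and DP for both samples.
    """
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for fmt in ("AD", "DP"):
            if fmt not in vf.header.formats:
                raise ValueError(f"{path}: required FORMAT field {fmt} missing")
        samples = list(vf.header.samples)
        for name in (tumour_sample, normal_sample):
            if name not in samples:
                raise ValueError(f"{path}: sample column {name!r} not found")
        declared = set(vf.header.info)
        for rec in vf:
            if pass_only and "PASS" not in rec.filter and len(rec.filter) > 0:
                continue
            if rec.alts is None:
                continue
            tum, nor = rec.samples[tumour_sample], rec.samples[normal_sample]
            tad, nad = tum.get("AD"), nor.get("AD")
            tdp = tum.get("DP") or (sum(tad) if tad else 0)
            ndp = nor.get("DP") or (sum(nad) if nad else 0)
            taf = tum.get("AF")
            multi = len(rec.alts) > 1
            pop_af = rec.info.get("POP_AF") if "POP_AF" in declared else None
            func = rec.info.get("FUNC") if "FUNC" in declared else None
            gene = rec.info.get("GENE") if "GENE" in declared else None
            for ai, alt in enumerate(rec.alts):
                vaf = None
                if taf is not None:
                    vaf = float(taf[ai] if isinstance(taf, tuple) else taf)
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        caller=caller,
                        tumour_depth=int(tdp),
                        normal_depth=int(ndp),
                        tumour_alt=int(tad[ai + 1]) if tad else 0,
                        normal_alt=int(nad[ai + 1]) if nad else 0,
                        vaf=vaf,
                        pop_af=_scalar(pop_af, ai),
                        func_class=_scalar(func, ai),
                        gene=_scalar(gene, ai),
                        multiallelic=multi,
                    )
                )
    return calls


def _scalar(value, allele_index):
    if value is None:
        return None
    if isinstance(value, tuple):
        return value[allele_index] if allele_index < len(value) else value[0]
    return value


def normalize_key(
    chrom: str, pos: int, ref: str, alt: str, reference: Reference
) -> tuple[str, int, str, str]:
    """Left-align and parsimony-trim a variant (vt-style algorithm).

    SNVs are returned unchanged; the operation is idempotent, so left- and
    right-aligned representations of the same indel map to one key.
    """
    if reference.fetch(chrom, pos - 1, pos - 1 + len(ref)) != ref:
        raise ValueError(
            f"REF mismatch at {chrom}:{pos}: variant says {ref!r}, "
            f"reference says {reference.fetch(chrom, pos - 1, pos - 1 + len(ref))!r}"
        )
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:  # cannot extend left past the contig start
                    base = reference.base(chrom, pos)
                    ref, alt = base + ref, base + alt
                    break
                pos -= 1
                base = reference.base(chrom, pos)
                ref, alt = base + ref, base + alt
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def normalize_variant(v: VariantCall, reference: Reference) -> VariantCall:
    """Return ``v`` with its key in canonical left-aligned parsimonious form."""
    chrom, pos, ref, alt = normalize_key(v.chrom, v.pos, v.ref, v.alt, reference)
    if (pos, ref, alt) == (v.pos, v.ref, v.alt):
        return v
    return replace(v, pos=pos, ref=ref, alt=alt)


def build_consensus(
    callsets: dict[str, list[VariantCall]],
    snv_callers: tuple = SNV_CALLERS,
    indel_callers: tuple = INDEL_CALLERS,
    vaf_precedence: tuple = VAF_PRECEDENCE,
) -> list[ConsensusVariant]:
    """Merge per-caller callsets into high-confidence consensus variants.

    SNVs require support from >= 2 of the SNV callers; indels require both
    indel-capable callers. All calls must already be normalized against the
    same reference. Duplicate keys within one caller are an error.
    """
    by_key: dict[tuple, dict[str, VariantCall]] = defaultdict(dict)
    for caller, calls in callsets.items():
        for call in calls:
            if call.key in by_key and caller in by_key[call.key]:
                raise ValueError(f"caller {caller} reports {call.key} twice")
            by_key[call.key][caller] = call

    out = []
    for key in sorted(by_key, key=lambda k: (k[0], k[1], k[2], k[3])):
        support = by_key[key]
        any_call = next(iter(support.values()))
        if any_call.variant_class == "SNV":
            if sum(c in support for c in snv_callers) < 2:
                continue
        else:
            if not all(c in support for c in indel_callers):
                continue
        primary = next(
            (support[c] for c in vaf_precedence if c in support and support[c].vaf is not None),
            None,
        )
        evidence_order = [support[c] for c in sorted(support)]
        depth_source = next(
            (support[c] for c in vaf_precedence if c in support), evidence_order[0]
        )
        if primary is not None:
            vaf = primary.vaf
        elif depth_source.tumour_depth > 0:
            vaf = depth_source.tumour_alt / depth_source.tumour_depth
        else:
            vaf = 0.0
        out.append(
            ConsensusVariant(
                chrom=key[0],
                pos=key[1],
                ref=key[2],
                alt=key[3],
                variant_class=any_call.variant_class,
                supporting_callers=frozenset(support),
                resolved_vaf=float(vaf),
                tumour_depth=depth_source.tumour_depth,
                normal_depth=depth_source.normal_depth,
                tumour_alt=depth_source.tumour_alt,
                normal_alt=depth_source.normal_alt,
                pop_af=_first_not_none(evidence_order, "pop_af"),
                func_class=_first_not_none(evidence_order, "func_class"),
                gene=_first_not_none(evidence_order, "gene"),
                multiallelic=any(c.multiallelic for c in evidence_order),
                evidence=evidence_order,
            )
        )
    return out


def _first_not_none(calls, attr):
    return next((getattr(c, attr) for c in calls if getattr(c, attr) is not None), None)
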