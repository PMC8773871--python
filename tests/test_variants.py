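import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetpair.filters import apply_post_hoc_filters
from hetpair.reference import Reference
from hetpair.simulate import SimulationConfig, simulate_mutation_set
from hetpair.io import write_vcf
from hetpair.variants import (
    VariantCall,
    build_consensus,
    normalize_key,
    normalize_variant,
    read_caller_vcf,
)


def call(pos=100, ref="C", alt="T", caller="callerA", vaf=0.3, **kw):
    defaults = dict(
        chrom="chr1", tumour_depth=40, normal_depth=40, tumour_alt=12, normal_alt=0
    )
    defaults.update(kw)
    return VariantCall(pos=pos, ref=ref, alt=alt, caller=caller, vaf=vaf, **defaults)


class TestVariantCall:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            call(tumour_alt=50, tumour_depth=40)
        with pytest.raises(ValueError):
            call(vaf=1.5)

    def test_variant_class(self):
        assert call().variant_class == "SNV"
        assert call(ref="CT", alt="C").variant_class == "indel"


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##FILTER=<ID=LowQual,Description="Low quality">
##INFO=<ID=POP_AF,Number=A,Type=Float,Description="x">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL
chr1\t100\t.\tC\tT\t.\tPASS\tPOP_AF=0.001\tDP:AD:AF\t40:30,10:0.25\t35:35,0:0.0
chr1\t200\t.\tG\tA\t.\tLowQual\t.\tDP:AD\t50:40,10\t30:30,0
chr1\t300\t.\tA\tC,T\t.\tPASS\t.\tDP:AD\t60:40,15,5\t25:25,0,0
"""


class TestReadCallerVcf:
    @pytest.fixture()
    def vcf_path(self, tmp_path):
        path = tmp_path / "caller.vcf"
        path.write_text(VCF_TEXT)
        return str(path)

    def test_field_mapping_and_pass_filter(self, vcf_path):
        calls = read_caller_vcf(vcf_path, "callerA")
        # LowQual record dropped; multiallelic record yields two calls
        assert len(calls) == 3
        first = calls[0]
        assert (first.pos, first.tumour_depth, first.tumour_alt) == (100, 40, 10)
        assert first.vaf == pytest.approx(0.25)
        assert first.pop_af == pytest.approx(0.001)
        assert not first.multiallelic

    def test_multiallelic_split(self, vcf_path):
        calls = read_caller_vcf(vcf_path, "callerA")
        multi = [c for c in calls if c.pos == 300]
        assert [c.alt for c in multi] == ["C", "T"]
        assert all(c.multiallelic for c in multi)
        assert [c.tumour_alt for c in multi] == [15, 5]

    def test_missing_sample_errors(self, vcf_path):
        with pytest.raises(ValueError, match="sample column"):
            read_caller_vcf(vcf_path, "callerA", tumour_sample="NOPE")


# reference with a homopolymer run and a dinucleotide repeat for alignment tests
NORM_REF = Reference({"c": "GGCATTTTTACACACAGG"})


class TestNormalize:
    def test_snv_unchanged(self):
        assert normalize_key("c", 3, "C", "T", NORM_REF) == ("c", 3, "C", "T")

    def test_deletion_left_aligned_in_homopolymer(self):
        # delete one T from the T-run (pos 5-9); any representation shifts
        # to the leftmost anchor (pos 4, AT>A)
        for pos in (5, 6, 7, 8):
            got = normalize_key("c", pos, NORM_REF.base("c", pos) + "T", NORM_REF.base("c", pos), NORM_REF)
            assert got == ("c", 4, "AT", "A")

    def test_insertion_left_aligned(self):
        # insert AC inside the AC repeat: left- and right-aligned
        # representations collapse onto one key
        a = normalize_key("c", 11, "C", "CAC", NORM_REF)
        b = normalize_key("c", 15, "C", "CAC", NORM_REF)
        assert a == b == ("c", 9, "T", "TAC")

    def test_parsimony_trimming(self):
        assert normalize_key("c", 3, "CAT", "CAC", NORM_REF) == ("c", 5, "T", "C")

    def test_idempotent(self):
        v = call(pos=6, ref="TT", alt="T", chrom="c", vaf=None)
        once = normalize_variant(v, NORM_REF)
        twice = normalize_variant(once, NORM_REF)
        assert once.key == twice.key

    def test_ref_mismatch_errors(self):
        with pytest.raises(ValueError, match="REF mismatch"):
            normalize_key("c", 3, "A", "T", NORM_REF)


class TestConsensus:
    def test_rule_table_exhaustive(self):
        """All 8 caller subsets: SNVs need >=2 of 3; indels need both
        indel-capable callers (callerA and callerB)."""
        all_callers = ("callerA", "callerB", "callerC")
        for subset in itertools.chain.from_iterable(
            itertools.combinations(all_callers, k) for k in range(4)
        ):
            snv_sets = {c: [call(pos=10)] if c in subset else [] for c in all_callers}
            kept = len(build_consensus(snv_sets)) == 1
            assert kept == (len(subset) >= 2), f"SNV rule broken for {subset}"
            indel_sets = {
                c: [call(pos=10, ref="CT", alt="C", vaf=0.2)] if c in subset else []
                for c in all_callers
            }
            kept = len(build_consensus(indel_sets)) == 1
            expected = {"callerA", "callerB"}.issubset(subset)
            assert kept == expected, f"indel rule broken for {subset}"

    def test_vaf_precedence(self):
        # callerA VAF wins; else callerB; else recomputed from counts
        cons = build_consensus(
            {
                "callerA": [call(vaf=0.31)],
                "callerB": [call(caller="callerB", vaf=0.29)],
                "callerC": [],
            }
        )[0]
        assert cons.resolved_vaf == pytest.approx(0.31)
        cons = build_consensus(
            {
                "callerA": [],
                "callerB": [call(caller="callerB", vaf=0.29)],
                "callerC": [call(caller="callerC", vaf=0.5)],
            }
        )[0]
        assert cons.resolved_vaf == pytest.approx(0.29)
        cons = build_consensus(
            {
                "callerB": [call(caller="callerB", vaf=None, tumour_alt=10, tumour_depth=40)],
                "callerC": [call(caller="callerC", vaf=None, tumour_alt=10, tumour_depth=40)],
            }
        )[0]
        assert cons.resolved_vaf == pytest.approx(0.25)

    def test_duplicate_key_within_caller_errors(self):
        with pytest.raises(ValueError, match="twice"):
            build_consensus({"callerA": [call(), call()]})

    @settings(max_examples=60, deadline=None)
    @given(
        support=st.sets(st.sampled_from(["callerA", "callerB", "callerC"])),
        extra=st.sampled_from(["callerA", "callerB", "callerC"]),
    )
    def test_consensus_monotone_in_support(self, support, extra):
        """Adding a caller's support never removes a variant."""
        def run(callers):
            sets = {c: [call(caller=c)] if c in callers else [] for c in
                    ("callerA", "callerB", "callerC")}
            return len(build_consensus(sets))

        assert run(support | {extra}) >= run(support)


class TestFileRoundTrip:
    def test_vcf_round_trip_preserves_filtered_consensus(self, tmp_path, reference):
        cfg = SimulationConfig(
            seed=42, n_mutations_total=120, trunk_fraction=0.5, n_contigs=5,
            contig_length=400_000,
        )
        pair = simulate_mutation_set(cfg, reference)
        for comp in ("Neg",):
            callsets_mem, callsets_file = {}, {}
            for caller in ("callerA", "callerB", "callerC"):
                calls = pair.calls[(comp, caller)]
                path = tmp_path / f"{comp}_{caller}.vcf"
                write_vcf(calls, str(path), reference)
                callsets_mem[caller] = [normalize_variant(v, reference) for v in calls]
                callsets_file[caller] = [
                    normalize_variant(v, reference)
                    for v in read_caller_vcf(str(path), caller)
                ]
            surv_mem, _ = apply_post_hoc_filters(build_consensus(callsets_mem))
            surv_file, _ = apply_post_hoc_filters(build_consensus(callsets_file))
            assert {v.key for v in surv_mem} == {v.key for v in surv_file}
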