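import pytest

from hetpair.reference import synthetic_reference
from hetpair.signatures import load_catalog
from hetpair.variants import ConsensusVariant


@pytest.fixture(scope="session")
def reference():
    """Shared synthetic reference; big enough for the largest draws."""
    return synthetic_reference(seed=2023, n_contigs=5, contig_length=400_000)


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


def make_consensus(
    pos=100,
    chrom="chr1",
    ref="C",
    alt="T",
    callers=("callerA", "callerB"),
    vaf=0.30,
    tumour_depth=40,
    tumour_alt=12,
    normal_depth=40,
    normal_alt=0,
    pop_af=0.0,
    func_class="nonsynonymous",
    gene="GENE0001",
    multiallelic=False,
):
    """Consensus-variant factory with innocuous defaults (passes all filters)."""
    variant_class = "SNV" if len(ref) == 1 and len(alt) == 1 else "indel"
    return ConsensusVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, variant_class=variant_class,
        supporting_callers=frozenset(callers), resolved_vaf=vaf,
        tumour_depth=tumour_depth, tumour_alt=tumour_alt,
        normal_depth=normal_depth, normal_alt=normal_alt,
        pop_af=pop_af, func_class=func_class, gene=gene,
        multiallelic=multiallelic,
    )


def filter_chain_fixture():
    """Twelve constructed variants: one violating each of the six rules plus
    six clean ones sitting exactly on the keep side of every boundary."""
    violators = [
        make_consensus(pos=10, multiallelic=True),
        make_consensus(pos=20, pop_af=0.05),
        make_consensus(pos=30, vaf=0.005),
        make_consensus(pos=40, tumour_depth=9, tumour_alt=5),
        make_consensus(pos=50, tumour_alt=4),
        make_consensus(pos=60, func_class="synonymous"),
    ]
    clean = [
        make_consensus(pos=70),
        make_consensus(pos=80, vaf=0.01),  # boundary: VAF exactly 0.01 kept
        make_consensus(pos=90, tumour_alt=5),  # boundary: >= 5 kept
        make_consensus(pos=100, normal_alt=2),  # boundary: <= 2 kept
        make_consensus(pos=110, tumour_depth=10, normal_depth=10, tumour_alt=5),
        make_consensus(pos=120, pop_af=0.01),  # boundary: exactly 1% kept
    ]
    return violators + clean
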