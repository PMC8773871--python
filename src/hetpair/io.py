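"""Writers for the simulator's on-disk artifact layout.

One VCFv4.2 per caller per component (TUMOR/NORMAL sample columns with
AD/DP/AF, INFO fields for population allele frequency, functional class
and gene), segment/probe/truth/gene TSVs and the reference FASTA with
its index. Multiallelic flagged SNVs are written as genuine two-ALT
records (a low-support second allele), so the parser and filter chain
see real multiallelic sites.
"""

from __future__ import annotations

import os

import pandas as pd
import pysam

from .reference import Reference
from .simulate import SimulatedPair
from .variants import CALLERS, COMPONENTS, VariantCall


def _vcf_header(reference: Reference, tumour: str, normal: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in reference.lengths().items():
        header.contigs.add(name, length=length)
    header.add_meta(
        "INFO",
        items=[("ID", "POP_AF"), ("Number", "A"), ("Type", "Float"),
               ("Description", "Population allele frequency (gnomAD-style)")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "FUNC"), ("Number", "1"), ("Type", "String"),
               ("Description", "Functional annotation class")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "GENE"), ("Number", "1"), ("Type", "String"),
               ("Description", "Overlapping gene")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
               ("Description", "Read depth")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
               ("Description", "Allelic depths")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "AF"), ("Number", "A"), ("Type", "Float"),
               ("Description", "Allele fraction")],
    )
    header.add_sample(tumour)
    header.add_sample(normal)
    return header


def _second_allele(ref: str, alt: str) -> str:
    return next(b for b in "ACGT" if b not in (ref, alt))


def write_vcf(
    calls: list[VariantCall],
    path: str,
    reference: Reference,
    tumour: str = "TUMOR",
    normal: str = "NORMAL",
) -> None:
    """Write one caller's calls as a sorted VCFv4.2 file."""
    header = _vcf_header(reference, tumour, normal)
    order = {name: i for i, name in enumerate(reference.names)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(calls, key=lambda c: (order[c.chrom], c.pos, c.ref, c.alt)):
            multi = v.multiallelic and v.variant_class == "SNV"
            alleles = (v.ref, v.alt, _second_allele(v.ref, v.alt)) if multi else (v.ref, v.alt)
            rec = out.new_record(contig=v.chrom, start=v.pos - 1, alleles=alleles)
            rec.filter.add("PASS")
            if v.pop_af is not None:
                rec.info["POP_AF"] = (v.pop_af, 0.0) if multi else (v.pop_af,)
            if v.func_class:
                rec.info["FUNC"] = v.func_class
            if v.gene:
                rec.info["GENE"] = v.gene
            t, n = rec.samples[tumour], rec.samples[normal]
            t["DP"] = v.tumour_depth
            n["DP"] = v.normal_depth
            if multi:
                ref_reads = max(0, v.tumour_depth - v.tumour_alt - 1)
                t["AD"] = (ref_reads, v.tumour_alt, 1)
                n["AD"] = (v.normal_depth - v.normal_alt, v.normal_alt, 0)
                t["AF"] = (v.vaf if v.vaf is not None else 0.0, 1.0 / max(1, v.tumour_depth))
            else:
                t["AD"] = (v.tumour_depth - v.tumour_alt, v.tumour_alt)
                n["AD"] = (v.normal_depth - v.normal_alt, v.normal_alt)
                if v.vaf is not None:
                    t["AF"] = (v.vaf,)
            out.write(rec)


def write_pair_artifacts(pair: SimulatedPair, outdir: str) -> dict[str, str]:
    """Write the full simulated artifact set; returns relative paths."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    ref_path = os.path.join(outdir, "reference.fa")
    pair.reference.to_fasta(ref_path)
    paths["reference"] = "reference.fa"
    vcf_dir = os.path.join(outdir, "vcf")
    os.makedirs(vcf_dir, exist_ok=True)
    for comp in COMPONENTS:
        for caller in CALLERS:
            if (comp, caller) not in pair.calls:
                continue
            rel = f"vcf/{comp}_{caller}.vcf"
            write_vcf(pair.calls[(comp, caller)], os.path.join(outdir, rel), pair.reference)
            paths[f"vcf_{comp}_{caller}"] = rel
    pair.genes.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
    paths["genes"] = "genes.tsv"
    pair.truth.to_csv(os.path.join(outdir, "truth_variants.tsv"), sep="\t", index=False)
    paths["truth_variants"] = "truth_variants.tsv"
    if pair.segments is not None:
        for comp, df in pair.segments.items():
            rel = f"segments_{comp}.tsv"
            df.to_csv(os.path.join(outdir, rel), sep="\t", index=False)
            paths[f"segments_{comp}"] = rel
        pair.cna_truth.to_csv(
            os.path.join(outdir, "truth_cna.tsv"), sep="\t", index=False
        )
        paths["truth_cna"] = "truth_cna.tsv"
    if pair.probes is not None:
        pair.probes.to_csv(os.path.join(outdir, "probes.tsv"), sep="\t", index=False)
        paths["probes"] = "probes.tsv"
        pair.methylation_truth.to_csv(
            os.path.join(outdir, "truth_methylation.tsv"), sep="\t", index=False
        )
        paths["truth_methylation"] = "truth_methylation.tsv"
    return paths


def write_consensus_tsv(variants, path: str) -> None:
    """Serialize consensus variants with the evidence the filters need."""
    pd.DataFrame(
        [
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "variant_class": v.variant_class,
                "supporting_callers": ",".join(sorted(v.supporting_callers)),
                "resolved_vaf": v.resolved_vaf,
                "tumour_depth": v.tumour_depth, "tumour_alt": v.tumour_alt,
                "normal_depth": v.normal_depth, "normal_alt": v.normal_alt,
                "pop_af": v.pop_af, "func_class": v.func_class, "gene": v.gene,
                "multiallelic": v.multiallelic,
            }
            for v in variants
        ]
    ).to_csv(path, sep="\t", index=False)


def read_consensus_tsv(path: str):
    """Round-trip a consensus TSV back into ConsensusVariant objects."""
    from .variants import ConsensusVariant

    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        out.append(
            ConsensusVariant(
                chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
                variant_class=str(r.variant_class),
                supporting_callers=frozenset(str(r.supporting_callers).split(",")),
                resolved_vaf=float(r.resolved_vaf),
                tumour_depth=int(r.tumour_depth), tumour_alt=int(r.tumour_alt),
                normal_depth=int(r.normal_depth), normal_alt=int(r.normal_alt),
                pop_af=None if pd.isna(r.pop_af) else float(r.pop_af),
                func_class=None if pd.isna(r.func_class) else str(r.func_class),
                gene=None if pd.isna(r.gene) else str(r.gene),
                multiallelic=bool(r.multiallelic),
            )
        )
    return out
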