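"""End-to-end orchestration: simulate -> consensus -> filter -> compare ->
signatures -> CNA -> methylation, with a machine-readable report.

Every stage reads and writes files in one artifact directory, so stages
can also be run individually from the CLI. The final ``report.json``
contains only relative artifact names and recomputable numbers: re-running
with the same config and seed reproduces it byte-identically.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cna as cna_mod
from . import methylation as meth_mod
from .filters import FilterThresholds, apply_post_hoc_filters
from .heterogeneity import (
    ComponentPair,
    fit_vaf_mixture,
    substitution_spectrum,
)
from .io import (
    read_consensus_tsv,
    write_consensus_tsv,
    write_pair_artifacts,
)
from .reference import Reference
from .signatures import (
    best_matches,
    build_sbs_profile,
    cluster_similarity,
    load_catalog,
    profile_catalog_similarity,
)
from .simulate import SimulationConfig, simulate_all
from .variants import (
    CALLERS,
    COMPONENTS,
    ComponentCallset,
    build_consensus,
    normalize_variant,
    read_caller_vcf,
)

log = logging.getLogger("hetpair")

ALL_STAGES = ("simulate", "consensus", "filter", "compare", "signatures", "cna", "methyl")


@dataclass
class RelatednessThresholds:
    """Rule-based clonality call on the SNV overlap coefficient. The
    boundaries are artifact-defined heuristics anchored by the observed
    range in related tumour pairs (median overlap ~0.6, with low-overlap
    pairs still related), surfaced in config rather than buried."""

    related_min: float = 0.3
    independent_max: float = 0.1


@dataclass
class RunConfig:
    seed: int = 0
    tumour_id: str = "SIM1"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterThresholds = field(default_factory=FilterThresholds)
    relatedness: RelatednessThresholds = field(default_factory=RelatednessThresholds)
    subclone_k_max: int = 3
    methylation_gene_panel: list | None = None
    signature_catalog: str | None = None  # path; None = bundled
    stages: tuple = ALL_STAGES

    @classmethod
    def from_yaml(cls, path: str, seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            seed=raw.get("seed", 0),
            tumour_id=raw.get("tumour_id", "SIM1"),
            simulation=SimulationConfig(**raw.get("simulation", {})),
            filters=FilterThresholds(**raw.get("filters", {})),
            relatedness=RelatednessThresholds(**raw.get("relatedness", {})),
            subclone_k_max=raw.get("subclone_k_max", 3),
            methylation_gene_panel=raw.get("methylation_gene_panel"),
            signature_catalog=raw.get("signature_catalog"),
            stages=tuple(raw.get("stages", ALL_STAGES)),
        )
        if seed is not None:
            cfg.seed = seed
        cfg.simulation.seed = cfg.seed
        cfg.simulation.validate()
        return cfg


def classify_relatedness(
    overlap_snv: float, thresholds: RelatednessThresholds | None = None
) -> str:
    """clonally_related / indeterminate / independent from the SNV overlap."""
    t = thresholds or RelatednessThresholds()
    if overlap_snv >= t.related_min:
        return "clonally_related"
    if overlap_snv < t.independent_max:
        return "independent"
    return "indeterminate"


def stage_simulate(cfg: RunConfig, outdir: str) -> None:
    pair = simulate_all(cfg.simulation)
    write_pair_artifacts(pair, outdir)
    log.info(
        "simulate: %d truth variants, %d probes",
        len(pair.truth), len(pair.probes) if pair.probes is not None else 0,
    )


def stage_consensus(cfg: RunConfig, outdir: str) -> None:
    reference = Reference.from_fasta(os.path.join(outdir, "reference.fa"))
    for comp in COMPONENTS:
        callsets = {}
        for caller in CALLERS:
            path = os.path.join(outdir, f"vcf/{comp}_{caller}.vcf")
            calls = read_caller_vcf(path, caller)
            callsets[caller] = [normalize_variant(v, reference) for v in calls]
        consensus = build_consensus(callsets)
        write_consensus_tsv(consensus, os.path.join(outdir, f"consensus_{comp}.tsv"))
        log.info("consensus %s: %d variants", comp, len(consensus))


def stage_filter(cfg: RunConfig, outdir: str) -> None:
    reports = {}
    for comp in COMPONENTS:
        variants = read_consensus_tsv(os.path.join(outdir, f"consensus_{comp}.tsv"))
        survivors, report = apply_post_hoc_filters(variants, cfg.filters)
        write_consensus_tsv(survivors, os.path.join(outdir, f"filtered_{comp}.tsv"))
        reports[comp] = {
            "input": report.input_count,
            "pass": report.pass_count,
            "removed": report.removed,
        }
        log.info("filter %s: %d -> %d", comp, report.input_count, report.pass_count)
    with open(os.path.join(outdir, "filter_report.json"), "w") as fh:
        json.dump(reports, fh, indent=2, sort_keys=True)


def _load_filtered(cfg: RunConfig, outdir: str) -> dict[str, ComponentCallset]:
    return {
        comp: ComponentCallset(
            cfg.tumour_id, comp,
            read_consensus_tsv(os.path.join(outdir, f"filtered_{comp}.tsv")),
        )
        for comp in COMPONENTS
    }


def stage_compare(cfg: RunConfig, outdir: str) -> None:
    callsets = _load_filtered(cfg, outdir)
    pair = ComponentPair.from_callsets(
        callsets["Neg"], callsets["Abr"], cfg.tumour_id
    )
    summary = {
        "tumour_id": cfg.tumour_id,
        "n_snv": {c: len(callsets[c].keys("SNV")) for c in COMPONENTS},
        "n_indel": {c: len(callsets[c].keys("indel")) for c in COMPONENTS},
        "n_shared": len(pair.shared),
        "n_private": {"Neg": len(pair.private_neg), "Abr": len(pair.private_abr)},
        "overlap_snv": pair.overlap_snv,
        "overlap_indel": pair.overlap_indel,
        "relatedness": classify_relatedness(pair.overlap_snv, cfg.relatedness),
        "spectrum": {
            c: substitution_spectrum(callsets[c].of_class("SNV")).as_dict()
            for c in COMPONENTS
        },
        "subclones": {},
    }
    for comp in COMPONENTS:
        snvs = callsets[comp].of_class("SNV")
        if len(snvs) >= 20:
            fit = fit_vaf_mixture(snvs, k_max=cfg.subclone_k_max)
            summary["subclones"][comp] = {
                "k": fit.k,
                "means": [round(float(m), 6) for m in fit.means],
                "weights": [round(float(w), 6) for w in fit.weights],
                "bic_by_k": {str(k): round(v, 3) for k, v in fit.bic_by_k.items()},
            }
    with open(os.path.join(outdir, "pair_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info(
        "compare: SNV overlap %.3f, indel overlap %.3f (%s)",
        pair.overlap_snv, pair.overlap_indel, summary["relatedness"],
    )


def stage_signatures(cfg: RunConfig, outdir: str) -> None:
    reference = Reference.from_fasta(os.path.join(outdir, "reference.fa"))
    catalog = load_catalog(cfg.signature_catalog)
    callsets = _load_filtered(cfg, outdir)
    profiles = [
        build_sbs_profile(
            callsets[c].of_class("SNV"), reference, sample_id=f"{cfg.tumour_id}_{c}"
        )
        for c in COMPONENTS
    ]
    sim = profile_catalog_similarity(profiles, catalog)
    sim.round(6).to_csv(os.path.join(outdir, "signature_similarity.tsv"), sep="\t")
    clusters = cluster_similarity(sim)
    payload = {
        "catalog_checksum": catalog.checksum,
        "best_match": best_matches(sim).to_dict(),
        "row_order": clusters.row_order,
        "col_order": clusters.col_order,
    }
    with open(os.path.join(outdir, "signature_clusters.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    log.info("signatures: best matches %s", payload["best_match"])


def stage_cna(cfg: RunConfig, outdir: str) -> None:
    genes = pd.read_csv(os.path.join(outdir, "genes.tsv"), sep="\t")
    states = {}
    for comp in COMPONENTS:
        segments = cna_mod.read_segments(os.path.join(outdir, f"segments_{comp}.tsv"))
        states[comp] = cna_mod.assign_segments_to_genes(segments, genes)
        cna_mod.write_gene_states(
            states[comp], os.path.join(outdir, f"gene_states_{comp}.tsv")
        )
    diff = cna_mod.differential_gene_states(states["Neg"], states["Abr"])
    diff.to_csv(os.path.join(outdir, "differential_cna.tsv"), sep="\t", index=False)
    log.info("cna: %d discordant genes", int((~diff["uncovered"]).sum()) if len(diff) else 0)


def stage_methyl(cfg: RunConfig, outdir: str) -> None:
    probes = meth_mod.read_probe_table(os.path.join(outdir, "probes.tsv"))
    survivors, removal = meth_mod.filter_probes(probes)
    diff = meth_mod.differential_probes(
        survivors, "Neg", "Abr",
        gene_filter=set(cfg.methylation_gene_panel) if cfg.methylation_gene_panel else None,
    )
    pd.DataFrame([vars(d) for d in diff]).to_csv(
        os.path.join(outdir, "differential_methylation.tsv"), sep="\t", index=False
    )
    summary = meth_mod.promoter_methylation_summary(survivors)
    summary.to_csv(os.path.join(outdir, "promoter_summary.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "methylation_filter_report.json"), "w") as fh:
        json.dump(removal, fh, indent=2, sort_keys=True)
    log.info("methyl: %d probes kept, %d differential", len(survivors), len(diff))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "consensus": stage_consensus,
    "filter": stage_filter,
    "compare": stage_compare,
    "signatures": stage_signatures,
    "cna": stage_cna,
    "methyl": stage_methyl,
}


def run_pipeline(cfg: RunConfig, outdir: str) -> dict:
    """Execute the enabled stages in dependency order and assemble the
    pair report. Raises on the first stage error, naming the stage."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "config_used.yaml"), "w") as fh:
        yaml.safe_dump(_config_dict(cfg), fh, sort_keys=True)
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        try:
            _STAGE_FUNCS[stage](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    report = _assemble_report(cfg, outdir)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_text_summary(report, os.path.join(outdir, "summary.txt"))
    return report


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["stages"] = list(cfg.stages)
    return json.loads(json.dumps(d, default=str))


def _assemble_report(cfg: RunConfig, outdir: str) -> dict:
    report: dict = {"tumour_id": cfg.tumour_id, "seed": cfg.seed, "artifacts": {}}
    for rel in sorted(os.listdir(outdir)):
        if rel.endswith((".tsv", ".json", ".fa", ".fai")) and rel != "report.json":
            report["artifacts"][rel] = rel
    pair_path = os.path.join(outdir, "pair_summary.json")
    if os.path.exists(pair_path):
        with open(pair_path) as fh:
            report["pair"] = json.load(fh)
    for name, rel in (
        ("filter_audit", "filter_report.json"),
        ("signatures", "signature_clusters.json"),
        ("methylation_filter", "methylation_filter_report.json"),
    ):
        path = os.path.join(outdir, rel)
        if os.path.exists(path):
            with open(path) as fh:
                report[name] = json.load(fh)
    diff_cna = os.path.join(outdir, "differential_cna.tsv")
    if os.path.exists(diff_cna):
        df = pd.read_csv(diff_cna, sep="\t")
        covered = df[~df["uncovered"]] if len(df) else df
        report["differential_cna_genes"] = sorted(covered["gene"].astype(str)) if len(covered) else []
    diff_meth = os.path.join(outdir, "differential_methylation.tsv")
    if os.path.exists(diff_meth):
        df = pd.read_csv(diff_meth, sep="\t")
        report["n_differential_probes"] = int(len(df))
    return report


def _write_text_summary(report: dict, path: str) -> None:
    lines = [f"tumour {report['tumour_id']} (seed {report['seed']})"]
    pair = report.get("pair")
    if pair:
        lines += [
            f"  SNVs: Neg={pair['n_snv']['Neg']} Abr={pair['n_snv']['Abr']}  "
            f"overlap={pair['overlap_snv']:.3f}",
            f"  indels: Neg={pair['n_indel']['Neg']} Abr={pair['n_indel']['Abr']}  "
            f"overlap={pair['overlap_indel']:.3f}",
            f"  relatedness call: {pair['relatedness']}",
        ]
        for comp, fit in sorted(pair.get("subclones", {}).items()):
            means = ", ".join(f"{m:.3f}" for m in fit["means"])
            lines.append(f"  subclones {comp}: k={fit['k']} means=[{means}]")
    sig = report.get("signatures")
    if sig:
        for sample, match in sorted(sig["best_match"].items()):
            lines.append(f"  best signature {sample}: {match}")
    if "differential_cna_genes" in report:
        lines.append(
            "  discordant CNA genes: "
            + (", ".join(report["differential_cna_genes"]) or "none")
        )
    if "n_differential_probes" in report:
        lines.append(f"  differential promoter probes: {report['n_differential_probes']}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
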