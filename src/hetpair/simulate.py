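"""Synthetic paired-tumour generator with known ground truth.

Emulates the data structure of a two-component dissected tumour with a
matched normal: a truncal mutation set shared by both components plus
private sets (and optional subclones), trinucleotide contexts drawn from
mutational-signature mixtures, read counts drawn binomially under purity
and depth, per-caller sensitivity and injected false positives,
allele-specific copy-number segments with plantable events, and a
promoter methylation probe matrix with plantable discordant probes.

Two evolutionary regimes are generable: a common ancestor
(trunk_fraction > 0) and the collision of two independent tumours
(trunk_fraction = 0).

All randomness flows from a single seed; identical config and seed give
byte-identical outputs. Read-level simulation (FASTQ/BAM), germline
variation and sequencing-error models beyond the binomial/Poisson are
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import ContextIndex, Reference, synthetic_reference
from .signatures import CHANNELS, SignatureCatalog, load_catalog
from .variants import CALLERS, COMPONENTS, INDEL_CALLERS, VariantCall, normalize_key

_SPECIAL_GENES = ("CDH1", "CTNNA1", "CTNNB1", "CDH3", "CTNND1")


@dataclass
class CallerProfile:
    sensitivity: float = 1.0
    false_positives: int = 0
    vaf_noise_sd: float = 0.0


@dataclass
class Subclone:
    cellular_fraction: float  # of tumour cells, in (0,1]
    n_mutations: int


@dataclass
class PlantedCNA:
    gene: str
    component: str
    total_cn: int
    minor_cn: int


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic tumour pair.

    ``signature_mixture`` is either one signature-id -> weight map used
    for truncal and both private sets, or a map with keys "truncal",
    "Neg", "Abr" giving a mixture per mutation group (so APOBEC-divergent
    pairs can be simulated).
    """

    seed: int = 0
    n_mutations_total: int = 2000  # per component (trunk + private)
    trunk_fraction: float = 0.6
    signature_mixture: dict = field(default_factory=lambda: {"SBS1": 0.5, "SBS5": 0.5})
    purity: dict = field(default_factory=lambda: {"Neg": 0.7, "Abr": 0.7})
    mean_depth_tumour: float = 80.0
    mean_depth_normal: float = 40.0
    subclones: dict = field(default_factory=lambda: {"Neg": [], "Abr": []})
    caller_profiles: dict = field(
        default_factory=lambda: {c: CallerProfile() for c in CALLERS}
    )
    indel_fraction: float = 0.1
    # annotation plumbing so every post hoc filter sees failing records
    multiallelic_fraction: float = 0.01
    common_variant_fraction: float = 0.03
    synonymous_fraction: float = 0.05
    normal_contamination_fraction: float = 0.01
    # reference / gene model
    reference_seed: int = 2023
    n_contigs: int = 5
    contig_length: int = 1_000_000
    n_genes: int = 60
    gene_length: int = 10_000
    # copy number
    ploidy: dict = field(default_factory=lambda: {"Neg": 2.0, "Abr": 2.0})
    segment_length: int = 250_000
    planted_cna: list = field(default_factory=list)
    # methylation
    n_probes: int = 10_000
    discordant_probe_fraction: float = 0.01
    probe_fail_fraction: float = 0.005
    y_probe_fraction: float = 0.005
    snp_probe_fraction: float = 0.005
    cross_reactive_fraction: float = 0.005
    beta_noise_sd: float = 0.02
    planted_promoter_methylation: list = field(default_factory=list)

    def __post_init__(self):
        if isinstance(self.purity, (int, float)):
            self.purity = {c: float(self.purity) for c in COMPONENTS}
        if isinstance(self.ploidy, (int, float)):
            self.ploidy = {c: float(self.ploidy) for c in COMPONENTS}
        self.caller_profiles = {
            k: (v if isinstance(v, CallerProfile) else CallerProfile(**v))
            for k, v in self.caller_profiles.items()
        }
        self.subclones = {
            comp: [s if isinstance(s, Subclone) else Subclone(*s) for s in subs]
            for comp, subs in self.subclones.items()
        }
        self.planted_cna = [
            p if isinstance(p, PlantedCNA) else PlantedCNA(**p) for p in self.planted_cna
        ]

    def mixture_for(self, group: str) -> dict[str, float]:
        mix = self.signature_mixture
        if mix and isinstance(next(iter(mix.values())), dict):
            if group in mix:
                return mix[group]
            if group == "truncal":  # ancestor defaults to the Neg process
                return mix.get("Neg") or next(iter(mix.values()))
            raise ValueError(f"no signature mixture for group {group!r}")
        return mix

    def validate(self) -> None:
        if not 0.0 <= self.trunk_fraction <= 1.0:
            raise ValueError(f"trunk_fraction {self.trunk_fraction} outside [0,1]")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction outside [0,1]")
        if not 0.0 <= self.discordant_probe_fraction <= 1.0:
            raise ValueError("discordant_probe_fraction outside [0,1]")
        for group in ("truncal", "Neg", "Abr"):
            weights = list(self.mixture_for(group).values())
            if any(w < 0 for w in weights):
                raise ValueError("signature weights must be non-negative")
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ValueError(
                    f"signature weights for {group} sum to {sum(weights)}, not 1"
                )
        for comp in COMPONENTS:
            if not 0.0 < self.purity[comp] <= 1.0:
                raise ValueError(f"purity for {comp} outside (0,1]")
            for sc in self.subclones.get(comp, []):
                if not 0.0 < sc.cellular_fraction <= 1.0:
                    raise ValueError("subclone cellular fraction outside (0,1]")
        for prof in self.caller_profiles.values():
            if not 0.0 <= prof.sensitivity <= 1.0:
                raise ValueError("caller sensitivity outside [0,1]")


@dataclass
class SimulatedPair:
    """In-memory result of one paired-tumour simulation."""

    config: SimulationConfig
    reference: Reference
    genes: pd.DataFrame
    calls: dict  # (component, caller) -> list[VariantCall]
    truth: pd.DataFrame
    segments: dict | None = None  # component -> DataFrame
    cna_truth: pd.DataFrame | None = None
    probes: pd.DataFrame | None = None
    methylation_truth: pd.DataFrame | None = None

    def truth_keys(self, component: str, variant_class: str | None = None) -> set:
        t = self.truth
        mask = t[f"in_{component.lower()}"] & (t["label"] != "false_positive")
        if variant_class is not None:
            mask &= t["variant_class"] == variant_class
        return set(
            zip(t.loc[mask, "chrom"], t.loc[mask, "pos"], t.loc[mask, "ref"], t.loc[mask, "alt"])
        )


_INDEX_CACHE: dict[int, tuple[Reference, ContextIndex]] = {}


def get_context_index(reference: Reference) -> ContextIndex:
    """Context index for a reference, cached by object identity (index
    construction scans the whole sequence and dominates small runs)."""
    entry = _INDEX_CACHE.get(id(reference))
    if entry is not None and entry[0] is reference:
        return entry[1]
    index = ContextIndex(reference)
    _INDEX_CACHE.clear()
    _INDEX_CACHE[id(reference)] = (reference, index)
    return index


def make_genes(config: SimulationConfig, reference: Reference) -> pd.DataFrame:
    """Deterministic gene intervals tiled over the contigs; the first
    intervals carry the named genes of interest (CDH1 etc.)."""
    names = list(_SPECIAL_GENES[: config.n_genes])
    names += [f"GENE{i + 1:04d}" for i in range(len(names), config.n_genes)]
    contigs = reference.names
    per_contig = int(np.ceil(config.n_genes / len(contigs)))
    rows = []
    for i, name in enumerate(names):
        contig = contigs[i % len(contigs)]
        slot = i // len(contigs)
        length = len(reference.contigs[contig])
        spacing = length // (per_contig + 1)
        start = (slot + 1) * spacing
        rows.append(
            {
                "gene": name,
                "chrom": contig,
                "start": start,
                "end": min(start + config.gene_length - 1, length),
            }
        )
    return pd.DataFrame(rows)


class _GeneLookup:
    def __init__(self, genes: pd.DataFrame):
        self._by_chrom = {}
        for chrom, sub in genes.groupby("chrom"):
            sub = sub.sort_values("start")
            self._by_chrom[chrom] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["gene"].to_numpy(),
            )

    def gene_at(self, chrom: str, pos: int) -> str | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, names = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and ends[i] >= pos:
            return str(names[i])
        return None


def _draw_indel(reference, index, rng, used):
    """Random 1-5 bp insertion or deletion, left-aligned."""
    total = sum(reference.lengths().values())
    for _ in range(1000):
        gpos = int(rng.integers(total))
        chrom, pos = index.decode(gpos)
        length = len(reference.contigs[chrom])
        if pos < 2 or pos > length - 10:
            continue
        if any((gpos + d) in used for d in range(-6, 7)):
            continue
        size = int(rng.integers(1, 6))
        anchor = reference.base(chrom, pos)
        if rng.random() < 0.5:  # insertion
            ins = "".join("ACGT"[b] for b in rng.integers(0, 4, size))
            ref, alt = anchor, anchor + ins
        else:  # deletion
            ref = reference.fetch(chrom, pos - 1, pos + size)
            alt = anchor
        chrom, pos, ref, alt = normalize_key(chrom, pos, ref, alt, reference)
        for d in range(-6, 7):
            used.add(gpos + d)
        return chrom, pos, ref, alt
    raise ValueError("reference too short to place the requested indels")


def simulate_mutation_set(
    config: SimulationConfig,
    reference: Reference | None = None,
    catalog: SignatureCatalog | None = None,
) -> SimulatedPair:
    """Generate per-caller callsets for both components plus a truth table.

    Mutation sites are chosen conditional on the reference carrying the
    trinucleotide context drawn from the signature mixture. The expected
    VAF of a clonal mutation is purity/2 (diploid heterozygous); observed
    alt counts are binomial at a per-site Poisson depth. Caller callsets
    are truth thinned by sensitivity plus injected false positives (truth
    VAF 0, low alt counts in tumour only).
    """
    config.validate()
    if reference is None:
        reference = synthetic_reference(
            config.reference_seed, config.n_contigs, config.contig_length
        )
    catalog = catalog or load_catalog()
    index = get_context_index(reference)
    rng = np.random.default_rng(config.seed)
    genes = make_genes(config, reference)
    lookup = _GeneLookup(genes)

    n_shared = int(round(config.trunk_fraction * config.n_mutations_total))
    n_private = config.n_mutations_total - n_shared
    plan = [("truncal", ("Neg", "Abr"), 1.0)] * n_shared
    for comp in COMPONENTS:
        plan += [(f"private_{comp.lower()}", (comp,), 1.0)] * n_private
        for si, sc in enumerate(config.subclones.get(comp, [])):
            plan += [
                (f"subclone_{comp.lower()}_{si + 1}", (comp,), sc.cellular_fraction)
            ] * sc.n_mutations

    used: set[int] = set()
    truth_rows = []
    obs: dict[str, list[dict]] = {c: [] for c in COMPONENTS}
    for label, comps, ccf in plan:
        group = "truncal" if label == "truncal" else ("Neg" if "_neg" in label else "Abr")
        mixture = config.mixture_for(group)
        is_indel = rng.random() < config.indel_fraction
        sig = None
        if is_indel:
            chrom, pos, ref, alt = _draw_indel(reference, index, rng, used)
        else:
            sig_ids = list(mixture)
            sig = sig_ids[rng.choice(len(sig_ids), p=np.array(list(mixture.values())))]
            probs = catalog.column(sig)
            ci = int(rng.choice(96, p=probs / probs.sum()))
            ch = CHANNELS[ci]
            five, sub, three = ch[0], ch[2:5], ch[6]
            context = five + sub[0] + three
            chrom, pos, gpos = index.sample(context, rng, used)
            used.add(gpos)
            ref, alt = sub[0], sub[2]
        gene = lookup.gene_at(chrom, pos)
        if gene is not None:
            if not is_indel and rng.random() < config.synonymous_fraction:
                func = "synonymous"
            else:
                func = "frameshift" if is_indel else "nonsynonymous"
        else:
            func = ["intergenic", "upstream", "downstream"][
                rng.choice(3, p=[0.8, 0.1, 0.1])
            ]
        pop_af = (
            float(rng.uniform(0.02, 0.2))
            if rng.random() < config.common_variant_fraction
            else 0.0
        )
        multi = (not is_indel) and rng.random() < config.multiallelic_fraction
        contaminated = rng.random() < config.normal_contamination_fraction
        row = {
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "variant_class": "indel" if is_indel else "SNV",
            "label": label, "signature": sig, "gene": gene, "func_class": func,
            "pop_af": pop_af, "multiallelic": multi,
            "in_neg": "Neg" in comps, "in_abr": "Abr" in comps,
            "vaf_neg": 0.0, "vaf_abr": 0.0,
        }
        for comp in COMPONENTS:
            if comp not in comps:
                continue
            vaf = config.purity[comp] * ccf / 2.0  # diploid heterozygous
            row[f"vaf_{comp.lower()}"] = vaf
            depth_t = max(1, int(rng.poisson(config.mean_depth_tumour)))
            alt_t = int(rng.binomial(depth_t, vaf))
            depth_n = max(1, int(rng.poisson(config.mean_depth_normal)))
            alt_n = int(min(depth_n, 3 + rng.binomial(3, 0.5))) if contaminated else 0
            obs[comp].append(
                {
                    "row": row, "tumour_depth": depth_t, "tumour_alt": alt_t,
                    "normal_depth": depth_n, "normal_alt": alt_n,
                }
            )
        truth_rows.append(row)

    calls: dict[tuple, list[VariantCall]] = {
        (comp, caller): [] for comp in COMPONENTS for caller in CALLERS
    }
    for comp in COMPONENTS:
        for o in obs[comp]:
            row = o["row"]
            for caller in CALLERS:
                prof = config.caller_profiles[caller]
                if row["variant_class"] == "indel" and caller not in INDEL_CALLERS:
                    continue
                if rng.random() >= prof.sensitivity:
                    continue
                vaf = o["tumour_alt"] / o["tumour_depth"]
                if prof.vaf_noise_sd > 0:
                    vaf = float(np.clip(vaf + rng.normal(0, prof.vaf_noise_sd), 0, 1))
                calls[(comp, caller)].append(
                    VariantCall(
                        chrom=row["chrom"], pos=row["pos"], ref=row["ref"],
                        alt=row["alt"], caller=caller,
                        tumour_depth=o["tumour_depth"], normal_depth=o["normal_depth"],
                        tumour_alt=o["tumour_alt"], normal_alt=o["normal_alt"],
                        vaf=vaf, pop_af=row["pop_af"], func_class=row["func_class"],
                        gene=row["gene"], multiallelic=row["multiallelic"],
                    )
                )
        # caller-specific false positives: no true mutant allele, a few
        # stray alt reads in the tumour only (caught by the alt-read filter)
        for caller in CALLERS:
            prof = config.caller_profiles[caller]
            for _ in range(prof.false_positives):
                context = "ACA"
                chrom, pos, gpos = index.sample(context, rng, used)
                used.add(gpos)
                depth_t = max(1, int(rng.poisson(config.mean_depth_tumour)))
                alt_t = int(min(depth_t, 1 + rng.binomial(3, 0.3)))
                depth_n = max(1, int(rng.poisson(config.mean_depth_normal)))
                alt = "G"
                calls[(comp, caller)].append(
                    VariantCall(
                        chrom=chrom, pos=pos, ref="C", alt=alt, caller=caller,
                        tumour_depth=depth_t, normal_depth=depth_n,
                        tumour_alt=alt_t, normal_alt=0,
                        vaf=alt_t / depth_t, pop_af=0.0, func_class="nonsynonymous",
                        gene=lookup.gene_at(chrom, pos), multiallelic=False,
                    )
                )
                truth_rows.append(
                    {
                        "chrom": chrom, "pos": pos, "ref": "C", "alt": alt,
                        "variant_class": "SNV", "label": "false_positive",
                        "signature": None, "gene": lookup.gene_at(chrom, pos),
                        "func_class": "nonsynonymous", "pop_af": 0.0,
                        "multiallelic": False, "in_neg": False, "in_abr": False,
                        "vaf_neg": 0.0, "vaf_abr": 0.0,
                    }
                )

    truth = pd.DataFrame(truth_rows)
    return SimulatedPair(
        config=config, reference=reference, genes=genes, calls=calls, truth=truth
    )


def simulate_cna_segments(
    config: SimulationConfig, genes: pd.DataFrame, reference: Reference
) -> tuple[dict, pd.DataFrame]:
    """Segment tables per component tiling every contig, with planted
    events carved out exactly over their gene intervals."""
    gene_rows = {r.gene: r for r in genes.itertuples(index=False)}
    for p in config.planted_cna:
        if p.gene not in gene_rows:
            raise ValueError(f"planted CNA names unknown gene {p.gene!r}")
    segments = {}
    truth_rows = []
    for comp in COMPONENTS:
        ploidy = config.ploidy[comp]
        base_total = int(round(ploidy))
        base_minor = base_total // 2
        planted_here = [p for p in config.planted_cna if p.component == comp]
        rows = []
        for chrom, length in reference.lengths().items():
            cuts = set(range(1, length + 1, config.segment_length)) | {length + 1}
            carved = []
            for p in planted_here:
                g = gene_rows[p.gene]
                if g.chrom != chrom:
                    continue
                cuts |= {g.start, g.end + 1}
                carved.append((g.start, g.end, p))
            bounds = sorted(cuts)
            for s, e_next in zip(bounds, bounds[1:]):
                e = e_next - 1
                total, minor = base_total, base_minor
                for gs, ge, p in carved:
                    if s >= gs and e <= ge:
                        total, minor = p.total_cn, p.minor_cn
                rows.append(
                    {
                        "chrom": chrom, "start": s, "end": e,
                        "total_cn": total, "minor_cn": minor,
                        "purity": config.purity[comp], "ploidy": ploidy,
                    }
                )
        segments[comp] = pd.DataFrame(rows)
        for p in planted_here:
            truth_rows.append(
                {
                    "gene": p.gene, "component": comp,
                    "total_cn": p.total_cn, "minor_cn": p.minor_cn,
                    "loh": p.minor_cn == 0 and p.total_cn > 0,
                }
            )
    return segments, pd.DataFrame(
        truth_rows, columns=["gene", "component", "total_cn", "minor_cn", "loh"]
    )


def simulate_methylation(
    config: SimulationConfig, genes: pd.DataFrame, reference: Reference
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe table with per-component betas plus the truth differential set.

    Background probes share one underlying beta per probe, drawn from a
    bimodal distribution kept clear of the 0.3 status threshold, with
    independent per-sample noise; planted discordant probes straddle the
    threshold with |delta| >= 0.3 by construction. A configurable
    fraction of probes fail detection p-value, sit on chrY, or carry
    SNP/cross-reactive flags to exercise the probe filters.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = config.n_probes
    if n < 1:
        raise ValueError("n_probes must be >= 1")
    gene_names = genes["gene"].to_list()
    has_gene = rng.random(n) < 0.6
    gene_col = np.where(
        has_gene, rng.choice(gene_names, size=n), None
    )
    promoter = has_gene & (rng.random(n) < 0.4)
    contigs = reference.names
    chrom = rng.choice(contigs, size=n).astype(object)
    is_y = rng.random(n) < config.y_probe_fraction
    chrom[is_y] = "chrY"
    pos = rng.integers(1, min(reference.lengths().values()), size=n)
    snp = rng.random(n) < config.snp_probe_fraction
    cross = rng.random(n) < config.cross_reactive_fraction
    fail = rng.random(n) < config.probe_fail_fraction
    fail_sample = rng.choice(list(COMPONENTS), size=n)

    detp = {c: rng.uniform(0.0, 0.01, size=n) for c in COMPONENTS}
    for c in COMPONENTS:
        mask = fail & (fail_sample == c)
        detp[c][mask] = rng.uniform(0.051, 0.5, size=int(mask.sum()))

    # background: one true beta per probe, bimodal and clear of 0.3
    methylated_state = rng.random(n) < 0.45
    base = np.where(
        methylated_state,
        0.4 + 0.55 * rng.beta(5, 2, size=n),
        0.2 * rng.beta(2, 5, size=n),
    )
    beta = {
        c: np.clip(base + rng.normal(0, config.beta_noise_sd, size=n), 0, 1)
        for c in COMPONENTS
    }

    clean = ~(fail | is_y | snp | cross)
    eligible = np.flatnonzero(clean & promoter & (gene_col != None))  # noqa: E711
    n_diff = int(round(config.discordant_probe_fraction * n))
    if n_diff > len(eligible):
        raise ValueError(
            f"cannot plant {n_diff} discordant probes: only {len(eligible)} "
            "clean promoter probes available"
        )
    planted = rng.choice(eligible, size=n_diff, replace=False) if n_diff else np.array([], int)
    meth_rows = []
    for i in planted:
        meth_comp = COMPONENTS[int(rng.integers(2))]
        for c in COMPONENTS:
            hi = c == meth_comp
            val = rng.uniform(0.5, 0.8) if hi else rng.uniform(0.05, 0.2)
            beta[c][i] = np.clip(val + rng.normal(0, config.beta_noise_sd), 0, 1)
        meth_rows.append(
            {"probe_id": f"cg{i:08d}", "gene": gene_col[i], "kind": "discordant_probe",
             "methylated_component": meth_comp}
        )

    # planted promoter hypermethylation: every clean promoter probe of the
    # gene methylated in one component, unmethylated in the other
    for planted_gene in config.planted_promoter_methylation:
        gname, comp = planted_gene["gene"], planted_gene["component"]
        idx = np.flatnonzero(clean & promoter & (gene_col == gname))
        for i in idx:
            for c in COMPONENTS:
                hi = c == comp
                val = rng.uniform(0.55, 0.85) if hi else rng.uniform(0.05, 0.15)
                beta[c][i] = np.clip(val + rng.normal(0, config.beta_noise_sd), 0, 1)
            meth_rows.append(
                {"probe_id": f"cg{i:08d}", "gene": gname,
                 "kind": "promoter_methylation", "methylated_component": comp}
            )

    probes = pd.DataFrame(
        {
            "probe_id": [f"cg{i:08d}" for i in range(n)],
            "chrom": chrom,
            "pos": pos,
            "gene": gene_col,
            "promoter": promoter,
            "snp_at_cpg": snp,
            "cross_reactive": cross,
            **{f"beta_{c}": beta[c] for c in COMPONENTS},
            **{f"detp_{c}": detp[c] for c in COMPONENTS},
        }
    )
    truth = pd.DataFrame(
        meth_rows, columns=["probe_id", "gene", "kind", "methylated_component"]
    ).drop_duplicates(subset="probe_id", keep="last").reset_index(drop=True)
    return probes, truth


def simulate_all(
    config: SimulationConfig,
    reference: Reference | None = None,
    catalog: SignatureCatalog | None = None,
) -> SimulatedPair:
    """Mutations, copy-number segments and methylation in one call."""
    pair = simulate_mutation_set(config, reference, catalog)
    pair.segments, pair.cna_truth = simulate_cna_segments(
        config, pair.genes, pair.reference
    )
    pair.probes, pair.methylation_truth = simulate_methylation(
        config, pair.genes, pair.reference
    )
    return pair
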