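"""Differential promoter methylation between two tumour components.

Probe-level beta values (fraction methylated, in [0,1]) from an
EPIC-style array are filtered, dichotomised into methylated
(beta > 0.3) versus unmethylated (beta <= 0.3), and promoter probes
whose status is opposite in the two components with an absolute beta
difference (delta) >= 0.1 are reported as differential.

Probe filtering removes, in order of attribution: probes with a
detection p-value > 0.05 in one or more samples, probes on the Y
chromosome, probes carrying common SNPs at the CpG site, and
cross-reactive probes. SNP/cross-reactive status arrives as input flags
(the published exclusion lists are external annotation, not bundled).

The probe table is wide: one row per probe with ``beta_<sample>`` and
``detp_<sample>`` columns plus ``probe_id, chrom, pos, gene, promoter,
snp_at_cpg, cross_reactive``. A long layout (probe metadata plus
``sample, beta, detection_p`` columns) is auto-detected and pivoted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

BETA_METHYLATED_THRESHOLD = 0.3  # strictly greater => methylated
DELTA_MIN = 0.1
DETECTION_P_MAX = 0.05  # strictly greater in any sample => removed

FILTER_REASONS = ("detection_p", "chrY", "snp_at_cpg", "cross_reactive")


def call_status(beta: float) -> str:
    """Dichotomise a beta value: methylated iff beta > 0.3 (strict)."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta value {beta} outside [0,1]")
    return "methylated" if beta > BETA_METHYLATED_THRESHOLD else "unmethylated"


def _sample_ids(probes: pd.DataFrame) -> list[str]:
    return [c[len("beta_"):] for c in probes.columns if c.startswith("beta_")]


def read_probe_table(path: str) -> pd.DataFrame:
    """Read a probe TSV in wide or long layout (auto-detected by header)."""
    df = pd.read_csv(path, sep="\t")
    if any(c.startswith("beta_") for c in df.columns):
        return df
    required = {"sample", "beta", "detection_p"}
    if not required.issubset(df.columns):
        raise ValueError(
            "probe table is neither wide (beta_<sample> columns) nor long "
            "(sample/beta/detection_p columns)"
        )
    meta_cols = [c for c in df.columns if c not in ("sample", "beta", "detection_p")]
    wide = df.pivot(index=meta_cols, columns="sample", values=["beta", "detection_p"])
    wide.columns = [
        ("beta_" if kind == "beta" else "detp_") + sample
        for kind, sample in wide.columns
    ]
    return wide.reset_index()


def filter_probes(probes: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove unreliable probes; returns survivors and per-reason counts.

    A probe failing several criteria is attributed to the first one in
    :data:`FILTER_REASONS`. Missing detection p-values are an error.
    """
    samples = _sample_ids(probes)
    detp_cols = [f"detp_{s}" for s in samples]
    for c in detp_cols:
        if c not in probes.columns:
            raise ValueError(f"missing detection p-value column {c}")
        if probes[c].isna().any():
            raise ValueError(f"missing detection p-values in column {c}")
    fails = {
        "detection_p": (probes[detp_cols] > DETECTION_P_MAX).any(axis=1),
        "chrY": probes["chrom"].astype(str).isin(("Y", "chrY")),
        "snp_at_cpg": probes["snp_at_cpg"].astype(bool),
        "cross_reactive": probes["cross_reactive"].astype(bool),
    }
    removed_by = pd.Series("", index=probes.index)
    for reason in FILTER_REASONS:
        newly = fails[reason] & (removed_by == "")
        removed_by[newly] = reason
    report = {reason: int((removed_by == reason).sum()) for reason in FILTER_REASONS}
    survivors = probes[removed_by == ""].reset_index(drop=True)
    assert sum(report.values()) + len(survivors) == len(probes)
    return survivors, report


@dataclass
class DifferentialProbe:
    probe_id: str
    gene: str
    beta_neg: float
    beta_abr: float
    delta: float
    status_neg: str
    status_abr: str

    def __post_init__(self):
        if self.status_neg == self.status_abr:
            raise ValueError("differential probe must have opposite statuses")
        if self.delta < DELTA_MIN:
            raise ValueError(f"delta {self.delta} below {DELTA_MIN}")


def differential_probes(
    probes: pd.DataFrame,
    neg: str,
    abr: str,
    gene_filter: set[str] | None = None,
    require_promoter: bool = True,
    delta_min: float = DELTA_MIN,
) -> list[DifferentialProbe]:
    """Promoter probes with opposite methylation status between the two
    components and |beta_neg - beta_abr| >= delta_min.

    ``gene_filter`` restricts to a gene panel (e.g. beta-catenin pathway
    genes); probes should already have passed :func:`filter_probes`.
    """
    for s in (neg, abr):
        if f"beta_{s}" not in probes.columns:
            raise ValueError(f"unknown sample id {s!r}")
    out = []
    for row in probes.itertuples(index=False):
        if require_promoter and not row.promoter:
            continue
        if gene_filter is not None and row.gene not in gene_filter:
            continue
        b_neg = getattr(row, f"beta_{neg}")
        b_abr = getattr(row, f"beta_{abr}")
        s_neg, s_abr = call_status(b_neg), call_status(b_abr)
        delta = abs(b_neg - b_abr)
        if s_neg != s_abr and delta >= delta_min:
            out.append(
                DifferentialProbe(
                    probe_id=row.probe_id,
                    gene=row.gene,
                    beta_neg=float(b_neg),
                    beta_abr=float(b_abr),
                    delta=float(delta),
                    status_neg=s_neg,
                    status_abr=s_abr,
                )
            )
    return out


def promoter_methylation_summary(
    probes: pd.DataFrame,
    genes: set[str] | None = None,
    samples: list[str] | None = None,
    methylated_fraction_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per gene and sample: promoter probe count, methylated count and
    fraction; a gene/sample is flagged promoter-methylated when more than
    ``methylated_fraction_threshold`` of its promoter probes are
    methylated. Genes with no promoter probes get a no-data row."""
    samples = samples or _sample_ids(probes)
    promoter = probes[probes["promoter"].astype(bool)]
    universe = sorted(genes) if genes is not None else sorted(
        g for g in promoter["gene"].dropna().unique()
    )
    rows = []
    for gene in universe:
        sub = promoter[promoter["gene"] == gene]
        for sample in samples:
            if len(sub) == 0:
                rows.append(
                    {
                        "gene": gene, "sample": sample, "n_probes": 0,
                        "n_methylated": None, "fraction": None,
                        "promoter_methylated": None,
                    }
                )
                continue
            betas = sub[f"beta_{sample}"]
            n_meth = int((betas > BETA_METHYLATED_THRESHOLD).sum())
            frac = n_meth / len(sub)
            rows.append(
                {
                    "gene": gene, "sample": sample, "n_probes": len(sub),
                    "n_methylated": n_meth, "fraction": frac,
                    "promoter_methylated": frac > methylated_fraction_threshold,
                }
            )
    return pd.DataFrame(rows)
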