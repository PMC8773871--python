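"""Paired-component heterogeneity statistics.

Given the filtered consensus callsets of the two dissected components of
one tumour, this module quantifies their clonal relatedness: the
shared/private partition of variant keys, overlap coefficients
(|A∩B| / min(|A|,|B|), computed separately for SNVs and indels), the
six-class substitution spectrum in pyrimidine context, a per-gene
recurrence proportion test between two groups of samples, and a
binomial-mixture subclone detector on VAFs.

The subclone detector is a simplified stand-in for full subclonal
deconvolution tools: a k-component binomial mixture on (alt, depth)
counts fitted by EM with BIC model selection, without a neutral-tail
component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2_contingency, fisher_exact

from .reference import revcomp
from .variants import ComponentCallset, ConsensusVariant, NONGENIC_CLASSES

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def overlap_coefficient(a: set, b: set) -> float:
    """|a ∩ b| / min(|a|, |b|); 0 when either set is empty."""
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


@dataclass
class ComponentPair:
    """Two components of one tumour with their shared/private structure."""

    tumour_id: str
    callset_neg: ComponentCallset
    callset_abr: ComponentCallset
    shared: set = field(default_factory=set)
    private_neg: set = field(default_factory=set)
    private_abr: set = field(default_factory=set)
    overlap_snv: float = 0.0
    overlap_indel: float = 0.0

    @classmethod
    def from_callsets(
        cls, neg: ComponentCallset, abr: ComponentCallset, tumour_id: str = ""
    ) -> "ComponentPair":
        pair = cls(tumour_id or neg.tumour_id, neg, abr)
        return partition_shared_private(pair)


def partition_shared_private(pair: ComponentPair) -> ComponentPair:
    """Split the two callsets into shared and private key sets and compute
    per-class overlap coefficients."""
    keys_neg = pair.callset_neg.keys()
    keys_abr = pair.callset_abr.keys()
    pair.shared = keys_neg & keys_abr
    pair.private_neg = keys_neg - keys_abr
    pair.private_abr = keys_abr - keys_neg
    pair.overlap_snv = overlap_coefficient(
        pair.callset_neg.keys("SNV"), pair.callset_abr.keys("SNV")
    )
    pair.overlap_indel = overlap_coefficient(
        pair.callset_neg.keys("indel"), pair.callset_abr.keys("indel")
    )
    return pair


@dataclass
class SubstitutionSpectrum:
    """Fractions of the six pyrimidine-context substitution classes."""

    fractions: np.ndarray
    counts: np.ndarray
    empty: bool = False

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SPECTRUM_CLASSES, map(float, self.fractions)))


def substitution_spectrum(snvs: list[ConsensusVariant]) -> SubstitutionSpectrum:
    """Six-class spectrum; purine-reference SNVs (G>., A>.) are folded to
    their pyrimidine reverse complement, so G>A counts as C>T."""
    counts = np.zeros(6)
    index = {c: i for i, c in enumerate(SPECTRUM_CLASSES)}
    for v in snvs:
        ref, alt = v.ref, v.alt
        if len(ref) != 1 or len(alt) != 1:
            raise ValueError(f"not an SNV: {ref}>{alt}")
        if ref not in "ACGT":
            raise ValueError(f"invalid reference allele {ref!r}")
        if ref in "AG":
            ref, alt = revcomp(ref), revcomp(alt)
        counts[index[f"{ref}>{alt}"]] += 1
    total = counts.sum()
    if total == 0:
        return SubstitutionSpectrum(np.zeros(6), counts, empty=True)
    return SubstitutionSpectrum(counts / total, counts)


def genes_carried(callset: ComponentCallset) -> set[str]:
    """Genes with at least one genic consensus variant in a sample."""
    return {
        v.gene
        for v in callset.variants
        if v.gene and (v.func_class is None or v.func_class not in NONGENIC_CLASSES)
    }


def recurrence_test(
    group1: list[ComponentCallset],
    group2: list[ComponentCallset],
    min_abs_diff: int = 3,
    method: str = "chisq",
) -> pd.DataFrame:
    """Per-gene difference in the proportion of samples carrying a variant.

    Variants in non-genic regions (intergenic/upstream/downstream) are
    excluded. Genes where the absolute difference in carrier *counts*
    between the groups is below ``min_abs_diff`` are dropped before
    testing; the rest get a two-sample proportion test (chi-squared with
    continuity correction, or Fisher's exact via ``method="fisher"``).
    """
    if not group1 or not group2:
        raise ValueError("both groups must contain at least one sample")
    carried1 = [genes_carried(cs) for cs in group1]
    carried2 = [genes_carried(cs) for cs in group2]
    n1, n2 = len(carried1), len(carried2)
    genes = sorted(set().union(*carried1, *carried2))
    rows = []
    for gene in genes:
        x1 = sum(gene in s for s in carried1)
        x2 = sum(gene in s for s in carried2)
        if abs(x1 - x2) < min_abs_diff:
            continue
        table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
        if method == "fisher":
            p = fisher_exact(table)[1]
        elif table.sum(axis=0).min() == 0:
            p = 1.0  # degenerate margin: proportions identical
        else:
            p = chi2_contingency(table, correction=True)[1]
        rows.append(
            {
                "gene": gene,
                "count_group1": x1,
                "count_group2": x2,
                "prop_group1": x1 / n1,
                "prop_group2": x2 / n2,
                "difference": x1 - x2,
                "p_value": float(p),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "count_group1", "count_group2",
            "prop_group1", "prop_group2", "difference", "p_value",
        ],
    )
    if len(df):
        # BH FDR reported alongside the raw p-values as an extension
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
        m = len(df)
        q = df["p_value"].to_numpy() * m / (np.arange(m) + 1)
        df["q_value"] = np.minimum.accumulate(q[::-1])[::-1].clip(max=1.0)
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df


@dataclass
class SubcloneFit:
    """Binomial-mixture fit of the VAF distribution."""

    k: int
    means: np.ndarray  # success probability per cluster, ascending
    weights: np.ndarray
    assignments: np.ndarray  # cluster index per variant
    log_likelihood: float
    bic: float
    bic_by_k: dict[int, float] = field(default_factory=dict)


def _binomial_mixture_em(
    alts: np.ndarray, depths: np.ndarray, k: int, max_iter: int = 300, tol: float = 1e-8
):
    n = len(alts)
    raw = alts / np.maximum(depths, 1)
    # k-quantile initialization: deterministic, order-preserving
    p = np.quantile(raw, (np.arange(k) + 0.5) / k)
    p = np.clip(p, 1e-4, 1 - 1e-4)
    w = np.full(k, 1.0 / k)
    const = gammaln(depths + 1) - gammaln(alts + 1) - gammaln(depths - alts + 1)
    ll_prev = -np.inf
    for _ in range(max_iter):
        logp = (
            np.log(w)[None, :]
            + alts[:, None] * np.log(p)[None, :]
            + (depths - alts)[:, None] * np.log1p(-p)[None, :]
            + const[:, None]
        )
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        resp = np.exp(logp - norm[:, None])
        w = resp.mean(axis=0)
        p = np.clip(
            (resp * alts[:, None]).sum(axis=0) / (resp * depths[:, None]).sum(axis=0),
            1e-6, 1 - 1e-6,
        )
        if abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
            break
        ll_prev = ll
    order = np.argsort(p)
    p, w, resp = p[order], w[order], resp[:, order]
    return p, w, resp.argmax(axis=1), ll


def fit_vaf_mixture(
    variants: list[ConsensusVariant] | None = None,
    k_max: int = 3,
    alts: np.ndarray | None = None,
    depths: np.ndarray | None = None,
) -> SubcloneFit:
    """Fit binomial mixtures with k = 1..k_max clusters and select k by BIC.

    Accepts either consensus variants (tumour alt/depth counts are taken
    from the resolved evidence) or raw count arrays. Requires at least 20
    variants with at least one alternate read overall.
    """
    if variants is not None:
        alts = np.array([v.tumour_alt for v in variants], dtype=float)
        depths = np.array([v.tumour_depth for v in variants], dtype=float)
    else:
        alts = np.asarray(alts, dtype=float)
        depths = np.asarray(depths, dtype=float)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if len(alts) < 20:
        raise ValueError(
            f"subclone fitting needs at least 20 variants, got {len(alts)}"
        )
    if alts.sum() == 0:
        raise ValueError("degenerate input: no variant has alternate reads")
    n = len(alts)
    best = None
    bic_by_k = {}
    for k in range(1, k_max + 1):
        p, w, assign, ll = _binomial_mixture_em(alts, depths, k)
        bic = -2.0 * ll + (2 * k - 1) * np.log(n)
        bic_by_k[k] = float(bic)
        if best is None or bic < best.bic:
            best = SubcloneFit(
                k=k, means=p, weights=w, assignments=assign,
                log_likelihood=ll, bic=float(bic),
            )
    best.bic_by_k = bic_by_k
    return best
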