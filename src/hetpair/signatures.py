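"""96-channel single-base-substitution (SBS) profiles and signature matching.

Mutational processes leave characteristic distributions over the 96 classes
of single-base substitution: six pyrimidine-centred substitution types
(C>A, C>G, C>T, T>A, T>C, T>G) by the 4 x 4 possible flanking bases.
Purine-reference SNVs are folded onto the pyrimidine strand by reverse
complement, following the COSMIC convention, so "G>A at CGT" counts as
A[C>T]G. Sample profiles are compared to a reference signature catalogue
by cosine similarity and the similarity matrix is clustered with
complete-linkage agglomerative clustering on Euclidean distances.

Signature *fitting* (NNLS decomposition, de novo extraction) is out of
scope: profiles are summarised by cosine similarity only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .reference import Reference, revcomp

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: Fixed channel order: substitution class major, then 5' base, then 3' base.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

_DEFAULT_CATALOG = "breast_sbs96_synthetic.tsv"


def channel_of(context: str, ref: str, alt: str) -> str:
    """96-channel label for an SNV with its reference trinucleotide context.

    ``context`` is the trinucleotide centred on the variant as read from the
    reference (so its middle base equals ``ref``). Purine references are
    folded to the reverse complement.
    """
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not centre on ref {ref!r}")
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise ValueError(f"invalid SNV {ref}>{alt}")
    if ref in "AG":  # fold purine reference onto the pyrimidine strand
        context = revcomp(context)
        ref = revcomp(ref)
        alt = revcomp(alt)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class SBSProfile:
    """Counts over the 96 channels for one sample."""

    counts: np.ndarray
    sample_id: str = ""
    n_skipped: int = 0  # SNVs at contig edges, no flanking base

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("an SBS profile has exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("channel counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def fractions(self) -> np.ndarray:
        t = self.total
        return self.counts / t if t > 0 else np.zeros(96)


@dataclass
class SignatureCatalog:
    """96 x S matrix of channel probabilities, one column per signature."""

    matrix: pd.DataFrame  # index = CHANNELS, columns = signature ids
    checksum: str = ""

    def __post_init__(self):
        if list(self.matrix.index) != list(CHANNELS):
            missing = set(CHANNELS) - set(self.matrix.index)
            if missing:
                raise ValueError(
                    f"catalogue is missing channels, e.g. {sorted(missing)[:3]}"
                )
            self.matrix = self.matrix.loc[list(CHANNELS)]
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = sums[~np.isclose(sums, 1.0, atol=1e-6)].index[0]
            raise ValueError(f"catalogue column {bad} does not sum to 1")

    @property
    def signature_ids(self) -> list[str]:
        return list(self.matrix.columns)

    def column(self, signature_id: str) -> np.ndarray:
        return self.matrix[signature_id].to_numpy()


def load_catalog(path: str | None = None) -> SignatureCatalog:
    """Load a 96 x S signature TSV (COSMIC layout: context rows, one column
    per signature). With no path, loads the bundled synthetic breast-cancer
    catalogue. A checksum of the file is recorded so outputs identify the
    catalogue actually used."""
    if path is None:
        ref = resources.files("hetpair.data").joinpath(_DEFAULT_CATALOG)
        raw = ref.read_bytes()
    else:
        with open(path, "rb") as fh:
            raw = fh.read()
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SignatureCatalog(df, checksum=hashlib.sha256(raw).hexdigest())


def build_sbs_profile(snvs, reference: Reference, sample_id: str = "") -> SBSProfile:
    """Count the 96-channel contexts of a set of SNVs against a reference.

    Variants at contig edges (no flanking base) are skipped and tallied in
    ``n_skipped``. Raises if a variant's REF disagrees with the reference.
    """
    counts = np.zeros(96)
    skipped = 0
    for v in snvs:
        if len(v.ref) != 1 or len(v.alt) != 1:
            raise ValueError(f"not an SNV: {v.ref}>{v.alt} at {v.chrom}:{v.pos}")
        if v.ref not in "ACGT":
            raise ValueError(f"invalid reference allele {v.ref!r} at {v.chrom}:{v.pos}")
        length = len(reference.contigs[v.chrom])
        if v.pos <= 1 or v.pos >= length:
            skipped += 1
            continue
        context = reference.fetch(v.chrom, v.pos - 2, v.pos + 1)
        if context[1] != v.ref:
            raise ValueError(
                f"REF mismatch at {v.chrom}:{v.pos}: variant {v.ref}, reference {context[1]}"
            )
        counts[_CHANNEL_INDEX[channel_of(context, v.ref, v.alt)]] += 1
    return SBSProfile(counts, sample_id=sample_id, n_skipped=skipped)


def cosine_similarity(p, q) -> float:
    """dot(p,q) / (|p| |q|); scale-invariant, in [0,1] for non-negative input."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    np_, nq = np.linalg.norm(p), np.linalg.norm(q)
    if np_ == 0 or nq == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(p, q) / (np_ * nq))


def profile_catalog_similarity(
    profiles: list[SBSProfile], catalog: SignatureCatalog
) -> pd.DataFrame:
    """Samples x signatures cosine-similarity matrix.

    Channel order agreement between profiles and catalogue is enforced by
    construction (both use :data:`CHANNELS`); empty profiles are an error.
    """
    rows = {}
    for prof in profiles:
        if prof.total == 0:
            raise ValueError(f"profile {prof.sample_id!r} has no mutations")
        rows[prof.sample_id] = [
            cosine_similarity(prof.counts, catalog.column(s))
            for s in catalog.signature_ids
        ]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=catalog.signature_ids
    )


def best_matches(similarity: pd.DataFrame) -> pd.Series:
    """Arg-max signature per sample."""
    return similarity.idxmax(axis=1)


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list = field(default_factory=list)
    col_order: list = field(default_factory=list)


def cluster_similarity(similarity: pd.DataFrame) -> ClusterResult:
    """Complete-linkage agglomerative clustering of both matrix dimensions
    under Euclidean distance; leaf orders are returned for heatmap layout."""
    if similarity.isna().any().any():
        raise ValueError("similarity matrix contains NaN")
    if similarity.shape[0] < 2 or similarity.shape[1] < 2:
        raise ValueError("clustering needs at least 2 rows and 2 columns")
    zr = linkage(pdist(similarity.to_numpy()), method="complete")
    zc = linkage(pdist(similarity.to_numpy().T), method="complete")
    return ClusterResult(
        row_linkage=zr,
        col_linkage=zc,
        row_order=[similarity.index[i] for i in leaves_list(zr)],
        col_order=[similarity.columns[i] for i in leaves_list(zc)],
    )
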