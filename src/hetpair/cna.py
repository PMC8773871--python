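"""Gene-level copy-number states from allele-specific segments.

Allele-specific copy-number segments (total and minor-allele copy number,
with a sample purity and ploidy from an upstream ASCAT/sequenza-style
caller) are mapped to gene intervals: where a gene spans several
segments, the segment with the largest overlap in bases is kept. The
effective state is read relative to tumour ploidy through the ratio
r = total_cn / ploidy:

    r < 0.75        loss
    0.75 <= r < 1.25  neutral
    1.25 <= r < 2     gain
    r >= 2           amplification

so at ploidy 2 the rule reduces to the conventional diploid calls
(0-1 loss, 2 neutral, 3 gain, >=4 amplification), and a tetraploid
sample with total copy number 4 and minor copy number 0 is copy neutral
with LOH. LOH is called when minor_cn == 0 and total_cn > 0. Segments
are assumed already purity-corrected by the upstream caller; purity is
carried but not used in state calls.

Coordinates are 1-based inclusive throughout; BED-style inputs must be
converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DEFAULT_STATE_THRESHOLDS = (0.75, 1.25, 2.0)


def from_bed_interval(start0: int, end0: int) -> tuple[int, int]:
    """BED half-open 0-based -> 1-based inclusive."""
    return start0 + 1, end0


def to_bed_interval(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> BED half-open 0-based."""
    return start1 - 1, end1


@dataclass
class CNASegment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    total_cn: int
    minor_cn: int
    purity: float = 1.0
    ploidy: float = 2.0

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment {self.chrom}:{self.start}-{self.end} reversed")
        if self.minor_cn > self.total_cn:
            raise ValueError(
                f"minor_cn {self.minor_cn} exceeds total_cn {self.total_cn}"
            )
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")


@dataclass
class GeneCopyState:
    gene: str
    segment: CNASegment | None
    effective_state: str | None  # loss/neutral/gain/amplification; None if uncovered
    loh: bool = False

    @property
    def covered(self) -> bool:
        return self.segment is not None


def effective_copy_state(
    total_cn: int, ploidy: float, thresholds: tuple = DEFAULT_STATE_THRESHOLDS
) -> str:
    """Ploidy-adjusted state from the ratio total_cn / ploidy."""
    if total_cn < 0:
        raise ValueError("total_cn must be non-negative")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    loss_t, gain_t, amp_t = thresholds
    r = total_cn / ploidy
    if r < loss_t:
        return "loss"
    if r < gain_t:
        return "neutral"
    if r < amp_t:
        return "gain"
    return "amplification"


def _check_non_overlapping(segments: list[CNASegment]) -> None:
    by_chrom: dict[str, list[CNASegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


def assign_segments_to_genes(
    segments: list[CNASegment],
    genes: pd.DataFrame,
    thresholds: tuple = DEFAULT_STATE_THRESHOLDS,
) -> list[GeneCopyState]:
    """One GeneCopyState per gene row (columns: gene, chrom, start, end).

    A gene overlapping several segments is assigned the one covering the
    most bases of it; exact ties go to the lower-coordinate segment.
    Genes with no overlapping segment are returned uncovered.
    """
    _check_non_overlapping(segments)
    by_chrom: dict[str, list[CNASegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.start)

    out = []
    for row in genes.itertuples(index=False):
        best, best_bases = None, 0
        for seg in by_chrom.get(row.chrom, ()):
            bases = min(row.end, seg.end) - max(row.start, seg.start) + 1
            if bases > best_bases:  # strict: ties keep the earlier segment
                best, best_bases = seg, bases
        if best is None:
            out.append(GeneCopyState(row.gene, None, None))
        else:
            out.append(
                GeneCopyState(
                    gene=row.gene,
                    segment=best,
                    effective_state=effective_copy_state(
                        best.total_cn, best.ploidy, thresholds
                    ),
                    loh=best.minor_cn == 0 and best.total_cn > 0,
                )
            )
    return out


def differential_gene_states(
    neg: list[GeneCopyState], abr: list[GeneCopyState]
) -> pd.DataFrame:
    """Genes whose effective state or LOH status differs between the two
    components. Genes uncovered in either component are reported in a
    separate ``uncovered`` flag column rather than called discordant."""
    by_gene_abr = {g.gene: g for g in abr}
    if set(by_gene_abr) != {g.gene for g in neg}:
        raise ValueError("components must share the same gene universe")
    rows = []
    for gn in neg:
        ga = by_gene_abr[gn.gene]
        uncovered = not (gn.covered and ga.covered)
        discordant = (not uncovered) and (
            gn.effective_state != ga.effective_state or gn.loh != ga.loh
        )
        if discordant or uncovered:
            rows.append(
                {
                    "gene": gn.gene,
                    "state_neg": gn.effective_state,
                    "state_abr": ga.effective_state,
                    "loh_neg": gn.loh,
                    "loh_abr": ga.loh,
                    "uncovered": uncovered,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "state_neg", "state_abr", "loh_neg", "loh_abr", "uncovered"],
    )


def read_segments(path: str, purity: float = 1.0, ploidy: float = 2.0) -> list[CNASegment]:
    """Read a segment TSV (chrom, start, end, total_cn, minor_cn; 1-based
    inclusive). Optional purity/ploidy columns override the arguments."""
    df = pd.read_csv(path, sep="\t")
    return [
        CNASegment(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            total_cn=int(r.total_cn),
            minor_cn=int(r.minor_cn),
            purity=float(getattr(r, "purity", purity)),
            ploidy=float(getattr(r, "ploidy", ploidy)),
        )
        for r in df.itertuples(index=False)
    ]


def write_gene_states(states: list[GeneCopyState], path: str) -> None:
    pd.DataFrame(
        [
            {
                "gene": g.gene,
                "covered": g.covered,
                "total_cn": g.segment.total_cn if g.covered else None,
                "minor_cn": g.segment.minor_cn if g.covered else None,
                "effective_state": g.effective_state,
                "loh": g.loh if g.covered else None,
            }
            for g in states
        ]
    ).to_csv(path, sep="\t", index=False)
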