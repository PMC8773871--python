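"""Reference sequences and trinucleotide-context indexing.

The pipeline never needs a real genome: mutations are placed on a small
synthetic multi-contig reference. Everything downstream (variant
normalization, 96-channel profiles) talks to a :class:`Reference`, which
wraps either in-memory sequences or an indexed FASTA on disk, with a
0-based half-open ``fetch`` like pyfaidx/pysam.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


class Reference:
    """A set of named contigs with coordinate-checked sequence access."""

    def __init__(self, contigs: dict[str, str]):
        self.contigs = {name: seq.upper() for name, seq in contigs.items()}

    @property
    def names(self) -> list[str]:
        return list(self.contigs)

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence for ``[start, end)`` in 0-based coordinates."""
        if chrom not in self.contigs:
            raise KeyError(f"unknown contig {chrom!r}")
        seq = self.contigs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(
                f"fetch({chrom}, {start}, {end}) outside contig of length {len(seq)}"
            )
        return seq[start:end]

    def base(self, chrom: str, pos: int) -> str:
        """Single base at 1-based position ``pos``."""
        return self.fetch(chrom, pos - 1, pos)

    @classmethod
    def from_fasta(cls, path: str) -> "Reference":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str, width: int = 70) -> None:
        """Write FASTA and build a .fai index alongside it."""
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        from pyfaidx import Faidx

        Faidx(str(path))


def synthetic_reference(
    seed: int = 2023, n_contigs: int = 5, contig_length: int = 1_000_000
) -> Reference:
    """Uniform-random synthetic contigs named chr1..chrN."""
    rng = np.random.default_rng(seed)
    contigs = {}
    for i in range(n_contigs):
        codes = rng.integers(0, 4, size=contig_length)
        contigs[f"chr{i + 1}"] = _BASE_ARR[codes].tobytes().decode()
    return Reference(contigs)


class ContextIndex:
    """Positions of every pyrimidine-centred trinucleotide in a reference.

    Used by the simulator to place a mutation whose drawn 96-channel
    context must match the reference sequence: sites are sampled from the
    positions carrying that trinucleotide (centre base C or T), so the
    context of each emitted variant is the context that was drawn.
    """

    def __init__(self, reference: Reference):
        self.reference = reference
        self._names = reference.names
        lengths = [len(reference.contigs[n]) for n in self._names]
        self._offsets = np.concatenate([[0], np.cumsum(lengths)])
        by_ctx: dict[str, list[np.ndarray]] = {}
        for ci, name in enumerate(self._names):
            seq = np.frombuffer(reference.contigs[name].encode(), dtype="S1")
            codes = np.full(seq.shape, -1, dtype=np.int8)
            for b, base in enumerate(BASES):
                codes[seq == base.encode()] = b
            centre = codes[1:-1]
            left = codes[:-2]
            right = codes[2:]
            valid = (centre >= 0) & (left >= 0) & (right >= 0)
            # pyrimidine centres only: C (1) or T (3)
            pyr = valid & ((centre == 1) | (centre == 3))
            tri = left * 16 + centre * 4 + right
            for code in np.unique(tri[pyr]):
                ctx = BASES[code // 16] + BASES[(code // 4) % 4] + BASES[code % 4]
                pos0 = np.flatnonzero(pyr & (tri == code)) + 1  # centre, 0-based
                by_ctx.setdefault(ctx, []).append(pos0 + self._offsets[ci])
        self._positions = {
            ctx: np.concatenate(chunks) for ctx, chunks in by_ctx.items()
        }

    def n_sites(self, context: str) -> int:
        return len(self._positions.get(context, ()))

    def decode(self, gpos: int) -> tuple[str, int]:
        """Global 0-based position -> (contig, 1-based position)."""
        ci = int(np.searchsorted(self._offsets, gpos, side="right") - 1)
        return self._names[ci], int(gpos - self._offsets[ci]) + 1

    def sample(
        self, context: str, rng: np.random.Generator, used: set[int]
    ) -> tuple[str, int, int]:
        """Draw an unused site with the given trinucleotide context.

        Returns (contig, 1-based position, global position); the global
        position is added to ``used`` by the caller to forbid collisions.
        """
        pool = self._positions.get(context)
        if pool is None or len(pool) == 0:
            raise ValueError(f"reference has no site with context {context!r}")
        for _ in range(1000):
            gpos = int(pool[rng.integers(len(pool))])
            if gpos not in used:
                chrom, pos = self.decode(gpos)
                return chrom, pos, gpos
        raise ValueError(
            f"could not place a mutation with context {context!r}: "
            "reference too short for the requested mutation count"
        )
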