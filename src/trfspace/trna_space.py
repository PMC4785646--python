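"""Mature tRNA construction and the genomic "tRNA space".

A tRNA gene is transcribed, its introns (if any) spliced out, and the
non-templated trinucleotide CCA appended enzymatically to the 3' end.  The
mature sequence therefore differs from the genomic locus in three ways that
matter for fragment mapping: strand resolution, absence of introns, and the
CCA tail.  This module parses a genome (FASTA) and a tRNA gene annotation
(BED12 + 3 auxiliary columns), builds :class:`MatureTRNA` objects carrying an
explicit mature-position -> genomic-coordinate map, and merges the annotated
loci into the strand-ignorant interval set called *tRNA space*: the portion
of the genome that harbors tRNA genes.

Coordinates are 0-based half-open internally; human-readable reports print
1-based inclusive positions.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "NONTEMPLATED",
    "GenomeSequence",
    "TRNALocus",
    "MatureTRNA",
    "TRNASpaceIntervals",
    "reverse_complement",
    "read_genome_fasta",
    "read_trna_annotation",
    "extract_locus_sequence",
    "build_mature_trna",
    "build_trna_space",
    "write_mature_fasta",
    "read_mature_fasta",
    "write_space_bed",
    "read_space_bed",
]

#: Marker used in :attr:`MatureTRNA.coord_map` for the three 3'-terminal CCA
#: positions, which have no genomic template.
NONTEMPLATED = None

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/contig: uppercase DNA over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - _VALID_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.name!r} contains non-DNA characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TRNALocus:
    """An annotated genomic tRNA gene.

    ``intron_blocks`` and ``anticodon_block`` are genomic 0-based half-open
    sub-intervals of ``[start, end)``.
    """

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    compartment: str
    intron_blocks: tuple[tuple[int, int], ...] = ()
    anticodon_block: tuple[int, int] | None = None
    amino_acid: str = ""
    anticodon: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.name}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: strand must be '+' or '-'")
        prev_end = None
        for a, b in self.intron_blocks:
            if not (self.start <= a < b <= self.end):
                raise ValueError(f"{self.name}: intron block [{a},{b}) outside locus")
            if prev_end is not None and a < prev_end:
                raise ValueError(f"{self.name}: intron blocks overlap or unsorted")
            prev_end = b
        if self.anticodon_block is not None:
            a, b = self.anticodon_block
            if b - a != 3:
                raise ValueError(f"{self.name}: anticodon block must span 3 nt")
            if not (self.start <= a < b <= self.end):
                raise ValueError(f"{self.name}: anticodon block outside locus")
            for ia, ib in self.intron_blocks:
                if a < ib and ia < b:
                    raise ValueError(f"{self.name}: anticodon block inside an intron")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def total_intron_length(self) -> int:
        return sum(b - a for a, b in self.intron_blocks)


@dataclass(frozen=True)
class MatureTRNA:
    """A spliced, strand-resolved, CCA-appended mature tRNA sequence.

    ``coord_map[i]`` is ``(chrom, genomic_position, strand)`` for templated
    mature position ``i`` (0-based), or :data:`NONTEMPLATED` for the three
    CCA positions.  ``anticodon_mature_start`` is the 1-based mature position
    of the anticodon's first base (0 when unknown).
    """

    name: str
    seq: str
    coord_map: tuple[tuple[str, int, str] | None, ...]
    anticodon_mature_start: int = 0
    contains_n: bool = False

    def __post_init__(self) -> None:
        if not self.seq.endswith("CCA"):
            raise ValueError(f"{self.name}: mature sequence must end with CCA")
        if len(self.coord_map) != len(self.seq):
            raise ValueError(f"{self.name}: coord_map length mismatch")
        if any(c is not NONTEMPLATED for c in self.coord_map[-3:]) or any(
            c is NONTEMPLATED for c in self.coord_map[:-3]
        ):
            raise ValueError(
                f"{self.name}: exactly the last 3 positions must be non-templated"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


class TRNASpaceIntervals:
    """Merged, strand-ignorant genomic interval set covering all tRNA loci.

    Supports fast full-containment queries (used millions of times during a
    genome scan) via per-chromosome sorted merged intervals and bisect.
    """

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]]) -> None:
        self._merged: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in intervals.items():
            merged: list[tuple[int, int]] = []
            for a, b in sorted(ivs):
                if a >= b:
                    raise ValueError(f"empty interval [{a},{b}) on {chrom}")
                if merged and a <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], b))
                else:
                    merged.append((a, b))
            if merged:
                self._merged[chrom] = merged
        self._starts = {c: [a for a, _ in ivs] for c, ivs in self._merged.items()}

    @classmethod
    def empty(cls) -> "TRNASpaceIntervals":
        return cls({})

    @property
    def intervals(self) -> dict[str, list[tuple[int, int]]]:
        return {c: list(ivs) for c, ivs in self._merged.items()}

    @property
    def total_span(self) -> int:
        return sum(b - a for ivs in self._merged.values() for a, b in ivs)

    def __len__(self) -> int:
        return sum(len(ivs) for ivs in self._merged.values())

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) is fully contained in one merged interval."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, start) - 1
        if i < 0:
            return False
        a, b = self._merged[chrom][i]
        return a <= start and end <= b

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TRNASpaceIntervals) and self._merged == other._merged


def read_genome_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a (multi-record) genome FASTA; sequences are uppercased.

    Duplicate record names and empty files are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: not FASTA (expected '>' header)"
                    )
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    genome: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
        genome[rec.id] = GenomeSequence(name=rec.id, seq=str(rec.seq).upper())
    if not genome:
        raise ValueError(f"{path}: no FASTA records found")
    return genome


def _parse_block_list(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x != ""]


def read_trna_annotation(
    path: str | Path, mito_chrom: str = "chrM"
) -> list[TRNALocus]:
    """Parse a BED12+3 tRNA gene annotation.

    Columns 1-12 are standard BED12 (blocks = exons; introns are the gaps
    between consecutive blocks).  Column 13 carries the amino acid, column 14
    the anticodon, column 15 the anticodon's 0-based genomic start.  A locus
    is mitochondrial iff its chromosome equals ``mito_chrom``.
    """
    loci: list[TRNALocus] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 15:
                raise ValueError(
                    f"{path}: line {lineno}: expected 15 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5]
            n_blocks = int(fields[9])
            sizes = _parse_block_list(fields[10])
            offsets = _parse_block_list(fields[11])
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(
                    f"{path}: line {lineno}: block count/size/start mismatch"
                )
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            for a, b in exons:
                if not (start <= a < b <= end):
                    raise ValueError(
                        f"{path}: line {lineno}: block [{a},{b}) outside [{start},{end})"
                    )
            introns = tuple(
                (exons[i][1], exons[i + 1][0])
                for i in range(len(exons) - 1)
                if exons[i + 1][0] > exons[i][1]
            )
            amino_acid, anticodon = fields[12], fields[13]
            ac_start = int(fields[14])
            try:
                locus = TRNALocus(
                    name=name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    compartment="mitochondrial" if chrom == mito_chrom else "nuclear",
                    intron_blocks=introns,
                    anticodon_block=(ac_start, ac_start + 3),
                    amino_acid=amino_acid,
                    anticodon=anticodon,
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            loci.append(locus)
    return loci


def extract_locus_sequence(
    genome: Mapping[str, GenomeSequence], locus: TRNALocus
) -> str:
    """Genomic subsequence of a locus, 5'->3' in transcript orientation.

    Minus-strand loci are reverse-complemented.
    """
    if locus.chrom not in genome:
        raise KeyError(f"{locus.name}: unknown chromosome {locus.chrom!r}")
    chrom = genome[locus.chrom]
    if locus.end > chrom.length:
        raise ValueError(
            f"{locus.name}: interval [{locus.start},{locus.end}) exceeds "
            f"{locus.chrom} length {chrom.length}"
        )
    sub = chrom.seq[locus.start : locus.end]
    return reverse_complement(sub) if locus.strand == "-" else sub


def build_mature_trna(locus: TRNALocus, locus_seq: str) -> MatureTRNA:
    """Splice introns out of a transcript-oriented locus sequence and append CCA.

    The returned coordinate map records, for every templated mature position,
    the genomic position it reads from; the three CCA positions map to
    :data:`NONTEMPLATED`.
    """
    if len(locus_seq) != locus.span:
        raise ValueError(
            f"{locus.name}: locus_seq length {len(locus_seq)} != span {locus.span}"
        )
    intronic = set()
    for a, b in locus.intron_blocks:
        intronic.update(range(a, b))
    chars: list[str] = []
    coord: list[tuple[str, int, str] | None] = []
    for i, base in enumerate(locus_seq):
        gpos = locus.start + i if locus.strand == "+" else locus.end - 1 - i
        if gpos in intronic:
            continue
        chars.append(base)
        coord.append((locus.chrom, gpos, locus.strand))
    if not chars:
        raise ValueError(f"{locus.name}: intron removal left an empty transcript")
    seq = "".join(chars) + "CCA"
    coord.extend([NONTEMPLATED] * 3)

    ac_mature_start = 0
    if locus.anticodon_block is not None:
        a, b = locus.anticodon_block
        first = a if locus.strand == "+" else b - 1
        target = (locus.chrom, first, locus.strand)
        for i, c in enumerate(coord):
            if c == target:
                ac_mature_start = i + 1
                break
    return MatureTRNA(
        name=locus.name,
        seq=seq,
        coord_map=tuple(coord),
        anticodon_mature_start=ac_mature_start,
        contains_n="N" in seq,
    )


def build_trna_space(loci: Sequence[TRNALocus]) -> TRNASpaceIntervals:
    """Merge tRNA gene loci into the strand-ignorant tRNA-space interval set."""
    if not loci:
        raise ValueError("cannot build tRNA space from an empty locus list")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append((locus.start, locus.end))
    return TRNASpaceIntervals(by_chrom)


def write_mature_fasta(matures: Iterable[MatureTRNA], path: str | Path) -> None:
    """Write mature tRNA sequences (CCA included) as FASTA, ids = locus names."""
    with open(path, "w") as fh:
        for m in matures:
            fh.write(f">{m.name} anticodon_mature_start={m.anticodon_mature_start}\n")
            fh.write(m.seq + "\n")


def read_mature_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a mature tRNA FASTA back as (name, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_space_bed(space: TRNASpaceIntervals, path: str | Path) -> None:
    """Write the merged tRNA-space intervals as BED3."""
    with open(path, "w") as fh:
        for chrom in sorted(space.intervals):
            for a, b in space.intervals[chrom]:
                fh.write(f"{chrom}\t{a}\t{b}\n")


def read_space_bed(path: str | Path) -> TRNASpaceIntervals:
    """Read a BED3 file into a :class:`TRNASpaceIntervals`."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, a, b = line.split("\t")[:3]
            by_chrom.setdefault(chrom, []).append((int(a), int(b)))
    return TRNASpaceIntervals(by_chrom)
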