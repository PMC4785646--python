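"""Synthetic genomes with planted tRNA-ambiguity mechanisms, plus naive oracles.

The generator plants, in an i.i.d. random background, every mechanism by
which a non-tRNA genomic sequence can masquerade as a tRNA fragment:

* intact tRNA genes (some intron-containing), which define tRNA space;
* truncated partial copies of those genes (<= 50 nt by default) outside
  tRNA space, mirroring short tRNA-class repeat segments;
* tRNA-lookalikes — gene bodies carrying a handful of point substitutions;
* CCA decoys — verbatim copies of a mature tRNA's CCA-ending terminal
  16-mer planted away from any tRNA gene.

Decoys are planted verbatim so their expected ambiguity is certain under
exact matching; lookalikes are mutated so k-mer sharing is partial.  Every
expected label in the emitted :class:`TruthTable` is recomputed from the
finished genome by exhaustive exact scanning — never assumed from the
construction.  :func:`brute_force_occurrences` is the deliberately naive
per-position oracle the fast scanning code is tested against.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .trna_space import (
    GenomeSequence,
    MatureTRNA,
    TRNALocus,
    TRNASpaceIntervals,
    build_mature_trna,
    build_trna_space,
    extract_locus_sequence,
    reverse_complement,
)

__all__ = [
    "SyntheticGenomeSpec",
    "PlantedFeature",
    "ReadTruth",
    "TruthTable",
    "SyntheticFixture",
    "generate_genome",
    "generate_reads",
    "brute_force_occurrences",
    "write_fixture",
    "write_reads_fastq",
]

_TRNA_BODY_LEN = 72
_ANTICODON_OFFSET = 33  # 0-based mature offset of anticodon first base (pos 34)
_INTRON_AFTER = 37  # canonical intron insertion point, one base 3' of anticodon
_CCA_DECOY_LEN = 16


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Study conditions for one synthetic genome.

    Defaults: a 100 kb chromosome with 6 tRNA genes (2 intron-containing),
    10 partial copies, 3 lookalikes, 3 CCA decoys, at human-like 41% GC.
    """

    genome_length: int = 100_000
    n_trnas: int = 6
    n_intronic_trnas: int = 2
    n_partial_copies: int = 10
    max_partial_len: int = 50
    n_lookalikes: int = 3
    n_cca_decoys: int = 3
    gc_content: float = 0.41
    seed: int = 0
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        if min(
            self.n_trnas,
            self.n_intronic_trnas,
            self.n_partial_copies,
            self.n_lookalikes,
            self.n_cca_decoys,
        ) < 0:
            raise ValueError("feature counts must be >= 0")
        if self.n_intronic_trnas > self.n_trnas:
            raise ValueError("n_intronic_trnas cannot exceed n_trnas")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if (self.n_partial_copies or self.n_lookalikes or self.n_cca_decoys) and not self.n_trnas:
            raise ValueError("decoy features require at least one tRNA")


@dataclass(frozen=True)
class PlantedFeature:
    feature_id: str
    kind: str  # TRNA | PARTIAL | LOOKALIKE | CCA_DECOY
    chrom: str
    start: int
    end: int
    strand: str
    source_trna: str | None = None


@dataclass(frozen=True)
class ReadTruth:
    seq: str
    origin_feature_id: str
    expected_ambiguity: str  # EXCLUSIVE | AMBIGUOUS
    expected_fragment_type: str | None = None


@dataclass
class TruthTable:
    features: list[PlantedFeature] = field(default_factory=list)
    reads: list[ReadTruth] = field(default_factory=list)


@dataclass
class SyntheticFixture:
    """A generated genome plus everything derived from it."""

    spec: SyntheticGenomeSpec
    genome: dict[str, GenomeSequence]
    loci: list[TRNALocus]
    matures: list[MatureTRNA]
    space: TRNASpaceIntervals
    lookalike_seqs: list[tuple[str, str]]
    truth: TruthTable


_AA_BY_ANTICODON_ROW = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_BASES = "TCAG"


def _amino_acid(anticodon: str) -> str:
    codon = reverse_complement(anticodon)
    idx = _BASES.index(codon[0]) * 16 + _BASES.index(codon[1]) * 4 + _BASES.index(codon[2])
    aa = _AA_BY_ANTICODON_ROW[idx]
    return "SeC" if aa == "*" else aa


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


class _Placer:
    """Places features at non-overlapping random positions with a margin."""

    def __init__(self, rng: np.random.Generator, genome_length: int, margin: int = 10):
        self.rng = rng
        self.length = genome_length
        self.margin = margin
        self.occupied: list[tuple[int, int]] = []

    def place(self, feat_len: int, retries: int = 2000) -> int:
        lo, hi = 50, self.length - feat_len - 50
        if hi <= lo:
            raise ValueError("genome_length too small for planted features")
        for _ in range(retries):
            start = int(self.rng.integers(lo, hi))
            end = start + feat_len
            if all(
                end + self.margin <= a or b + self.margin <= start
                for a, b in self.occupied
            ):
                self.occupied.append((start, end))
                return start
        raise ValueError(
            "could not place all features without overlap; increase genome_length"
        )


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticFixture:
    """Build a deterministic synthetic genome with planted features and truth.

    tRNA genes are random 72-nt bodies (anticodon at mature positions 34-36;
    intron-containing genes carry a 10-20 nt intron immediately 3' of the
    anticodon).  Partial copies, lookalikes and CCA decoys are planted
    outside tRNA space on random strands.  Every planted feature's sequence
    is re-read from the finished genome as a self-check.
    """
    rng = np.random.default_rng(spec.seed)
    chrom = spec.chrom_name
    genome_arr = bytearray(_random_dna(rng, spec.genome_length, spec.gc_content), "ascii")
    placer = _Placer(rng, spec.genome_length)
    features: list[PlantedFeature] = []
    planted_seqs: list[str] = []  # genomic-orientation string per feature
    loci: list[TRNALocus] = []

    def plant(seq: str) -> int:
        start = placer.place(len(seq))
        genome_arr[start : start + len(seq)] = seq.encode()
        planted_seqs.append(seq)
        return start

    bodies: list[str] = []  # mature bodies without CCA, transcript orientation
    gene_seqs: list[str] = []  # genomic-template transcripts (introns included)
    for i in range(spec.n_trnas):
        body = _random_dna(rng, _TRNA_BODY_LEN, spec.gc_content)
        anticodon = body[_ANTICODON_OFFSET : _ANTICODON_OFFSET + 3]
        intronic = i < spec.n_intronic_trnas
        if intronic:
            intron = _random_dna(rng, int(rng.integers(10, 21)), spec.gc_content)
            gene = body[:_INTRON_AFTER] + intron + body[_INTRON_AFTER:]
        else:
            intron = ""
            gene = body
        strand = "+" if rng.integers(2) == 0 else "-"
        planted = gene if strand == "+" else reverse_complement(gene)
        start = plant(planted)
        end = start + len(gene)
        if strand == "+":
            intron_blocks = (
                ((start + _INTRON_AFTER, start + _INTRON_AFTER + len(intron)),)
                if intron
                else ()
            )
            ac_block = (start + _ANTICODON_OFFSET, start + _ANTICODON_OFFSET + 3)
        else:
            intron_blocks = (
                ((end - _INTRON_AFTER - len(intron), end - _INTRON_AFTER),)
                if intron
                else ()
            )
            ac_block = (end - _ANTICODON_OFFSET - 3, end - _ANTICODON_OFFSET)
        aa = _amino_acid(anticodon)
        name = f"tRNA-{aa}-{anticodon}-{i + 1}"
        loci.append(
            TRNALocus(
                name=name,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                compartment="nuclear",
                intron_blocks=intron_blocks,
                anticodon_block=ac_block,
                amino_acid=aa,
                anticodon=anticodon,
            )
        )
        features.append(
            PlantedFeature(
                feature_id=name, kind="TRNA", chrom=chrom, start=start, end=end,
                strand=strand,
            )
        )
        bodies.append(body)
        gene_seqs.append(gene)

    for j in range(spec.n_partial_copies):
        src = int(rng.integers(spec.n_trnas))
        gene = gene_seqs[src]
        plen = int(rng.integers(20, min(spec.max_partial_len, len(gene)) + 1))
        off = int(rng.integers(0, len(gene) - plen + 1))
        frag = gene[off : off + plen]
        strand = "+" if rng.integers(2) == 0 else "-"
        planted = frag if strand == "+" else reverse_complement(frag)
        start = plant(planted)
        features.append(
            PlantedFeature(
                feature_id=f"partial-{j + 1}", kind="PARTIAL", chrom=chrom,
                start=start, end=start + plen, strand=strand,
                source_trna=loci[src].name,
            )
        )

    lookalike_seqs: list[tuple[str, str]] = []
    for j in range(spec.n_lookalikes):
        src = int(rng.integers(spec.n_trnas))
        body = list(bodies[src])
        n_subs = int(rng.integers(2, 11))
        for pos in rng.choice(len(body), size=n_subs, replace=False):
            body[pos] = str(rng.choice([b for b in "ACGT" if b != body[pos]]))
        seq = "".join(body)
        strand = "+" if rng.integers(2) == 0 else "-"
        planted = seq if strand == "+" else reverse_complement(seq)
        start = plant(planted)
        fid = f"lookalike-{j + 1}"
        features.append(
            PlantedFeature(
                feature_id=fid, kind="LOOKALIKE", chrom=chrom, start=start,
                end=start + len(seq), strand=strand, source_trna=loci[src].name,
            )
        )
        lookalike_seqs.append((fid, seq))

    for j in range(spec.n_cca_decoys):
        src = int(rng.integers(spec.n_trnas))
        mature_seq = bodies[src] + "CCA"
        decoy = mature_seq[-_CCA_DECOY_LEN:]
        strand = "+" if rng.integers(2) == 0 else "-"
        planted = decoy if strand == "+" else reverse_complement(decoy)
        start = plant(planted)
        features.append(
            PlantedFeature(
                feature_id=f"cca-decoy-{j + 1}", kind="CCA_DECOY", chrom=chrom,
                start=start, end=start + len(decoy), strand=strand,
                source_trna=loci[src].name,
            )
        )

    genome = {chrom: GenomeSequence(name=chrom, seq=genome_arr.decode())}
    matures = [
        build_mature_trna(locus, extract_locus_sequence(genome, locus))
        for locus in loci
    ]
    space = build_trna_space(loci) if loci else TRNASpaceIntervals.empty()

    # self-check: every planted feature reads back from the finished genome
    for feat, planted in zip(features, planted_seqs):
        if genome[feat.chrom].seq[feat.start : feat.end] != planted:
            raise AssertionError(f"feature {feat.feature_id} does not read back")
    for locus, gene in zip(loci, gene_seqs):
        if extract_locus_sequence(genome, locus) != gene:
            raise AssertionError(f"locus {locus.name} does not read back")

    return SyntheticFixture(
        spec=spec,
        genome=genome,
        loci=loci,
        matures=matures,
        space=space,
        lookalike_seqs=lookalike_seqs,
        truth=TruthTable(features=features),
    )


def _outside_occurrences(
    genome: Mapping[str, GenomeSequence], query: str, space: TRNASpaceIntervals
) -> int:
    """Exact both-strand outside-of-space copy count via overlapping regex.

    Used to compute expected truth labels at generation time; written on a
    different code path (re lookahead) than the package's scanning routines.
    """
    rc = reverse_complement(query)
    patterns = {query, rc}
    outside = 0
    for chrom in genome.values():
        for pat in patterns:
            for m in re.finditer(f"(?=({re.escape(pat)}))", chrom.seq):
                s = m.start()
                if not space.contains(chrom.name, s, s + len(pat)):
                    outside += 1
    return outside


def _window_fragment_type(
    start: int, end: int, mature_len: int, anticodon_start: int, window: int = 2
) -> str:
    lo, hi = anticodon_start - window, anticodon_start + 2 + window
    if start == 1:
        return "5'-half" if lo <= end <= hi else "5'-tRF"
    if end == mature_len:
        return "3'-half" if lo <= start <= hi else "3'-tRF"
    return "i-tRF"


def generate_reads(
    fixture: SyntheticFixture,
    n_reads: int = 1000,
    length_range: tuple[int, int] = (16, 30),
    seed: int = 0,
    mature_fraction: float = 0.6,
) -> list[ReadTruth]:
    """Sample reads from mature tRNAs and planted decoy features.

    Mature-origin reads are random windows of the spliced, CCA-appended
    sequences (so junction- and CCA-spanning reads arise naturally); decoy
    reads are windows of the planted feature in its plant orientation.  Each
    read's expected ambiguity is recomputed from the finished genome by
    exhaustive exact scanning.  Appends to and returns the fixture's truth.
    """
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length_range")
    if fixture.matures and lo > min(m.length for m in fixture.matures):
        raise ValueError("length_range minimum exceeds the shortest mature tRNA")
    rng = np.random.default_rng(seed)
    decoys = [f for f in fixture.truth.features if f.kind != "TRNA"]
    reads: list[ReadTruth] = []
    for _ in range(n_reads):
        from_mature = (not decoys) or (
            bool(fixture.matures) and rng.random() < mature_fraction
        )
        if from_mature:
            m = fixture.matures[int(rng.integers(len(fixture.matures)))]
            length = int(rng.integers(lo, min(hi, m.length) + 1))
            start0 = int(rng.integers(0, m.length - length + 1))
            seq = m.seq[start0 : start0 + length]
            origin = m.name
            ftype = _window_fragment_type(
                start0 + 1, start0 + length, m.length, m.anticodon_mature_start
            )
        else:
            feat = decoys[int(rng.integers(len(decoys)))]
            fseq = fixture.genome[feat.chrom].seq[feat.start : feat.end]
            if feat.strand == "-":
                fseq = reverse_complement(fseq)
            length = int(rng.integers(lo, min(hi, len(fseq)) + 1))
            start0 = int(rng.integers(0, len(fseq) - length + 1))
            seq = fseq[start0 : start0 + length]
            origin = feat.feature_id
            ftype = None
        outside = _outside_occurrences(fixture.genome, seq, fixture.space)
        reads.append(
            ReadTruth(
                seq=seq,
                origin_feature_id=origin,
                expected_ambiguity="EXCLUSIVE" if outside == 0 else "AMBIGUOUS",
                expected_fragment_type=ftype,
            )
        )
    fixture.truth.reads.extend(reads)
    return reads


def brute_force_occurrences(
    genome: Mapping[str, GenomeSequence], query: str
) -> list[tuple[str, int, int, str]]:
    """Naive O(genome x query) both-strand exact scan; the test oracle.

    Checks every window by direct slice comparison.  A palindromic query
    matching a window both ways is reported once, as '+'.
    """
    if not query:
        raise ValueError("query must be non-empty")
    rc = reverse_complement(query)
    L = len(query)
    hits: list[tuple[str, int, int, str]] = []
    for chrom in genome.values():
        seq = chrom.seq
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            if window == query:
                hits.append((chrom.name, i, i + L, "+"))
            elif window == rc:
                hits.append((chrom.name, i, i + L, "-"))
    return hits


def write_fixture(fixture: SyntheticFixture, out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture as plain-text files: FASTA, BED12+3, BED, .out, TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "annotation": out / "trnas.bed",
        "lookalikes_bed": out / "lookalikes.bed",
        "lookalikes_fasta": out / "lookalikes.fa",
        "repeats": out / "repeats.out",
        "truth": out / "truth_features.tsv",
    }
    with open(paths["genome"], "w") as fh:
        for chrom in fixture.genome.values():
            fh.write(f">{chrom.name}\n")
            for i in range(0, chrom.length, 70):
                fh.write(chrom.seq[i : i + 70] + "\n")
    with open(paths["annotation"], "w") as fh:
        for locus in fixture.loci:
            exons: list[tuple[int, int]] = []
            prev = locus.start
            for a, b in locus.intron_blocks:
                exons.append((prev, a))
                prev = b
            exons.append((prev, locus.end))
            sizes = ",".join(str(b - a) for a, b in exons)
            offsets = ",".join(str(a - locus.start) for a, b in exons)
            ac = locus.anticodon_block[0] if locus.anticodon_block else 0
            fh.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.name}\t0\t"
                f"{locus.strand}\t{locus.start}\t{locus.end}\t0\t{len(exons)}\t"
                f"{sizes}\t{offsets}\t{locus.amino_acid}\t{locus.anticodon}\t{ac}\n"
            )
    lookalikes = {f.feature_id: f for f in fixture.truth.features if f.kind == "LOOKALIKE"}
    with open(paths["lookalikes_bed"], "w") as fh:
        for fid, feat in lookalikes.items():
            fh.write(
                f"{feat.chrom}\t{feat.start}\t{feat.end}\t{fid}\t0\t{feat.strand}\n"
            )
    with open(paths["lookalikes_fasta"], "w") as fh:
        for fid, seq in fixture.lookalike_seqs:
            fh.write(f">{fid}\n{seq}\n")
    with open(paths["repeats"], "w") as fh:
        fh.write(
            "   SW   perc perc perc  query     position in query         matching"
            "  repeat          position in repeat\n"
            "score   div. del. ins.  sequence  begin  end      (left)    repeat"
            "  class/family    begin  end  (left)  ID\n\n"
        )
        rm_id = 0
        for feat in fixture.truth.features:
            if feat.kind != "PARTIAL":
                continue
            rm_id += 1
            strand = "C" if feat.strand == "-" else "+"
            left = fixture.genome[feat.chrom].length - feat.end
            fh.write(
                f"  463  1.3 0.6 1.7  {feat.chrom}  {feat.start + 1}  {feat.end}"
                f"  ({left})  {strand}  {feat.source_trna}  tRNA  1"
                f"  {feat.end - feat.start}  (0)  {rm_id}\n"
            )
    with open(paths["truth"], "w") as fh:
        fh.write("feature_id\tkind\tchrom\tstart\tend\tstrand\tsource_trna\n")
        for feat in fixture.truth.features:
            fh.write(
                f"{feat.feature_id}\t{feat.kind}\t{feat.chrom}\t{feat.start}\t"
                f"{feat.end}\t{feat.strand}\t{feat.source_trna or '.'}\n"
            )
    return paths


def write_reads_fastq(
    reads: Sequence[ReadTruth], path: str | Path, truth_path: str | Path | None = None
) -> None:
    """Write sampled reads as FASTQ (constant quality) plus an optional truth TSV."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads, 1):
            fh.write(f"@read{i} origin={read.origin_feature_id}\n{read.seq}\n+\n")
            fh.write("I" * len(read.seq) + "\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("read_seq\torigin_feature_id\texpected_ambiguity\texpected_fragment_type\n")
            for read in reads:
                fh.write(
                    f"{read.seq}\t{read.origin_feature_id}\t{read.expected_ambiguity}\t"
                    f"{read.expected_fragment_type or '.'}\n"
                )
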