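"""Ambiguity-aware classification of small-RNA reads as tRNA fragments.

Reads are matched to mature tRNA sequences with zero mismatches (exact
substring placement only: mismatch/indel tolerance is precisely what lets
non-tRNA reads masquerade as tRFs).  Each placed read gets a fragment type
from its mature coordinates — 5'-tRF / 5'-half (starting at position 1),
i-tRF (internal), 3'-half / 3'-tRF (reaching the CCA-inclusive 3' end),
halves being the variants whose inner boundary falls in a window around the
anticodon — and, crucially, a genomic ambiguity label: a read is EXCLUSIVE
only when it has zero exact copies in the genome outside tRNA space, and
AMBIGUOUS otherwise.  Labeling requires the genome; transcript-space-only
labeling is not offered.

Per-tRNA fragment profiles keep one row per distinct fragment sequence.
Distinct fragments are never collapsed into a composite count, because
distinct fragments from the same tRNA can behave independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .kmer_ambiguity import count_sequence_occurrences
from .trna_space import GenomeSequence, MatureTRNA, TRNASpaceIntervals

__all__ = [
    "FragmentType",
    "Ambiguity",
    "SmallRNARead",
    "Placement",
    "TRFCall",
    "FragmentProfile",
    "load_and_dereplicate",
    "length_filter",
    "place_on_matures",
    "call_fragment_type",
    "label_ambiguity",
    "classify_reads",
    "build_profiles",
    "write_calls_tsv",
    "write_profiles_tsv",
]

_ACGTN = frozenset("ACGTN")
_ACGT = frozenset("ACGT")


class FragmentType(str, Enum):
    FIVE_TRF = "5'-tRF"
    FIVE_HALF = "5'-half"
    I_TRF = "i-tRF"
    THREE_HALF = "3'-half"
    THREE_TRF = "3'-tRF"


class Ambiguity(str, Enum):
    EXCLUSIVE = "EXCLUSIVE"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class SmallRNARead:
    """A dereplicated small-RNA read with its multiplicity."""

    seq: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("read count must be >= 1")
        if not _ACGTN.issuperset(self.seq):
            raise ValueError(f"read contains non-DNA characters: {self.seq!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Placement:
    """One exact placement of a read on a mature tRNA (1-based inclusive)."""

    trna_name: str
    start: int
    end: int


@dataclass
class TRFCall:
    """Full classification of one read: placements, types, ambiguity, filter."""

    read: SmallRNARead
    placements: list[Placement] = field(default_factory=list)
    fragment_types: list[FragmentType] = field(default_factory=list)
    ambiguity: Ambiguity | None = None
    outside_count: int = 0
    filtered: str = "PASS"  # PASS | TOO_SHORT

    @property
    def is_multi(self) -> bool:
        """Read places on more than one mature tRNA position."""
        return len(self.placements) > 1


@dataclass
class FragmentProfile:
    """Per-tRNA fragment table; one row per distinct fragment sequence."""

    trna_name: str
    # (fragment seq, mature start, mature end, fragment_type, count, ambiguity, multi)
    rows: list[tuple[str, int, int, FragmentType, int, Ambiguity | None, bool]] = field(
        default_factory=list
    )


def load_and_dereplicate(path: str | Path) -> list[SmallRNARead]:
    """Load FASTA/FASTQ reads, uppercase, and merge identical sequences.

    The dialect is auto-detected from the first non-blank character ('>' =
    FASTA, '@' = FASTQ).  Output is sorted by descending count, then
    lexicographically.
    """
    path = Path(path)
    fmt = None
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line[0]
                fmt = {"@": "fastq", ">": "fasta"}.get(first)
                if fmt is None:
                    raise ValueError(
                        f"{path}: not FASTA or FASTQ (first character {first!r})"
                    )
                break
    if fmt is None:
        warnings.warn(f"{path}: empty reads file")
        return []
    counts: dict[str, int] = {}
    try:
        for rec in SeqIO.parse(str(path), fmt):
            seq = str(rec.seq).upper()
            counts[seq] = counts.get(seq, 0) + 1
    except ValueError as exc:
        raise ValueError(f"{path}: malformed {fmt.upper()} ({exc})") from exc
    reads = [SmallRNARead(seq=s, count=c) for s, c in counts.items()]
    reads.sort(key=lambda r: (-r.count, r.seq))
    return reads


def length_filter(
    reads: Sequence[SmallRNARead], min_len: int = 16
) -> tuple[list[SmallRNARead], list[SmallRNARead]]:
    """Partition reads into (pass, too_short) by a minimum-length cutoff.

    Very short reads (14-mers, and to a lesser degree 15-mers) occur
    identically at so many genomic locations that admitting them inflates
    false-positive tRF calls; the default cutoff of 16 nt dismisses them.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    passed = [r for r in reads if r.length >= min_len]
    too_short = [r for r in reads if r.length < min_len]
    return passed, too_short


def place_on_matures(
    read: SmallRNARead, matures: Sequence[MatureTRNA | tuple[str, str]]
) -> list[Placement]:
    """All exact-substring placements of a read on the mature tRNA set.

    Matching is forward-orientation only: mature sequences are already
    transcript-oriented (5'->3'), as are sequenced small-RNA reads.
    Reads containing N are unplaceable.
    """
    if "N" in read.seq:
        return []
    placements: list[Placement] = []
    L = read.length
    for m in matures:
        name, seq = (m if isinstance(m, tuple) else (m.name, m.seq))
        pos = seq.find(read.seq)
        while pos != -1:
            placements.append(Placement(trna_name=name, start=pos + 1, end=pos + L))
            pos = seq.find(read.seq, pos + 1)
    return placements


def call_fragment_type(
    placement: Placement,
    mature: MatureTRNA | tuple[str, str, int],
    halves_window: int = 2,
    three_prime_slack: int = 0,
) -> FragmentType:
    """Assign a fragment type from mature coordinates.

    With anticodon first base at mature position ``a`` (1-based), the
    anticodon window is ``[a - halves_window, a + 2 + halves_window]``.
    A fragment starting at position 1 is a 5'-half if its 3' end falls in the
    window, else a 5'-tRF; a fragment reaching the mature 3' end (the last
    CCA base, minus an optional slack) is a 3'-half if its 5' end falls in
    the window, else a 3'-tRF; everything else is an i-tRF.
    """
    if isinstance(mature, tuple):
        _, seq, ac_start = mature
    else:
        seq, ac_start = mature.seq, mature.anticodon_mature_start
    L = len(seq)
    lo, hi = ac_start - halves_window, ac_start + 2 + halves_window
    if placement.start == 1:
        if ac_start and lo <= placement.end <= hi:
            return FragmentType.FIVE_HALF
        return FragmentType.FIVE_TRF
    if placement.end >= L - three_prime_slack:
        if ac_start and lo <= placement.start <= hi:
            return FragmentType.THREE_HALF
        return FragmentType.THREE_TRF
    return FragmentType.I_TRF


def label_ambiguity(
    read: SmallRNARead,
    genome: Mapping[str, GenomeSequence],
    space: TRNASpaceIntervals,
) -> tuple[Ambiguity, int]:
    """Label a read by its exact genomic copies outside tRNA space.

    EXCLUSIVE iff the read has zero exact occurrences (either strand) outside
    tRNA space.  The genome is mandatory: deciding tRNA origin from tRNA
    space alone is exactly the practice this label exists to prevent.
    """
    if genome is None or not genome:
        raise ValueError(
            "ambiguity labeling requires the genome; tRNA-space-only labeling "
            "is not supported"
        )
    outside = count_sequence_occurrences(genome, read.seq, space)[1]
    return (Ambiguity.EXCLUSIVE if outside == 0 else Ambiguity.AMBIGUOUS), outside


def classify_reads(
    reads: Sequence[SmallRNARead],
    matures: Sequence[MatureTRNA | tuple[str, str, int]],
    genome: Mapping[str, GenomeSequence],
    space: TRNASpaceIntervals,
    min_len: int = 16,
    halves_window: int = 2,
    three_prime_slack: int = 0,
) -> list[TRFCall]:
    """Run the full classification pipeline over dereplicated reads.

    ``matures`` may be :class:`MatureTRNA` objects or plain
    ``(name, seq, anticodon_mature_start)`` triples.  Every read yields one
    :class:`TRFCall`: too-short reads are marked TOO_SHORT and not placed;
    N-containing reads pass through unplaced and unlabeled; all other reads
    are placed on the matures, typed per placement, and ambiguity-labeled
    against the genome (also when they place on no mature — a read's genomic
    multiplicity is a property of its sequence, not of its transcript
    placements).
    """
    triples = [
        m if isinstance(m, tuple) else (m.name, m.seq, m.anticodon_mature_start)
        for m in matures
    ]
    pairs = [(name, seq) for name, seq, _ in triples]
    by_name = {t[0]: t for t in triples}
    passed, too_short = length_filter(reads, min_len=min_len)
    calls = [TRFCall(read=r, filtered="TOO_SHORT") for r in too_short]
    amb_cache: dict[str, tuple[Ambiguity, int]] = {}
    for read in passed:
        call = TRFCall(read=read)
        if "N" not in read.seq:
            call.placements = place_on_matures(read, pairs)
            call.fragment_types = [
                call_fragment_type(
                    p, by_name[p.trna_name], halves_window, three_prime_slack
                )
                for p in call.placements
            ]
            if read.seq not in amb_cache:
                amb_cache[read.seq] = label_ambiguity(read, genome, space)
            call.ambiguity, call.outside_count = amb_cache[read.seq]
        calls.append(call)
    return calls


def build_profiles(calls: Sequence[TRFCall]) -> list[FragmentProfile]:
    """Group calls into per-tRNA fragment profiles.

    One row per distinct fragment sequence per tRNA; counts are never summed
    across distinct sequences, and no "dominant" fragment is designated.
    Multi-placing reads appear in every matching profile, flagged multi.
    Rows are sorted by mature start, then descending count.
    """
    acc: dict[str, dict[tuple[str, int, int], tuple[FragmentType, int, Ambiguity | None, bool]]] = {}
    for call in calls:
        for placement, ftype in zip(call.placements, call.fragment_types):
            rows = acc.setdefault(placement.trna_name, {})
            key = (call.read.seq, placement.start, placement.end)
            if key in rows:
                prev = rows[key]
                rows[key] = (ftype, prev[1] + call.read.count, call.ambiguity, prev[3] or call.is_multi)
            else:
                rows[key] = (ftype, call.read.count, call.ambiguity, call.is_multi)
    profiles = []
    for trna_name in sorted(acc):
        rows = [
            (seq, start, end, ftype, count, amb, multi)
            for (seq, start, end), (ftype, count, amb, multi) in acc[trna_name].items()
        ]
        rows.sort(key=lambda r: (r[1], -r[4], r[0]))
        profiles.append(FragmentProfile(trna_name=trna_name, rows=rows))
    return profiles


def write_calls_tsv(
    calls: Sequence[TRFCall], path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """One TSV row per (read, placement); unplaced reads get a single row."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "read_seq\tcount\tn_placements\ttrna\tmature_start\tmature_end\t"
            "fragment_type\tambiguity\toutside_count\tfiltered\n"
        )
        for call in calls:
            amb = call.ambiguity.value if call.ambiguity else "."
            base = f"{call.read.seq}\t{call.read.count}\t{len(call.placements)}"
            if not call.placements:
                fh.write(f"{base}\t.\t.\t.\t.\t{amb}\t{call.outside_count}\t{call.filtered}\n")
                continue
            for placement, ftype in zip(call.placements, call.fragment_types):
                fh.write(
                    f"{base}\t{placement.trna_name}\t{placement.start}\t"
                    f"{placement.end}\t{ftype.value}\t{amb}\t{call.outside_count}\t"
                    f"{call.filtered}\n"
                )


def write_profiles_tsv(
    profiles: Sequence[FragmentProfile], path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """All per-tRNA fragment profiles in one TSV, one row per distinct fragment."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "trna\tfragment_seq\tmature_start\tmature_end\tfragment_type\t"
            "count\tambiguity\tmulti\n"
        )
        for profile in profiles:
            for seq, start, end, ftype, count, amb, multi in profile.rows:
                amb_s = amb.value if amb else "."
                fh.write(
                    f"{profile.trna_name}\t{seq}\t{start}\t{end}\t{ftype.value}\t"
                    f"{count}\t{amb_s}\t{'MULTI' if multi else '.'}\n"
                )
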