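"""Exact k-mer exclusivity of the mature tRNA transcriptome against a genome.

The central question: of all distinct k-mers present in mature tRNA
sequences (spliced, CCA-appended), how many occur in the genome *only*
inside tRNA space, and how many also occur elsewhere?  A k-mer with even a
single exact copy outside tRNA space cannot, on its own, prove that a
sequenced read of that k-mer came from a tRNA.

Counting conventions (applied uniformly to every reported count):

* both strands — a genomic window is a hit for a k-mer when it equals the
  k-mer or its reverse complement, since a sequenced read may derive from
  either strand's transcript;
* a palindromic hit (window matching both ways at one position) counts once;
* "inside" requires the occurrence interval to be *fully contained* in a
  tRNA-space interval; partial overlap counts as outside.

Also here: the CCA-terminal decoy report, the tRNA-lookalike cross-talk
report, and the RepeatMasker partial-tRNA filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .trna_space import (
    GenomeSequence,
    MatureTRNA,
    TRNASpaceIntervals,
    reverse_complement,
)

__all__ = [
    "KmerEntry",
    "ExclusivityTable",
    "AmbiguitySummaryRow",
    "RepeatFeature",
    "CrosstalkReport",
    "enumerate_mature_kmers",
    "scan_genome",
    "summarize_ambiguity",
    "count_sequence_occurrences",
    "cca_terminal_report",
    "crosstalk_report",
    "read_repeatmasker_out",
    "filter_short_trna_repeats",
    "write_exclusivity_tsv",
    "write_summary_tsv",
]

_ACGT = frozenset("ACGT")


def _name_seq(mature: MatureTRNA | tuple[str, str]) -> tuple[str, str]:
    """Accept either MatureTRNA objects or plain (name, seq) pairs."""
    if isinstance(mature, tuple):
        return mature
    return mature.name, mature.seq


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero (so 92.35 -> 92.4, not banker's 92.3)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class KmerEntry:
    """Genomic occurrence counts and transcript sources of one k-mer."""

    inside_count: int = 0
    outside_count: int = 0
    sources: list[tuple[str, int]] = field(default_factory=list)  # (tRNA, 1-based start)


@dataclass
class ExclusivityTable:
    """All distinct k-mers of a mature tRNA set, with genomic occurrence counts."""

    k: int
    entries: dict[str, KmerEntry] = field(default_factory=dict)

    @property
    def n_distinct(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class AmbiguitySummaryRow:
    """One summary row: how many k-mers are genomically exclusive to tRNA space."""

    k: int
    n_distinct: int
    n_exclusive: int
    n_nonexclusive: int
    pct_exclusive: float
    pct_nonexclusive: float


@dataclass(frozen=True)
class RepeatFeature:
    """One RepeatMasker annotation line; coordinates 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_class: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"repeat {self.repeat_name}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CrosstalkReport:
    """Exact k-mer sharing between mature tRNAs and a foreign sequence set."""

    n_trnas_sharing: int
    n_shared_kmers: int
    per_trna: dict[str, int]


def enumerate_mature_kmers(
    matures: Sequence[MatureTRNA | tuple[str, str]], k: int
) -> ExclusivityTable:
    """Collect every distinct k-length window over the mature tRNA sequences.

    Windows spanning splice junctions and the non-templated CCA are included
    (they exist in the transcriptome even if nowhere in the genome); windows
    containing N are skipped.  Counts are zeroed; sources record every
    (tRNA name, 1-based mature start) of each k-mer.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not matures:
        raise ValueError("mature tRNA set is empty")
    table = ExclusivityTable(k=k)
    any_window = False
    for m in matures:
        name, seq = _name_seq(m)
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if not _ACGT.issuperset(window):
                continue
            any_window = True
            table.entries.setdefault(window, KmerEntry()).sources.append((name, i + 1))
    if not any_window:
        warnings.warn(f"k={k} exceeds every mature tRNA length; table is empty")
    return table


def scan_genome(
    genome: Mapping[str, GenomeSequence],
    tables: Sequence[ExclusivityTable],
    space: TRNASpaceIntervals,
) -> Sequence[ExclusivityTable]:
    """Fill genomic occurrence counts for every table in one pass per k.

    For every genomic window of each k, a hit is recorded when the window
    equals a key or the reverse complement of a key; the hit is *inside* iff
    its interval is fully contained in tRNA space.  A palindromic key matches
    a given window only once.
    """
    if not genome:
        warnings.warn("empty genome: all occurrence counts remain zero")
        return tables
    # window string -> the table keys it testifies for (key itself and/or
    # keys whose reverse complement it is; deduplicated for palindromes)
    match_maps: list[dict[str, list[str]]] = []
    for table in tables:
        mm: dict[str, list[str]] = {}
        for key in table.entries:
            mm.setdefault(key, []).append(key)
            rc = reverse_complement(key)
            if rc != key:
                mm.setdefault(rc, []).append(key)
        match_maps.append(mm)
    for chrom in genome.values():
        seq = chrom.seq
        n = len(seq)
        for table, mm in zip(tables, match_maps):
            k = table.k
            entries = table.entries
            for i in range(n - k + 1):
                keys = mm.get(seq[i : i + k])
                if keys is None:
                    continue
                inside = space.contains(chrom.name, i, i + k)
                for key in keys:
                    e = entries[key]
                    if inside:
                        e.inside_count += 1
                    else:
                        e.outside_count += 1
    return tables


def summarize_ambiguity(table: ExclusivityTable) -> AmbiguitySummaryRow:
    """Summarize a filled table: exclusive = zero occurrences outside tRNA space.

    A k-mer whose only existence is in the transcriptome (junction- or
    CCA-spanning, zero genomic copies anywhere) counts as exclusive.
    """
    if table.n_distinct == 0:
        raise ValueError(f"k={table.k}: cannot summarize an empty table")
    n_excl = sum(1 for e in table.entries.values() if e.outside_count == 0)
    n = table.n_distinct
    return AmbiguitySummaryRow(
        k=table.k,
        n_distinct=n,
        n_exclusive=n_excl,
        n_nonexclusive=n - n_excl,
        pct_exclusive=round_half_up(100.0 * n_excl / n),
        pct_nonexclusive=round_half_up(100.0 * (n - n_excl) / n),
    )


def count_sequence_occurrences(
    genome: Mapping[str, GenomeSequence],
    query: str,
    space: TRNASpaceIntervals,
) -> tuple[int, int]:
    """Count exact genomic copies of one query, split (inside, outside) tRNA space.

    Same both-strand, full-containment convention as :func:`scan_genome`.
    """
    if not query:
        raise ValueError("query must be non-empty")
    if not _ACGT.issuperset(query):
        raise ValueError("query must be over {A,C,G,T} (no N)")
    rc = reverse_complement(query)
    patterns = [query] if rc == query else [query, rc]
    inside = outside = 0
    for chrom in genome.values():
        seq = chrom.seq
        for pat in patterns:
            pos = seq.find(pat)
            while pos != -1:
                if space.contains(chrom.name, pos, pos + len(pat)):
                    inside += 1
                else:
                    outside += 1
                pos = seq.find(pat, pos + 1)
    return inside, outside


def cca_terminal_report(
    matures: Sequence[MatureTRNA | tuple[str, str]],
    genome: Mapping[str, GenomeSequence],
    space: TRNASpaceIntervals,
    k: int = 16,
) -> tuple[int, int, dict[str, int]]:
    """Outside-of-tRNA-space copies of every mature tRNA's CCA-ending 3' k-mer.

    Returns (number of tRNAs whose terminal k-mer has >=1 outside copy,
    grand total of outside copies summed over tRNAs, per-tRNA counts).  The
    grand total sums over tRNAs, not distinct k-mers: two tRNAs sharing a
    terminal k-mer each contribute its outside count.
    """
    per_trna: dict[str, int] = {}
    cache: dict[str, int] = {}
    for m in matures:
        name, seq = _name_seq(m)
        if len(seq) < k:
            warnings.warn(f"{name}: mature length {len(seq)} < k={k}; skipped")
            continue
        term = seq[-k:]
        if not seq.endswith("CCA"):
            raise ValueError(f"{name}: mature sequence does not end with CCA")
        if term not in cache:
            if _ACGT.issuperset(term):
                cache[term] = count_sequence_occurrences(genome, term, space)[1]
            else:
                warnings.warn(f"{name}: terminal {k}-mer contains N; counted as 0")
                cache[term] = 0
        per_trna[name] = cache[term]
    n_with = sum(1 for c in per_trna.values() if c >= 1)
    grand_total = sum(per_trna.values())
    return n_with, grand_total, per_trna


def crosstalk_report(
    matures: Sequence[MatureTRNA | tuple[str, str]],
    foreign_seqs: Sequence[tuple[str, str]],
    k: int = 16,
) -> CrosstalkReport:
    """Exact k-mer sharing between mature tRNAs and a foreign set (e.g. lookalikes).

    A shared k-mer is present in >=1 mature tRNA and >=1 foreign sequence,
    matching forward or as reverse complement; a k-mer and its reverse
    complement count as one.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not foreign_seqs:
        raise ValueError("foreign sequence set is empty")

    def canonical_kmers(seq: str) -> set[str]:
        out = set()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if _ACGT.issuperset(w):
                out.add(min(w, reverse_complement(w)))
        return out

    foreign = set()
    for _, seq in foreign_seqs:
        foreign |= canonical_kmers(seq.upper())
    per_trna: dict[str, int] = {}
    shared_union: set[str] = set()
    for m in matures:
        name, seq = _name_seq(m)
        shared = canonical_kmers(seq) & foreign
        if shared:
            per_trna[name] = len(shared)
            shared_union |= shared
    return CrosstalkReport(
        n_trnas_sharing=len(per_trna),
        n_shared_kmers=len(shared_union),
        per_trna=per_trna,
    )


def read_repeatmasker_out(path: str | Path) -> list[RepeatFeature]:
    """Parse a standard RepeatMasker ``.out`` report.

    The first three lines (two column-header lines and a blank line) are
    skipped; each remaining line is one repeat annotation with 1-based
    inclusive coordinates.  The class is the class/family column truncated
    at '/'. Strand 'C' (complement) is normalized to '-'.
    """
    features: list[RepeatFeature] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if lineno <= 3:
                continue
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 11:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=11 whitespace-delimited "
                    f"fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[5]), int(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad coordinates") from exc
            strand = "-" if fields[8] in ("C", "-") else "+"
            features.append(
                RepeatFeature(
                    chrom=fields[4],
                    start=start,
                    end=end,
                    strand=strand,
                    repeat_name=fields[9],
                    repeat_class=fields[10].split("/")[0],
                )
            )
    return features


def filter_short_trna_repeats(
    features: Sequence[RepeatFeature],
    space: TRNASpaceIntervals,
    max_len: int = 50,
    bed_path: str | Path | None = None,
) -> tuple[int, list[RepeatFeature]]:
    """Short tRNA-class repeat segments lying outside tRNA space.

    Keeps features with class exactly "tRNA", length <= max_len, and interval
    not fully contained in tRNA space; optionally writes survivors as BED
    (0-based half-open).
    """
    kept = [
        f
        for f in features
        if f.repeat_class == "tRNA"
        and f.length <= max_len
        and not space.contains(f.chrom, f.start - 1, f.end)
    ]
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for f in kept:
                fh.write(
                    f"{f.chrom}\t{f.start - 1}\t{f.end}\t{f.repeat_name}\t0\t{f.strand}\n"
                )
    return len(kept), kept


def write_exclusivity_tsv(
    table: ExclusivityTable, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """Write one filled table as TSV (one row per distinct k-mer)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("kmer\tk\tinside_count\toutside_count\tn_sources\texclusive\n")
        for kmer in sorted(table.entries):
            e = table.entries[kmer]
            excl = "Y" if e.outside_count == 0 else "N"
            fh.write(
                f"{kmer}\t{table.k}\t{e.inside_count}\t{e.outside_count}\t"
                f"{len(e.sources)}\t{excl}\n"
            )


def write_summary_tsv(
    rows: Sequence[AmbiguitySummaryRow], path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """Write per-k exclusivity summary rows as TSV."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "k\tn_distinct\tn_exclusive\tpct_exclusive\tn_nonexclusive\t"
            "pct_nonexclusive\n"
        )
        for r in rows:
            fh.write(
                f"{r.k}\t{r.n_distinct}\t{r.n_exclusive}\t{r.pct_exclusive}\t"
                f"{r.n_nonexclusive}\t{r.pct_nonexclusive}\n"
            )
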