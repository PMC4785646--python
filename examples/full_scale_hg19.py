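"""Full-scale run against the human genome (several hours of wall clock).

Stage these inputs under data/full_scale/ first:

* ``genome.fa``      — hg19, all chromosomes, uncompressed FASTA;
* ``trnas.bed``      — the 632 tRNA gene loci (610 nuclear + 22
  mitochondrial) as BED12+3: cols 1-12 standard BED12 with exon blocks,
  col 13 amino acid, col 14 anticodon, col 15 anticodon 0-based genomic
  start (gtRNAdb exports convert directly);
* ``repeats.out``    — RepeatMasker .out for hg19 (library 2014/01/31);
* ``lookalikes.fa``  — the 497 tRNA-lookalike locus sequences.

Expected results under the default convention (both-strand matching, hits
inside tRNA space only when fully contained): 16,380 / 16,733 / 17,006
distinct 14/15/16-mers of which 92.4% / 79.0% / 59.0% also occur outside
tRNA space; 99 outside copies of ACTTCTAATTCAAA and 421 of
CTCACTGGAACCTCCA; 480 tRNAs with 2,643 outside CCA-terminal copies in
total; 350 tRNAs sharing 1,493 exact 16-mers with the lookalikes; and 716
short (<= 50 nt) tRNA-class repeat segments outside tRNA space.  Because
the strand and containment conventions behind the published counts are not
stated, rerun with single-strand or overlap-tolerant variants and report
every variant if the defaults disagree.
"""

import sys
from pathlib import Path

from trfspace import (
    build_mature_trna,
    build_trna_space,
    cca_terminal_report,
    count_sequence_occurrences,
    crosstalk_report,
    enumerate_mature_kmers,
    extract_locus_sequence,
    filter_short_trna_repeats,
    read_genome_fasta,
    read_mature_fasta,
    read_repeatmasker_out,
    read_trna_annotation,
    scan_genome,
    summarize_ambiguity,
)

data = Path(sys.argv[1] if len(sys.argv) > 1 else "data/full_scale")
for name in ("genome.fa", "trnas.bed", "repeats.out", "lookalikes.fa"):
    if not (data / name).is_file():
        sys.exit(f"missing input: {data / name} (see module docstring)")

print("loading genome ...", flush=True)
genome = read_genome_fasta(data / "genome.fa")
loci = read_trna_annotation(data / "trnas.bed")
print(f"{len(loci)} tRNA loci", flush=True)
matures = [build_mature_trna(l, extract_locus_sequence(genome, l)) for l in loci]
space = build_trna_space(loci)

print("scanning genome for 14/15/16-mers ...", flush=True)
tables = [enumerate_mature_kmers(matures, k) for k in (14, 15, 16)]
scan_genome(genome, tables, space)
for table in tables:
    r = summarize_ambiguity(table)
    print(f"k={r.k}: {r.n_distinct} distinct, {r.n_exclusive} ({r.pct_exclusive}%) "
          f"exclusive, {r.n_nonexclusive} ({r.pct_nonexclusive}%) also outside")

for query in ("ACTTCTAATTCAAA", "CTCACTGGAACCTCCA"):
    _, outside = count_sequence_occurrences(genome, query, space)
    print(f"{query}: {outside} exact copies outside tRNA space")

n_with, grand_total, _ = cca_terminal_report(matures, genome, space, k=16)
print(f"CCA-terminal 16-mers: {n_with} of {len(matures)} tRNAs, "
      f"{grand_total} outside copies in total")

lookalikes = read_mature_fasta(data / "lookalikes.fa")
report = crosstalk_report(matures, lookalikes, k=16)
print(f"lookalike cross-talk: {report.n_trnas_sharing} tRNAs share "
      f"{report.n_shared_kmers} exact 16-mers with {len(lookalikes)} lookalikes")

repeats = read_repeatmasker_out(data / "repeats.out")
count, _ = filter_short_trna_repeats(repeats, space, max_len=50)
print(f"{count} tRNA-class repeat segments <= 50 nt outside tRNA space")
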