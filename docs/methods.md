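# Methods

## Model

A tRNA gene occupies a genomic interval on one strand; its mature product is
the transcript-oriented sequence with introns removed and the trinucleotide
CCA appended enzymatically at the 3′ end. `trfspace` represents a mature
tRNA as the spliced, strand-resolved string plus an explicit coordinate map:
every mature position is either a genomic `(chrom, pos, strand)` triple or a
`NONTEMPLATED` marker (exactly the three CCA positions). The map makes the
two transcript features that have no contiguous genomic counterpart —
exon–exon junctions and the CCA tail — first-class objects rather than
artifacts.

*tRNA space* is the union of the annotated tRNA gene intervals, merged and
strand-ignorant. A sequence is *exclusive* to tRNA space when every exact
genomic occurrence of it lies fully inside that union (or when it has no
genomic occurrence at all, which happens for junction- and CCA-spanning
windows). A candidate tRF read that is not exclusive is labeled
`AMBIGUOUS`: nothing in the read's sequence ties it to a tRNA.

## Counting conventions

These conventions are applied uniformly to every count the package reports:

* **Exact matching only.** No mismatches, no indels. Mismatch tolerance is
  the mechanism by which unrelated genomic sequences acquire tRF labels, so
  it is deliberately not offered.
* **Both strands.** A genomic window matches a k-mer if it equals the k-mer
  or its reverse complement, because a sequenced read can derive from either
  strand's transcript. A palindromic match at one position counts once.
* **Full containment.** An occurrence is *inside* tRNA space only when its
  interval is fully contained in a merged tRNA-space interval; a hit hanging
  off a locus boundary is not tRNA-templated end to end and counts as
  outside.
* **Percent rounding** is half-up to one decimal.

Whether published whole-genome counts of this kind used one or both strands,
and how partial overlaps were treated, is generally not stated; these
defaults are documented so full-scale runs can be repeated under single-
strand or overlap-tolerant variants and all variants reported.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k_values` | 14, 15, 16 | k-mer lengths profiled for exclusivity; the 14→16 range brackets the shortest read lengths practitioners consider |
| `min_read_len` | 16 | reads shorter than this are reported `TOO_SHORT` and not called; 14- and 15-mers are too genomically promiscuous to trust |
| `halves_window` | ±2 nt | half vs tRF boundary: a 5′ (3′) fragment is a *half* when its inner end falls within this window around the anticodon |
| `three_prime_slack` | 0 | how far short of the CCA-inclusive 3′ end a fragment may stop and still be called 3′; 0 = must reach the end |
| `mito_chrom_name` | `chrM` | chromosome whose loci are tagged mitochondrial |
| `max_partial_len` | 50 nt | length ceiling for the short tRNA-class repeat filter |

Fragment-type boundaries follow the common 5-class nomenclature (5′-tRF,
5′-half, i-tRF, 3′-half, 3′-tRF); the numeric window is a convention of this
package, surfaced as a parameter because no standard formula exists. 3′
calls require reaching the final mature position (CCA included) by default,
since CCA-ending strings define the 3′ fragment boundary.

CCA is appended unconditionally to every mature tRNA, nuclear and
mitochondrial: human tRNA genes do not encode CCA. Histidine G−1 addition
and 5′ leader / 3′ trailer (pre-tRNA) fragments are not modeled. Loci whose
extracted sequence contains N are kept but flagged; windows containing N are
excluded from enumeration, and N-containing reads are reported unplaced.

## Coordinates and formats

Internally everything is 0-based half-open; human-readable output is 1-based
inclusive. Annotations enter as BED12 plus three columns (amino acid,
anticodon, anticodon 0-based genomic start) — BED12 blocks encode introns
naturally and gtRNAdb-style exports convert directly. RepeatMasker `.out`
coordinates are kept 1-based inclusive as in the file, and converted at the
containment check. All outputs are TSV/BED/FASTA with `#`-prefixed
provenance headers; logging goes to stderr.

## Algorithmic choices

Genome scanning is a single forward pass per chromosome with per-k rolling
windows: each window is looked up in a precomputed map from window string to
the k-mer keys it testifies for (the key itself and any key whose reverse
complement it equals). This keeps the scan exact, one-pass, and linear in
genome length times the number of k values. Containment queries run against
merged, sorted per-chromosome interval arrays via bisection. Single-query
counting (`count_sequence_occurrences`) uses substring search over both
orientations with palindrome deduplication.

Reads are dereplicated before placement and ambiguity labels are cached per
distinct sequence; multiplicities are carried through to the profiles.
Profiles keep one row per distinct (fragment sequence, mature start) per
tRNA; counts are never summed across distinct sequences, because distinct
fragments from the same tRNA vary independently across samples and a
composite count suppresses that signal. Multi-placing reads appear in every
matching profile with a `MULTI` flag, so downstream users can see — rather
than silently inherit — multi-gene assignments.

## Synthetic data: what it emulates and what it does not

The generator plants, in an i.i.d. background of configurable GC (default
0.41, human-like), the four decoy mechanisms: intact tRNA genes (random
72-nt bodies, anticodon at mature positions 34–36, a 10–20 nt intron
immediately 3′ of the anticodon in the intronic ones), truncated gene copies
(20–50 nt) outside tRNA space, lookalikes (gene bodies with 2–10 point
substitutions), and verbatim CCA-terminal 16-mer decoys. Decoys are planted
verbatim so their expected ambiguity is certain under exact matching;
lookalikes are mutated so k-mer sharing is partial and the cross-talk report
is exercised non-trivially.

Default study conditions: 100 kb genome, 6 tRNAs (2 intronic), 10 partial
copies, 3 lookalikes, 3 CCA decoys, 1,000 reads of 16–30 nt. At these sizes
accidental 16-mer collisions with the background are improbable but not
impossible, which is why every expected label in the truth table is
recomputed from the finished genome by exhaustive exact scanning rather than
assumed from the construction. The acceptance checks and tests use these
sizes; they are large enough to exercise every mechanism and every code path
while keeping the whole suite fast on a single CPU.

What the synthetic data does **not** emulate: tRNA secondary structure and
covariance constraints, realistic repeat-family evolution, sequencing errors
and adapter artifacts, base modifications that interfere with reverse
transcription, and non-uniform fragment-abundance distributions. Passing
the planted-truth tests therefore demonstrates correctness of the exact
combinatorial machinery (splicing, CCA handling, both-strand counting,
containment, labeling) — not performance on real small-RNA-seq libraries,
where exactness of matching interacts with sequencing error.

## Numerical and degenerate-input behavior

Percentages use decimal half-up rounding (so the exclusive and non-exclusive
percentages can sum to 100.0 ± 0.1). Empty exclusivity tables cannot be
summarized (error); a k exceeding every mature length yields an empty table
with a warning; an empty genome leaves counts at zero with a warning; a
mature shorter than the CCA-report k is skipped with a warning. Ambiguity
labeling without a genome is a hard error, never a default label — deciding
tRNA origin from tRNA space alone is the failure mode this package exists to
prevent. Ties in profile ordering break by mature start, then descending
count, then sequence.

## Oracles

Two independent routes back every exact count: the fast scanning code, and
`brute_force_occurrences`, a deliberately naive per-position slice-comparison
scan of both strands. The test suite asserts exact agreement on hundreds of
random (genome, k, query) fixtures, plus strand-symmetry (reverse-
complementing the genome leaves counts unchanged) and space-nesting
(enlarging tRNA space never increases an outside count) properties. The
synthetic truth labels are computed at generation time on a third code path
(overlapping regex search) to stay independent of both.

## Known limitations

* Exact matching means any sequencing error unplaces a read; on real
  libraries this understates tRF abundance (by design — the package measures
  ambiguity, it is not an abundance estimator).
* Whole-genome scans at hg19 scale run in pure Python in hours, not minutes;
  the scan is one pass, but no suffix-automaton or multi-pattern index is
  used.
* The anticodon window and 3′ slack are conventions; profiles report the
  coordinates so users can re-bin fragment types under their own rules.
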