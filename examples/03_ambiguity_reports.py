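"""The three decoy reports: CCA-terminal copies, lookalike cross-talk,
short partial-tRNA repeat segments.

Each report quantifies one mechanism by which a read can look tRNA-derived
while having copies of its sequence outside tRNA space.
"""

import tempfile
from pathlib import Path

from trfspace import (
    SyntheticGenomeSpec,
    cca_terminal_report,
    crosstalk_report,
    filter_short_trna_repeats,
    generate_genome,
    read_repeatmasker_out,
    write_fixture,
)

fx = generate_genome(SyntheticGenomeSpec(seed=11))
spec = fx.spec

n_with, grand_total, per_trna = cca_terminal_report(fx.matures, fx.genome, fx.space)
print(f"CCA-terminal 16-mers: {n_with} of {len(per_trna)} tRNAs have copies outside "
      f"tRNA space, {grand_total} copies in total "
      f"(the generator planted {spec.n_cca_decoys} verbatim decoys).")

report = crosstalk_report(fx.matures, fx.lookalike_seqs, k=16)
print(f"Lookalike cross-talk: {report.n_trnas_sharing} of {len(fx.matures)} tRNAs "
      f"share {report.n_shared_kmers} exact 16-mers with {len(fx.lookalike_seqs)} "
      "lookalike loci (mutated gene bodies), so reads matching those k-mers are "
      "of ambiguous origin.")

with tempfile.TemporaryDirectory() as tmp:
    paths = write_fixture(fx, Path(tmp))
    features = read_repeatmasker_out(paths["repeats"])
    count, kept = filter_short_trna_repeats(features, fx.space, max_len=50)
print(f"Repeat segments: {count} tRNA-class segments of length <= 50 nt lie outside "
      f"tRNA space ({spec.n_partial_copies} truncated copies were planted); reads "
      "from them would be miscalled as tRFs by transcript-only mapping.")
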