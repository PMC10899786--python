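"""The 3'-TGG mispriming filter on an engineered genome.

PCR mispriming rescues fragments lacking a 3' adapter when they contain an
adapter-homologous TGG; adapter trimming then truncates them, leaving TGG as
the genomic 3' flank. On a genome engineered so TGG can never follow a true
fragment end, the flank filter removes exactly the truncated reads.
"""

from xrdeam.readqc import flank_motif_profile, tgg_filter
from xrdeam.simdata import engineered_mispriming_dataset

genome, reads, truth = engineered_mispriming_dataset(
    n_fragments=300, n_truncated=120, read_length=26, lmin=20, seed=4)

kept, removed = tgg_filter(reads, genome)
removed_ids = {r.read_id for r in removed}
truncated_ids = set(truth.loc[truth["truncated"], "fragment_id"])
print(f"reads: {len(reads)}, truncated by mispriming: {len(truncated_ids)}")
print(f"removed by TGG filter: {len(removed_ids)}")
print(f"filter removals == truncated set: {removed_ids == truncated_ids}")

prof = flank_motif_profile(reads, genome)
at_flank = prof[prof["position"] == 1].sort_values("read_length")
print("\nTGG frequency immediately past the 3' cut site, by read length:")
for row in at_flank.itertuples(index=False):
    print(f"  length {row.read_length}: {row.frequency:.2f} (n={row.n_reads})")
# truncated lengths (20-23 here) show frequency 1.0 at position +1 -- the
# mispriming signature; the full length (26) shows none
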