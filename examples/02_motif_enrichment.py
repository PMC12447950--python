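"""Scan promoters for the bipartite motif and locate its TSS enrichment.

Simulates promoter windows with CAAC-spacer-GATG instances planted near
the TSS of target genes (and uniformly in controls), scans both strands,
and computes the binned/smoothed/min-max-scaled positional enrichment
ratio of target versus control occurrences.
"""

import numpy as np

from regennet import motif as mo
from regennet import simulate as sim

genes = [f"g{i:03d}" for i in range(120)]
targets = set(genes[:60])
genome = sim.simulate_sequences(genes, window_halfwidth=2000,
                                target_genes=targets, seed=5,
                                per_gene_rate=4.0, control_rate=1.0,
                                offset_sd=250.0)
windows = mo.extract_windows(genome.annotation, genome.sequences,
                             halfwidth=2000)

motif = mo.MotifModel(kind="bipartite", forward="CAAC", reverse="GATG",
                      spacer=(0, 2))
hits = mo.scan({g: w.seq for g, w in windows.items()}, motif)
print(f"{len(hits)} bipartite hits across {len(windows)} promoter windows "
      f"({len(genome.planted_hits)} instances were planted)")

is_target = hits["seq_id"].isin(targets).to_numpy()
offsets = mo.hits_to_offsets(hits, windows)
curve = mo.positional_enrichment(offsets[is_target], offsets[~is_target],
                                 halfwidth=2000)
peak = curve.argmax_offset
print(f"enrichment ratio peaks at {peak:+.0f} bp relative to the TSS")
near = np.abs(curve.bin_centers) <= 300
far = np.abs(curve.bin_centers) >= 1000
print(f"median ratio within 300 bp of the TSS: "
      f"{np.median(curve.ratio[near]):.2f} vs beyond 1 kb: "
      f"{np.median(curve.ratio[far]):.2f}")
# A ratio well above 1 near the origin says target promoters carry the
# motif preferentially close to their transcription start sites.
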