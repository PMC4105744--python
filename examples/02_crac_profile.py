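"""Simulate a CRAC library over a planted protein-binding site and build
per-nucleotide cross-linking profiles.

Prints the called peaks (5%-of-maximum rule), the mutation-rate maximum
that localizes the cross-linked nucleotide, and per-snoRNA enrichment.
"""

import numpy as np

from craclash import (
    build_coverage,
    build_mutation_profile,
    call_peaks,
    map_reads,
    simulate_crac_reads,
    snorna_enrichment,
    standard_scenario,
)

# One pre-rRNA-like reference with a planted binding site (20x background)
# and three snoRNAs; 10,000 reads, 30% cross-link mutation rate.
ref, sites, _, cfg, background = standard_scenario(seed=7)
site = sites[0]
print(f"planted site {site.rna_id}:{site.start}-{site.end}, "
      f"cross-link at {site.crosslink_pos}, weight {site.weight}x background")

reads, _ = simulate_crac_reads(ref, sites, cfg, background_weight=background)
alignments = map_reads(reads, ref)
print(f"mapped {len(alignments)} / {len(reads)} reads")

coverage = build_coverage(alignments, ref)      # hits per million mapped
_, rates = build_mutation_profile(alignments, ref)
peaks = call_peaks(coverage, threshold_fraction=0.05,
                   scope_rna_ids=[site.rna_id])
for p in peaks:
    print(f"peak {p.rna_id}:{p.start}-{p.end}  "
          f"height {p.max_height_hpm:.0f} hpm  "
          f"relative {p.relative_height:.2f}")

track = rates[site.rna_id].values
peak = max(peaks, key=lambda p: p.max_height_hpm)
argmax = int(np.argmax(track[peak.start - 1 : peak.end])) + peak.start
print(f"mutation-rate argmax inside the peak: {argmax} "
      f"(planted cross-link {site.crosslink_pos}), "
      f"rate {track[argmax - 1]:.3f} (simulated 0.30)")
print("-> reverse-transcription mutations pinpoint the cross-linked base "
      "inside the broader coverage peak")

print("\nper-snoRNA relative cross-linking (reads per million mapped, "
      "scaled to the top snoRNA):")
print(snorna_enrichment(alignments, ref).to_string(index=False))
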