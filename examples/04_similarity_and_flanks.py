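"""Similarity of putative STEs to the known motif, and upstream flanks.

Shows both similarity measures (ungapped window identity and global
alignment with gap columns counted against similarity) and the 30 bp
upstream flank report with adenine statistics.
"""

from stescan import (
    DEFAULT_QUERY,
    STE_MOTIF,
    gapped_similarity,
    generate_background,
    plant_motif_copy,
    scan_sequence,
    ungapped_identity,
    upstream_flank,
)

# a divergent putative STE: 18 of 22 positions identical
putative = plant_motif_copy("A" * 22, DEFAULT_QUERY, 18, "+", 0, seed=3)
print(f"known motif   : {STE_MOTIF}")
print(f"putative motif: {putative}")
print(f"ungapped identity: {ungapped_identity(putative, STE_MOTIF):.1f}%")

length, matches, pct = gapped_similarity(putative + "TA", STE_MOTIF)
print(f"gapped alignment : {matches}/{length} columns = {pct:.1f}% "
      "(gap columns count against similarity)")

# flank inspection on a scanned sequence
region = generate_background(400, (0.30, 0.15, 0.20, 0.35), seed=4)
region = plant_motif_copy(region, DEFAULT_QUERY, 22, "+", 200, seed=5)
hit = scan_sequence(region, target_id="demo")[0]
rec = upstream_flank(region, hit)
print(f"\nhit at {hit.start} ({hit.strand}), 30 bp upstream: {rec.flank30}")
print(f"A fraction {rec.flank_A_fraction:.2f}, longest A run {rec.flank_longest_A_run} bp")
# Mytilid STEs sit downstream of adenine-rich tracts; the flank report
# makes that property inspectable for newly found signatures.
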