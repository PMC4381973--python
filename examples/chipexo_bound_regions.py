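"""ChIP-exo bound regions from strand-specific peak pairing.

Simulates exonuclease reads around hidden binding sites, reduces them to
5'-end cross-linking points, calls peaks on each strand, pairs left/right
peaks within 20 bp, and summarises the bound regions genome-wide.
"""

import numpy as np

from tfmap import chipexo as exo
from tfmap import synth

chrom_sizes = {"chr1": 2_000_000, "chr2": 1_500_000}
_, _, truth = synth.gen_strand_peaks(60, 10, 0, chrom_sizes, seed=17)
reads = synth.gen_exo_reads(truth, left_right_offset_bp=10, reads_per_site=40,
                            read_length_bp=30, spread_bp=3.0, seed=18)

counts = exo.reads_to_5prime(reads)
print(f"{len(reads)} reads -> {counts['count'].sum()} 5'-end points "
      "(count conserved)")

left = exo.call_peaks(counts, "+")
right = exo.call_peaks(counts, "-")
regions, unpaired_l, unpaired_r = exo.pair_peaks(left, right, max_dist_bp=20)
print(f"{len(left)} forward and {len(right)} reverse peaks -> "
      f"{len(regions)} bound regions ({len(unpaired_l)}+{len(unpaired_r)} unpaired)")

widths = regions["end"] - regions["start"]
print(f"bound-region width: median {widths.median():.0f} bp "
      "(the left/right 5' offset around the cross-link point)")

mids = (regions["start"] + regions["end"]) // 2
recovered = sum(
    bool((regions["chrom"].eq(s.chrom) & (abs(mids - s.pos) <= 15)).any())
    for _, s in truth.iterrows()
)
print(f"sites recovered: {recovered}/{len(truth)}")

tss = truth[["chrom", "pos"]]  # pretend the true sites are annotated TSSs
out = exo.tss_distance_cdf(regions, tss, chrom_sizes=chrom_sizes, seed=19)
print(f"median distance to nearest TSS: bound regions "
      f"{np.median(out['distances']):.0f} bp vs random positions "
      f"{np.median(out['random_distances']):.0f} bp")
print("  -> bound regions sit on the annotation; random positions are"
      " hundreds of kb away on this sparse toy genome.")
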