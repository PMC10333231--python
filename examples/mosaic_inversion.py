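"""Invert segment-mean log2 ratios to mosaic cell fractions.

For a monoallelic event in a fraction f of cells the mean copy number is
2 - f (loss) or 2 + f (gain): f = 2(1 - 2^L) or f = 2(2^L - 1).  The three
classic segment means of an LOH-sorted bulk invert to ~46% duplication,
~35% terminal deletion and ~41% deletion; the round trip through a
simulated noisy probe track recovers the same fraction.
"""

import numpy as np

from famred import cgh, popgen

for L, direction in [(+0.30, "gain"), (-0.28, "loss"), (-0.33, "loss")]:
    f, _ = cgh.mosaic_fraction_from_log2ratio(L, direction)
    print(f"L = {L:+.2f} ({direction}): mosaic fraction = {f:.1%}")

# round trip: simulate a 36% mosaic terminal deletion with probe noise,
# segment the track at the known cut-site, invert the segment mean
track = popgen.simulate_cnv_baf_track(
    f_del=0.36, del_interval=(126.5, 135.0), probes=2000, noise_sd=0.15, seed=0
)
seg = cgh.segment_track(track, known_breakpoints=[126.5])[-1]
f_hat, _ = cgh.mosaic_fraction_from_log2ratio(
    float(np.clip(seg.mean_log2ratio, -1.0, -1e-9)), "loss"
)
print(f"\nsimulated f = 36%: segment mean L = {seg.mean_log2ratio:+.3f} "
      f"over {seg.n_probes} probes -> recovered f = {f_hat:.1%}")
# In a fully LOH-sorted bulk (every cell carries LOH) the deletion fraction
# is the copy-loss component; the rest is copy-neutral LOH.
cl, cn = cgh.decompose_loh(1.0, f_hat)
print(f"decomposition of the sorted bulk: {cl:.1%} CL-LOH, {cn:.1%} CN-LOH")
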