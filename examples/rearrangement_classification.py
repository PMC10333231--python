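"""Classify rearrangements from combined copy-number + BAF probe tracks.

Copy-neutral LOH leaves the log2 ratio flat and is visible only as a
terminal run of homozygous B-allele frequencies; a mosaic deletion shows
both a negative log2 ratio and allelic imbalance.
"""

from famred import cgh, popgen

# a clone with a terminal CN-LOH starting at the cut-site (108.5 Mb):
# flat copy number, BAF pushed to 0/1 telomeric to the cut
cn_loh_track = popgen.simulate_cnv_baf_track(
    f_del=0.0, f_loh=1.0, loh_interval=(108.5, 135.0),
    probes=1500, noise_sd=0.05, seed=1, het_probe_rate=0.4,
)
print("clone with terminal copy-neutral LOH:")
for seg in cgh.call_track(cn_loh_track, known_breakpoints=[108.5]):
    print(f"  {seg.start_mb:6.1f}-{seg.end_mb:6.1f} Mb  L = {seg.mean_log2ratio:+.3f}"
          f"  state = {seg.state.value:16s} rearrangement = {seg.rearrangement.value}")

# an LOH-sorted bulk with a 36% mosaic terminal deletion over the same run
bulk_track = popgen.simulate_cnv_baf_track(
    f_del=0.36, del_interval=(108.5, 135.0), f_loh=1.0,
    loh_interval=(108.5, 135.0), probes=1500, noise_sd=0.05, seed=2,
    het_probe_rate=0.4,
)
print("\nLOH-sorted bulk with mosaic terminal deletion:")
for seg in cgh.call_track(bulk_track, known_breakpoints=[108.5]):
    f = f"  mosaic f = {seg.mosaic_fraction:.1%}" if seg.mosaic_fraction else ""
    print(f"  {seg.start_mb:6.1f}-{seg.end_mb:6.1f} Mb  L = {seg.mean_log2ratio:+.3f}"
          f"  state = {seg.state.value:16s} rearrangement = {seg.rearrangement.value}{f}")
# The terminal segment carries both the copy-number dip (CL-LOH component)
# and the homozygosity run; the flat centromeric segment stays NORMAL.
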