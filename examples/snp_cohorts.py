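"""Clone-level LOH calling from allele-specific qPCR, and cohort comparison.

Simulates colony assays of sorted low-division (tracking-high) and
high-division (tracking-low) progenitors, calls SNP losses with the
Ct < 37 / delta-Ct > 6 rules, requires losses at >= 2 telomeric SNPs per
clone, and compares the cohorts by chi-square and Fisher's exact test.
"""

import numpy as np

from famred import popgen, snp

rng = np.random.default_rng(0)
truth_high = rng.random(500) < 0.006  # low-division cohort, rare LOH
truth_low = rng.random(82) < 0.061    # high-division cohort, 10x the rate

counts = {}
for name, truths, seed in (("high", truth_high, 1), ("low", truth_low, 2)):
    curves = popgen.simulate_qpcr_panel([[bool(t)] * 3 for t in truths], seed=seed)
    panels = snp.build_panels(curves)
    loh = sum(p.verdict is snp.CloneVerdict.LOH for p in panels)
    counts[name] = (loh, len(panels))
    print(f"tracking-{name}: {loh}/{len(panels)} clones with LOH "
          f"({loh / len(panels):.1%}), truth {truths.sum()}")

cmp = snp.compare_cohorts(counts["high"], counts["low"])
print(f"\nchi-square = {cmp.chi_square:.2f}  p = {cmp.p_value:.3g}  "
      f"Fisher p = {cmp.fisher_p:.3g}")
# A significant comparison shows the division-rate effect: clones from
# slowly dividing cells carry megabase-scale LOH an order of magnitude
# less often.
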