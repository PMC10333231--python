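"""Fit the clearance of LOH-positive cells under selection.

Rearranged cells proliferate more slowly; the LOH-positive fraction decays
as f(g) = f0 w^g / (f0 w^g + 1 - f0) with relative fitness w per
generation.  Three genotypes are simulated from the same initial burst:
rapid clearance (WT, w = 0.4), slowed clearance (p21-null, w = 0.7) and
persistence (p53-null, w = 1.0), measured at days 3/7/10/14 with binomial
counting noise over 1e5 events and a 0.5% assay background.
"""

import numpy as np

from famred import kinetics

DAYS = [3.0, 7.0, 10.0, 14.0]
N = 100_000
rng = np.random.default_rng(0)

fits = {}
for label, w in {"WT": 0.4, "p21-null": 0.7, "p53-null": 1.0}.items():
    clean = kinetics.project_timecourse(0.0385, w, 1.0, DAYS, background=0.005)
    noisy = kinetics.LohTimecourse(
        days=clean.days,
        loh_fraction=rng.binomial(N, clean.loh_fraction) / N,
        genotype_label=label, background=0.005, n_events=N,
    )
    print(f"{label:9s} measured fractions:",
          "  ".join(f"d{int(d)}: {f:.3%}" for d, f in zip(DAYS, noisy.loh_fraction)))
    fits[label] = kinetics.fit_clearance(noisy, generation_time=1.0)

report = kinetics.compare_genotypes(fits, n_boot=200, seed=1)
print()
for label in report["ordering"]:
    entry = report["genotypes"][label]
    if entry["w"] is None:
        print(f"{label:9s} cleared below background before a slope could be fit")
    else:
        lo, hi = entry["w_ci"]
        tag = "persistent" if entry["persistent"] else "clearing"
        print(f"{label:9s} w = {entry['w']:.3f} (95% CI {lo:.3f}-{hi:.3f})  {tag}")
# The fitted w values recover the simulated ordering: the wild type clears
# fastest, p21 loss slows clearance, and p53 loss lets LOH persist.
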