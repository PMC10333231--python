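# Methods

This note documents the models behind `famred`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical choices that affect results.

## The reporter logic and the ×2 correction

The assay modeled here detects terminal megabase-scale LOH through a
phenotype switch: a cell line heterozygous for a loss-of-function variant in
a reporter-coupled gene switches fluorescent state when the remaining
functional allele is lost with the arm telomeric to the cut-site. A
rearrangement that removes the already-inactive homolog changes nothing
observable. With no reason for the break to resolve preferentially onto one
homolog, the generator assigns each LOH event to the reporter-bearing
homolog with probability `homolog_targeting` (default 0.5), and the
estimator symmetrically doubles the background-subtracted observed fraction
to estimate total LOH. The default is a symmetry argument, not a
measurement; `homolog_targeting` is exposed for sensitivity analyses.

## Population simulator (`popgen`)

Each cell draws an outcome from
{UNEDITED, INDEL_ONLY, CL_LOH, CN_LOH, CN_LOH_DUP} with profile
probabilities summing to 1. Divisions completed during the editing window
are Poisson with mean `mean_divisions` (default 2) — a single-parameter,
non-negative count model; nothing in the data constrains the shape beyond
that. The division–LOH link is encoded by multiplying the three LOH-class
probabilities by `division_modifier`^divisions and renormalizing the whole
vector, which makes actively cycling cells proportionally more likely to
acquire LOH with one interpretable knob. The tracking dye halves per
division exactly; optional log-normal noise (`intensity_cv`) can blur the
sort. `sort_by_tracking` takes the top/bottom `decile` by intensity with
ties broken by cell id, so sorts are deterministic.

The two-channel flow model is log10-normal: negatives at `mu_neg = 2.0`
(sd 0.3), switched cells at `mu_pos = 4.5` (sd 0.35) — nearly three decades
of separation, as in a working reporter assay. Assay noise
(`background_switch_rate`, default 0.02% to match untransfected /
irrelevant-locus controls; ~0.5% would describe a murine fluorescence-loss
assay) produces an intermediate cluster at `mu_bg = 3.5` (sd 0.5) that
straddles the gate boundary. This matters: if control "positive" events were
drawn fully bright, a quantile gate set on a realistic control would land
inside the positive cluster and clip half the true signal, which is neither
how instruments behave nor how operators gate. Autofluorescent cells (rate
configurable, default 0) are bright in both channels.

The probe-track generator places evenly spaced probes on a single synthetic
135 Mb chromosome (coordinates in Mb, matching the hChr10q geometry of the
motivating experiments). Log2 ratios are exact closed forms plus i.i.d.
Gaussian noise. Heterozygous probes (rate `het_probe_rate` = 0.3) carry
BAF 0.5; inside an LOH interval the BAF of a fraction-`f_loh` mosaic is
shifted by ±f/2 with the lost allele mirrored at random per probe. That
shift is exact for CN-LOH; for a deletion mosaic the exact values are
1/(2−f) and (1−f)/(2−f), within 0.04 of the symmetric form at the fractions
used here — one parameter was preferred over three-branch bookkeeping, and
the BAF track is used only as an imbalance flag, never inverted.

qPCR simulation: a retained heterozygous SNP yields two curves whose ΔCt is
N(0, 0.5); a lost allele either drops out entirely (probability 0.5) or
amplifies late, ΔCt uniform on [6.5, 14]. These guarantee the generated
truth is recoverable by the stated calling rules, which is the point of the
generator: it produces decision-rule-exercising data, not a physical model
of amplification chemistry.

**What passing tests show — and don't.** The generator draws i.i.d. cells,
Gaussian probe noise, and binomial counting error. Real data add spillover
and debris in flow, GC waves and dye bias on arrays, PCR inhibition in
colony lysates, and clone-sampling pedigree structure. Tests passing here
certify the *inference rules* (gating arithmetic, interval coverage,
inversion algebra, rule composition, fit recovery) under the stated noise,
not robustness to those unmodeled artifacts.

## Flow quantification (`flow`)

The gate threshold is an upper quantile (default 0.9999) of the negative
control's reporter intensities. The control-channel threshold is the same
quantile of control-channel intensities *among reporter-negative events*:
restricting to that subset keeps autofluorescent events (bright in both
channels) from dragging the threshold above their own cluster, which would
defeat the exclusion gate.

The 95% interval is Wilson's score interval — valid at proportions near 0
where the Wald interval collapses; at 0 positives it correctly returns
[0, >0). The limit of detection is mean + 3 SD of gated control fractions,
a standard blank-based rule; frequencies below it are flagged undetected.
Both the raw observed fraction and the background-subtracted, ×2-corrected
value are always reported, since published percentages do not always state
whether controls were subtracted. Two-group comparison uses the two-sided
Mann–Whitney U (asymptotic, midrank ties, no continuity correction, so
identical groups give p = 1 exactly); more than two groups, one-way ANOVA.

## Mosaic inversion and classification (`cgh`)

Inversion assumes a diploid reference and a *monoallelic* event: mean copy
number 2 ± f. Levels outside [−1, 0) / (0, log2 1.5] are rejected with an
error naming the multi-copy ambiguity rather than silently extrapolated.
`f` is clamped to [0, 1] with a flag when probe noise pushes it past a
limit.

Segmentation with a known cut-site is an induced partition; without one, a
two-means single-changepoint scan minimizes residual sum of squares (O(n)
via cumulative sums, minimum 10 probes per segment), and the split is kept
only when it lowers the BIC (two extra parameters) relative to the flat
model — so flat tracks stay single segments. At signal-to-noise 2
(step 0.3, sd 0.15) the changepoint lands within 2 probes of truth in ~89%
of runs and within 10 essentially always; that accuracy is a property of
the estimation problem, not of the implementation.

Classification thresholds: clonal heterozygous deletion below L = −0.5,
clonal duplication above +0.3 (standard array-calling bounds); between
those and the mosaic floor |L| ≥ 0.05 the segment is a quantified mosaic.
The floor at 0.05 keeps shallow events (L ≈ −0.08, f ≈ 11%) callable while
ignoring baseline wobble; it is configurable. BAF imbalance requires ≥ 20
informative probes with mean |BAF − 0.5| > 0.15. A flat segment with
imbalance is CN-LOH; a negative segment with imbalance is CL-LOH; without
BAF the call is copy-number-only and flagged. Note one deliberate reading:
for a shallow deletion mosaic the module reports the *cell* fraction
(f = 2(1 − 2^L), e.g. 10.7% of cells at L = −0.08); describing the same
segment as "10% of alleles" would imply a different denominator
(alleles ≈ f/2 of total), and the cell-fraction model is used consistently
throughout.

`decompose_loh` splits a sorted bulk (total LOH = 1) into copy-loss
(= deletion mosaic fraction) and copy-neutral remainders, assuming the
deletion and duplication subpopulations are disjoint classes — overlap is
not identifiable from one bulk track. The distance–frequency report calls
R² < 0.5 "no correlation", matching how such panels are read in practice.

## SNP-loss rules (`snp`)

Rule composition order is: inclusion filter first (Ct < 37), then count
surviving curves. A single survivor is a LOSS unconditionally — the
alternative reading (a lone curve must also satisfy a ΔCt condition against
nothing) is vacuous, so filter-then-count is the only self-consistent
composition. ΔCt uses the absolute difference: loss of either allele
counts. Boundary semantics are strict: Ct = 37 is excluded, ΔCt = 6 is
heterozygous. Clone verdicts need ≥ 2 lost SNPs; NO_CALL SNPs leave the
denominator, and clones that cannot reach 2 informative SNPs are
UNEVALUABLE rather than negative. The 2×2 cohort test is Pearson chi-square
without continuity correction (the common default at these sample sizes),
with Fisher's exact p always co-reported because the rare-event cell counts
are small.

## Clearance kinetics (`kinetics`)

Discrete-generation relative fitness was chosen over a continuous ODE: one
interpretable parameter (w), directly matched to the generation-count
framing of the tracking-dye experiments. Generations are counted as
g = t/generation_time from t = 0, so the fitted f0 is an extrapolated model
parameter — the earliest usable measurement is delayed by reporter
clearance, and nothing before the first observed day is interpreted.
`generation_time` is a fixed input: it is not jointly identifiable with w
from fractions alone.

Fitting is linear regression of logit(fraction − background) on g. A point
enters only if it exceeds background by > 2 binomial SE of the background
(when per-day event counts are known): floor-level measurements carry no
slope information and bias w toward 1. With event counts the regression is
precision-weighted (delta-method logit variance 1/(n p(1−p))). One usable
point or none returns a qualitative "cleared" verdict instead of a fit.
Genotype comparison bootstraps w parametrically (binomial redraws of each
day's fraction, 200 replicates by default); a genotype is "persistent" when
its interval reaches 1 or its point estimate is within ±0.05 of 1 — the
equivalence band matters because at 10⁵ events the bootstrap interval is
narrower than biologically meaningful deviations from neutrality. The
default assay background 0.5% describes a murine fluorescence-loss readout.

## Orchestration and determinism (`io`, `cli`)

Every stochastic operation takes an explicit seed; pipelines derive child
seeds as BLAKE2b(master_seed, operation-name) mod 2³¹, so adding an
operation never perturbs another's stream, and a run is a pure function of
its config: identical configs give byte-identical `results.json`. Outputs
stage into a temporary sibling directory and move into place only on
success. Fractions are fractions everywhere in memory and on disk; percent
appears only in human-readable summaries. Readers validate schemas and name
the offending line. The bundled scenario uses 10⁶ events, a 2000-probe
track, 500 + 82 clone cohorts and 10⁵-event kinetics days; test
configurations scale these down (5×10⁴ events, smaller cohorts), sizes
chosen so the suite exercises every path at meaningful counting statistics.

## Known limitations

Single chromosome, single breakpoint pair, diploid reference; no
multi-chromosome calling, no array QC or wave correction, no modeling of
transfection efficiency, apoptosis, repair-pathway choice or chromothripsis;
Ct values are taken as given (no curve fitting); flow events carry no
scatter channels, so no debris or doublet gating. The changepoint scan
handles one breakpoint per scan — multi-segment tracks need known
breakpoints, which the simulator always has.
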