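# Methods

This note documents the models, conventions and numerical choices behind
olfquant, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the procedures admit more than one reading.

## Behavioral statistics

Sessions are streams of beam-break intervals scored against an epoch schedule
(air or odor presentation windows; the gaps between presentations are
unscored). Intervals spanning an epoch boundary are clipped and contribute
their overlap to each side; the "long event" count uses bouts **strictly**
longer than 1 s, the convention used to mark investigative bouts in raster
displays. The air baseline `TAve.Air` is the arithmetic mean of `T` over the
air epochs preceding the first odor epoch (the four baseline airs in the
preference layout, the eight initial airs in habituation layouts), not over
every air period in the session.

The preference index uses the printed denominator `4·TAve.Air` and takes
`TAir` as the **last** baseline air epoch. ΔNPI is implemented as the
difference `100·(TOdor2.1 − TOdor1.5)/TAve.Air` — novel-odor first
presentation minus habituated-odor last presentation — which is the quantity
the assay defines (renewed investigation after habituation).

The detection-threshold scan runs one paired t-test per concentration (odor
NPI vs the mean NPI of the two flanking air presentations, across subjects)
at a fixed α = 0.05 with **no multiplicity correction**, and reports the
lowest significant concentration. A consequence worth knowing: with k null
concentrations below the true threshold, the probability that the first
flagged concentration is the true one is at most 0.95^k even at infinite
effect size; the per-test type-I rate, not the first-flag accuracy, is the
calibrated property (verified at 0.05 ± 0.02 under the null generator).
With a single subject the scan returns means only.

One-way ANOVA is the classical fixed-effects F-test with Tukey HSD post-hoc
(via statsmodels). When the between-group sum of squares is exactly zero the
result is reported as F = 0, p = 1 (scipy returns NaN there); when the
within-group sum of squares is zero but groups differ, F = ∞, p = 0.

## Psychometric model

`SR(x) = A − (A−g)·exp(−c·(x/T)^b)` with `c = −ln((A−criterion)/(A−g))`, so
`SR(0) = g`, `SR(T) = criterion`, and the curve is monotone non-decreasing.
The criterion defaults to the half-range point `(A+g)/2` (then `c = ln 2`),
the standard psychometric convention; it is configurable because the
threshold's defining performance level is a free choice of the assay.
`g` is fixed by the assay: 0 % for dishabituation (no false alarms by
construction), 50 % for Go/No-Go (chance).

Fitting: nonlinear least squares on the **mean response per concentration**
(not per trial), with the concentration axis handled as log10 internally
since designs span four decades. Because these fits are
initialization-sensitive, a multi-start grid is used (7 threshold starts
spanning the data range ± 1 decade × 3 steepness starts at b = 0.5, 1, 2),
keeping the lowest-SSE solution; bounds keep A above g, b in (0.001, 50), and
log10 T within 4 decades of the data. A fit is declared failed — with a
diagnostic message and no threshold — when the fitted amplitude (A − g) is
within twice the residual RMSE of zero (flat data), rather than returning an
arbitrary threshold. Confidence intervals for T come from a seeded percentile
bootstrap resampling subjects (1,000 resamples recommended; tests use fewer).

## Occupancy metric

"Filter radius r" is realized as non-overlapping **square tiles of side 2r**
anchored at the ROI bounding-box origin (fixed grid, no sliding, for
determinism). Tiles overlapping the ROI by ≥ 1 pixel form the denominator;
tiles containing ≥ 1 in-ROI signal pixel the numerator; signal outside the
ROI is ignored. Any non-empty signal reaches 100 % once one tile covers the
ROI. The implementation is exactly equivalent to exhaustive tile enumeration
(asserted against an independent brute-force oracle on random instances).

Monotonicity in radius holds as a theorem for nested tilings (e.g. sides
4, 8, 16) **when every coarse in-ROI tile decomposes exactly into in-ROI fine
tiles**, e.g. a rectangular ROI aligned to the grid: each occupied fine tile
forces its parent occupied while parents are 4× fewer. For irregular ROIs an
edge sliver (a coarse tile overlapping the ROI by one empty fine tile) can
lower coarse occupancy below fine occupancy, so monotonicity is asserted only
on grid-respecting ROIs; in practice curves on disc ROIs are monotone except
for small boundary dips.

Maximum-intensity projection is applied before thresholding when a z-stack is
supplied. Binarization is a hard threshold (pixels strictly above) or Otsu on
the in-ROI histogram; Otsu on a constant channel raises an error advising a
fixed threshold. Component counting is 8-connected with a 50 px default
minimum area (no size criterion is inherent to a labeled glomerulus; the
default suppresses stray fibers). Coordinates are 0-based row-major.

The occupancy group comparison is a two-way fixed-effects ANOVA with factors
group and radius (additive model, type-II sums of squares), reporting the
group main effect; radius enters as a categorical factor because the curve is
nonlinear in r.

## Activation densities

Density = Σcounts / Σareas per region × hemisphere (cells/mm²), so the value
is invariant to how cells are partitioned among sections; hemispheres are
independent samples. The shipped section table (series length and bregma
range per region, e.g. AHA: 4 sections at −1.05 to −0.85 mm) is a default
configuration; analyses warn rather than fail on deviating series. The unit
is stated in the output column name (`density_cells_per_mm2`).

## Synthetic data: what it emulates, and what it does not

All generators take a single integer seed (child seeds derived via
`SeedSequence`) and are bit-reproducible.

**Investigation sessions.** Bout onsets are homogeneous Poisson within each
epoch with exponential bout durations, clipped at the epoch end and merged if
overlapping. The air rate decays geometrically per air epoch (habituation to
the chamber); odor epochs modulate the most recent air baseline by valence:
attractive odors multiply rate and mean duration by the novelty gain for the
first two presentations, neutral odors get the gain on the first presentation
only, aversive odors match baseline on the first presentation (risk
assessment) and are multiplied by the suppression factor thereafter.
Defaults — 2 bouts/min, 1.5 s mean bout, novelty gain 3, habituation constant
0.85, suppression 0.3 — were chosen once to produce raster statistics in the
regime of real sessions (sparse ~1 s bouts waning over air trials, clear
rebound at odor onset). The generator's `truth` carries the per-epoch rate
plan and the closed-form expected investigation time
`rate/60 · epoch_length · mean_bout`, exact up to end-clipping and merging
(a few percent at default sparseness); estimator tests score against it.
The model deliberately omits within-epoch nonstationarity, sniffing dynamics,
inter-bout refractoriness and circadian drift — passing tests demonstrate the
statistics are computed correctly under the stated bout process, not that the
process captures all structure of mouse behavior.

**Psychometric tables.** Continuous responses are the Weibull mean plus i.i.d.
Gaussian noise per subject × concentration; binary responses are Bernoulli
with p = SR(x)/100 aggregated over a configurable trial count. Real ΔNPI
noise is heteroscedastic and subject-correlated; the generator is not.

**Glomerulus images.** Circular ROI; marker and dendrite channels fill it
uniformly; the axon channel is grown by random-walk region growth to exactly
the requested pixel count (contiguous per compartment), giving an occupied
fraction exact to pixel quantization. Multi-glomerulus fields place disjoint
glomeruli on a jittered grid. Real glomeruli are neither circular nor
uniform, and real compartments have smoother boundaries; the generator's role
is constructive ground truth for the pixel-counting metrics.

**Spike trains** draw i.i.d. lognormal ISIs (σ = 0 degenerates to a regular
train); **region counts** draw Poisson(density × area) per section.

**Scan tables.** The threshold-scan null generator draws odor and air NPIs
i.i.d. Normal(1, 0.25²) truncated at 0 (truncation is negligible at that SD);
the step variant adds a fixed NPI offset at and above a chosen concentration.

## Problem sizes in tests

The test suite and acceptance checks use desk-scale designs chosen to make
the statistical assertions sharp: 1,000 random instances for the
occupancy/brute-force equivalence (up to 64×64), 500 masks for nested-tiling
monotonicity, 200 seeds for Weibull threshold recovery (10 subjects, noise
SD 20), 1,000 simulated scans for the type-I rate, ~5,000-spike trains and
1,000 simulations for the ISI/ANOVA-uniformity checks, with 4-standard-error
bands for moment-recovery oracles.

## Known limitations

- The epoch scheduler assumes non-overlapping epochs on one clock; it does
  not model olfactometer valve delays or odor clearance time.
- The Weibull fit has no lapse-rate parameter and no adaptive-staircase
  support; thresholds from low-asymptote data rely on the fitted A.
- Occupancy is 2-D only (post-projection); no 3-D tiling.
- Region ROIs and atlas registration are taken as given; counting starts from
  point sets or thresholded masks.
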