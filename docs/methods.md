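# Methods

`sptconfine` analyses two-dimensional single-particle-tracking (SPT) data of
cytoplasmic proteins in rod-shaped bacteria. A trajectory is an ordered list
of localizations (frame index, x, y in micrometres) at a fixed frame
interval tau (default 13.76 ms). All statistics below assume free 2-D
diffusion as the null model: mean squared displacement (MSD)
`<r^2(t)> = 4 D t`, and a Rayleigh law with scale `sqrt(2 D tau)` for the
single-step jump distance.

## Trajectory bookkeeping

Frames are 0-based; a *step* is a pair of localizations at consecutive
frames. Displacements across a one-frame tracking gap are never pooled as
single steps for jump-distance or MSD purposes, because a bridged gap spans
two frame intervals and would inflate the apparent displacement. Dwell-event
detection has its own, explicit gap tolerance (below). Track-length filters
count consecutive-frame steps; the standard filters are >= 5 steps for
ensemble statistics and >= 9 steps for per-trajectory exponent fits. When
two conditions are compared, datasets can be equalized by uniform
subsampling of the larger one to the smaller one's trajectory count.

## MSD estimation and localization error

The time-averaged MSD (TAMSD) of one track uses, by default, every
overlapping pair of localizations separated by k frames; the
ensemble-averaged MSD (EAMSD) pools squared displacements across tracks per
lag and is algebraically the pair-count-weighted mean of the TAMSDs. The
overall diffusion coefficient is the slope/4 of an ordinary least-squares
line through the first five lags.

Static localization noise of per-axis SD sigma adds a constant
`4 sigma^2` to the 2-D MSD. The per-track intercept of the five-lag linear
TAMSD fit therefore estimates sigma as `sqrt(max(intercept, 0) / 4)`;
the dataset's mean localization error is the mean over all tracks with at
least five usable lags. Clamping negative intercepts at zero makes the
mean estimate biased slightly upward for short tracks (the benchmark
dataset with injected 50 nm noise reads back ~58 nm); this is a property of
the estimator itself, and downstream consumers (confinement radius, offset
correction) deliberately use the same estimate rather than the unknown
truth.

## Per-trajectory motion classification

Each track with >= 9 consecutive steps is fitted over its first nine TAMSD
lags with two nested models, `4 K t` (Brownian, exponent fixed at 1) and
`4 K_alpha t^alpha` with alpha bounded to (0, 2]; the F statistic
`(RSS1 - RSS2) / (RSS2 / (m - 2))` with m fitted points is referred to
F(1, m-2). If p >= 0.1 the track is called Brownian regardless of the
fitted exponent; otherwise alpha < 1 is subdiffusive, 1 < alpha < 2
superdiffusive, and alpha at the upper bound directed. The power-law fits
profile out the amplitude (closed form at fixed alpha) and minimize over
alpha with a bounded scalar search, evaluating alpha = 1 and both bounds
explicitly so the nested inequality RSS2 <= RSS1 holds exactly.

Two estimator choices here matter and are deliberate:

* **Disjoint TAMSD windows for the test.** Overlapping-window TAMSD points
  of a ~10-frame track are so strongly correlated that the free exponent
  absorbs stochastic smooth curvature and the F-test rejects roughly three
  quarters of genuinely Brownian tracks at confidence 0.1. Classification
  therefore evaluates the TAMSD on non-overlapping (chained disjoint)
  windows, whose points are approximately independent, restoring a usable
  null behaviour. The overlapping estimator remains the default everywhere
  else (and is available via `overlap=True`).
* **Localization-error offset correction.** Neither nested model carries an
  additive offset, so the static-noise term `4 sigma^2` masquerades as
  subdiffusion. Before fitting, the census subtracts the dataset-mean
  offset `4 sigma_hat^2`, with sigma_hat the localization-error estimate
  described above — the same quantity that sets the confinement radius.
  Weighted fits (residuals divided by the per-lag SD of the squared
  displacements) are available but off by default.

On the benchmark simulation (next section) this classifier reproduces the
expected census: ~78% Brownian and ~10% subdiffusive. The split of the
remaining tracks between "superdiffusive" and "directed" depends on how
often the fitted exponent lands exactly on the alpha = 2 bound, which is a
property of the optimizer's treatment of boundary minima more than of the
data; our bounded profile search yields ~6% at the bound and ~6% strictly
inside, whereas reference values for this census put more mass strictly
inside (~10%) and less at the bound (~3%). The combined
super-plus-directed fraction (~12-13%) is reproduced.

## Jump-distance (JD) mixture analysis

All consecutive-frame displacements are pooled and their density-normalized
histogram (Freedman-Diaconis widths by default, capped at 500 bins; a fixed
rule with 100 bins to the 99.5th percentile is available; the rule used is
recorded in the fit object) is fitted with a mixture of 1-3 Rayleigh
densities by bounded Levenberg-Marquardt least squares. Weights are fitted
as free non-negative amplitudes and renormalized to sum to one; components
are reported sorted by D. Initialization is multi-start: quantile-spaced
scale seeds, geometric spreads of the closed-form single-Rayleigh MLE
(`D = mean(r^2) / (4 tau)`), and the (k-1)-component solution extended by
one component; the lowest residual sum of squares wins.

Model selection accepts k+1 over k only if (i) the nested F-test
(2 extra parameters, residual dof = bins - 2(k+1)) gives p < 0.05,
(ii) the BIC decreases by at least 5% relative to |BIC_k|, and (iii) the
richer model contains no two components closer than 5% in relative D
(duplicate-component collapse). The BIC uses a Gaussian residual likelihood
with residuals expressed on the count scale (density residuals times
N_jumps times bin width) so that its value is positive for realistic
histograms and a *relative* decrease is meaningful.

Static localization noise inflates every apparent coefficient by
`sigma^2 / tau` (each observed step gains `4 sigma^2` in expectation);
comparisons against ground truth subtract this documented bias. Two
caveats are documented rather than hidden. First, reflecting walls make
the pooled jump distribution slightly lighter-tailed than a Rayleigh
mixture, biasing fitted coefficients a few percent low in small cells.
Second, when the noise floor compresses the ratios between apparent
components (e.g. 0.26 / 0.53 / 1.07 um^2/s for the benchmark mixture), the
three-component least-squares problem develops a flat ridge: weight can
trade against the low component's scale with almost no residual cost, and
the fitted intermediate coefficient scatters by roughly +/- 15-30% between
realizations even with ~4.5 x 10^5 jumps, and the BIC gain from the third
component can fall under the 5% guard. The package reports what the
estimator produces; it does not tune around this identifiability limit.

A simultaneous variant fits two datasets jointly with shared component
coefficients and per-dataset weights (used when one condition is expected
to change population sizes but not mobilities), and a
prediction-versus-observation curve (mixture CDF against empirical CDF at
the sorted jumps) visualizes goodness of fit.

## Confinement analysis

The confinement radius is `R = 2.5 x` the mean estimated localization
error. A *dwell event* is a run of consecutive points lying within R of
one of the trajectory's own nodes, tolerating per event at most one
single-frame gap **or** one single-point excursion that returns inside on
the very next frame (a flag allows both at once; the default is the
conservative reading). Events must span at least `min_steps` steps
(typical values 3, 5, 6, 9); detection is greedy — the window covering the
most steps is recorded, excised, and the remaining segments are searched
again — with ties broken toward the earliest start, then the earliest
centre node. The greedy detector is verified against an exhaustive
enumeration oracle on hundreds of random tracks.

A track with no event is *free*, a track whose events cover every step is
*confined*, anything else is *mixed*. Dwell times are counted in steps
(intervals) times tau. Their survival curve (1 - ECDF) is fitted with
`sum_i A_i exp(-t / tau_i)`, `sum A_i = 1`, for one or two components,
the pair decided by a nested F-test at p < 0.05. Transitions between the
confined and free states are counted only when the non-confined stretch
spans at least three steps with mean step length above R; shorter or
slower inter-event stretches emit no transition.

## Normalized-cell maps

Each cell's localizations are affinely mapped into a standard 3 x 1 um
rectangle using the cell's centroid, long-axis direction, length and width;
points outside the rectangle (localization noise at the membrane) are
clipped with a warning so that map totals conserve counts. Spot maps are
2-D histograms (optionally normalized by total count for cross-condition
comparison); speed maps bin the single-step diffusion estimate
`d^2 / (4 tau)` by step midpoint over bins of ~0.1 um^2 (a 10 x 3 grid
gives exactly 0.1 um^2 per bin), with unoccupied bins as missing values,
not zeros. Confined/free map pairs partition the localizations using the
dwell events (covered points vs everything else). Cells can be split into
small/medium/large by length terciles, and a one-dimensional long-axis
marginal (density-normalized) summarizes polar versus mid-cell occupancy.
Because pole identity is arbitrary in the raw images, an optional per-cell
random end-for-end flip prevents artifactual left-right asymmetry.

## Synthetic data generator

The generator is first-class, tested code and defines the benchmark
conditions: N tracks (default 50,000) inside a 1 x 3 um rectangle, each
assigned one diffusion coefficient from the mixture 0.08 / 0.375 / 1.01
um^2/s with weights 10 / 65 / 25 % and keeping it for its whole lifetime.
True positions advance in 100 sub-steps per frame with per-axis increment
SD `sqrt(2 D tau / sub_steps)`; walls reflect specularly, implemented by
folding the free path with the triangle map of period twice the box length
— the exact reflection image of a discrete Gaussian walk, which preserves
the uniform stationary density and vectorizes. Observed positions add
isotropic Gaussian noise of SD 50 nm to the true positions; the noise does
not propagate into the dynamics. Lifetimes default to a geometric law with
mean 10 frames truncated to [2, 100], chosen to match photobleaching-
limited average track lengths of about 10 frames (0.14 s) reported for
capsid-scale particles; the law is configurable because real lifetime
distributions vary. Identical seed and configuration give bit-identical
datasets.

A polar-trap variant places caps of configurable depth at both poles:
a particle inside a cap becomes trapped with a per-frame probability,
diffuses with a reduced coefficient while trapped, and escapes on a
per-frame Bernoulli; the per-frame ground-truth state sequence is stored
alongside. This generator exercises the confinement and mapping stages
against known truth.

What the generator does *not* emulate: spherocylindrical geometry (the cell
is a rectangle), motion blur within the 12 ms integration window, tracking
errors (misconnections, gap closing artifacts), photophysics beyond a
lifetime law, and spatially varying viscosity. Passing tests on synthetic
data therefore validate the estimators under idealized imaging, not the
biology of any particular dataset.

## Hydrodynamic calculations

Stokes-Einstein arithmetic is exact closed form in SI units:
`D = k_B T / (6 pi eta r_H)` and its inversions for viscosity and radius,
with k_B = 1.380649e-23 J/K and T defaulting to 298.15 K. Oligomer-mass
scaling ratios `(MM_ref / MM_target)^(1/e)` with e = 3 (compact globule)
or e = 2 predict a related assembly's coefficient from a reference one,
and `eta = eta_0 D_0 / D_obs` converts a dilute-buffer reference
coefficient plus an in vivo measurement into an effective cytoplasmic
viscosity. Worked numbers: a 7.8 nm sphere observed at 0.51 um^2/s implies
0.0549 Pa s; at that viscosity, 0.38 um^2/s implies a 10.468 nm radius
(2.668 nm above the bare capsid); the cubic mass ratio for the
fluorescently labelled versus tag-inside capsid masses is 0.7503. The
squared-relation ratio of the same masses evaluates to 0.6499.

## Problem sizes and numerical choices

The test suite regenerates the full 50,000-track benchmark once (about one
minute) and sizes all other simulations in the hundreds-to-thousands of
tracks so the whole suite completes in a few minutes. Scalar optimizations
use bounded Brent with 1e-6 tolerance; mixture and decay fits use
Levenberg-Marquardt (lmfit) with bounds; ties at the alpha = 2 bound are
classified directed; degenerate inputs (constant MSD curves, constant
dwell samples, all-equal cell lengths) return flagged results rather than
raising. Every random path is driven by an explicit seed.
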