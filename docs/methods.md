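# Methods

## The measurement being modeled

A nucleosome array is held between two optically trapped beads at a
constant force for a 10-minute observation window while the end-to-end
distance is recorded at 50 Hz.  Each release of a nucleosome's ~80 bp
inner DNA turn lengthens the tether abruptly; after the window the
construct is stretched to ≥35 pN and each still-wrapped nucleosome
ruptures, appearing as a ~26 nm contour-length shift on the
force–extension curve.  Confocal line scans across the tether (75 nm
pixels) give kymographs of fluorescently labelled remodeler and
histones; sliding histones are tracked manually as position–time
trajectories.

## Two-state unwrapping model

Inner-turn unwrapping within the window is treated as a two-state
(wrapped/unwrapped) transition whose probability is logistic in force,

    P(F) = 1 / (1 + exp(−(Δx/k_BT)(F − F_1/2))),

with half force F_1/2 (pN) and transition-state distance Δx (nm);
k_BT = 4.114 pN·nm (298 K; the experiments are at room temperature, and
the choice is configurable).  The barrier is ΔG‡ = F_1/2·Δx.  The model
is fitted to per-force unwrap counts by binomial maximum likelihood
(statsmodels GLM on the logit scale; per-force counts and per-nucleosome
binary outcomes give identical likelihoods).  Standard errors for
(F_1/2, Δx) come from the (intercept, slope) covariance by the delta
method.  Complete separation (all counts 0 or all n) is an error;
quasi-separation at the extreme forces of a steep sigmoid is routine and
simply yields large slope SEs.

The with/without difference curve D(F) = P_with − P_without is
characterized by bounded 1-D maximization on [0, 30] pN and bisection
for the half-maximum crossings.

## From probability to kinetics

The generator converts the window probability into a homogeneous
exponential rate, k = −ln(1 − P)/T with T = 600 s, so the fraction
analysis and the lifetime analysis are self-consistent by construction.
Tetrasomes — the minor (~26%) population of partially assembled
particles — carry the same rate multiplied by a speed-up factor
(default 137, i.e. two orders of magnitude faster at the 10 pN
reference).  Both numbers are configuration values, not fitted.

Lifetimes are the times from clamp start to each detected plateau
start; a double step contributes the same duration twice; each
nucleosome that survives the window contributes a censored duration at
600 s.  The CPD divides the running count of uncensored durations by
the total sample count (censored included), so its plateau equals the
unwrapped fraction; an `events_only` switch normalizes by events
instead.  The bi-exponential model

    CPD(t) = S·[1 − A·e^(−t/τ1) − (1 − A)·e^(−t/τ2)]

is fitted by least squares (lmfit, bounded).  Because every nucleosome
unwraps eventually under constant force, the total-normalized CPD
asymptotes to exactly 1, and S is pinned at 1 by default: with the slow
time constant (hundreds of seconds) exceeding the window, a free S is
nearly collinear with τ_slow and the fit is unidentifiable (replicate
scatter on τ_slow grows several-fold).  `scale=None` restores the
free-plateau variant.  Components are relabeled so the major population
is the slower one; fits whose amplitudes (<5%/>95%) or time-constant
ratio (<2) make the second component meaningless are flagged
degenerate.  Least-squares covariance SEs are reported but understate
uncertainty because empirical-CDF residuals are correlated;
`bootstrap_biexponential` resamples the lifetime ensemble for honest
errors, and a censored-mixture direct MLE is provided as an independent
cross-check.

## Step detection

Plateaus are found by recursive binary segmentation: each candidate
split minimizes the two-mean residual sum of squares (prefix-sum
computation, O(n) per level) and is accepted when the level change
exceeds `sensitivity` (default 3) times the robust noise SD (median
absolute successive difference / 0.6745 / √2) and both sides last at
least `min_dwell` (default 0.5 s).  Accepted breakpoints are then
iteratively re-placed at the exact least-squares position between their
neighbors — binary segmentation places a compromise boundary when two
steps fall close together, and the local re-optimization recovers the
true positions — and boundaries whose level change falls below
threshold after refinement are merged away.  On noiseless staircases
the result coincides with exhaustive least-squares change-point
enumeration (verified against a brute-force oracle in the tests).

Event classification follows the assay's rules.  A step is an
unwrapping event only when the new plateau exceeds the running maximum
level by more than 5 nm (the "net increase" filter; the tolerance is a
module choice, as the qualitative rule defines none), which excludes
loop-extrusion shortening and its recovery while still crediting an
unwrap that terminates an excursion.  Step sizes ≥40 nm are double
events; ≥66 nm (2.5× the canonical step) would imply three or more
simultaneous unwraps and is flagged anomalous.  Anomalous steps are
excluded from lifetime kinetics but carry an implied multiplicity
(size/26, rounded) so that event accounting can resolve them
explicitly — the programmatic analog of visually verifying the trace.

Rupture counting on stretch curves maps each point to its implied
contour length through the WLC inverse (below ~2 pN the inverse is
ill-conditioned and skipped) and counts positive jumps within ±8 nm of
a multiple of 26 nm, crediting k counts to a k-fold jump.

## Polymer mechanics

The extensible worm-like chain interpolation formula

    x = Lc·(1 − ½√(k_BT/(F·Lp)) + F/S)

with standard dsDNA values Lp = 50 nm, S = 1200 pN, 0.34 nm/bp gives
the expected end-to-end gain from released DNA: 80 bp at 10 pN extends
to 26.2 nm.  The step is modeled as the extension of the released
contour alone, with no octamer-geometry offset; that choice reproduces
the observed ~26 nm step.  All parameters are overridable.

## Fraction accounting

Operationally, α is computed as detected events (with multiplicity)
divided by events plus stretch-curve ruptures — the quantities the
assay actually measures.  Using the rupture count (rather than a known
array size) in the denominator cancels most of the bias from unwraps
that occur in the first fraction of a second of the clamp, which no
plateau detector can see.  Corrected fractions are clipped at 0 when
α < 0.26; near the clip the correction is slightly biased upward, which
is a property of the published procedure itself at moderate per-force
sample sizes and is visible as a mild downward pull on fitted Δx.

## Fluorescence quantification

Intensity profiles average background-corrected photon counts per pixel
over the first 6 s of line scans (10 s for coverage analyses), flooring
at zero; the background is the median count in the bead-free flanking
pixels.  The monomer PSF is calibrated from ≥50 centroid-aligned
profiles of ≥5 isolated monomers; a Gaussian plus constant offset is
fitted to their average (the offset absorbs the small pedestal the
zero-floor leaves), giving the PSF width σ and the unit photon area per
monomer.  Construct profiles are decomposed into Gaussians with widths
fixed at σ, positions refined within one pixel of local maxima, and
non-negative areas; each area is quantized to the nearest integer
multiple of the unit area (ties rounded down, capped at 5).  Total
fitted intensity must agree with the profile integral within 15%, else
peaks are flagged unresolved.  Co-located monomers are intrinsically
indistinguishable from true oligomers ("apparent" oligomers);
photobleaching is not modeled or corrected, consistent with its
negligible effect on the analysis timescales.

Trajectories are segmented by a 5 s sliding-window regression velocity:
samples with |v| ≥ 3 nm/s (inclusive) are active translocation, below
are pauses; runs are merged, each segment's velocity is its own
regression slope, and kinds are re-derived from that slope so the
threshold invariant holds for the reported segments.  Active segments
of ≥3 s enter the mean |velocity|; per-oligomer summaries report means
± SEM and, for two classes, the difference ± pooled SE without a
significance claim.

## What the generator does and does not emulate

Emulated: exponential waiting times consistent with P(F); the ~26%
fast (tetrasome) subpopulation; Gaussian step sizes (26 ± 3.5 nm) and
distance noise (2 nm per 50 Hz sample); transient triangular
loop-extrusion excursions (ATP condition only; default 0.005 events/s,
depth up to 100 nm at 10 nm/s — placeholders, as event frequency and
depth are not quantified in published work); stretch-curve ruptures
above 15 pN; Poisson photon counts over Gaussian PSFs on a 75 nm pixel
grid; piecewise-constant-velocity tracks with localization noise.

Not emulated: instrument drift and bead-position noise correlations,
the force-ramp approach to the clamp setpoint, torque and twist,
photobleaching/blinking, diffusive (sub-threshold) motion within
pauses.  Passing recovery tests therefore demonstrates the estimators
are correct under the assumed statistical structure, not that they are
robust to every instrumental artifact of real traces.

A known consequence of the rate-multiplier tetrasome model: at 12.5–15
pN the tetrasome mean lifetime falls below the detector's 0.5 s dwell
resolution, so several unwraps can merge into one large step.  Implied
multiplicities and rupture-based denominators keep the fraction
analysis accurate; exact event-for-event accounting holds on ensembles
without such coincidences (e.g. the 10 pN no-remodeler condition).

## Problem sizes and numerical choices

Tests and analysis scripts use 10-minute, 50 Hz traces (30 000 samples)
with 15–20 nucleosomes per construct, 2–3 constructs per force at six
forces (3–15 pN), 200-lifetime ensembles for mixture recovery, 200
replicates for the F_1/2 coverage study, 60 calibration profiles for
the PSF, and 11 trajectories for the sliding analysis — sizes chosen to
match the scale of the corresponding published ensembles while keeping
a full run to a few minutes.  All randomness flows from explicit seeds
(numpy `default_rng` / `SeedSequence`); identical configurations
reproduce outputs bit for bit.
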