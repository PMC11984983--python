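# Methods

`chromodyn` quantifies the dynamics of proteins at yeast spindle pole
bodies (SPBs) and of the microtubules they organize, from four kinds of
measurement: single-molecule tracking movies, astral-microtubule (aMT)
length–time traces, half-spindle FRAP traces, and a handful of bench
assays. Because raw microscopy data of this kind is rarely shareable, the
package includes a first-class synthetic-data module that generates every
input with known ground truth; all statements below about estimator
accuracy refer to recovery of that ground truth, at the problem sizes the
test suite actually runs.

## Coordinate and unit conventions

Frames are 0-based; positions are in pixels with a pixel-center origin
(x = column, y = row); micrometres are `px * pixel_size_nm / 1000`. The
reference acquisition uses 110 nm pixels, a 200 ms frame interval for
dwell-time (residence-time) movies and a 15 ms interval for jump-length
movies, and an axial detection slab of 294 nm within which a fluorophore
is detectable. Diffusion coefficients are in µm²/s, rates in 1/s (dwell
kinetics) or events/min (microtubule dynamics), and FRAP times in seconds.

## Synthetic trajectories (`synth`)

Each simulated molecule is assigned an initial state — bound-specific,
bound-non-specific, or free — from the mixture
(`frac_bound`, `frac_ns_of_bound`). Lateral motion is 2D Brownian with the
state's diffusion coefficient; observed positions add independent Gaussian
localization error per coordinate (default σ = 35 nm, inside the range
typically fitted from data). Tracks end at an exponential photobleach time
(default mean 20 s; the dye lifetime is instrument-specific and
configurable), and a free molecule's track additionally ends when its 1D
axial Brownian position leaves the detection slab — bound molecules are
held at the focal plane. With `interconvert` off (the jump-length fixture
convention) molecules keep their state for the whole track, matching the
two-state displacement model's no-switching assumption; with it on (the
dwell fixture convention) bound molecules unbind into the free state after
an exponential dwell at their state's rate. Rebinding is not modelled —
no binding rate is defined anywhere in the analysis chain, and an unbound
molecule that diffuses away is indistinguishable from a fresh free one.

What the generator deliberately omits: blinking photophysics beyond
closed track gaps, EMCCD/sCMOS noise models, 3D PSFs, motion blur within
an exposure, and any spatial structure in the binding sites. Passing tests
therefore demonstrate the correctness of the estimators under the models
they assume, not robustness to every artefact of real movies.

Microtubule traces follow the standard two-state dynamic-instability
model: growth and shrinkage phases alternate with exponential durations
(catastrophe rate per time spent growing, rescue rate per time spent
shrinking), length changes linearly at the polymerization or
depolymerization speed, a rescue is forced when length reaches zero, and
the trace is sampled every 15 s by linear interpolation. Ground-truth
phase boundaries are returned with the trace, so segmentation can be
tested exactly.

FRAP traces: pre-bleach points sit at 1 (normalized); the bleached half
recovers as `(1-depth) + (plateau-(1-depth))*(1-exp(-t/τ))` and the
unbleached half mirrors the recovered amount so the post-bleach total
`2 - depth` is conserved (subunit exchange moves fluorescence, it does not
create it). A consequence worth knowing: under this conservation rule, a
trace can recover ≥50% of its lost signal only if
`plateau > (2-depth)/2`, and in that case the late bleached/unbleached
ratio is ≥1. Real spindles also bleach during monitoring, which is why
published corrected ratios of ~0.7 coexist with defined half-times; the
generator does not model monitoring bleach. Defaults (full-depth bleach,
plateau 0.55, τ = 150 s) give a defined t50 of a few hundred seconds.

## Detection and linking (`spots`)

Detection: per frame, candidate maxima more than 4 robust standard
deviations (median ± 1.4826·MAD) above the median background are refined
with a local 2D Gaussian fit for sub-pixel position. Candidates are kept
if the fitted amplitude lies in a configurable intensity band (the
"remove dim" filter; the absolute scale is camera-specific and the default
50–250 band is a placeholder, not an attempt to match any instrument) and
if a normalized sharpness score — fitted amplitude over fitted σ², scaled
by the frame maximum — exceeds the "remove blur" threshold (default 0.02).
The score is a re-interpretation of a tracker-specific blur metric; on
synthetic fixtures with known truth it is irrelevant, and it is exposed
for tuning on real data.

Linking is nearest-neighbor with deterministic tie-breaking: per frame,
all (open track end, detection) pairs within the search radius are sorted
by distance and assigned greedily, so results do not depend on input
order. The radius is `max_jump` (default 6 px) for adjacent frames and
`max_jump·√(gap+1)` across a photoblinking gap of up to 4 frames
(diffusive scaling — the expected displacement grows with the square root
of elapsed time). Tracks shorter than 4 observed detections are dropped.
The test suite checks this greedy scheme against an exhaustive
minimum-total-displacement assignment on well-separated configurations,
where both must coincide; global optimization for dense fields
(u-track-style) is out of scope.

## Residence times (`dwell`)

Bound segments are maximal runs in which every frame-to-frame displacement
is ≤ 470 nm and every two-frame displacement ≤ 610 nm (thresholds
calibrated on chromatin-bound histone motion), with at least 7 time points
(the 200 ms-interval setting). The two-frame test is skipped across closed
gaps, where no position exists. An important geometry fact, verified by
simulation against a brute-force window oracle: these displacement
thresholds *alone* only suppress free-molecule contamination below 1% for
diffusion faster than ≈1 µm²/s; at the slow end of the free range
(0.5 µm²/s) roughly a quarter of full-length free tracks would slip
through. What makes the rule effective in practice is the acquisition
geometry: a molecule diffusing at ≥0.5 µm²/s leaves the 294 nm axial slab
within one or two 200 ms frames and never accumulates seven in-focus
points. The simulation-checked exclusion bound in the acceptance script is
therefore run under the full acquisition geometry.

The bound fraction B is the fraction of tracks contributing at least one
bound segment. The photobleach rate λ is fitted as an exponential decay of
the detected-molecule count per frame; this estimator assumes detection
loss is dominated by bleaching, which holds in fixtures without axial loss
(free molecules remain tracked after unbinding) and must be borne in mind
on real data, where it absorbs any other loss process.

The empirical survival of segment durations is divided by `exp(-λt)`,
renormalized to start at B, and clipped to be non-increasing (the
correction can produce upticks at sparse long durations; clipping is
logged). Two models are fitted by least squares with B fixed:

    S(t) = B · exp(-k (t - t₀))
    S(t) = B · (F_ns · exp(-k_ns (t - t₀)) + (1 - F_ns) · exp(-k_s (t - t₀)))

with residence times T_ns = 1/k_ns (non-specific, short) and T_s = 1/k_s
(specific, long). Three numerical choices matter:

* **Time origin t₀ at the shortest observed duration.** The minimum-length
  rule left-truncates the duration distribution; an exponential mixture
  conditioned on t ≥ t₀ is again a mixture with the *same rates* and
  shifted weights, so the shifted fit recovers rates unbiased, whereas an
  unshifted amplitude-fixed model cannot even represent the truncated
  curve. The reported F_ns is correspondingly the truncated-sample weight.
* **Residual weighting by `exp(-λt)`.** The bleach correction amplifies
  tail noise by `exp(+λt)`; weighting by the inverse restores the raw
  curve's noise scale. Without it, recovery of long residence times
  (comparable to the bleach lifetime) degrades badly.
* **Model selection on increments.** Survival-curve residuals are
  cumulative and strongly correlated; a naive nested F-test on them
  selects the double model on ~half of purely single-exponential
  replicates. The F statistic (1 vs 3 free parameters, Δdf = 2) is
  therefore evaluated on interval probabilities — survival increments
  between consecutive observed durations plus the right tail — weighted by
  their binomial standard errors, whose noise is approximately
  independent. Measured false-selection rate: ~2% at α = 0.05. A
  degenerate double fit (F_ns pinned at 0 or 1, or coincident rates)
  collapses to the single model regardless of p-value.

Multi-start initialization uses 10 deterministic log-spaced rate pairs
around the inverse mean duration. `residence_time` on the result reports
the selected model's time constant, mirroring the practice of reporting a
single component when the two-component fit is not supported.

Accuracy at the suite's problem size (2,000 tracks, 200-frame movies,
20 s bleach): T_s is recovered within ~15% for T_s = 5 s and, averaged
over three replicates, within 20% across T_s ∈ {2, 5, 40} s. A single
replicate at T_s = 40 s has ~16% sampling scatter — the residence time
then exceeds the bleach lifetime and approaches the movie length, which is
close to the information-theoretic floor for this design, not an
implementation artefact.

## Jump-length kinetics (`jumps`)

Displacement histograms are built for lags 1..6 (default), taking at most
4 jumps from the start of each ≥3-frame track per lag (limiting the weight
of long tracks, which are depleted of fast molecules), discarding jumps
above 1.5 µm, binning at 10 nm. The two-state model for the jump length r
at lag time τ is

    p(r, τ) = F₁ · r/(2(D₁τ+σ²)) · exp(-r²/(4(D₁τ+σ²)))
            + Z(τ) · (1-F₁) · r/(2(D₂τ+σ²)) · exp(-r²/(4(D₂τ+σ²)))

where σ is the localization error (it adds σ² to every apparent
mean-square displacement) and Z(τ) is the axial-loss correction: the
probability that a molecule starting uniformly inside the detection slab
is still inside after 1D free diffusion for τ, computed in closed form.
The correction is off by default — matching the analysis setting the
model reproduces — but implemented and tested (it converges to the
uncorrected model as the slab widens). Fitting is least squares on the
analytic model CDF against the empirical CDFs jointly across lags, each
lag weighted equally, inside box constraints (D_bound ∈ [1e-4, 0.5],
D_free ∈ [0.5, 5] µm²/s, F_bound ∈ [0, 1], σ ∈ [0.01, 0.1] µm), with a
deterministic mid-box start plus 3 seeded random restarts; estimates
within 0.1% of a box edge are flagged as pinned. On 10,000+ simulated
jumps (no switching), F_bound is recovered within ±0.05 and D_free within
10%; part of the residual D_free bias comes from the 1.5 µm jump cutoff
truncating the free tail, which the model CDF deliberately does not
renormalize for.

## Microtubule dynamics (`mtdyn`)

Sampled length traces are segmented by merging consecutive same-sign
length changes; a merged run whose net change is below `min_delta`
(default 0.2 µm ≈ 2 pixels) is a pause. Pauses are transparent for event
detection between opposite-sign phases — a growth→pause→shrink sequence
counts one catastrophe, placed at the pause end — and excluded from all
time denominators. Setting `min_delta = 0` disables the pause category,
since the underlying definitions mention only growth and shrinkage; the
CLI reports f_cat at `min_delta` ∈ {0.1, 0.2, 0.3} µm on request so the
sensitivity is visible. The four statistics follow their definitions
directly: catastrophe (rescue) frequency is the transition count divided
by the total growth (shrinkage) time; per-event polymerization and
depolymerization rates are net length change over duration.

Censoring convention: a phase truncated by the end of the trace is not a
completed event — it is excluded from the frequency denominators, though
it still contributes a per-event velocity; a phase truncated at the trace
*start* but ending in an observed transition is included in the
denominators, and no transition is ever counted at a trace boundary.
Pooling over cells is event-count-over-pooled-time, not a mean of
per-cell frequencies. Phases shorter than the 15 s sampling interval are
invisible at the sampling resolution; segmentation is exact whenever every
true phase spans at least two samples, and frequency estimates on
exponentially distributed phases carry a small downward bias from the
unresolvable fraction (kept below sampling error in the tests by using
slow switching).

## FRAP (`frap`)

Each ROI channel is background-subtracted and normalized to its own
pre-bleach mean, making all outputs invariant to global intensity
rescaling. t50 is the first post-bleach sample at which the normalized
bleached intensity reaches `min_post + 0.5·(1 - min_post)` — 50% of the
lost signal, the standard FRAP convention; `absolute=True` switches to 50%
of pre-bleach intensity, since the phrase "50% recovery" is ambiguous.
No curve fit is involved by default (half-times are read off the sampled
curve, so t50 is quantized to the 30 s sampling interval); an optional
exponential-fit t50 is available for noisy traces. The corrected ratio is
the literal bleached/unbleached quotient averaged over the last three
points (after full recovery); values outside [0, 1.5] trigger a warning
rather than an error, because contrived fixtures can legitimately exceed
it.

## Assay calculators (`assays`)

β-galactosidase activity: `1000·(OD420 − 1.75·OD550)/(t·v·OD610)` Miller
units; negative (blank-dominated) results are allowed but flagged.
Plasmid mitotic stability is selective colonies per 100 non-selective
colonies; chromosome loss is the first-division loss frequency, with fold
change as the frequency ratio. The attached intervals — Clopper–Pearson
for proportions, Koopman score for the frequency ratio — are additions of
this package (the original quantifications report replicate dispersion)
and every output labels them as such. SPB-inheritance and Kar9-asymmetry
classification use max/min intensity ratios against explicit thresholds
(defaults 1.5 for the symmetry band and 1.5/5.0 for weak/strong, echoed in
every output; no numeric thresholds are defined by the underlying
protocol, so these are configuration, not constants). Spindle geometry
reports Euclidean spindle length, the smaller angle between spindle and
mother–bud axis (always in [0°, 90°]), and the daughter/mother diameter
ratio with the >0.6 large-budded and 1.5–2.0 µm metaphase-length flags.
Interaction-network filtering pools distinct publications per undirected
gene pair from a BioGRID TAB export (physical and genetic evidence pooled
unless `physical_only`), keeps pairs supported by ≥3 studies, and returns
the retained subnetwork within two hops of the seed proteins; absent
seeds remain as logged isolates.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible
given one. The test suite runs at 2,000–5,000 molecules for tracking
fixtures, ~10,000 jumps for the two-state fit, 200 replicates for the
model-selection error rate, and 20 two-hour traces for microtubule
statistics — sizes chosen so each estimate's sampling error is well inside
the asserted tolerance while the whole suite completes in well under a
minute of compute.
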