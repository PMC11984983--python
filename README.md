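# chromodyn

Quantitative kinetics for spindle-pole-body (SPB) biology in budding
yeast: single-molecule tracking analysis, microtubule dynamic-instability
statistics, FRAP quantification, and the small bench-assay calculators
that surround them — with a synthetic-data module that stands in for the
microscope so every stage can be validated against known ground truth.

## What it computes

**Residence times from slow (200 ms) tracking movies.** Bound portions of
each trajectory are classified with a two-threshold displacement rule
(frame-to-frame ≤ 470 nm, two-frame ≤ 610 nm, ≥ 7 time points), the
survival distribution of bound durations is corrected for photobleaching,
and fitted by least squares to a mixed exponential decay

    S(t) = B · (F_ns · e^(−k_ns t) + (1 − F_ns) · e^(−k_s t))

with B the measured bound fraction. T_ns = 1/k_ns and T_s = 1/k_s are the
non-specific (short) and specific (long) residence times; a nested F-test
decides whether the two-component model is supported over a single
exponential.

**Bound fractions and diffusion coefficients from fast (15 ms) movies.**
Displacement histograms over several time lags are fitted with the
two-state jump-length model

    p(r, τ) = F₁ · r/(2(D₁τ+σ²)) · e^(−r²/(4(D₁τ+σ²)))
            + Z(τ) · (1−F₁) · r/(2(D₂τ+σ²)) · e^(−r²/(4(D₂τ+σ²)))

(CDF fit, box constraints, σ fitted from data, optional axial-loss
correction Z), yielding F_bound, D_bound and D_free.

**Microtubule dynamic instability.** Length–time traces are segmented
into growth/shrink/pause phases; catastrophe and rescue frequencies are
transition counts over total growth/shrinkage time, and per-event
polymerization/depolymerization rates are net length change over duration.

**FRAP.** Half-spindle ROI traces are background-subtracted, normalized
to the pre-bleach mean, and summarized by t50 (time to recover 50% of the
bleach-lost signal) and the late bleached/unbleached ratio.

**Assays.** Miller units, centromeric-plasmid mitotic stability,
chromosome-loss frequency and fold change, SPB-inheritance and Kar9
asymmetry classification, spindle length/angle/budding-index geometry,
and ≥3-study filtering of BioGRID interaction networks.

`docs/methods.md` describes the models, their assumptions and the
numerical choices in detail.

## Worked example

Simulate a dwell-time experiment with known kinetics and recover them:

```python
from chromodyn import AcquisitionParams, KineticTruth, simulate_tracks
from chromodyn.dwell import (classify_bound_trackset, bound_fraction,
                             estimate_bleach_rate, survival_curve, fit_survival)

truth = KineticTruth(frac_bound=0.5, frac_ns_of_bound=0.6,
                     k_ns=2.0, k_s=0.2,            # T_ns = 0.5 s, T_s = 5 s
                     D_bound=0.005, D_free=2.0,
                     bleach_lifetime_s=20.0, interconvert=True)
acq = AcquisitionParams(frame_interval_s=0.2, n_frames=200,
                        axial_range_nm=0.0, localization_error_um=0.035)
tracks = simulate_tracks(truth, acq, 2000, seed=7)

segments = classify_bound_trackset(tracks)
B = bound_fraction(tracks)
lam = estimate_bleach_rate(tracks)
fit = fit_survival(survival_curve(segments, bleach_rate=lam, bound_fraction=B))

print(f"tracks: {len(tracks)}   bound segments: {len(segments)}")
print(f"bound fraction B = {B:.3f}   bleach rate = {lam:.4f} /s")
print(f"selected model: {fit.selected_model}  (F = {fit.f_statistic:.1f}, p = {fit.p_value:.2e})")
print(f"T_s = {fit.T_s:.2f} s   T_ns = {fit.T_ns:.2f} s   F_ns = {fit.F_ns:.2f}")
```

Output:

```
tracks: 1981   bound segments: 384
bound fraction B = 0.194   bleach rate = 0.0485 /s
selected model: double  (F = 5.0, p = 1.02e-02)
T_s = 4.32 s   T_ns = 0.42 s   F_ns = 0.17
```

The F-test supports two bound populations; the specific residence time
(truth 5 s) is recovered within 15% from 2,000 tracks, and the fitted
bleach rate matches the simulated 1/20 s⁻¹. B (0.19) is smaller than the
simulated bound fraction (0.5) because segments shorter than 7 time
points — most of the fast, non-specific dwells at T_ns = 0.5 s — are
excluded by design, which also shifts the apparent F_ns; the rates are
unaffected (see `docs/methods.md` on truncation).

The same workflow is available from the shell:

```sh
chromodyn simulate tracks --config cfg.json --seed 7 --out tracks.csv
chromodyn dwell --tracks tracks.csv --interval 0.2 --rmin 470 --rmax 610 --nmin 7
chromodyn jumps --tracks fast.csv --interval 0.015 --lags 6 --jumps 4
chromodyn mtdyn --traces amt.csv --min-delta 0.2 --bud-directed-only
chromodyn frap  --trace frap.csv
chromodyn assay miller --od420 0.5 --od550 0.2 --od610 0.8 --time 15 --volume 0.1
```

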