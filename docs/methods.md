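# Methods

This note documents the models, estimators and design choices behind
`dendrogain`, in the order the pipeline uses them: compartmental biophysics,
stimulus construction and calibration, the dynamic transfer-gain readout,
AP-waveform analysis, cohort statistics, and the synthetic-data generators
that stand in for the experimental recordings.

## Compartmental model

**Geometry.** Morphologies are rooted trees of 3-D sample points with radii
and region labels (soma, axon initial segment, myelinated axon,
basal/apical dendrite), read and written as 7-column SWC.  SWC type 2 is
interpreted as unmyelinated axon (AIS) and type 6 as myelinated axon so the
axonal split survives a round trip.  The soma is represented as a cylinder
whose length equals its diameter (default 20 µm), the common
single-compartment convention when no soma reconstruction is available.
Each morphology edge becomes one or more cylindrical compartments: somatic
and dendritic edges are split so that no compartment exceeds a maximum
length (default 20 µm; the in-silico experiments use 100 µm, about 0.1 of
the dendritic DC space constant, after verifying that halving it moves the
somatic AP peak time by well under 1%).  The axon is always a 50 µm AIS in
exactly 25 compartments followed by a 1 mm myelinated section in exactly
21 compartments, both 1 µm in diameter.

**Passive membrane.** Cm = 0.75 µF/cm², Ra = 100 Ω·cm, Rm = 30.3 kΩ·cm²,
leak reversal −70 mV (membrane time constant 22.7 ms).  Dendritic
compartments use Cm × 1.84 and Rm ÷ 1.84 to account for spine membrane —
division rather than subtraction, so the membrane time constant is
preserved; the myelinated axon uses Cm ÷ 37.5 and Rm × 5.

**Active conductances.** Fast-inactivating Na (m³h) and delayed-rectifier
K (n) in Hodgkin–Huxley form with the Mainen & Sejnowski (1996)
cortical-pyramidal rate functions, including the published −10 mV shift of
Na activation/inactivation and Q10 = 2.3 scaling of both rate constants
and peak conductances from 23 °C to the working temperature of 37 °C.
Peak densities (pS/µm²): AIS 8000/1500, soma 800/320, dendrites 20/10,
myelin 0/0; E_Na = +50 mV, E_K = −85 mV.  The Na activation rate constants
carry one additional calibration factor (1.25 on α_m and β_m equally, so
no steady state changes): it speeds the activation time constant until
simulated APs reach the onset sharpness (~20 /ms phase-plane slope for
large cells) and tracking bandwidth (cutoffs in the 400–500 Hz band)
reported for human pyramidal-cell models, while leaving the resting
potential mathematically untouched.  With these settings the human-scale
reference model rests at ≈ −70.5 mV and spikes initiate in the AIS; the
kinetics are a documented stand-in validated against that operating point
and the qualitative AP properties, not a clone of any one database entry.

**Integration.** Voltage is advanced by an implicit theta-method on the
branched cable: one Hines elimination (children are numbered after
parents, so a single reverse sweep folds the tree onto the root) solves
the symmetric tree-tridiagonal system exactly per step.  Gating variables
are advanced first by Rush–Larsen exponential updates read from
pre-tabulated steady states and decay factors (0.02 mV grid, linear
interpolation), which keeps them in [0, 1] unconditionally; the ionic
current is then linear in voltage, so the voltage step is implicit and
unconditionally stable.  Backward Euler (θ = 1) is the robust default for
equilibration, calibration and long operating-point runs (step 10–25 µs).
First-order damping measurably blunts the AP upstroke and with it
high-frequency phase locking — at 25 µs the measured gain near the cutoff
sits well below its step-refined limit, and 10 µs backward Euler still
under-reads it — so sweeps that feed cutoff estimates use Crank–Nicolson
(θ = 0.5, second order) at the reference 10 µs step, whose crossing-region
gain agrees with the Richardson limit of the backward-Euler family.  An
integration error (|V| > 200 mV or non-finite) aborts with the step
index.

**Readouts.** Resting potential is the somatic voltage after ≥ 1 s of
zero-current integration with a drift check (< 1 µV/ms).  Input resistance
is ΔV/ΔI for a −10 pA somatic step from rest.  Spikes are upward crossings
of 0 mV, linearly interpolated between samples, with a 2 ms refractory
rule (the threshold and refractory time are conventions; the underlying
data are unambiguous somatic APs).

## Stimulus and calibration

The dynamic-gain stimulus is I(t) = I0 + I1·sin(2πFt) + I_noise(t), where
I_noise follows the literal discrete iteration

    I_noise(t+dt) = (1 − dt/τ_I)·I_noise(t) + sqrt(s²·dt/τ_I)·ξ_t

with τ_I = 5 ms and i.i.d. standard-normal ξ.  The stationary variance of
this iterate is s²·(dt/τ_I)/(1 − (1−dt/τ_I)²) → s²/2 as dt → 0; the
package treats s² as the variance parameter of the iteration (the printed
equation), not of the process, and tests the closed form.  Noise arrays
are pre-generated at the integration step from a seed, so every experiment
is replayable bit-for-bit.

Calibration reproduces the experiment's operating point per model:

* a DC holding current places the soma at −75 ± 0.5 mV (two rounds of
  linear correction through the measured input resistance);
* bisection on s (fixed noise seed) until the subthreshold somatic voltage
  SD is 3 mV ± 5% at that holding potential — the subthreshold response is
  nearly linear in s, so a single probe provides the bracket;
* bisection on I0 until the mean firing rate with the calibrated noise is
  10 ± 1 spike/s; then I1 = I0/6.

Both calibrations are verified on holdout noise seeds in the acceptance
suite (tolerances: SD ± 10%, rate ± 1 spike/s — the study targets are
stated only as approximate).

## Transfer gain, cutoff, onset rapidity

The gain at frequency F is the vector strength of the spike train,
r1(F) = |Σ exp(i2πF·t_k)|/N, normalized by r1(F0 = 3 Hz).  The cutoff Fc
is the highest frequency at which the normalized gain is ≥ 1/√2, located
by log-linear interpolation between bracketing probe points; a curve that
never falls below threshold is censored at the highest probe, one below
threshold everywhere above F0 degenerates to F0.  The 1/√2 constant is the
standard −3 dB convention matching the plotted 0.7 line (one rendering of
the methods prints r1(F0)/2; −3 dB was adopted and is overridable).

Probe sets default to 16 log-spaced frequencies in [1, 1000] Hz plus the
3 Hz reference.  The full protocol integrates 120 s per frequency; the
scaled-down experiments use 20–30 s (≥ 200 spikes per point at the 10
spike/s operating point).  The F0 reference is integrated 4× longer than
other probes: its estimation error propagates coherently into every
normalized point and hence into Fc, so extra averaging there stabilises
the whole curve at minimal cost.  Each probe frequency uses an independent
recorded noise seed; the per-frequency seeds are stored in the gain-curve
sidecar, and reusing a template seed across models yields paired
comparisons.

Onset rapidity is the slope of dV/dt against V on the AP rising phase,
evaluated where dV/dt = 10 mV/ms: per AP, a line is fitted over
rising-phase samples with dV/dt in [5, 15] mV/ms (the window is a
numerical choice; the evaluation point is anchored at 10 mV/ms), falling
back to the local secant when fewer than two samples land in the window;
APs that never reach 10 mV/ms are excluded with a warning.  Units 1/ms.

## AP waveform analysis

APs are extracted from step-protocol sweeps (sampling must lie in
10–50 kHz), given instantaneous frequencies (1/interval to the previous AP
in the same sweep) and a first-in-train flag.  Rise speed is the peak of
centred-difference dV/dt on the upstroke at native sampling (no
resampling); events whose derivative peak spans fewer than 3 samples or
whose waveform is flat-topped (clipped) are flagged and excluded.  Rise
speeds are averaged in half-open 10 Hz bins (10(k−1), 10k] — matching the
"1–10, 11–20, ..." labels, so exactly 20 Hz falls in the 11–20 Hz bin —
with first APs isolated in their own bin.  Relative rise speed divides
each bin mean by the first-AP mean; the 20–40 Hz aggregate is the mean of
the (20,30] and (30,40] bins (bin-level averaging is robust to unequal AP
counts per bin; pooling APs instead is the other defensible convention).
Subject values are unweighted means across the subject's neurons.
Experimental exclusion criteria (bridge balance, epileptiform activity)
are upstream decisions; the module accepts a per-sweep include mask.

## Cohort statistics

All correlations operate on per-subject means.  `pearson_regression`
reports Pearson r, the two-sided p from the t transform with n−2 degrees
of freedom, the least-squares line and the pointwise 95% confidence band
of the fitted mean (the band is cross-checked against statsmodels OLS in
the tests).  The IQ split is low < 100 < high, with exactly 100 routed to
the high group with a warning (no such score occurs in realistic WAIS
cohorts, but the convention is fixed).  Group contrasts use the
equal-variance Student t-test by default, Welch behind a flag.  No
multiple-testing correction is applied, matching the single-comparison
reporting convention; summaries say so.  The statsmodels-style front end
(`CohortAssociation.from_dataframe(df, x, y).fit()` → results with
`summary()` and `plot()`) wraps the same computation.

## Synthetic data

The generator emulates everything the pipeline consumes.

**Cohort.** Default 31 subjects, IQ ~ normal(90, 17²) truncated to
[60, 130]; 1–11 neurons per subject with median 3 (1 + Poisson(2), capped).
Subject latents are built from the standardized truncated-IQ score z as
latent = mean + SD·(ρz + sqrt(1−ρ²)ε), which makes the population
correlation exactly ρ: TDL (mean 14.67 mm, SD 4 mm, planted R² = 0.26),
first-AP rise speed (300 ± 38 mV/ms, R² = 0.17) and relative 20–40 Hz rise
speed (0.79 ± 0.09, R² = 0.14).  Neurons perturb their subject's latents
mildly (TDL ×lognormal(0, 0.08), speeds ± 10 mV/ms, relative ± 0.03).
Morphologies come from the branched-tree generator at the cohort branch
density (64 branch points per 14.67 mm); each neuron's measured TDL equals
its latent exactly.  Every draw is recorded in a ground-truth ledger.

**Sweeps.** Step-protocol sweeps at 25 kHz (the recordings span
10–50 kHz): baseline −70 mV with 0.3 mV SD of exponentially correlated
noise (τ = 1 ms — white noise would be unrealistic and would bias the
max-of-derivative estimator), an 8 mV step depolarization, and AP trains
whose nominal instantaneous frequency ramps from ~5 to ~38 Hz across
sweeps with 8% ISI jitter.  AP upstrokes are parametric logistic sigmoids
(not simulated membrane potential, so the waveform analysis is tested
independently of the biophysics); the logistic time constant is chosen per
AP so that the centred-difference derivative at the native sampling rate
peaks exactly at the planted rise speed, making the generator's
calibration exact under the analysis that will consume it.  The planted
fatigue model is linear: speed(f) = first-AP speed × (1 − c·f), with
c = (1 − relative-rise)/30 so the 20–40 Hz band centre reproduces the
planted relative value.

**What passing tests do and do not show.** The generator plants linear
fatigue, Gaussian latents and clean sigmoidal upstrokes; real recordings
have bridge-balance artefacts, electrode filtering, non-linear fatigue and
non-Gaussian cohort structure.  Recovery of the planted effects therefore
validates the estimators and their wiring, not the biological claims;
conversely the in-silico transfer-gain results depend only on the
compartmental model, not on the sweep generator.

## Model neurons for the in-silico experiments

The dendritic-size experiments use synthetic branched arbors, not single
cables.  For a passive cable the AC space constant at AP-relevant
frequencies is a few hundred µm, so at fixed diameter any cable longer
than ~2λ presents the same proximal load regardless of total length — a
fixed-diameter ball-and-stick family saturates and cannot reproduce a
TDL-dependence (verified numerically: 10 and 15 mm cables give identical
cutoffs).  Real arbors grow by adding branches, and larger human L2/3
cells also carry thicker primary dendrites; the family therefore scales
branch count with TDL (the cohort density) and stem diameter
allometrically, d0 = 2.5 µm·sqrt(TDL/14.67 mm) clipped to [1.0, 3.5] µm.
With this geometry the somato-dendritic load, AP onset rapidity and
tracking bandwidth all increase monotonically across the
{1, 5, 10, 15} mm family, and the large/small cutoff contrast falls in
the observed 400–500 Hz vs ≲200 Hz regime.  The simple ball-and-stick
generator remains available for closed-form checks.

## Problem sizes and numerical tolerances

The shipped experiments are scaled down from the full protocol as their
own design choice: gain sweeps use 10-12-point probe sets instead of
120 s at every frequency, with integration time allocated where it
matters — 90 s per probe around the threshold crossing, 15-25 s
elsewhere, 4× at the F0 reference (the paired dendritic-size family uses
a uniform 25 s per probe); calibration bisections evaluate 8-40 s
simulations; cutoff-bearing sweeps integrate with Crank-Nicolson at
dt = 10 µs, other long simulations with backward Euler at 25 µs; spatial
discretization for the experiments is 100 µm (halving it moves the
crossing-region gain within its estimation noise).  Monte-Carlo suites use 100–500 replicates as
stated per test.  Closed-form oracles are asserted at 1–2%
(discretization-limited), exact identities at 1e-9–1e-12.  All randomness
flows from explicit integer seeds; fixed seeds reproduce results
bit-for-bit.

## Known limitations

* Channel kinetics are a documented stand-in; absolute onset-rapidity
  values (≈5–18 /ms across the family) sit below the fastest experimental
  phase-plane slopes, though all comparative statements are unaffected.
* In the compartmental models, somatic peak dV/dt and onset rapidity move
  in opposite directions across cell sizes (a larger dendritic load speeds
  the AP foot but slows the somatic peak), so the strong positive
  rise-speed/onset-rapidity correlation holds across neurons of varying AP
  speed, not across dendritic sizes at fixed kinetics.
* The cutoff estimator inherits the spec's "highest crossing" definition,
  which is noise-sensitive when the normalized curve plateaus near
  threshold; the F0 oversampling and long per-point integrations mitigate
  but do not remove this.
* No synapses, calcium dynamics, ion accumulation or axonal propagation;
  the myelinated section is a passive load ending in a sealed tip.
* The IQ = 100 split convention and the bin-level 20–40 Hz aggregation are
  documented conventions where the underlying protocol is ambiguous.
* Truncation-artefact screening of reconstructions is an expert judgement
  upstream of this package; no algorithmic filter is provided.
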