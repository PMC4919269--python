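# Methods

## Scope and model

`renalpet` quantifies dynamic PET of a renally excreted, non-metabolised
organic-cation tracer. All activity concentrations are decay-corrected to
injection time, so radioactive decay appears nowhere in the kinetics. The
tissue model is the one-tissue compartment model (1TCM),

    dC_T/dt = K1 · C_p(t) − k2 · C_T(t),

with influx K1 and backflux k2 in min⁻¹ and the plasma curve C_p
approximated by a heart image-derived input function (IDIF). No
blood-volume fraction term is included — the two-parameter model is a
deliberate fidelity choice, and the scalar `idif_dilution` factor is the
only partial-volume mechanism. Total body clearance is
TBC = ID / AUC(0–90 min) with ID the injected dose per kg body weight;
because the tracer is cleared exclusively via plasma, the IDIF AUC fully
determines it.

## Synthetic cohort generator

The generator emulates what the scanner and study design produce at the
time-activity-curve level; it is the ground-truth source for every
recovery test.

**Frame schedule.** 33 frames spanning 5400 s: 10×6 s, 8×30 s, 5×60 s,
4×300 s, 6×600 s. Only the frame count and total duration are anchored to
the study design; the progression is the usual geometric densification
around the bolus. Any schedule can be supplied as a CSV of
`frame_start_s, frame_duration_s`.

**Input function.** C_p is a delayed tri-exponential (delay t0 = 0.1 min).
The control curve uses amplitudes (−480, 400, 80) kBq/mL with rate
constants (8, 0.8, 0.02) min⁻¹: the fast negative term is a wash-in so the
bolus rises continuously from zero (an instantaneous-jump bolus is neither
physiological nor resolvable from 6-s frame averages), the 0.8 min⁻¹
phase is distribution, and the 0.02 min⁻¹ tail is clearance-limited
washout. Absolute magnitudes are calibrated only to put the control TBC
near 80 mL/min/kg, a realistic value for a renally excreted organic
cation in the mouse; no measured curve is published for this design, so
only group *ratios* are meaningful.

**Group presets.** Control/WT kinetics are K1 = 0.80 min⁻¹,
k2 = 0.15 min⁻¹. The CKD transgenic preset divides K1 by 2.2 and scales
the plasma curve by 1.8; OCT1/2-KO and cimetidine divide K1 by 3.0 and
2.5 with plasma scales 3.0 and 2.5; pyrimethamine keeps control K1 with
plasma scale 1/1.1. k2 is shared across groups. Because TBC is dose over
input AUC, a preset's TBC fold-change versus control equals its plasma
scale *by construction* — the generator encodes the designed effect sizes
exactly, and recovery tests measure how well the analysis chain returns
them. Default group sizes: WT 5, Tg 8, control 5, KO 4, cimetidine 5,
pyrimethamine 4.

**Subjects.** Body weight ~ Normal(25 g, 2 g) truncated at 15 g; injected
dose ~ Normal(7.7 MBq, 1 MBq) truncated at 1 MBq (the dose spread is kept
narrower than a typical reported ±4 MBq so all subjects sit in one noise
regime; both are configurable). Each subject's plasma amplitude scales
with (ID/7.7 MBq)/(BW/25 g) — dose per distribution volume — which makes
TBC automatically invariant to jointly scaling dose and input amplitude
and keeps the noiseless TBC fold-changes exact even with subject
variability.

**Noise.** Frame value i receives Gaussian noise with
σᵢ = noise_scale · sqrt(max(valueᵢ, 0.01 kBq/mL) / durationᵢ[s]), clipped
at zero — variance inversely proportional to frame duration emulates
count statistics in reconstructed frames. The default noise_scale is 1.0,
giving roughly 2 % relative noise at the bolus peak (6-s frames) and ~1 %
on the late 600-s frames. Per-subject random substreams are derived from
(seed, CRC-32 of subject id), so adding a subject never perturbs the
others.

**What is not emulated.** No sinograms, attenuation, scatter, randoms,
reconstruction, motion, or spill-over between organs; noise is applied at
the TAC (or voxel) level and is Gaussian, not Poisson; the IDIF bias
mechanism is a single scalar dilution. Passing recovery tests therefore
demonstrates correctness of the analysis chain under the stated noise
model, not robustness to reconstruction artefacts in real scans.

## Phantom imaging layer

The 4D phantom (default 64×64×96 voxels, 0.4 mm isotropic) paints each
organ's TAC into a labelled geometry: ellipsoidal heart and liver,
crescent ("half-moon") renal cortices built as a sphere minus a medially
offset sphere, and a spherical bladder carrying the cumulative excretion
curve (monotone by construction). Organ overlap is a validation error.
The IDIF procedure averages all frames whose full window lies within the
first 20 s (avoiding partial-frame weighting ambiguity), ranks axial
slices by mean early intensity (mean, not max — the choice is not
determined by the source design), keeps the top six, and places a filled
15-pixel circle on each slice's intensity-weighted centroid; the circle
may be clipped at the image edge with a warning. For a homogeneous heart
with fully interior circles, the IDIF equals the heart curve exactly, so
the imaging layer adds no bias and the phantom and TAC-only pipeline
paths agree on noiseless data.

## Numerical choices

**Forward model from sampled input.** Fitting needs C_p between frame
samples. The running integral of the input is known *exactly* at frame
edges (frame mean × duration, summed); a monotone cubic (PCHIP) through
these points, differentiated, yields a smooth non-negative curve whose
frame means reproduce the measured TAC identically. This reconstruction
resolves the bolus far better than interpolating frame means at
midpoints. The convolution with e^(−k2 t) is advanced on a fine grid
(default 0.25 s) with the exact update for a linear input segment — a
first-order recursion evaluated as an IIR filter — and predictions are
frame-averaged via the cumulative trapezoid. The only discretisation
error is the sampling of the reconstructed input; halving the grid step
changes predictions by well under 0.1 %.

**Fitting.** Unweighted least squares over all frames (frame-duration
weighting available behind a flag, off by default, since no weighting
scheme is canonical here). Initial values (K1, k2) = (0.1, 0.1); bounds
K1 ∈ [10⁻⁴, 10] min⁻¹, k2 ∈ [0, 5] min⁻¹; trust-region-reflective least
squares (the bounded analogue of Levenberg–Marquardt) with
ftol = xtol = gtol = 10⁻¹⁰. Standard errors come from the Jacobian at the
optimum (σ² (JᵀJ)⁻¹ with σ² = RSS/(n−2)). Non-convergence and optimizer
failures are reported through flags, never raised.

**Exclusion policy.** A fit is non-physiological if it did not converge,
K1 or k2 sits at/outside [10⁻⁴, 10] resp. (0, 5) min⁻¹ (with relative
1e-6 slack because interior-point optimizers stop fractionally inside the
box), or se(K1)/K1 > 2 (unidentifiable). These windows are reporting
policy — labelled as such in outputs — not biology. A subject is excluded
from group statistics if either kidney's fit is flagged; excluded
subjects remain in the subject table.

**Integrals.** TAC integrals use the frame-rectangle rule (value ×
window overlap): frame values are time-averages, so this reconstructs the
integral of the underlying curve exactly and is refinement-invariant.
AUC runs to 90.0 min exactly. The Logan plot regresses
∫C_T/C_T on ∫C_p/C_T over frames with midpoint ≥ t* (default 20 min),
with integrals taken to frame midpoints by the same rule; at least three
points and strictly positive tissue values are required.

**Statistics.** The Lilliefors-corrected KS normality P value is Monte
Carlo (default 10 000 simulated null samples, each re-standardised;
P = (1 + #{D ≥ D_obs})/(n_mc + 1)), seeded, so any sample size is
supported reproducibly. Both groups must pass at α = 0.05 for the
pooled-variance Student's t test (Welch behind a flag); otherwise
Mann-Whitney — exact by full enumeration of label assignments (midranks
for ties) up to combined n = 12, tie-corrected normal approximation
beyond. Significance is P < 0.05 with no multiple-testing correction,
matching common bench practice. Groups too small or too degenerate for
the normality screen fall back to the rank test.

**Determinism.** Every random draw flows from the configured seed; report
CSVs are byte-identical across runs of the same configuration. Statistics
seeds are derived from the study seed at fixed offsets.

## Problem sizes

Default analyses fit 2 kidneys × 31 subjects in a few seconds (one fit
≈ 40 ms at the 0.25-s grid). The recovery studies in the test suite use
100 single-subject replicates for fit bias and 2000 replicates for the
type-I-error calibration of the gated comparison (with the normality
Monte Carlo reduced to 400 draws per test, which leaves the validity of
the Monte-Carlo P value unchanged). The phantom tests run on a reduced
40×40×64 grid; the default grid is exercised by the imaging layer in
phantom-mode pipeline runs.

## Limitations

- Absolute K1, k2, V_T, TBC and input-curve magnitudes are generator
  conventions; only ratios across groups are anchored to the study design.
- The Gaussian, frame-duration-scaled noise model ignores the full PET
  covariance structure (reconstruction correlations, randoms/scatter).
- The IDIF is used as-is as the plasma input: no whole-blood-to-plasma
  ratio, no metabolite correction (appropriate for a non-metabolised
  tracer), and partial-volume effects reduce to one scalar.
- The exclusion thresholds are pragmatic policy; real studies should
  justify their own windows.
- TBC-vs-K1 correlations within simulated groups are driven by the noise
  and dosimetry model, not by a physiological coupling between renal
  uptake and whole-body exposure; the generator does not attempt to
  reproduce observed correlation strengths.
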