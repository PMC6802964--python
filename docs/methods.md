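# Methods

This note documents the models behind `endotrace`, the reasoning behind
the default parameters, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Event model and trace analysis

An endocytic accumulation event is modelled as a trapezoid in molecule
number: linear assembly at rate `rise_rate` (molecules/s) to
`peak_molecules`, a plateau of `plateau_duration` seconds, and linear
disassembly at `fall_rate`. Events that end by vesicle scission instead
terminate with the loss of the whole population within one frame
(`scission_mode="abrupt"`), the signature of the labelled vesicle
leaving the evanescent TIRF field.

Timing is measured exactly as in the classic ramp-intercept procedure:
least-squares lines are fitted in every contiguous 60-sample window
(3 s at the 20-fps default); the maximum-gradient window defines the
rising line and the minimum-gradient window the falling line, ties going
to the earliest window; `T_start`/`T_end` are their intercepts with zero
intensity (background correction re-zeroes the baseline, so "baseline
intensity" is exactly zero by construction; a nonzero robust baseline
can be configured for real data). The amplitude `A_av` averages the
half-open window `[T_start + 5 s, T_start + 8 s)` — 60 samples at
20 fps — truncated and flagged for shorter events.

Properties worth knowing:

* **Exactness on long ramps.** For noiseless trapezoids whose rise and
  fall phases are at least as long as the 3-s fitting window, `T_dur` is
  recovered to within one frame (tested for rise times 3–10 s).
* **Short-ramp bias.** When a flank is *shorter* than the window the
  fitted line necessarily spans the trapezoid corners, the gradient is
  underestimated and the intercept moves outward: `T_dur` is
  overestimated by ≈0.18 s for a 2-s flank and ≈0.55 s for a 1-s flank
  (noiseless values). This is a property of the fixed-window method
  itself, not of the implementation; it contributes a small (≈ +0.2 s)
  positive bias to the Cam1 condition, whose flanks are ~2.3 s.
* **Scale and offset invariance.** Timing depends only on ratios, so
  rescaling the intensity axis leaves all times unchanged.

Scission is detected as the first transition from above 50% of the
plateau amplitude to below 20% of it within 0.5 s. The thresholds are
configuration options; 0.5 s cleanly separates single-frame vesicle
departure from the fastest gradual disassembly in the study conditions
(a 45-molecule event falling at 14 molecules/s crosses the same band in
≈0.96 s, so a 1-s window would misclassify it).

Averaged profiles align traces on a chosen anchor (`T_start`, `T_end`,
or an externally supplied time such as the co-imaged channel's
`T_start`) by nearest-frame shifting — no interpolation, since anchors
are frame-quantised — and report per-point mean, SEM and n, plus the
mean duration for profile reconstruction.

## Molecule counting

The 5×5-pixel core captures only part of a diffraction-limited spot
(the Gaussian mass inside the window is 92.7% at the default
σ = 0.12 µm = 1.2 px), and the background annulus catches most of the
spilled tail, so background-corrected amplitudes carry a net capture
factor of ≈0.915. Counting is therefore *ratiometric*: single-molecule
calibration intensities are measured with the same 5×5-minus-annulus
geometry, so the capture factor cancels in
`molecules = A_av / (I₁ · excitation_scale)`. The excitation scale
defaults to 0.2 — events are imaged at 20% of the laser power used for
single-molecule calibration, assuming linear excitation — and is
explicitly configurable.

The calibration statistic is the median of per-track mean intensities
(robust against double occupancy and mis-links). In movie pipelines, an
ROI only contributes to molecule counts when both ramp fits have
r² ≥ 0.5: spurious detections from projection noise fail this gate, the
automated counterpart of excluding unanalysable traces by hand.

## Detection and tracking

Endocytic sites: per-pixel temporal standard deviation (sample SD,
ddof = 1) over the whole movie; local maxima above
`median + 6·MAD` with non-maximum suppression at 1 µm. Sites closer
than the 1.5-µm background diameter are flagged overlap-contaminated
and excluded from analyses by default. The thresholds are robust-scale
units because absolute intensities are instrument-specific; k = 6 keeps
false positives below one per 50×50-px field of pure noise.

Single molecules: detection runs on a Gaussian-smoothed copy of each
frame (matched filter at the PSF scale) with the same robust threshold
idea; positions are refined by centre of mass of the raw 5×5
neighbourhood (a slight inward shrinkage of sub-pixel displacements is
visible as a few-percent underestimate of D — see limitations).
Linking is greedy mutual-nearest-neighbour within 0.3 µm/frame
(≈5× the expected RMS step for D = 0.03 µm²/s at 63 fps) with
single-frame gap bridging; any ambiguity (two tracks competing for one
detection, or two candidates for one track) terminates the tracks
involved rather than guessing.

Track duration uses the presence-time convention
`n_frames × frame_interval`. The off-rate is the maximum-likelihood
exponential rate for left-truncated dwells (durations below
`min_duration`, default 2 frames, are excluded). For frame-quantised
durations the excess over the truncation point is geometric, and the
geometric MLE `k = −ln(1 − 1/(1 + m̄))/Δt` (m̄ = mean excess in frames)
is used; it converges to the continuous form `1/(mean − min_duration)`
as Δt → 0 and removes a ≈+6% bias at 8-frame mean dwells. Off-rate
estimation excludes tracks within 1 µm of the field edge, whose dwells
are censored by the measurable region rather than by unbinding.

Diffusion comes from the ensemble MSD over the first 4 lags
(consecutive-frame pairs only), fitted with a count-weighted straight
line whose free intercept absorbs static localisation noise (≈4σ²_loc);
`D = slope/4` for 2-D motion.

## Binding models

The sequential two-site scheme is structural: with free-ligand
concentration L, the reporter partition function is
`Z = 1 + L/K1 + L²/(K1·K2)`, so IQ2 occupancy requires IQ1 occupancy by
construction. Observables are `F = F0 + dF1·f1 + dF2·f2` with
`f1 = (L/K1 + L²/K1K2)/Z` (at least one site bound) and
`f2 = (L²/K1K2)/Z` (both bound). Because titrations run at reporter
concentrations comparable to K1, free ligand is recovered from total by
Brent root-finding on the strictly increasing mass-balance function
(relative tolerance 1e−10); the one-site model is the K2 → ∞ limit.

Fitting is weighted least squares (weights 1/|y|, floored at 5% of the
maximum — fluorimeter noise scales with signal), with dissociation
constants parameterised in log10, 32 log-uniform multistarts, amplitude
bounds of twice the observed span, and a Kd search capped at 10× the
titrated range (constants far above the range are not measurable). When
the fitted K1 is tighter than a fifth of the reporter concentration it
is reported as an upper bound (`K1 < reporter_total`): at
stoichiometric conditions the data say only "tight". Residual-bootstrap
confidence intervals are available.

Calcium dependence is phenomenological (Hill in pCa) because only
midpoint/steepness information is available at this level; the
transition direction is inferred from the data and a fit whose midpoint
falls outside the titrated range is rejected as non-bracketing. FRET
efficiency/distance conversion uses the CyPet–YPet Förster radius
5.301 nm by default.

**Identifiability caveat.** At the default simulated design — a single
12-point, 0–10 µM curve at 0.5 µM reporter with 2% multiplicative
noise — the weaker-site constant K2 is weakly identified: its
Cramér–Rao bound is ≈23% of the true value (the curve reaches only
~93% saturation of the second site, and K2 trades off against the
amplitude split). Single-curve K2 estimates therefore scatter by
±20–45% across noise realisations even though the fitter reliably finds
the global optimum (verified against truth-started refits). Precise K2
determination needs replicate curves or a wider concentration range;
the pCa midpoint, by contrast, is recovered to ±0.02 units under the
same noise.

## Transient kinetics

Multi-exponential fits use variable projection: for any candidate rate
set the amplitudes and offset are solved exactly by linear least
squares, and the nonlinear search runs only over log-rates
(Levenberg–Marquardt, 16 multistarts log-spaced/log-uniform between
0.5/t_max and 2/t_min). Rates are reported strictly descending;
amplitude signs are unconstrained (indicator signals may rise or fall).
Phase count: fit n = 1…4, recommend the smallest n not rejected against
n+1 by an extra-sum-of-squares F-test at α = 0.01, with AIC tabulated
alongside. Rate pairs closer than a factor of ~2 are not reliably
separable at realistic noise — the test suite asserts this as a
negative control. The bundled calcium-release record uses a split time
base (10 kHz to 60 ms, then 400 Hz to 2.5 s), mimicking stopped-flow
split-timebase acquisition, so a single record resolves both a
137 s⁻¹ and a 2 s⁻¹ phase and covers ≥5/k_slow.

## Synthetic data: what is and is not emulated

Movies render every fluorophore population as a pixel-integrated
isotropic 2-D Gaussian PSF (σ 0.12 µm ≈ the diffraction limit at
510 nm/NA 1.45) on a uniform (optionally planar-gradient) baseline,
with Poisson shot noise on expected counts and additive Gaussian read
noise — the standard EMCCD approximation. Endocytic sites are immobile;
single molecules arrive as a spatial Poisson process, diffuse with a
fixed D and unbind exponentially. Camera defaults: 0.1 µm pixels (so
the 0.5-µm ROI is 5×5 px), 20 fps for endocytosis scenes, 63 fps for
single-molecule scenes; single-molecule scenes use a lower background
(baseline 30 AU, read noise 4 AU vs 100/10) reflecting their shorter
exposures and TIRF sectioning — with patch-scene background a single
fluorophore (peak pixel ≈27 AU) would be undetectable, contrary to the
imaging the generator emulates.

Not emulated: axial optics and evanescent-decay intensity gradients
(presence is binary), astigmatism, camera gain registers and EM excess
noise, photobleaching separate from unbinding, drift, cell boundaries
and cytosolic autofluorescence structure. Consequently, passing tests
demonstrate correctness of the analysis given the stated image model;
they do not certify performance on data whose noise or background
violates it (notably, EM excess noise roughly doubles shot variance,
and evanescent-field decay converts axial motion into intensity
fluctuations that the scission detector could misread).

Trace-level generators produce background-corrected traces directly
(baseline zero, shot noise including the subtracted-baseline
contribution of a 25-pixel core), bypassing rendering; movie-derived
and trace-level signals agree to the analytic capture factor above.

## Preset calibration

Presets are data (`sim/presets.yaml`), calibrated so that the full
pipeline recovers the study's reported summary statistics from
simulated data at the reported sample sizes:

* **myo1** — rise 13 mol/s, peak 45, fall 14 mol/s (reported values);
  plateau 7.10 s so the mean trapezoid duration equals the reported
  mean T_dur of 13.84 s (the reported "~6 s" plateau together with the
  other three values would imply 12.68 s and is the less precise
  statement). Event-to-event variability (peak CV 0.25, plateau SD
  2.2 s, rate CV 0.10) reproduces the reported SEM of 0.39 s at n = 50.
* **cam1** — peak 90 (twice Myo1), true T_dur 10.99 s, SEM 0.21 at
  n = 52; rates 38/40 mol/s chosen (they are not reported per event) so
  the plateau extends past the fixed 5–8-s amplitude window — slower
  rates would make the window truncate A_av and the reported duration
  and ~90-molecule plateau could not both be recovered.
* **myo1_S742A** — Myo1 rates and peak, plateau 5.56 s → T_dur 12.3 s,
  SEM 0.31 at n = 67.
* **cam2** — steady rise (5 mol/s) to 30 molecules, abrupt scission at
  11.4 ± 1.5 s after the event start; two-colour pairs co-start with a
  Cam1-kinetics channel so the scission offset is measured against the
  Cam1 ramp intercept.
* **single_molecule** — off-rate 7.8 s⁻¹, D 0.03 µm²/s, arrival density
  0.075 µm⁻²s⁻¹ (sparse enough that linking ambiguities are rare).
* **cam1_titration / cam2_titration** — K1 0.05 µM (below the 0.1 µM
  reporting bound), K2 0.68 / 1.10 µM, amplitude splits 50/50 and
  30/70, F0 = 10 AU on the instrument scale implied by the ~46 AU total
  amplitudes, 2% multiplicative noise.
* **pca_titration** — pCa50 5.87, Hill n = 2 (typical for a
  two-EF-hand lobe; the steepness is not otherwise constrained).
* **ca_release** — three phases of equal amplitude at 137, 12.9 and
  2.0 s⁻¹.

## Problem sizes used in tests and the acceptance script

Event-duration statistics use the reported ns (50/52/67 traces;
65 two-colour pairs). Molecule-count scenes use 48 events per movie —
enough that sampling error (≈3.6%) is comfortably inside the 10%
comparison — with events on a 4-µm grid plus sub-pixel jitter (real
sites are not pixel-aligned, and the calibration scene samples
sub-pixel positions uniformly). The single-molecule scene is
20 × 20 µm for 20 s (≈350–400 usable dwells, ≈250 tracks for the MSD).
These sizes are the package's defaults for a desk-scale reproduction;
all are parameters of the pipeline functions.

## Known limitations

* Centre-of-mass localisation in a truncated 5×5 window shrinks
  sub-pixel displacements slightly; the recovered D runs ≈3–5% low.
  A Gaussian-fit localiser would remove this at some speed cost.
* The fixed 60-point ramp window biases T_dur upward for flanks shorter
  than 3 s (see above).
* Single-curve K2 estimates from the default titration design are
  information-limited (see the identifiability caveat).
* The linker's terminate-on-ambiguity policy slightly shortens dwell
  estimates in dense scenes; at the default arrival density the effect
  is negligible.
* No photobleaching term: single-molecule disappearance is entirely
  unbinding, so calibration intensities have no within-track decay.
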