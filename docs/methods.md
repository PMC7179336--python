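# Methods

This note documents the estimators, the synthetic-data model, the
numerical choices, and what the validation suite does and does not show.

## Signal path

Recordings are channels × samples matrices in microvolts at 250 Hz
(19-channel 10–20 montage by default). Event tables cut each recording
into per-condition fragments; epochs are half-open sample slices
`[round(onset·fs), round(onset·fs) + round(dur·fs))` with
round-half-to-even, so segmentation is exhaustive, non-overlapping and
platform-stable. Every epoch is processed independently and per-channel
feature values are averaged across a condition's surviving epochs;
concatenating epochs instead would create phase discontinuities that
bias the Hilbert- and FFT-based estimators (a concatenated mode is
deliberately not offered for that reason).

### Filtering

Three Butterworth band-passes: wideband 1.6–30 Hz (acquisition band;
Hjorth, wideband envelope, PSD), 2–20 Hz (fractal dimension), 8–13 Hz
(alpha envelope). Nominal order 12, applied zero-phase as a
forward–backward pass of an order-6 design in second-order sections, so
the magnitude roll-off is that of the full order while the phase is
identically zero — the feature estimators are waveform-sensitive and a
causal pass would distort them. A causal mode (single pass of the full
order) is available via `FeatureParams(filter_mode="causal")`.

Finite-length zero-phase filtering leaves boundary transients: the 2 Hz
high-pass poles ring for roughly 1–2 s at each end of a record. These
transients sit inside the signal (they originate at the boundary itself,
so padding cannot remove them) and are the reason the envelope carries a
0.5-s edge trim and the stopband-attenuation check is evaluated on the
steady-state interior.

### Artifact screening

Manual artifact editing is not reproducible, so the pipeline uses a
deterministic stand-in: an epoch is discarded if any channel of the
wideband-filtered signal exceeds a peak amplitude threshold (default
100 µV, configurable). Decisions are logged; a condition whose epochs
are all rejected yields an empty table with a warning, and downstream
paired analyses drop subjects missing one side of a pair.

## Feature estimators

**Higuchi fractal dimension.** For k = 1..k_max and offsets m = 0..k−1,
the normalized curve length L_m(k) = Σ|y[m+ik] − y[m+(i−1)k]| ·
(n−1)/(n_m k) / k; FD is minus the least-squares slope of ln mean L(k)
on ln k. k_max defaults to 8 at 250 Hz — large enough that the log–log
fit spans a decade of lags on multi-second epochs, small enough that the
longest lag (32 ms) stays inside the 2–20 Hz band's correlation
structure. The estimator is exact for a line (FD = 1) and recovers
2 − H on fractional Brownian motion within ±0.1 for H ∈ [0.2, 0.8]
(validated against an exact circulant-embedding generator).

**Hjorth parameters.** The derivative is the unscaled per-sample first
difference. That convention makes the white-noise closed forms exact
(mobility √2, complexity √1.5) and leaves complexity invariant to the
sampling-rate scale factor; cross-implementation comparisons that use
a per-second derivative must rescale mobility by fs. Time-domain values
agree with periodogram spectral moments √(m2/m0) and √(m4·m0)/m2 within
1% for signals band-limited to 30 Hz at 250 Hz (the difference operator's
|2 sin(ω/2)| response deviates from ω by < 2.5% there).

**Envelope metrics.** The envelope is the magnitude of the analytic
signal (`scipy.signal.hilbert`), with 0.5 s trimmed per side before any
statistic. EMF is the amplitude-spectrum centroid of the mean-removed
envelope over (0, 12] Hz: "mean frequency" is not otherwise a unique
definition, and the centroid is the standard choice; DC must be removed
because the envelope mean is large and carries no instability
information; the 12 Hz cap keeps the measure in the physiologically
meaningful amplitude-modulation range (a peak-frequency mode is
available). A near-constant envelope (relative std < 0.02) has no
oscillatory energy: EMF is reported as 0 with a warning. RAT is the
envelope's coefficient of variation.

One regime subtlety: for an alpha-dominated signal, moderate added band
power acts on the envelope through cross-beating with the alpha carrier
(difference frequencies), so added 15–19 Hz power raises EMF; if a
4-Hz-wide band *dominates* the signal, its self-envelope fluctuates
below ~4 Hz and EMF falls toward that value regardless of the band's
center frequency. The group-level positive correlation between EMF and
fast-band power therefore rides on the between-group structure (slowed
groups have both low EMF and little fast power), and the signal-level
sign test is run in the alpha-dominated regime.

**PSD unit bins.** Welch estimate with 4-s Hann windows, 50% overlap,
constant detrend, density scaling; each unit bin is the Riemann sum of
the density over the half-open interval [b, b+1) Hz, b = 2..19, so the
bins sum to the in-band variance (Parseval) and a tone on the 0.25-Hz
grid keeps ≥ 95% of its power inside its own bin. Shorter windows were
rejected: with 2-s windows the 0.5-Hz grid puts one Hann leakage
coefficient exactly on the next unit-bin boundary and a mid-bin tone
loses 1/6 of its power across it.

## Synthetic cohort model

Each channel is the sum of

1. **1/f^γ colored Gaussian noise** (flat below 1 Hz), unit variance,
   scaled to a per-profile base RMS;
2. **band-limited noise components** realizing band-power elevations:
   a boost (lo, hi, g) adds independent band noise with variance
   (g−1) times the base's in-band variance (g < 1 attenuates the base's
   own band component instead);
3. a **shared amplitude-modulated alpha oscillation** — sinusoidal
   carrier (subject-jittered frequency), narrowband-noise modulator,
   weighted toward posterior electrodes (O1/O2 = 1.0 down to
   Fp1/Fp2 = 0.15).

Group profiles (defaults, each subject log-normally jittered):

| group | γ | boosts | alpha (amp µV @ O, freq, mod freq, depth) | base RMS |
|---|---|---|---|---|
| control, mTBI | 1.0 | — | 12, 10.5 Hz, 1.0 Hz, 0.5 | 10 |
| schizophrenia | 1.0 | 15–19 Hz ×2.5 | 9.5, 10.5 Hz, 2.0 Hz, 0.6 | 10 |
| stroke | 1.5 | 5–9.5 Hz ×50 | 6, 9.4 Hz, 0.8 Hz, 0.4 | 6 |
| coma | 2.5 | 2–5 Hz ×100 | 1, 10 Hz, 0.6 Hz, 0.3 | 2.5 |

The large slow-band gains are deliberate: pathological slow EEG is
nearly monomorphic, and only when the slow rhythm dominates the 1/f
tail does Hjorth complexity drop below the control value — a broadband
slow elevation over a shallow tail *raises* complexity. mTBI equals
control because no resting feature separates the two populations.

Two per-subject latent traits scale 3–8 Hz and 15–19 Hz power by
exp(0.5·z) in every group; they are negatively correlated (ρ = −0.5),
modelling a single "diffuse slowing" axis (slow power up, fast power
down). These latents create the cross-subject spectral variability
behind the PSD×feature correlation maps, and ratings couple to them:
irritation loads +0.6 on the standardized slowing score, empathy and
arousal on its negation (+0.6 / +0.5). Ratings are truncated Gaussians
on each scale's range (pleasantness −5..5, others 0..10) with
per-stimulus offsets; comatose subjects give no ratings. Stimulus-locked
effects are band-power elevations applied inside event windows with a
short Tukey taper (default set: a fast-band elevation during "crying"
for controls, slow-band elevations during coughing/vomiting for mTBI and
barking for coma, a fast-band elevation during birdsong for
schizophrenia).

All magnitudes were set once so that the clinical contrasts are
statistically detectable at study-scale group sizes, which is the
simulator's purpose; they are not estimates of patient effect sizes.
Everything is driven by one `SeedSequence`: identical specs (including
the seed) give byte-identical files, and adding a subject never perturbs
another subject's stream.

**What the simulator does not emulate:** dipole/forward-model
topography, ocular and muscle artifacts, evoked-potential morphology,
non-stationarity beyond alpha amplitude modulation, inter-channel
correlation beyond the shared alpha component, and realistic absolute
amplitudes for pathological slow waves (kept below the artifact
threshold by design). Passing tests therefore demonstrate that the
pipeline recovers the statistical structure it assumes, not that it is
robust to every property of real patient EEG.

## Statistics

Resting group contrasts are per-(feature, channel) one-way ANOVAs —
consistent with a five-level group factor and F(4, ·) reporting — with
Bonferroni correction across the 19-channel family within each feature
(the family scope follows the per-feature channel-list style of
reporting; "significant" means adjusted p ≤ α, α = 0.05). Tukey HSD
post-hoc runs only on significant omnibus tests. Stimulation-vs-rest is
a paired t-test per channel against the eyes-closed rest baseline, with
a Wilcoxon signed-rank fallback below n = 8 and signs reported as
"+" = higher in rest. Correlation maps use Pearson r; the default
observation unit is the (subject × condition) cell with channel-averaged
values (a per-channel pooling mode exists), masked at p < 0.05 and
|r| > 0.35. Rating correlations are computed within group × stimulus
strata over subjects.

Calibration: under a simulated null (i.i.d. Gaussian feature values,
five groups of eight), the family-wise rejection rate of the
Bonferroni-corrected channel family over 1000 repetitions stays at or
below the nominal α = 0.05 within Monte-Carlo error.

## Problem sizes used in validation

The full study design (seven 30-s stimuli × 8 presentations plus two
2-min rests, 19 channels, 141 subjects) is supported but not exercised
wholesale; the validation suite uses scaled cohorts chosen as the
smallest sizes at which the qualitative contrasts are stable:
10 subjects/group with 40-s rest fragments for the end-to-end resting
signature, 20–30 subjects for paired-contrast and rating-coupling
recovery, 50 seeds × 5000 samples for fractal-dimension recovery, and
1000 repetitions for the type-I calibration. The sign patterns being
checked are scale-free; only their statistical margins grow with n.

## Known limitations

- EDF support is classic 16-bit EDF with 1-s records and integer-Hz
  sampling; BDF and proprietary vendor formats are out of scope.
- The envelope mean frequency is one of several defensible readings of
  "average frequency of the envelope"; comparisons with other software
  should check the definition (centroid vs peak, cap, detrending).
- The FD band (2–20 Hz) and Hjorth/envelope band (1.6–30 Hz) differ by
  design, following the feature definitions as used in practice.
- Schizophrenia's elevated alpha-band envelope frequency (EMFA) is
  emulated only weakly (via faster alpha modulation); alpha-band-noise
  dominated profiles (coma) show high EMFA for a different reason
  (Rayleigh envelope fluctuations), so EMFA group contrasts beyond the
  frontal control/schizophrenia comparison should not be over-read.
- Bonferroni is the only multiplicity scheme offered (by design); no
  mixed-effects or cluster-permutation alternatives.
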