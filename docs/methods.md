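# Methods

This note records the models, conventions, parameter choices and known
limitations behind `spikefield`, in the order data flows through the
package.

## Session model and segment selection

A session holds 1 kHz LFP channels (acquisition band 0.5–200 Hz), sorted
spike trains (timestamps in seconds; 20 kHz waveform snippets), and
behavioural-state annotations. All times are seconds from recording start;
intervals are half-open `[start, start + duration)`. The on-disk container
is HDF5 with a documented layout (`/lfp`, `/units`, `/states`, `/meta`);
round trips are bit-exact.

Per neuron and state, six analysis segments are drawn at random: rest
segments are fixed 10-s windows, locomotion segments are whole annotated
bouts. Selection samples without replacement from a tiling of the rest
intervals, which guarantees non-overlap by construction and makes the draw
a pure function of the seed. Whether overlapping segments should be allowed
is a genuinely open design point; we forbid overlap so segment values are
not artificially correlated. The neuron-level value of any measure is the
arithmetic mean over its segments; segments without a value (Rayleigh-gated
out, or too few spikes for SFC equalisation) are skipped, and a neuron with
no surviving segment is excluded from group statistics. The choice to
average over *surviving* segments only (rather than requiring all six) is
ours and is logged per unit in the tidy output's `note` column.

## Multitaper spectral core

DPSS tapers are unit-energy and concentration-ordered; taper counts follow
K = 2·NW − 1, so the two parameter sets used downstream — (NW = 5, K = 9)
for coherence and (NW = 3, K = 5) for spike-triggered spectra — are
instances of one rule. PSDs average eigenspectra with uniform weights
(adaptive weighting is deliberately not the default) and fold two-sided
power to one-sided so the PSD integrates to the signal variance. FFT length
equals the window length (no zero padding), giving 2 Hz resolution for
0.5-s windows at 1 kHz.

Band-pass filtering is a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`). Zero phase is mandatory: the downstream phase convention
(peak = 0) would be biased by any group delay. The effective 8th-order
magnitude response gives ≥ 40 dB attenuation one octave outside a band
edge but only partial rejection just across an edge (e.g. a 10 Hz tone
leaks ~19 % amplitude into beta); the half-open band intervals
[low, high) ensure shared edges belong to exactly one band when averaging.

## Coherence

The spike train enters as a mean-centred binned count series at the LFP
rate (floor convention, half-open 1-ms bins) — a deliberate simplification
that pairs the two signals on one time grid without point-process
corrections. Cross- and auto-spectra are pooled over all (window, taper)
pairs *before* the modulus, giving an estimator with 9 × n_windows degrees
of freedom; its band summary is the mean over in-band grid frequencies (a
peak option exists). Zero-variance inputs produce missing values with a
warning, never coherence 0, because "no spikes" is an absence of evidence,
not evidence of independence. Segments shorter than one window are
rejected.

## Spike-field coherence

fSTA and STP use *identical* spectral settings (NW = 3, K = 5, 500-sample
Welch sub-windows at 50 % overlap — three sub-windows per ±500 ms trace);
any asymmetry would break the SFC ≤ 100 % bound, which is the averaging
inequality |mean of spectra of traces| ≥ spectrum of mean trace. The Welch
sub-window length is the one SFC parameter not fixed by the reference
protocol; 500 samples matches the coherence module's 0.5-s resolution.
Spikes whose window would cross a recording edge are excluded *before* the
spike-count equalisation, so exactly 50 (rest) or 20 (locomotion) spikes
contribute when enough exist; otherwise the segment is marked insufficient
rather than analysed with an unequal count, since SFC's bias depends on
spike count. Subsampling uses a dedicated per-(unit, segment) seeded
stream.

## Phase-locking

Phase extraction is zero-phase band-pass followed by the analytic-signal
angle, which realises the stated convention exactly: peak ↦ 0, trough ↦ ±π,
ascending zero crossing ↦ −π/2. Spike phases are linearly interpolated on
the unwrapped phase (the ±π seam produces no spurious midpoints). The
Rayleigh p-value uses the standard small-sample-corrected exponential
approximation, p = exp(√(1+4n+4(n²−R²)) − (1+2n)); the gate is applied per
segment (p < 0.05), matching the protocol's wording, and gated-out segments
contribute nothing to the neuron mean. Note the Rayleigh test assumes
independent angles; successive spike phases are serially correlated through
the narrowband LFP autocorrelation, so the realised null gate rate runs
slightly above the nominal 5 % (measured ≈ 7.5 % on synthetic nulls) —
a property of the statistic, not a defect of the implementation. Rose
histograms default to 20 equal bins of (−π, π].

## Unit cleaning and classification

Cleaning drops every spike whose interval to its immediate predecessor is
below 2 ms (one pass over the original ISIs, so a burst keeps only its
first spike; the rule is idempotent) and flags cross-channel artifacts when
≥ 70 % of other channels fire within ±0.5 ms. A unit is kept only if its
SNR — mean peak-to-trough amplitude over twice the noise RMS — strictly
exceeds 2. Waveform sorting is PCA to 3 components then seeded k-means
(≥ 10 restarts); cluster distinctness is checked by one-way MANOVA (Wilks'
lambda F approximation, p < 0.05) over the PC scores.

Type A/B assignment is data-driven: 2-means on standardised
(trough-to-peak, log firing rate) across a session's units, the
shorter-duration cluster labelled A. Because 2-means will force a split
even when a cohort contains one class, both cluster mean durations are
compared against the 0.4 ms fallback boundary; if they fall on the same
side the cohort is treated as homogeneous and gets a single label. A
single unit uses the 0.4 ms boundary directly. Trough-to-peak is measured
from the global trough to the subsequent maximum with parabolic sub-sample
refinement. Manual curation of borderline clusters is inherently
non-algorithmic; the per-unit report (duration, rate, SNR, cluster F, p)
is the package's substitute.

## Synthetic sessions

The generator's purpose is verifiability: every downstream claim is tested
against planted ground truth.

* **LFP**: each band component is Gaussian noise band-pass filtered into
  the band — not a sinusoid — so analytic phase is well-defined and
  non-degenerate; component RMS is amplitude/√2 (sinusoid-equivalent);
  default amplitudes fall from 40 µV (delta) to 10 µV (gamma) over a
  1/f^γ background (γ = 1, 15 µV), the standard shape of field-potential
  spectra.
* **Units**: Type A defaults to 12 spikes/s with gamma-renewal shape 1
  (Poisson-like, ISI CV ≈ 1) and a 0.25-ms trough-to-peak template; Type B
  to 4 spikes/s, shape 4 (regular), 0.60 ms. The exact rates are the
  package's choice (the reference study reports the contrast, not values);
  the template durations straddle any sensible classifier boundary.
* **Coupling**: the firing hazard is multiplied by
  exp(κ·cos(φ_b(t) − μ))/I₀(κ), where φ_b is the analytic phase of the
  *generated* band component — exact ground truth, not a re-filtered
  estimate. The I₀ normalisation keeps the realised rate within 15 % of
  nominal for κ ≤ 2. Spikes are drawn by time rescaling (gamma ISIs in
  operational time Λ(t) = ∫rate), which preserves the renewal structure
  under modulation; a hard 2-ms refractory period matches the cleaning
  rule. LFP and spike generation use independent streams spawned from the
  master seed, so identical configs are bit-reproducible and regenerating
  spikes never perturbs the field.
* **Group studies** scale each unit's κ per (unit type, state, band) by
  group-specific multipliers; true κ values are recorded in a ground-truth
  sidecar. Effect sizes are calibration knobs — the reference study prints
  F statistics, not effect sizes — so the defaults (base κ = 0.5, lesioned
  ×3) were chosen once to represent a clear but not saturating effect.

What the generator does *not* emulate: biophysical membrane dynamics,
cross-frequency or cross-unit correlations, non-stationary rhythms,
electrode drift, or sorting contamination. Passing tests therefore certify
the estimators and pipeline logic, not robustness to those real-data
features.

## Group statistics

One value per neuron (the segment mean) enters a one-way ANOVA
(df = (k−1, N−k)) with Tukey HSD post-hoc pairs (Tukey–Kramer for unequal
n); exactly two groups route to a two-tailed unpaired t-test. A KS
normality check per group is advisory only. No nesting correction for
units within sessions and no multiplicity control across bands or measures
is applied — this mirrors the per-band testing convention of the protocol
being reproduced and is a documented caveat, not an endorsement.

## Problem sizes and tolerances

The verification suite uses desk-scale problem sizes chosen as the
smallest that make each claim statistically decisive: 60–80-s sessions,
κ sweeps over {0, 0.5, 1, 2} × 10 seeds, 200 null gates for the Rayleigh
calibration, 100 cohorts of 40 units for classification recovery, and 20
replicate three-group studies of 30 units/group for the end-to-end
direction check. Analytic identities are asserted tightly (coherence
ceiling 1e−9, SFC ceiling 1e−6, resultant-length ceiling 1e−3 after
filtering and interpolation); Monte-Carlo quantities use intervals sized
to their replicate counts. Numerical edge cases are resolved explicitly:
zero-variance signals give missing values, zero STP gives NaN at that
frequency, a zero resultant leaves the mean angle undefined, and antipodal
angle pairs give R = 0 exactly.
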