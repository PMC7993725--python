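# spikefield

Spike–LFP synchronisation analysis for extracellular recordings: multitaper
coherence, spike-field coherence (SFC), and phase-locking between sorted
single units and local field potentials, together with the unit
classification and segment selection that feed them, a group-comparison
layer, and a synthetic session generator with ground-truth coupling.

The package targets the kind of study in which single-unit spikes and a
1 kHz LFP are recorded simultaneously from a deep-brain structure (e.g. the
pedunculopontine nucleus of rats in a dopamine-lesion model of Parkinson's
disease), units are split into electrophysiological classes — Type A
(narrow waveform, high irregular rate) and Type B (broad waveform, low
regular rate) — and spike–field coupling is compared across experimental
groups (control / lesioned / L-DOPA) in five frequency bands: delta
[1, 4) Hz, theta [4, 7), alpha [7, 12), beta [12, 30), gamma [30, 70).

## The three measures

For a spike train binned at the LFP rate, **coherence** is the segment- and
taper-pooled multitaper magnitude coherence

C(f) = |Σ S_xy(f)| / √(Σ S_xx(f) · Σ S_yy(f)) ∈ [0, 1],

estimated with 0.5-s windows stepped by 0.1 s, time-bandwidth NW = 5 and
K = 9 DPSS tapers.

**Spike-field coherence** is the ratio of the spectrum of the
spike-triggered average to the average spike-triggered power spectrum,

SFC(f) = 100 · fSTA(f) / STP(f) [%],

from unfiltered ±500 ms LFP windows around each spike (NW = 3, K = 5,
50 %-overlap Welch sub-windows), after equalising the spike count per
segment (50 at rest, 20 in locomotion). 100 % means every spike sees the
identical field trace; incoherent windows fall toward 100/n %.

**Phase-locking**: each spike is assigned the analytic phase of the
band-passed LFP (oscillation peak = 0, trough = ±π), the Rayleigh test
screens segments (only p < 0.05 contributes downstream), and the mean phase
angle and resultant vector length R ∈ [0, 1] summarise the locking.

Per neuron, each measure is the mean over six randomly selected 10-s rest
segments (or six locomotion bouts); groups are compared per band with
one-way ANOVA and Tukey's post-hoc test.

## Worked example

`examples/spike_field_metrics.py` simulates one unit coupled to the beta
rhythm (von Mises concentration κ = 2) and computes all three measures on a
60-s resting segment:

```
band    coherence   SFC(%)   resultant  Rayleigh p  gate
delta       0.024     1.78      0.044    2.70e-01  shut
theta       0.008     1.75      0.007    9.67e-01  shut
alpha       0.047     1.56      0.038    3.73e-01  shut
beta        0.283     4.21      0.591   3.11e-115  open
gamma       0.060     2.15      0.035    4.32e-01  shut
```

Only the coupled band shows elevated coherence (0.28 vs noise floors
≤ 0.06), SFC above the ~2 % incoherent floor for 50 spikes, and a large
resultant length that passes the Rayleigh gate. The other examples generate
and classify a mixed Type A/B session (`synthesize_and_classify.py`) and
detect a tripled lesioned-group beta coupling through the full pipeline and
ANOVA layer (`group_comparison.py`, omnibus `F (2,24) = 75.007`, Tukey
control-vs-lesioned p < 0.0001).

A thin CLI wraps the same functions:

```bash
spikefield synth --config cfg.yaml --out session.h5 --seed 42
spikefield analyze session.h5 --out-dir results --seed 1
spikefield stats results/neurons.csv --measure sfc --band beta
```

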