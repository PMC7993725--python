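"""Compute the three spike-LFP synchronisation measures for one unit.

The unit is coupled to the beta rhythm (von Mises concentration kappa = 2
at phase 0), so all three measures — multitaper coherence, spike-field
coherence (STA/STP ratio), and the Rayleigh-gated resultant length — should
single out the beta band.
"""

import spikefield as sf

config = sf.default_session_config(
    duration=80.0, n_type_a=1, n_type_b=0, kappa=2.0, coupled_band="beta",
    seed=11,
)
session, _ = sf.generate_session(config)
segment = sf.Segment(start=0.0, duration=60.0, state="rest", segment_id="demo")

coh = sf.coherence_for_unit_segment(session, "u00", segment)
sfc = sf.sfc_for_unit_segment(session, "u00", segment, rng=0)

print("band    coherence   SFC(%)   resultant  Rayleigh p  gate")
for band in sf.CANONICAL_BANDS:
    pl = sf.gated_phaselock(session, "u00", segment, band)
    print(f"{band:6s}  {coh.band_means[band]:9.3f}  {sfc.band_means[band]:7.2f}"
          f"   {pl.resultant_length:8.3f}  {pl.rayleigh_p:10.2e}  "
          f"{'open' if pl.passed_gate else 'shut'}")
print(f"\nSFC used {sfc.n_spikes_used} spikes (resting-state equalisation "
      "target); coherence pooled", coh.n_windows, "windows x 9 tapers.")
print("Only the coupled beta band passes the p < 0.05 Rayleigh gate with a "
      "large resultant; uncoupled bands stay at their noise floors.")
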