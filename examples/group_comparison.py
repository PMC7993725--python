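"""Detect an injected group effect with the full pipeline.

Simulates a three-group study (control / lesioned / L-DOPA) in which the
lesioned group's Type A resting beta coupling is tripled, runs the
spike-field coherence pipeline (6 random 10-s rest segments per neuron,
50-spike equalisation), and compares the neuron-level beta SFC across
groups with one-way ANOVA + Tukey.
"""

import spikefield as sf
from spikefield.pipeline import PipelineConfig, run_analysis

template = sf.default_session_config(
    duration=80.0, n_type_a=3, n_type_b=0, kappa=0.5, coupled_band="beta"
)
effects = {
    "control": {},
    "lesioned": {("A", "rest", "beta"): 3.0},
    "L-DOPA": {},
}
study = sf.generate_group_study(template, effects, n_per_group=3, seed=42)
sessions = {
    f"{group}-{i}": session
    for group, reps in study.items()
    for i, (session, _) in enumerate(reps)
}

result = run_analysis(sessions, PipelineConfig(measures=("sfc",), seed=1))
comp = next(
    c for c in result["comparisons"] if c.measure == "sfc" and c.band == "beta"
)
print("beta-band SFC, one value per neuron (mean over 6 segments):")
for group in ("control", "lesioned", "L-DOPA"):
    print(f"  {group:9s} {comp.group_means[group]:5.2f}% "
          f"+- {comp.group_sems[group]:.2f} (n = {comp.group_ns[group]})")
print("omnibus:", comp.format_f())
for (g1, g2), p in comp.pairwise_p.items():
    print(f"  Tukey {g1} vs {g2}: p = {p:.4f}")
print("\nThe tripled coupling in the lesioned group raises its SFC well "
      "above both other groups; the identical control and L-DOPA groups "
      "do not separate.")
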