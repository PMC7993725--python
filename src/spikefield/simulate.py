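"""Synthetic electrophysiology sessions with known spike-LFP coupling.

The generator emulates the statistical structure the analysis pipeline
assumes so that every stage can be verified against ground truth:

* **LFP** — five narrowband rhythms (delta/theta/alpha/beta/gamma) realised
  as Gaussian noise band-pass filtered into each band (so analytic phase is
  well defined and non-degenerate), superimposed on 1/f^gamma background
  noise.
* **Units** — two classes: Type A (narrow biphasic "V" waveform,
  trough-to-peak 0.25 ms, high irregular rate, default 12 spikes/s) and
  Type B (broad waveform, 0.60 ms, low regular rate, default 4 spikes/s).
  ISI regularity is the shape parameter of a gamma renewal process: shape 1
  reproduces Poisson firing, larger shapes give the concentrated ISI
  distribution of regular units.
* **Coupling** — the firing hazard is modulated by
  ``exp(kappa * cos(phi_b(t) - mu)) / I0(kappa)`` where ``phi_b`` is the
  analytic phase of the *generated* band component (exact ground truth,
  not a re-filtered estimate).  ``kappa = 0`` means no coupling; the
  ``I0`` normalisation keeps the realised mean rate at the nominal rate.
  Coupling strength can differ per behavioural state and, via the group
  study builder, per experimental group (control / lesioned / L-DOPA).

Spikes are produced by time rescaling: unit-mean gamma ISIs are drawn in
operational time ``Lambda(t) = integral of rate`` and mapped back, which
preserves the renewal structure under rate modulation.  A hard 2-ms
refractory period is enforced, matching the cleaning rule the analysis
assumes.  LFP and spike generation use independent random streams derived
from the master seed, so regenerating spikes never perturbs the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.special import i0

from .io import LfpChannel, Session, SpikeTrain, StateInterval
from .spectral import CANONICAL_BANDS, bandpass

__all__ = [
    "CouplingSpec",
    "UnitSpec",
    "SessionConfig",
    "GROUPS",
    "make_waveform_template",
    "generate_lfp",
    "generate_coupled_spike_train",
    "generate_session",
    "generate_group_study",
    "default_session_config",
]

GROUPS = ("control", "lesioned", "L-DOPA")

REFRACTORY = 0.002  # s; hard floor on generated ISIs

#: Default band oscillation amplitudes (uV) — strongest at low frequencies,
#: as in cortical/brainstem field recordings.
DEFAULT_BAND_AMPLITUDES = {
    "delta": 40.0,
    "theta": 30.0,
    "alpha": 25.0,
    "beta": 20.0,
    "gamma": 10.0,
}


@dataclass(frozen=True)
class CouplingSpec:
    """Phase coupling of a unit to one LFP band.

    ``kappa`` is a von Mises concentration (>= 0; 0 = no coupling) and
    ``preferred_phase`` the phase (rad, peak = 0 convention) at which the
    firing hazard is maximal.
    """

    band_name: str
    kappa: float
    preferred_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.band_name not in CANONICAL_BANDS:
            raise ValueError(f"unknown band {self.band_name!r}")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


@dataclass(frozen=True)
class UnitSpec:
    """Ground-truth description of one simulated unit.

    ``coupling`` maps behavioural state -> list of per-band CouplingSpec;
    states absent from the map are uncoupled.
    """

    unit_type: str = "A"
    mean_rate: float = 12.0
    isi_regularity: float = 1.0
    trough_to_peak_ms: float | None = None
    waveform_template: np.ndarray | None = None
    waveform_noise: float = 4.0
    coupling: dict[str, tuple[CouplingSpec, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit_type not in ("A", "B"):
            raise ValueError("unit_type must be 'A' or 'B'")
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be positive")
        if self.isi_regularity < 1:
            raise ValueError("isi_regularity must be >= 1")

    @property
    def ttp_ms(self) -> float:
        if self.trough_to_peak_ms is not None:
            return self.trough_to_peak_ms
        return 0.25 if self.unit_type == "A" else 0.60


@dataclass(frozen=True)
class SessionConfig:
    """Full recipe for one synthetic session."""

    duration: float
    units: tuple[UnitSpec, ...] = ()
    states: tuple[tuple[str, float, float], ...] = ()
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    noise_exponent: float = 1.0
    noise_scale: float = 15.0
    lfp_fs: float = 1000.0
    wf_fs: float = 20000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("session duration must be positive")
        if self.lfp_fs <= 0 or self.wf_fs <= 0:
            raise ValueError("sample rates must be positive")
        intervals = sorted((s, e) for _, s, e in self.states)
        for (state, s, e) in self.states:
            if not (0 <= s < e <= self.duration + 1e-9):
                raise ValueError(
                    f"state interval [{s}, {e}) outside the session duration"
                )
        for (s0, e0), (s1, e1) in zip(intervals, intervals[1:]):
            if s1 < e0:
                raise ValueError("state intervals must not overlap")

    @property
    def state_intervals(self) -> list[StateInterval]:
        return [StateInterval(st, s, e) for st, s, e in self.states]


def make_waveform_template(
    unit_type: str = "A",
    trough_to_peak_ms: float | None = None,
    wf_fs: float = 20000.0,
    snippet_ms: float = 1.6,
    trough_amplitude: float = -80.0,
) -> np.ndarray:
    """Biphasic extracellular waveform template (uV at ``wf_fs``).

    A negative Gaussian trough followed by a positive Gaussian peak
    ``trough_to_peak_ms`` later (defaults: Type A 0.25 ms, Type B 0.60 ms).
    """
    if trough_to_peak_ms is None:
        trough_to_peak_ms = 0.25 if unit_type == "A" else 0.60
    n = int(round(snippet_ms * wf_fs / 1000.0))
    t_ms = np.arange(n) / wf_fs * 1000.0
    t_trough = 0.4
    t_peak = t_trough + trough_to_peak_ms
    sigma_t = trough_to_peak_ms / 3.0
    sigma_p = trough_to_peak_ms / 2.0
    w = trough_amplitude * np.exp(-0.5 * ((t_ms - t_trough) / sigma_t) ** 2)
    w += (-0.45 * trough_amplitude) * np.exp(-0.5 * ((t_ms - t_peak) / sigma_p) ** 2)
    return w


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent generator streams derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _one_over_f_noise(
    n: int, fs: float, exponent: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with power spectrum proportional to 1/f^exponent."""
    if scale == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0
    shaped = np.fft.irfft(spectrum * shaping, n=n)
    std = shaped.std()
    return shaped * (scale / std) if std > 0 else shaped


def _band_components(
    config: SessionConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Narrowband LFP components: filtered Gaussian noise per band, scaled
    so the component RMS equals amplitude / sqrt(2) (sinusoid-equivalent)."""
    n = int(round(config.duration * config.lfp_fs))
    components: dict[str, np.ndarray] = {}
    for name, amplitude in config.band_amplitudes.items():
        if name not in CANONICAL_BANDS:
            raise ValueError(f"unknown band {name!r} in band_amplitudes")
        if amplitude == 0:
            continue
        raw = bandpass(rng.standard_normal(n), config.lfp_fs, name)
        rms = np.sqrt(np.mean(raw**2))
        target_rms = amplitude / np.sqrt(2.0)
        components[name] = raw * (target_rms / rms) if rms > 0 else raw
    return components


def _lfp_with_components(
    config: SessionConfig, rng: np.random.Generator
) -> tuple[LfpChannel, dict[str, np.ndarray]]:
    n = int(round(config.duration * config.lfp_fs))
    components = _band_components(config, rng)
    samples = _one_over_f_noise(
        n, config.lfp_fs, config.noise_exponent, config.noise_scale, rng
    )
    for comp in components.values():
        samples = samples + comp
    channel = LfpChannel(samples=samples, fs=config.lfp_fs, channel_id="lfp0")
    return channel, components


def generate_lfp(config: SessionConfig) -> LfpChannel:
    """Generate the session LFP alone (deterministic given ``config.seed``)."""
    rng_lfp, _ = _spawn_rngs(config.seed, 2)
    channel, _ = _lfp_with_components(config, rng_lfp)
    return channel


def _modulation(
    spec: UnitSpec,
    state: str,
    band_phases: dict[str, np.ndarray],
) -> np.ndarray | float:
    """Multiplicative hazard modulation for one state, normalised to mean
    ~1 over uniform phase (so the realised rate stays near nominal)."""
    specs = spec.coupling.get(state, ())
    mod: np.ndarray | float = 1.0
    for c in specs:
        if c.kappa == 0:
            continue
        if c.band_name not in band_phases:
            raise ValueError(
                f"coupling requests band {c.band_name!r} but the LFP has no "
                "such component"
            )
        phi = band_phases[c.band_name]
        mod = mod * np.exp(c.kappa * np.cos(phi - c.preferred_phase)) / i0(c.kappa)
    return mod


def generate_coupled_spike_train(
    lfp: LfpChannel,
    spec: UnitSpec,
    state_intervals: list[StateInterval],
    rng: np.random.Generator | int | None = None,
    band_components: dict[str, np.ndarray] | None = None,
    wf_fs: float = 20000.0,
    unit_id: str = "u00",
) -> SpikeTrain:
    """Simulate a phase-coupled gamma-renewal spike train over the states.

    The hazard is the nominal rate times the von Mises-style modulation of
    the analytic phase of each coupled band component (the generated ground
    truth when ``band_components`` is supplied; otherwise re-filtered from
    the composite LFP).  ISIs follow a gamma renewal process with shape
    ``isi_regularity`` via time rescaling; a 2-ms refractory period is
    enforced; each spike carries the class template plus additive noise.
    """
    if not state_intervals:
        raise ValueError("at least one state interval is required")
    rng = np.random.default_rng(rng)
    fs = lfp.fs
    if band_components is None:
        band_components = {
            name: bandpass(lfp.samples, fs, name) for name in CANONICAL_BANDS
        }
    needed = {c.band_name for specs in spec.coupling.values() for c in specs}
    band_phases = {
        name: np.angle(signal.hilbert(band_components[name]))
        for name in needed
        if name in band_components
    }
    spikes: list[np.ndarray] = []
    shape = spec.isi_regularity
    for iv in state_intervals:
        i0_, i1 = int(round(iv.start * fs)), int(round(iv.end * fs))
        n_grid = i1 - i0_
        if n_grid <= 0:
            continue
        mod = _modulation(spec, iv.state, {k: v[i0_:i1] for k, v in band_phases.items()})
        rate = spec.mean_rate * (
            mod if isinstance(mod, np.ndarray) else np.full(n_grid, mod)
        )
        # operational time Lambda(t); invert with linear interpolation
        lam = np.concatenate([[0.0], np.cumsum(rate) / fs])
        total = lam[-1]
        n_draw = int(total + 6 * np.sqrt(total + 1) + 20)
        isis = rng.gamma(shape, 1.0 / shape, size=n_draw)
        arrival_ops = np.cumsum(isis)
        arrival_ops = arrival_ops[arrival_ops < total]
        grid_t = iv.start + np.arange(n_grid + 1) / fs
        times = np.interp(arrival_ops, lam, grid_t)
        spikes.append(times)
    t = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
    # hard refractory: greedy removal of the later spike of close pairs
    if t.size:
        keep = np.ones(t.size, dtype=bool)
        last = -np.inf
        for i, ti in enumerate(t):
            if ti - last < REFRACTORY:
                keep[i] = False
            else:
                last = ti
        t = t[keep]
    template = (
        spec.waveform_template
        if spec.waveform_template is not None
        else make_waveform_template(spec.unit_type, spec.trough_to_peak_ms, wf_fs)
    )
    waveforms = template[None, :] + spec.waveform_noise * rng.standard_normal(
        (t.size, template.size)
    )
    return SpikeTrain(
        timestamps=t,
        waveforms=waveforms,
        wf_fs=wf_fs,
        unit_id=unit_id,
        channel_id=lfp.channel_id,
        unit_type="unclassified",
    )


def generate_session(config: SessionConfig) -> tuple[Session, dict]:
    """Generate a full session plus its ground truth.

    Ground truth records, per unit: true type, nominal rate, ISI shape, and
    the coupling kappas per (state, band).  Deterministic given the config
    (including its seed); the LFP stream is independent of the spike
    streams.
    """
    rng_lfp, rng_master = _spawn_rngs(config.seed, 2)
    lfp, components = _lfp_with_components(config, rng_lfp)
    unit_rngs = _spawn_rngs(config.seed + 1, max(len(config.units), 1))
    units: dict[str, SpikeTrain] = {}
    truth_units = {}
    intervals = config.state_intervals or [
        StateInterval("rest", 0.0, config.duration)
    ]
    for i, spec in enumerate(config.units):
        uid = f"u{i:02d}"
        units[uid] = generate_coupled_spike_train(
            lfp,
            spec,
            intervals,
            rng=unit_rngs[i],
            band_components=components,
            wf_fs=config.wf_fs,
            unit_id=uid,
        )
        truth_units[uid] = {
            "unit_type": spec.unit_type,
            "mean_rate": spec.mean_rate,
            "isi_regularity": spec.isi_regularity,
            "trough_to_peak_ms": spec.ttp_ms,
            "coupling": {
                state: {c.band_name: {"kappa": c.kappa, "phase": c.preferred_phase}
                        for c in specs}
                for state, specs in spec.coupling.items()
            },
        }
    session = Session(
        lfp={"lfp0": lfp},
        units=units,
        states=intervals,
        metadata={"seed": config.seed, "synthetic": True},
    )
    truth = {"seed": config.seed, "units": truth_units}
    return session, truth


def default_session_config(
    duration: float = 80.0,
    n_type_a: int = 3,
    n_type_b: int = 2,
    kappa: float = 0.5,
    coupled_band: str = "beta",
    seed: int = 0,
) -> SessionConfig:
    """A representative resting-state session: Type A units coupled to one
    band at rest (default beta, kappa 0.5), Type B units uncoupled."""
    units = tuple(
        UnitSpec(
            unit_type="A",
            mean_rate=12.0,
            isi_regularity=1.0,
            coupling={"rest": (CouplingSpec(coupled_band, kappa),)},
        )
        for _ in range(n_type_a)
    ) + tuple(
        UnitSpec(unit_type="B", mean_rate=4.0, isi_regularity=4.0)
        for _ in range(n_type_b)
    )
    return SessionConfig(
        duration=duration,
        units=units,
        states=(("rest", 0.0, duration),),
        seed=seed,
    )


def generate_group_study(
    template: SessionConfig,
    group_effects: dict[str, dict[tuple[str, str, str], float]],
    n_per_group: int,
    seed: int = 0,
) -> dict[str, list[tuple[Session, dict]]]:
    """Generate replicate sessions per experimental group.

    ``group_effects`` maps group name (control / lesioned / L-DOPA) to a map
    ``(unit_type, state, band) -> kappa multiplier`` applied to the
    template's coupling.  Each of the ``n_per_group`` sessions per group
    gets a distinct seed derived from ``seed``; ground-truth kappas are
    recorded in each session's truth dict.  ``n_per_group = 0`` yields an
    empty study.
    """
    for group in group_effects:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    study: dict[str, list[tuple[Session, dict]]] = {}
    for g_idx, (group, effects) in enumerate(sorted(group_effects.items())):
        sessions = []
        for rep in range(n_per_group):
            units = tuple(
                _apply_effects(spec, effects) for spec in template.units
            )
            cfg = replace(
                template,
                units=units,
                seed=int(seed) * 100003 + g_idx * 1009 + rep,
            )
            session, truth = generate_session(cfg)
            session.metadata.update({"group": group, "replicate": rep})
            truth["group"] = group
            sessions.append((session, truth))
        study[group] = sessions
    return study


def _apply_effects(
    spec: UnitSpec, effects: dict[tuple[str, str, str], float]
) -> UnitSpec:
    coupling = {}
    for state, specs in spec.coupling.items():
        coupling[state] = tuple(
            replace(
                c,
                kappa=c.kappa * effects.get((spec.unit_type, state, c.band_name), 1.0),
            )
            for c in specs
        )
    return replace(spec, coupling=coupling)
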