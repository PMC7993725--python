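"""Spike-phase extraction, Rayleigh testing, and circular summaries.

The phase convention is fixed by the analysis definition: a spike at an
oscillation *peak* of the band-passed LFP has phase 0, a spike at a *trough*
has phase +-pi (cosine phase).  The band component is obtained by zero-phase
band-pass filtering and its instantaneous phase by the analytic (Hilbert)
signal, which realises exactly that convention.

Per segment and band, spikes yield a set of angles; the Rayleigh test asks
whether they are non-uniform, and only segments with p < 0.05 contribute a
resultant length downstream (the significance "gate").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import Segment, Session
from .spectral import FrequencyBand, CANONICAL_BANDS, bandpass

__all__ = [
    "PhaseLockResult",
    "instantaneous_phase",
    "spike_phases",
    "rayleigh_test",
    "mean_phase",
    "gated_phaselock",
    "rose_histogram",
]

GATE_ALPHA = 0.05


@dataclass
class PhaseLockResult:
    """Circular statistics of spike phases for one (unit, segment, band).

    ``rayleigh_z = n * resultant_length**2``; ``passed_gate`` is True iff
    the Rayleigh p-value is below 0.05.
    """

    angles: np.ndarray
    mean_angle: float
    resultant_length: float
    rayleigh_z: float
    rayleigh_p: float
    band: FrequencyBand
    passed_gate: bool
    n_spikes: int
    low_n: bool = False


def wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap angles into ``(-pi, pi]``."""
    wrapped = np.mod(np.asarray(theta) + np.pi, 2 * np.pi) - np.pi
    return np.where(wrapped == -np.pi, np.pi, wrapped)


def instantaneous_phase(
    lfp: np.ndarray, fs: float, band: FrequencyBand | str
) -> np.ndarray:
    """Instantaneous phase of the band component, peak = 0 convention.

    Zero-phase band-pass into *band*, then the angle of the analytic signal.
    For a component ``a(t) * cos(phi(t))`` this returns ``phi``: 0 at peaks,
    +-pi at troughs, -pi/2 at ascending zero crossings.

    Raises
    ------
    ValueError
        If the band component vanishes (phase undefined).
    """
    if isinstance(band, str):
        band = CANONICAL_BANDS[band]
    narrow = bandpass(lfp, fs, band)
    if not np.any(narrow):
        raise ValueError(
            f"band {band.name!r} component is identically zero; phase undefined"
        )
    return np.angle(signal.hilbert(narrow))


def spike_phases(
    phase: np.ndarray, fs: float, spike_times: np.ndarray, t0: float = 0.0
) -> np.ndarray:
    """Phase at each spike time, linearly interpolated between samples.

    Interpolation is done on the unwrapped phase so the +-pi seam does not
    produce spurious midpoints, then wrapped back to ``(-pi, pi]``.
    ``t0`` is the time of ``phase[0]`` (segment start).  A spike falling in
    the final sample interval (past the last sample but inside the segment)
    takes the last sample's phase.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    n = np.asarray(phase).size
    rel = spike_times - t0
    if spike_times.size and (rel.min() < 0 or rel.max() * fs >= n):
        raise ValueError("spike time outside the phase series")
    unwrapped = np.unwrap(phase)
    sample_times = np.arange(n) / fs
    return wrap_angle(np.interp(rel, sample_times, unwrapped))


def mean_phase(angles: np.ndarray) -> tuple[float, float]:
    """Circular mean angle and resultant vector length.

    Returns ``(mean_angle, R)`` where ``R`` is the modulus of the mean unit
    vector, in [0, 1]: 1 for perfectly concentrated angles, 0 for balanced
    (e.g. antipodal) configurations.  With zero resultant the mean angle is
    undefined and NaN is returned for it.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("mean phase of an empty angle set is undefined")
    vector = np.exp(1j * angles).mean()
    r = float(np.abs(vector))
    if r < 1e-15:
        return float("nan"), 0.0 if r == 0 else r
    return float(np.angle(vector)), r


def rayleigh_test(angles: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns ``(z, p)`` with ``z = n * Rbar**2`` and the standard
    small-sample-corrected exponential approximation for p (as used in
    circular-statistics toolboxes):

        p = exp( sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n) ),  R = n * Rbar.

    p is clipped to (0, 1].
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    if n == 0:
        raise ValueError("Rayleigh test requires at least one angle")
    _, rbar = mean_phase(angles)
    z = n * rbar**2
    big_r = n * rbar
    p = math.exp(math.sqrt(1 + 4 * n + 4 * (n**2 - big_r**2)) - (1 + 2 * n))
    return float(z), float(min(max(p, np.nextafter(0, 1)), 1.0))


def gated_phaselock(
    session: Session,
    unit_id: str,
    segment: Segment,
    band: FrequencyBand | str,
    min_spikes: int = 5,
) -> PhaseLockResult | None:
    """Full phase-lock chain for one (unit, segment, band), Rayleigh-gated.

    Band-pass the segment's LFP, extract analytic phase, interpolate phases
    at the spike times, run the Rayleigh test.  ``passed_gate`` marks
    whether the segment's resultant length may be used downstream
    (p < 0.05).  Returns None if the segment contains no spikes.
    """
    if isinstance(band, str):
        band = CANONICAL_BANDS[band]
    train = session.units[unit_id]
    lfp = session.lfp[train.channel_id]
    seg_lfp = lfp.time_slice(segment.start, segment.duration)
    spikes = train.in_interval(segment.start, segment.duration)
    if spikes.size == 0:
        return None
    phase = instantaneous_phase(seg_lfp, lfp.fs, band)
    angles = spike_phases(phase, lfp.fs, spikes, t0=segment.start)
    angle, r = mean_phase(angles)
    z, p = rayleigh_test(angles)
    return PhaseLockResult(
        angles=angles,
        mean_angle=angle,
        resultant_length=r,
        rayleigh_z=z,
        rayleigh_p=p,
        band=band,
        passed_gate=p < GATE_ALPHA,
        n_spikes=int(spikes.size),
        low_n=spikes.size < min_spikes,
    )


def rose_histogram(
    angles: np.ndarray, n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of angles over equal bins partitioning ``(-pi, pi]``.

    Returns ``(counts, edges)`` with ``len(edges) = n_bins + 1`` and
    ``counts.sum() == len(angles)``.
    """
    if n_bins < 4:
        raise ValueError("a rose histogram needs at least 4 bins")
    angles = wrap_angle(np.asarray(angles, dtype=float))
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    # (-pi, pi]: put any angle equal to -pi (cannot occur after wrapping)
    # aside; np.histogram's closed last bin handles +pi.
    counts, _ = np.histogram(angles, bins=edges)
    return counts, edges
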