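"""Spike-field coherence via the STA/STP spectrum ratio.

For each spike, the *unfiltered* LFP is extracted in a window of +-500 ms
around the spike (1001 samples at 1 kHz).  The spike-triggered average
(STA) is the pointwise mean of these windows; fSTA is the multitaper power
spectrum of the STA, and the spike-triggered power (STP) is the mean of the
identically computed spectra of the individual windows.  Then

    SFC(f) = 100 * fSTA(f) / STP(f)   [percent]

is 100% when every spike sees the identical field trace and falls towards
100/n_spikes for phase-incoherent windows (averaging n incoherent complex
amplitudes shrinks power by ~1/n).  Because the numerator and denominator
use the same spectral settings, SFC <= 100% up to rounding.

Spectra use NW = 3 / K = 5 tapers over Welch-style sub-windows of 500
samples with 50% overlap (three sub-windows per 1001-sample trace).  Before
analysis the spike count per segment is equalised (50 in rest, 20 in
locomotion) by seeded random subsampling, so SFC values are comparable
across segments despite its spike-count-dependent bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Segment, Session
from .spectral import CANONICAL_BANDS, dpss_tapers, _fold_one_sided
from .coherence import band_mean_curve

__all__ = [
    "SfcParams",
    "SfcResult",
    "EQUALIZE_TARGETS",
    "equalize_spike_count",
    "spike_triggered_windows",
    "compute_sfc",
    "sfc_for_unit_segment",
]

#: Equalisation targets per behavioural state (spikes per segment).
EQUALIZE_TARGETS = {"rest": 50, "locomotion": 20}


@dataclass(frozen=True)
class SfcParams:
    """Spectral settings for the STA/STP ratio (NW 3, K 5, 50% overlap,
    500-sample Welch sub-windows inside each +-500 ms trace)."""

    half_window: float = 0.5
    nw: float = 3
    k: int = 5
    subwindow: int = 500
    overlap: float = 0.5
    fs: float = 1000.0


@dataclass
class SfcResult:
    """STA trace, its spectrum, the mean per-window spectrum, and the ratio."""

    frequencies: np.ndarray
    sta: np.ndarray
    fsta: np.ndarray
    stp: np.ndarray
    sfc_curve: np.ndarray
    band_means: dict[str, float]
    n_spikes_used: int
    params: SfcParams = field(default_factory=SfcParams)


def equalize_spike_count(
    spike_times: np.ndarray,
    target: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray | None:
    """Uniform random subsample of exactly ``target`` spikes (sorted).

    Returns None when fewer than ``target`` spikes are available: the
    segment is then excluded rather than analysed with an unequal count.
    With exactly ``target`` spikes the input is returned unchanged.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size < target:
        return None
    if spike_times.size == target:
        return spike_times
    rng = np.random.default_rng(rng)
    keep = rng.choice(spike_times.size, size=target, replace=False)
    return np.sort(spike_times[keep])


def spike_triggered_windows(
    lfp_samples: np.ndarray,
    spike_times: np.ndarray,
    fs: float = 1000.0,
    half_window: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the +-half_window LFP trace around each spike.

    Spikes whose full window would run off either end of the recording are
    excluded.  Returns ``(windows, kept_mask)`` where ``windows`` has one
    row of ``2*half_window*fs + 1`` samples per retained spike (both
    endpoints inclusive: a spike at 5.0 s with fs 1 kHz yields samples
    4500..5500).
    """
    lfp_samples = np.asarray(lfp_samples, dtype=float)
    spike_times = np.asarray(spike_times, dtype=float)
    half = int(round(half_window * fs))
    centres = np.round(spike_times * fs).astype(int)
    kept = (centres - half >= 0) & (centres + half < lfp_samples.size)
    rows = [lfp_samples[c - half : c + half + 1] for c in centres[kept]]
    windows = (
        np.stack(rows) if rows else np.empty((0, 2 * half + 1))
    )
    return windows, kept


def _welch_multitaper_psd(
    traces: np.ndarray, params: SfcParams
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper Welch PSD of each row of ``traces``.

    Sub-windows of ``params.subwindow`` samples with the configured overlap
    are tapered with K DPSS tapers; power is averaged over sub-windows and
    tapers.  Returns ``(frequencies, psd_rows)``.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n = traces.shape[1]
    sub = params.subwindow
    step = max(1, int(round(sub * (1 - params.overlap))))
    starts = np.arange(0, n - sub + 1, step)
    tapers = dpss_tapers(sub, params.nw, params.k)
    freqs = np.fft.rfftfreq(sub, d=1.0 / params.fs)
    # (n_traces, n_sub, sub) -> taper -> (n_traces, n_sub, k, n_freq)
    segs = np.stack([traces[:, s : s + sub] for s in starts], axis=1)
    spectra = (
        np.abs(np.fft.rfft(segs[:, :, None, :] * tapers[None, None, :, :], axis=-1))
        ** 2
    )
    psd = spectra.mean(axis=(1, 2)) / params.fs
    psd = np.apply_along_axis(_fold_one_sided, -1, psd, sub)
    return freqs, psd


def compute_sfc(windows: np.ndarray, params: SfcParams = SfcParams()) -> SfcResult:
    """SFC from a matrix of spike-triggered LFP windows (one row per spike).

    ``fSTA`` is the spectrum of the mean trace; ``STP`` the mean of the
    per-trace spectra, computed with identical settings so the ratio
    isolates across-spike phase consistency.  Frequencies where STP is zero
    get NaN (logged as missing), not 0 or infinity.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    if windows.shape[0] < 2:
        raise ValueError("SFC needs at least 2 spike-triggered windows")
    sta = windows.mean(axis=0)
    freqs, fsta = _welch_multitaper_psd(sta, params)
    fsta = fsta[0]
    _, per_window = _welch_multitaper_psd(windows, params)
    stp = per_window.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = 100.0 * fsta / stp
    zero_stp = stp == 0
    if np.any(zero_stp):
        warnings.warn(
            f"STP is zero at {int(zero_stp.sum())} frequencies; "
            "SFC undefined there",
            RuntimeWarning,
            stacklevel=2,
        )
        curve = np.where(zero_stp, np.nan, curve)
    band_means = {}
    for name in CANONICAL_BANDS:
        try:
            band_means[name] = band_mean_curve(freqs, curve, name)
        except ValueError:
            band_means[name] = float("nan")
    return SfcResult(
        frequencies=freqs,
        sta=sta,
        fsta=fsta,
        stp=stp,
        sfc_curve=curve,
        band_means=band_means,
        n_spikes_used=windows.shape[0],
        params=params,
    )


def sfc_for_unit_segment(
    session: Session,
    unit_id: str,
    segment: Segment,
    rng: np.random.Generator | int | None = None,
    params: SfcParams = SfcParams(),
    target: int | None = None,
) -> SfcResult | None:
    """Equalise, window, and compute SFC for one (unit, segment) pair.

    The equalisation target follows the segment's behavioural state
    (rest 50 / locomotion 20) unless overridden.  Edge-excluded spikes are
    removed *before* equalisation so exactly ``target`` spikes contribute.
    Returns None (missing value) when too few eligible spikes remain.
    """
    if target is None:
        target = EQUALIZE_TARGETS[segment.state]
    train = session.units[unit_id]
    lfp = session.lfp[train.channel_id]
    spikes = train.in_interval(segment.start, segment.duration)
    half = int(round(params.half_window * lfp.fs))
    centres = np.round(spikes * lfp.fs).astype(int)
    eligible = spikes[(centres - half >= 0) & (centres + half < lfp.samples.size)]
    subsample = equalize_spike_count(eligible, target, rng)
    if subsample is None:
        return None
    windows, _ = spike_triggered_windows(
        lfp.samples, subsample, fs=lfp.fs, half_window=params.half_window
    )
    return compute_sfc(windows, params)
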