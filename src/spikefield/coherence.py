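"""Spike-LFP magnitude coherence by segment-averaged multitaper estimation.

The spike train enters as a mean-centred binned count series at the LFP
sample rate (1 kHz), so the two signals share one time grid.  Coherence is
estimated with sliding 0.5-s windows stepped by 0.1 s, NW = 5 and K = 9
DPSS tapers; cross- and auto-spectra are pooled over all (window, taper)
pairs *before* the modulus:

    C(f) = |sum S_xy(f)| / sqrt( sum S_xx(f) * sum S_yy(f) )

which lies in [0, 1]; 1 means a perfect linear relation at that frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as _fft

from .io import Segment, Session
from .spectral import CANONICAL_BANDS, FrequencyBand, band_mask, dpss_tapers

__all__ = [
    "CoherenceParams",
    "CoherenceResult",
    "bin_spike_train",
    "spike_field_coherence_mt",
    "band_mean",
    "coherence_for_unit_segment",
]


@dataclass(frozen=True)
class CoherenceParams:
    """Multitaper sliding-window parameters (defaults: 0.5 s window,
    0.1 s step, NW 5, K 9, fs 1000 Hz)."""

    window: float = 0.5
    step: float = 0.1
    nw: float = 5
    k: int = 9
    fs: float = 1000.0


@dataclass
class CoherenceResult:
    """Frequency-resolved coherence plus per-band scalar summaries."""

    frequencies: np.ndarray
    coherence: np.ndarray
    band_means: dict[str, float]
    params: CoherenceParams
    n_windows: int

    @property
    def is_missing(self) -> bool:
        return bool(np.all(np.isnan(self.coherence)))


def bin_spike_train(
    train, segment: Segment | tuple[float, float], fs: float = 1000.0
) -> np.ndarray:
    """Spike counts per ``1/fs`` bin over the segment (half-open bins).

    A spike at time ``t`` lands in bin ``floor((t - start) * fs)``; bins are
    ``[t_bin, t_bin + 1/fs)`` so a spike exactly on a bin edge belongs to
    that bin.  The counts sum to the number of spikes in the segment.
    """
    if isinstance(segment, Segment):
        start, duration = segment.start, segment.duration
    else:
        start, duration = segment
    times = train.timestamps if hasattr(train, "timestamps") else np.asarray(train)
    n_bins = int(round(duration * fs))
    spikes = times[(times >= start) & (times < start + duration)]
    idx = np.floor((spikes - start) * fs).astype(int)
    idx = idx[idx < n_bins]  # guard float round-up at the segment end
    counts = np.zeros(n_bins)
    np.add.at(counts, idx, 1.0)
    return counts


def spike_field_coherence_mt(
    spike_series: np.ndarray,
    lfp_segment: np.ndarray,
    params: CoherenceParams = CoherenceParams(),
) -> CoherenceResult:
    """Segment-averaged multitaper coherence between two equal-length series.

    Both series are mean-centred once; per sliding window and taper, the
    cross-spectrum and the two auto-spectra are accumulated, and the
    coherence magnitude is formed from the pooled sums (9 x n_windows
    degrees of freedom at the default parameters).

    A zero-variance input (no spikes, or flat LFP) yields an all-NaN
    missing-value result with a warning, not coherence 0.
    """
    x = np.asarray(spike_series, dtype=float)
    y = np.asarray(lfp_segment, dtype=float)
    if x.shape != y.shape:
        raise ValueError("spike series and LFP segment must have equal length")
    n_win = int(round(params.window * params.fs))
    n_step = int(round(params.step * params.fs))
    if x.size < n_win:
        raise ValueError(
            f"segment of {x.size} samples shorter than one "
            f"{params.window}-s window"
        )
    freqs = np.fft.rfftfreq(n_win, d=1.0 / params.fs)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            "zero-variance input; coherence undefined (missing values)",
            RuntimeWarning,
            stacklevel=2,
        )
        nan_curve = np.full(freqs.size, np.nan)
        return CoherenceResult(
            freqs, nan_curve, {b: float("nan") for b in CANONICAL_BANDS}, params, 0
        )
    x = x - x.mean()
    y = y - y.mean()
    tapers = dpss_tapers(n_win, params.nw, params.k)
    starts = np.arange(0, x.size - n_win + 1, n_step)
    xw = np.stack([x[s : s + n_win] for s in starts])  # (n_windows, n_win)
    yw = np.stack([y[s : s + n_win] for s in starts])
    # batched tapered FFTs: (n_windows, k, n_freq)
    fx = _fft.rfft(xw[:, None, :] * tapers[None, :, :], axis=-1)
    fy = _fft.rfft(yw[:, None, :] * tapers[None, :, :], axis=-1)
    sxy = (fx * np.conj(fy)).sum(axis=(0, 1))
    sxx = (np.abs(fx) ** 2).sum(axis=(0, 1))
    syy = (np.abs(fy) ** 2).sum(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) / np.sqrt(sxx * syy)
    coh = np.where((sxx > 0) & (syy > 0), coh, np.nan)
    band_means = {}
    for name in CANONICAL_BANDS:
        try:
            band_means[name] = band_mean_curve(freqs, coh, name)
        except ValueError:
            band_means[name] = float("nan")
    return CoherenceResult(freqs, coh, band_means, params, len(starts))


def band_mean_curve(
    frequencies: np.ndarray, curve: np.ndarray, band: FrequencyBand | str
) -> float:
    """Arithmetic mean of a spectral curve over the band's grid points."""
    mask = band_mask(frequencies, band)
    if not np.any(mask):
        name = band if isinstance(band, str) else band.name
        raise ValueError(f"no frequency-grid points inside band {name!r}")
    return float(np.mean(curve[mask]))


def band_mean(result: CoherenceResult, band: FrequencyBand | str) -> float:
    """Mean coherence over grid frequencies with ``low <= f < high``."""
    return band_mean_curve(result.frequencies, result.coherence, band)


def coherence_for_unit_segment(
    session: Session,
    unit_id: str,
    segment: Segment,
    params: CoherenceParams = CoherenceParams(),
) -> CoherenceResult:
    """Bin a unit's spikes over the segment and run the coherence estimator
    against the segment's LFP (both at the LFP sample rate)."""
    train = session.units[unit_id]
    lfp = session.lfp[train.channel_id]
    counts = bin_spike_train(train, segment, fs=lfp.fs)
    seg_lfp = lfp.time_slice(segment.start, segment.duration)
    n = min(counts.size, seg_lfp.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return spike_field_coherence_mt(counts[:n], seg_lfp[:n], params)
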