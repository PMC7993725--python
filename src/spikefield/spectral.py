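"""Multitaper spectral estimation and band-pass filtering.

The estimators here follow the classic Thomson multitaper recipe: a signal
window is multiplied by ``K`` orthonormal discrete prolate spheroidal
sequences (DPSS, "Slepian" tapers) with time-bandwidth product ``NW``, the
eigenspectra are averaged, and two-sided power is folded to a one-sided
spectrum.  Taper counts follow the ``K = 2*NW - 1`` convention, so the two
parameter sets used throughout the package — (NW=5, K=9) for coherence and
(NW=3, K=5) for spike-triggered spectra — are instances of one rule.

Band-pass filtering is zero-phase (forward-backward Butterworth) because the
spike-phase convention downstream (oscillation peak = 0 rad) is only
meaningful if filtering does not shift phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "FrequencyBand",
    "CANONICAL_BANDS",
    "Spectrum",
    "dpss_tapers",
    "multitaper_psd",
    "multitaper_spectrogram",
    "bandpass",
    "band_mask",
]


@dataclass(frozen=True)
class FrequencyBand:
    """A half-open frequency interval ``[low, high)`` in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r} requires 0 < low < high, "
                f"got [{self.low}, {self.high})"
            )

    def contains(self, frequencies: np.ndarray) -> np.ndarray:
        """Boolean mask of grid frequencies inside ``[low, high)``."""
        f = np.asarray(frequencies)
        return (f >= self.low) & (f < self.high)


#: The five analysis bands.  Half-open intervals so the shared edges
#: (4, 7, 12, 30 Hz) belong to exactly one band when averaging.
CANONICAL_BANDS: dict[str, FrequencyBand] = {
    "delta": FrequencyBand("delta", 1.0, 4.0),
    "theta": FrequencyBand("theta", 4.0, 7.0),
    "alpha": FrequencyBand("alpha", 7.0, 12.0),
    "beta": FrequencyBand("beta", 12.0, 30.0),
    "gamma": FrequencyBand("gamma", 30.0, 70.0),
}


def band_mask(frequencies: np.ndarray, band: FrequencyBand | str) -> np.ndarray:
    """Mask of frequency-grid points falling inside *band* (half-open)."""
    if isinstance(band, str):
        band = CANONICAL_BANDS[band]
    return band.contains(frequencies)


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectral density on an ascending frequency grid.

    Attributes
    ----------
    frequencies : ndarray
        Frequency grid in Hz, resolution ``fs / n_fft``.
    power : ndarray
        One-sided PSD, same length as ``frequencies``; units
        (signal unit)^2 / Hz.
    params : tuple
        ``(n_window, nw, k)`` used for the estimate.
    """

    frequencies: np.ndarray
    power: np.ndarray
    params: tuple

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power spectral density must be non-negative")


def dpss_tapers(n_samples: int, nw: float, k: int) -> np.ndarray:
    """Return ``k`` orthonormal DPSS tapers of length ``n_samples``.

    Parameters
    ----------
    n_samples : int
        Window length in samples; must exceed ``2 * nw``.
    nw : float
        Time-bandwidth product.
    k : int
        Number of tapers; at most ``2*nw - 1`` (higher-order tapers have
        poor spectral concentration and would leak).

    Returns
    -------
    ndarray of shape (k, n_samples)
        Unit-energy tapers ordered by decreasing concentration eigenvalue.
    """
    if k < 1:
        raise ValueError("at least one taper is required")
    if k > 2 * nw - 1:
        raise ValueError(
            f"k={k} tapers exceed the leakage-safe limit 2*NW-1 = {2 * nw - 1:g}"
        )
    if n_samples <= 2 * nw:
        raise ValueError(f"window of {n_samples} samples too short for NW={nw}")
    tapers = signal.windows.dpss(n_samples, nw, Kmax=k, sym=True, norm=2)
    return np.atleast_2d(tapers)


def _eigenspectra(x: np.ndarray, tapers: np.ndarray, n_fft: int) -> np.ndarray:
    """|FFT|^2 of each tapered copy of ``x`` (rows: tapers; two-sided scale)."""
    return np.abs(np.fft.rfft(tapers * x, n=n_fft, axis=-1)) ** 2


def multitaper_psd(
    x: np.ndarray,
    fs: float,
    nw: float = 3,
    k: int = 5,
    n_fft: int | None = None,
) -> Spectrum:
    """Multitaper one-sided PSD of a single window.

    Eigenspectra of the ``k`` tapered copies are averaged with uniform
    weights.  Power is scaled so that the one-sided PSD integrates to the
    signal variance (Parseval) for stationary noise.

    Raises
    ------
    ValueError
        If the signal contains NaN, is too short, or ``fs <= 0``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if fs <= 0:
        raise ValueError("sample rate must be positive")
    n = x.size
    tapers = dpss_tapers(n, nw, k)
    n_fft = n if n_fft is None else int(n_fft)
    psd = _eigenspectra(x, tapers, n_fft).mean(axis=0) / fs
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    psd = _fold_one_sided(psd, n_fft)
    return Spectrum(freqs, psd, (n, nw, k))


def _fold_one_sided(psd: np.ndarray, n_fft: int) -> np.ndarray:
    """Double the interior bins of an rfft-grid PSD (DC and Nyquist excluded)."""
    psd = psd.copy()
    if n_fft % 2 == 0:
        psd[1:-1] *= 2.0
    else:
        psd[1:] *= 2.0
    return psd


def multitaper_spectrogram(
    x: np.ndarray,
    fs: float,
    window: float = 0.5,
    step: float = 0.1,
    nw: float = 3,
    k: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window multitaper spectrogram in log10 power.

    Parameters
    ----------
    x : ndarray
        Signal.
    fs : float
        Sample rate (Hz).
    window, step : float
        Window length and hop, in seconds.

    Returns
    -------
    times : ndarray
        Window-centre times (s), ``floor((T - window)/step) + 1`` of them.
    frequencies : ndarray
        One-sided frequency grid (Hz).
    log_power : ndarray, shape (n_windows, n_freqs)
        ``log10`` of the one-sided multitaper PSD per window; ``-inf``
        where the power is exactly zero.
    """
    x = np.asarray(x, dtype=float)
    if step <= 0:
        raise ValueError("step must be positive")
    n_win = int(round(window * fs))
    n_step = int(round(step * fs))
    if n_win > x.size:
        raise ValueError("window longer than the signal")
    tapers = dpss_tapers(n_win, nw, k)
    starts = np.arange(0, x.size - n_win + 1, n_step)
    freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    segs = np.stack([x[s : s + n_win] for s in starts])
    # batched: (n_windows, k, n_freq)
    spectra = np.abs(np.fft.rfft(segs[:, None, :] * tapers[None, :, :], axis=-1)) ** 2
    psd = spectra.mean(axis=1) / fs
    psd = np.apply_along_axis(_fold_one_sided, -1, psd, n_win)
    with np.errstate(divide="ignore"):
        log_power = np.log10(psd)
    times = (starts + n_win / 2) / fs
    return times, freqs, log_power


def bandpass(
    x: np.ndarray, fs: float, band: FrequencyBand | str, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass into *band*.

    A 4th-order Butterworth is applied forward and backward
    (``sosfiltfilt``), doubling the effective attenuation and cancelling
    phase distortion — required so spike-phase estimates are not skewed.
    """
    if isinstance(band, str):
        band = CANONICAL_BANDS[band]
    x = np.asarray(x, dtype=float)
    if band.high >= fs / 2:
        raise ValueError(
            f"band {band.name!r} upper edge {band.high} Hz is at or above "
            f"Nyquist ({fs / 2} Hz)"
        )
    sos = signal.butter(order, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)
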