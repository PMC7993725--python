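"""Spike-train cleaning, waveform sorting, and Type A/B unit classification.

The classification scheme mirrors standard extracellular practice: snippets
are cleaned of refractory-period violations (ISI < 2 ms) and cross-channel
artifacts, sorted by k-means in 3-component PCA space, cluster separation is
verified with a one-way MANOVA over the PC scores, and accepted units are
assigned to two electrophysiological classes:

* **Type A** — narrow "V"-shaped waveform (short trough-to-peak), high and
  irregular (near-Poisson) firing;
* **Type B** — broad waveform, low and regular firing.

No fixed duration boundary separates the classes; the primary rule is
2-means clustering on (trough-to-peak, log firing rate) across a session's
units, labelling the shorter-duration cluster A.  For a single unit a
documented fallback threshold of 0.4 ms is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.multivariate.manova import MANOVA

from .io import SpikeTrain

__all__ = [
    "CleaningLog",
    "clean_spike_train",
    "snr",
    "snr_filter",
    "sort_waveforms",
    "cluster_separation_test",
    "trough_to_peak",
    "classify_units",
    "classify_unit",
    "isi_histogram",
]

MIN_ISI = 0.002  # refractory-period cleaning threshold, seconds
SINGLE_UNIT_BOUNDARY_MS = 0.4  # fallback A/B trough-to-peak cut, ms


@dataclass
class CleaningLog:
    """Counts of spikes removed per cleaning rule."""

    n_input: int
    n_isi_removed: int
    n_artifact_removed: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_isi_removed - self.n_artifact_removed


def clean_spike_train(
    train: SpikeTrain,
    min_isi: float = MIN_ISI,
    other_channel_trains: list[np.ndarray] | None = None,
    artifact_window: float = 0.0005,
    artifact_fraction: float = 0.7,
) -> tuple[SpikeTrain, CleaningLog]:
    """Remove refractory violations and cross-channel artifacts.

    For each ISI shorter than ``min_isi`` the *later* spike of the pair is
    removed: a single pass drops every spike whose interval to its
    immediate predecessor violates the floor, so a burst of near-coincident
    events keeps only its first spike.  A spike is a cross-channel
    artifact if at least ``artifact_fraction`` of the other channels carry
    a spike within ``+-artifact_window`` of it.  Idempotent.
    """
    t = train.timestamps
    wf = train.waveforms
    n_input = t.size

    artifact = np.zeros(n_input, dtype=bool)
    if other_channel_trains:
        n_other = len(other_channel_trains)
        for i, ti in enumerate(t):
            hits = sum(
                1
                for other in other_channel_trains
                if np.any(np.abs(np.asarray(other) - ti) <= artifact_window)
            )
            artifact[i] = hits / n_other >= artifact_fraction
    t_a = t[~artifact]
    wf_a = wf[~artifact] if wf is not None else None

    keep = np.ones(t_a.size, dtype=bool)
    if t_a.size > 1:
        keep[1:] = np.diff(t_a) >= min_isi
    cleaned = SpikeTrain(
        timestamps=t_a[keep],
        waveforms=wf_a[keep] if wf_a is not None else None,
        wf_fs=train.wf_fs,
        unit_id=train.unit_id,
        channel_id=train.channel_id,
        unit_type=train.unit_type,
    )
    log = CleaningLog(
        n_input=n_input,
        n_isi_removed=int((~keep).sum()),
        n_artifact_removed=int(artifact.sum()),
    )
    return cleaned, log


def snr(waveforms: np.ndarray, noise_rms: float) -> float:
    """Unit SNR: mean peak-to-trough amplitude over twice the noise RMS."""
    if noise_rms <= 0:
        raise ValueError("noise RMS must be positive")
    waveforms = np.atleast_2d(waveforms)
    peak_to_trough = waveforms.max(axis=1) - waveforms.min(axis=1)
    return float(peak_to_trough.mean() / (2.0 * noise_rms))


def snr_filter(train: SpikeTrain, noise_rms: float, threshold: float = 2.0) -> bool:
    """Keep a unit iff its SNR strictly exceeds ``threshold`` (default 2)."""
    if train.waveforms is None:
        raise ValueError("SNR filtering requires waveform snippets")
    return snr(train.waveforms, noise_rms) > threshold


def sort_waveforms(
    waveforms: np.ndarray,
    k_clusters: int,
    n_components: int = 3,
    random_state: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort waveform snippets: PCA to 3 components, then seeded k-means.

    Returns ``(labels, pc_scores, centroids)`` with centroids in PC space.
    Degenerate input (identical snippets, zero variance) falls back to a
    single cluster with a warning.
    """
    waveforms = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if waveforms.shape[0] < 10 * k_clusters:
        raise ValueError(
            f"need at least {10 * k_clusters} spikes to sort into "
            f"{k_clusters} clusters"
        )
    if np.allclose(waveforms.var(axis=0), 0):
        import warnings

        warnings.warn(
            "degenerate (identical) waveforms; returning a single cluster",
            RuntimeWarning,
            stacklevel=2,
        )
        scores = np.zeros((waveforms.shape[0], n_components))
        return np.zeros(waveforms.shape[0], dtype=int), scores, np.zeros((1, n_components))
    n_components = min(n_components, waveforms.shape[1], waveforms.shape[0])
    pca = PCA(n_components=n_components, random_state=random_state)
    scores = pca.fit_transform(waveforms)
    km = KMeans(n_clusters=k_clusters, n_init=10, random_state=random_state)
    labels = km.fit_predict(scores)
    return labels, scores, km.cluster_centers_


def cluster_separation_test(
    pc_scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """One-way MANOVA over the PC dimensions across waveform clusters.

    Uses Wilks' lambda with its F approximation; clusters are accepted as
    distinct units iff p < ``alpha``.  Returns ``(F, p, distinct)``.
    """
    pc_scores = np.atleast_2d(np.asarray(pc_scores, dtype=float))
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("cluster separation requires at least two clusters")
    dims = pc_scores.shape[1]
    for g in groups:
        if (labels == g).sum() < dims + 1:
            raise ValueError(
                f"cluster {g!r} has fewer than {dims + 1} points; "
                "within-cluster covariance singular"
            )
    df = pd.DataFrame(pc_scores, columns=[f"pc{i + 1}" for i in range(dims)])
    df["label"] = labels
    lhs = " + ".join(df.columns[:-1])
    fit = MANOVA.from_formula(f"{lhs} ~ C(label)", data=df)
    stat = fit.mv_test().results["C(label)"]["stat"]
    f_value = float(stat.loc["Wilks' lambda", "F Value"])
    p_value = float(stat.loc["Wilks' lambda", "Pr > F"])
    return f_value, p_value, p_value < alpha


def trough_to_peak(waveform: np.ndarray, wf_fs: float) -> float:
    """Duration from the global trough to the subsequent peak, in ms.

    Extremum positions are refined by parabolic interpolation through the
    three samples around each extremum, giving sub-sample resolution.

    Raises
    ------
    ValueError
        If no peak follows the trough (monotone tail).
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 3:
        raise ValueError("waveform too short")
    i_trough = int(np.argmin(w))
    if i_trough >= w.size - 1:
        raise ValueError("no peak after the waveform trough")
    i_peak = i_trough + 1 + int(np.argmax(w[i_trough + 1 :]))
    if w[i_peak] <= w[i_trough]:
        raise ValueError("waveform has no rising phase after its trough")

    def refine(i: int) -> float:
        if 0 < i < w.size - 1:
            denom = w[i - 1] - 2 * w[i] + w[i + 1]
            if denom != 0:
                return i + 0.5 * (w[i - 1] - w[i + 1]) / denom
        return float(i)

    return (refine(i_peak) - refine(i_trough)) / wf_fs * 1000.0


def classify_units(
    durations_ms: np.ndarray,
    firing_rates: np.ndarray,
    random_state: int = 0,
) -> list[str]:
    """Assign Type A/B labels across a cohort of units.

    2-means on standardised (trough-to-peak, log firing rate); the cluster
    with the smaller mean duration is Type A (narrow, fast).  If both
    cluster mean durations fall on the same side of the 0.4 ms boundary the
    cohort is treated as homogeneous and every unit gets that single label
    (2-means would otherwise force a split of a one-class cohort).
    Invariant to unit ordering and to amplitude rescaling of the waveforms
    (duration and rate are scale-free).  A single unit falls back to the
    fixed 0.4 ms boundary.
    """
    durations_ms = np.asarray(durations_ms, dtype=float)
    firing_rates = np.asarray(firing_rates, dtype=float)
    if durations_ms.size != firing_rates.size:
        raise ValueError("durations and rates must have equal length")
    if durations_ms.size == 0:
        return []
    if durations_ms.size == 1:
        return [classify_unit(durations_ms[0], firing_rates[0])]
    feats = np.column_stack([durations_ms, np.log(np.maximum(firing_rates, 1e-6))])
    std = feats.std(axis=0)
    std[std == 0] = 1.0
    z = (feats - feats.mean(axis=0)) / std
    km = KMeans(n_clusters=2, n_init=10, random_state=random_state)
    labels = km.fit_predict(z)
    mean_dur = [durations_ms[labels == c].mean() for c in (0, 1)]
    sides = [d < SINGLE_UNIT_BOUNDARY_MS for d in mean_dur]
    if sides[0] == sides[1]:  # homogeneous cohort: no real A/B split
        label = "A" if sides[0] else "B"
        return [label] * durations_ms.size
    a_cluster = int(np.argmin(mean_dur))
    return ["A" if lab == a_cluster else "B" for lab in labels]


def classify_unit(duration_ms: float, firing_rate: float) -> str:
    """Single-unit fallback: Type A iff trough-to-peak < 0.4 ms."""
    if not (np.isfinite(duration_ms) and np.isfinite(firing_rate)):
        raise ValueError("classification features must be finite")
    return "A" if duration_ms < SINGLE_UNIT_BOUNDARY_MS else "B"


def isi_histogram(
    train: SpikeTrain | np.ndarray,
    bin_width: float = 0.005,
    max_isi: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of successive inter-spike intervals.

    Returns ``(counts, edges)``; intervals above ``max_isi`` land in the
    final bin so the counts always sum to ``n_spikes - 1``.  Fewer than two
    spikes yield an empty (all-zero) histogram.
    """
    t = train.timestamps if isinstance(train, SpikeTrain) else np.asarray(train)
    edges = np.arange(0.0, max_isi + bin_width, bin_width)
    if t.size < 2:
        return np.zeros(edges.size - 1, dtype=int), edges
    isi = np.clip(np.diff(t), None, edges[-1] - bin_width / 2)
    counts, _ = np.histogram(isi, bins=edges)
    return counts, edges
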