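"""Session data model, HDF5 container, and segment selection.

A *session* is one recording: LFP channels sampled at 1 kHz (recording band
0.5-200 Hz), sorted single-unit spike trains (timestamps in seconds plus
waveform snippets at 20 kHz), and behavioural-state annotations (rest /
locomotion intervals).  All times are seconds from recording start, with
half-open intervals ``[start, start + duration)``.

The on-disk container is HDF5::

    /lfp/<channel_id>/samples, fs, band
    /units/<unit_id>/timestamps, waveforms, wf_fs  (+ attrs)
    /segments                                     (state table)
    /meta                                         (attrs)

Segment selection implements the "six random segments per neurone" rule:
rest segments are fixed-length windows drawn without overlap from the
annotated rest intervals; locomotion segments are whole annotated bouts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "LfpChannel",
    "SpikeTrain",
    "Segment",
    "StateInterval",
    "Session",
    "SessionLoadError",
    "read_session",
    "write_session",
    "select_segments",
    "neuron_mean",
]

_SCHEMA_VERSION = 1


class SessionLoadError(RuntimeError):
    """Raised when an on-disk session container is malformed."""


@dataclass
class LfpChannel:
    """Uniformly sampled extracellular field potential.

    ``samples`` are in microvolts; ``filter_band`` records the acquisition
    band-pass (default 0.5-200 Hz).
    """

    samples: np.ndarray
    fs: float
    filter_band: tuple[float, float] = (0.5, 200.0)
    channel_id: str = "lfp0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must be finite")
        low, high = self.filter_band
        if not low < high:
            raise ValueError("filter band requires low < high")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def time_slice(self, start: float, duration: float) -> np.ndarray:
        """Samples in ``[start, start + duration)``."""
        i0 = int(round(start * self.fs))
        i1 = i0 + int(round(duration * self.fs))
        if i0 < 0 or i1 > self.samples.size:
            raise ValueError("requested slice extends beyond the recording")
        return self.samples[i0:i1]


@dataclass
class SpikeTrain:
    """Timestamps and aligned waveform snippets for one sorted unit."""

    timestamps: np.ndarray
    waveforms: np.ndarray | None = None
    wf_fs: float = 20000.0
    unit_id: str = "unit0"
    channel_id: str = "lfp0"
    unit_type: str = "unclassified"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1:
            raise ValueError("timestamps must be one-dimensional")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.wf_fs <= 0:
            raise ValueError("waveform sample rate must be positive")
        if self.waveforms is not None:
            self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=float))
            if self.waveforms.shape[0] != self.timestamps.size:
                raise ValueError(
                    f"waveform rows ({self.waveforms.shape[0]}) must match "
                    f"timestamp count ({self.timestamps.size})"
                )
        if self.unit_type not in ("A", "B", "unclassified"):
            raise ValueError(f"unknown unit type {self.unit_type!r}")

    @property
    def n_spikes(self) -> int:
        return self.timestamps.size

    def in_interval(self, start: float, duration: float) -> np.ndarray:
        """Timestamps falling in ``[start, start + duration)``."""
        t = self.timestamps
        return t[(t >= start) & (t < start + duration)]

    def mean_rate(self, duration: float) -> float:
        return self.n_spikes / duration


@dataclass(frozen=True)
class Segment:
    """A state-labelled interval from which one analysis value is computed."""

    start: float
    duration: float
    state: str
    segment_id: str = ""

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.state not in ("rest", "locomotion"):
            raise ValueError(f"unknown behavioural state {self.state!r}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class StateInterval:
    """An annotated behavioural-state interval of the recording."""

    state: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("state interval must have positive length")


@dataclass
class Session:
    """One recording session: LFP channels, spike trains, state annotations."""

    lfp: dict[str, LfpChannel]
    units: dict[str, SpikeTrain]
    states: list[StateInterval] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for uid, train in self.units.items():
            if train.channel_id not in self.lfp:
                raise ValueError(
                    f"unit {uid!r} references unknown LFP channel "
                    f"{train.channel_id!r}"
                )

    @property
    def duration(self) -> float:
        return max(ch.duration for ch in self.lfp.values())

    def state_intervals(self, state: str) -> list[StateInterval]:
        return [s for s in self.states if s.state == state]


def write_session(session: Session, path) -> None:
    """Write a session to the HDF5 container (bit-exact round trip)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = _SCHEMA_VERSION
        g_lfp = f.create_group("lfp")
        for cid, ch in session.lfp.items():
            g = g_lfp.create_group(cid)
            g.create_dataset("samples", data=ch.samples)
            g.attrs["fs"] = ch.fs
            g.attrs["filter_band"] = ch.filter_band
        g_units = f.create_group("units")
        for uid, train in session.units.items():
            g = g_units.create_group(uid)
            g.create_dataset("timestamps", data=train.timestamps)
            if train.waveforms is not None:
                g.create_dataset("waveforms", data=train.waveforms)
            g.attrs["wf_fs"] = train.wf_fs
            g.attrs["channel_id"] = train.channel_id
            g.attrs["unit_type"] = train.unit_type
        states = f.create_group("states")
        states.create_dataset(
            "state", data=np.array([s.state for s in session.states], dtype="S16")
        )
        states.create_dataset("start", data=[s.start for s in session.states])
        states.create_dataset("end", data=[s.end for s in session.states])
        meta = f.create_group("meta")
        for key, value in session.metadata.items():
            meta.attrs[key] = value


def read_session(path) -> Session:
    """Load a session, validating the container schema."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != _SCHEMA_VERSION:
            raise SessionLoadError(
                f"unsupported schema version {version!r} (expected {_SCHEMA_VERSION})"
            )
        for group in ("lfp", "units", "states"):
            if group not in f:
                raise SessionLoadError(f"container missing required group '/{group}'")
        lfp: dict[str, LfpChannel] = {}
        for cid, g in f["lfp"].items():
            lfp[cid] = LfpChannel(
                samples=g["samples"][:],
                fs=float(g.attrs["fs"]),
                filter_band=tuple(g.attrs["filter_band"]),
                channel_id=cid,
            )
        units: dict[str, SpikeTrain] = {}
        for uid, g in f["units"].items():
            ts = g["timestamps"][:]
            if np.any(np.diff(ts) <= 0):
                raise SessionLoadError(
                    f"unit {uid!r} has non-monotone timestamps"
                )
            units[uid] = SpikeTrain(
                timestamps=ts,
                waveforms=g["waveforms"][:] if "waveforms" in g else None,
                wf_fs=float(g.attrs["wf_fs"]),
                unit_id=uid,
                channel_id=str(g.attrs["channel_id"]),
                unit_type=str(g.attrs["unit_type"]),
            )
        g = f["states"]
        states = [
            StateInterval(state.decode(), float(start), float(end))
            for state, start, end in zip(g["state"][:], g["start"][:], g["end"][:])
        ]
        metadata = dict(f["meta"].attrs) if "meta" in f else {}
    return Session(lfp=lfp, units=units, states=states, metadata=metadata)


def select_segments(
    session: Session,
    state: str,
    n_segments: int = 6,
    rest_len: float = 10.0,
    rng: np.random.Generator | int | None = None,
) -> list[Segment]:
    """Randomly select non-overlapping analysis segments for one state.

    Rest segments are ``rest_len``-second windows drawn without replacement
    from a tiling of the annotated rest intervals (so non-overlap is
    guaranteed by construction); locomotion segments are whole annotated
    bouts.  Selection is a seeded uniform draw, so a fixed ``rng`` seed is
    fully reproducible.

    Raises
    ------
    ValueError
        If the annotated state time cannot supply ``n_segments`` candidates;
        the message reports the deficit.
    """
    rng = np.random.default_rng(rng)
    if state == "rest":
        candidates: list[tuple[float, float]] = []
        for iv in session.state_intervals(state):
            n_fit = int(math.floor((iv.end - iv.start) / rest_len + 1e-9))
            candidates.extend(
                (iv.start + j * rest_len, rest_len) for j in range(n_fit)
            )
    elif state == "locomotion":
        candidates = [
            (iv.start, iv.end - iv.start) for iv in session.state_intervals(state)
        ]
    else:
        raise ValueError(f"unknown behavioural state {state!r}")
    if len(candidates) < n_segments:
        raise ValueError(
            f"insufficient {state} time: {len(candidates)} candidate "
            f"segment(s) available, {n_segments} requested "
            f"(deficit {n_segments - len(candidates)})"
        )
    chosen = rng.choice(len(candidates), size=n_segments, replace=False)
    chosen = sorted(chosen)
    return [
        Segment(
            start=candidates[i][0],
            duration=candidates[i][1],
            state=state,
            segment_id=f"{state}{rank:02d}",
        )
        for rank, i in enumerate(chosen)
    ]


def neuron_mean(values) -> float:
    """Neuron-level summary: mean of the available per-segment values.

    Per-segment values may be missing (NaN), e.g. segments that failed the
    Rayleigh significance gate or had too few spikes; the mean is then taken
    over the surviving segments only.  If no segment survives, NaN is
    returned and the unit is excluded downstream.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0 or np.all(np.isnan(values)):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmean(values))
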