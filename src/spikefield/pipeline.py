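"""End-to-end orchestration: classify units, select segments, compute the
three synchronisation measures, aggregate to neuron level, compare groups.

Every stage is deterministic given the pipeline seed: segment selection,
SFC spike-count equalisation, and unit sorting all draw from streams spawned
from it.  Results are tidy tables (one row = unit x segment x band x
measure) so the group-statistics layer and figure exports need no special
containers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import classify as uc
from .coherence import CoherenceParams, coherence_for_unit_segment
from .group_stats import GroupComparison, compare_groups
from .io import Session, neuron_mean, select_segments
from .phaselock import GATE_ALPHA, gated_phaselock
from .sfc import EQUALIZE_TARGETS, SfcParams, sfc_for_unit_segment
from .spectral import CANONICAL_BANDS

__all__ = ["PipelineConfig", "analyze_session", "neuron_table", "run_analysis"]

MEASURES = ("coherence", "sfc", "plv")


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis parameters; the defaults are the reference protocol
    (0.5 s / 0.1 s NW=5 K=9 coherence windows; +-500 ms NW=3 K=5 50%-overlap
    SFC with 50/20 spike equalisation; Rayleigh gate at alpha = 0.05;
    six 10-s rest segments per neuron)."""

    bands: tuple[str, ...] = tuple(CANONICAL_BANDS)
    coherence: CoherenceParams = field(default_factory=CoherenceParams)
    sfc: SfcParams = field(default_factory=SfcParams)
    equalize_targets: dict = field(default_factory=lambda: dict(EQUALIZE_TARGETS))
    gate_alpha: float = GATE_ALPHA
    n_segments: int = 6
    rest_len: float = 10.0
    states: tuple[str, ...] = ("rest",)
    measures: tuple[str, ...] = MEASURES
    seed: int = 0


def classify_session_units(session: Session) -> dict[str, str]:
    """Type A/B labels for all units of a session (cohort 2-means)."""
    uids = sorted(session.units)
    durations, rates = [], []
    for uid in uids:
        train = session.units[uid]
        if train.waveforms is None or train.n_spikes == 0:
            durations.append(np.nan)
            rates.append(np.nan)
            continue
        durations.append(uc.trough_to_peak(train.waveforms.mean(axis=0), train.wf_fs))
        rates.append(train.n_spikes / session.duration)
    valid = [i for i, d in enumerate(durations) if np.isfinite(d)]
    labels = uc.classify_units(
        np.asarray(durations)[valid], np.asarray(rates)[valid]
    )
    out = {uid: "unclassified" for uid in uids}
    for i, lab in zip(valid, labels):
        out[uids[i]] = lab
    return out


def analyze_session(
    session: Session,
    config: PipelineConfig = PipelineConfig(),
    session_id: str = "s00",
) -> pd.DataFrame:
    """Compute coherence, SFC and phase-lock per (unit, segment, band).

    Returns a tidy frame with columns: session_id, group, unit_id,
    unit_type, segment_id, state, band, measure, value, rayleigh_p,
    passed_gate, note.  Values that could not be computed (too few spikes,
    gated out) appear as NaN with a note, never as silent omissions.
    """
    labels = classify_session_units(session)
    group = session.metadata.get("group", "")
    master = np.random.SeedSequence([config.seed, abs(hash(session_id)) % (2**31)])
    rows: list[dict] = []
    phase_cache: dict[tuple[float, float, str], np.ndarray | None] = {}
    uids = sorted(session.units)
    unit_seeds = master.spawn(len(uids))
    for u_idx, uid in enumerate(uids):
        train = session.units[uid]
        lfp = session.lfp[train.channel_id]
        for state in config.states:
            seg_rng, sfc_seed = unit_seeds[u_idx].spawn(2)
            try:
                segments = select_segments(
                    session,
                    state,
                    n_segments=config.n_segments,
                    rest_len=config.rest_len,
                    rng=np.random.default_rng(seg_rng),
                )
            except ValueError as exc:
                rows.append(
                    _row(session_id, group, uid, labels[uid], "", state, "", "segments",
                         np.nan, note=str(exc))
                )
                continue
            sfc_rngs = [np.random.default_rng(s) for s in sfc_seed.spawn(len(segments))]
            for s_idx, seg in enumerate(segments):
                coh = (
                    coherence_for_unit_segment(session, uid, seg, config.coherence)
                    if "coherence" in config.measures
                    else None
                )
                sfc_res = (
                    sfc_for_unit_segment(
                        session, uid, seg, rng=sfc_rngs[s_idx], params=config.sfc,
                        target=config.equalize_targets[state],
                    )
                    if "sfc" in config.measures
                    else None
                )
                for band in config.bands:
                    if coh is not None:
                        rows.append(
                            _row(session_id, group, uid, labels[uid], seg.segment_id,
                                 state, band, "coherence",
                                 coh.band_means.get(band, np.nan),
                                 note="" if not coh.is_missing else "zero-variance input")
                        )
                    if "sfc" in config.measures:
                        rows.append(
                            _row(session_id, group, uid, labels[uid], seg.segment_id,
                                 state, band, "sfc",
                                 sfc_res.band_means.get(band, np.nan)
                                 if sfc_res is not None else np.nan,
                                 note="" if sfc_res is not None else "insufficient spikes")
                        )
                    if "plv" not in config.measures:
                        continue
                    pl = _phaselock_cached(
                        session, uid, seg, band, phase_cache, lfp.fs
                    )
                    if pl is None:
                        rows.append(
                            _row(session_id, group, uid, labels[uid], seg.segment_id,
                                 state, band, "plv", np.nan, note="no spikes")
                        )
                    else:
                        rows.append(
                            _row(session_id, group, uid, labels[uid], seg.segment_id,
                                 state, band, "plv",
                                 pl.resultant_length if pl.passed_gate else np.nan,
                                 rayleigh_p=pl.rayleigh_p, passed_gate=pl.passed_gate,
                                 note="" if pl.passed_gate else "gated out")
                        )
    return pd.DataFrame(rows)


def _row(session_id, group, uid, unit_type, segment_id, state, band, measure,
         value, rayleigh_p=np.nan, passed_gate=None, note=""):
    return {
        "session_id": session_id,
        "group": group,
        "unit_id": uid,
        "unit_type": unit_type,
        "segment_id": segment_id,
        "state": state,
        "band": band,
        "measure": measure,
        "value": float(value) if value is not None else np.nan,
        "rayleigh_p": rayleigh_p,
        "passed_gate": passed_gate,
        "note": note,
    }


def _phaselock_cached(session, uid, seg, band, cache, fs):
    """Phase-lock with the band-passed phase series cached per (segment, band)."""
    from .phaselock import PhaseLockResult, mean_phase, rayleigh_test, spike_phases
    from .spectral import CANONICAL_BANDS as BANDS

    key = (seg.start, seg.duration, band)
    if key not in cache:
        from .phaselock import instantaneous_phase

        train0 = session.units[uid]
        lfp = session.lfp[train0.channel_id]
        seg_lfp = lfp.time_slice(seg.start, seg.duration)
        try:
            cache[key] = instantaneous_phase(seg_lfp, fs, band)
        except ValueError:
            cache[key] = None
    phase = cache[key]
    if phase is None:
        return None
    train = session.units[uid]
    spikes = train.in_interval(seg.start, seg.duration)
    if spikes.size == 0:
        return None
    angles = spike_phases(phase, fs, spikes, t0=seg.start)
    angle, r = mean_phase(angles)
    z, p = rayleigh_test(angles)
    return PhaseLockResult(
        angles=angles, mean_angle=angle, resultant_length=r, rayleigh_z=z,
        rayleigh_p=p, band=BANDS[band], passed_gate=p < GATE_ALPHA,
        n_spikes=int(spikes.size), low_n=spikes.size < 5,
    )


def neuron_table(segment_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate segment values to one value per neuron (the segment mean).

    Missing per-segment values (gated-out phase-lock, excluded SFC) are
    skipped; a neuron with no surviving segment keeps NaN and is excluded
    by the group-comparison layer.
    """
    sub = segment_table[segment_table["measure"].isin(MEASURES)]
    grouped = (
        sub.groupby(
            ["session_id", "group", "unit_id", "unit_type", "state", "band",
             "measure"],
            dropna=False,
        )["value"]
        .apply(lambda v: neuron_mean(v.to_numpy()))
        .reset_index()
    )
    return grouped


def run_analysis(
    sessions: dict[str, Session] | list[Session],
    config: PipelineConfig = PipelineConfig(),
    out_dir=None,
) -> dict:
    """Run the full analysis over a set of sessions.

    Returns ``{"segments": DataFrame, "neurons": DataFrame,
    "comparisons": list[GroupComparison], "manifest": dict}``; when
    ``out_dir`` is given, writes segments.csv, neurons.csv,
    comparisons.csv and manifest.json there.  Re-running with the same
    config and sessions reproduces the CSVs exactly.
    """
    if isinstance(sessions, list):
        sessions = {f"s{i:02d}": s for i, s in enumerate(sessions)}
    seg_frames = [
        analyze_session(session, config, session_id=sid)
        for sid, session in sorted(sessions.items())
    ]
    segments = pd.concat(seg_frames, ignore_index=True)
    neurons = neuron_table(segments)
    comparisons: list[GroupComparison] = []
    if neurons["group"].nunique() > 1:
        for (measure, band, unit_type, state), _ in neurons.groupby(
            ["measure", "band", "unit_type", "state"]
        ):
            comp = compare_groups(
                neurons, measure, band, unit_type=unit_type, state=state
            )
            if comp is not None:
                comparisons.append(comp)
    manifest = {
        "n_sessions": len(sessions),
        "session_ids": sorted(sessions),
        "config": _config_dict(config),
        "n_segment_rows": int(len(segments)),
        "n_neuron_rows": int(len(neurons)),
    }
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        segments.to_csv(out / "segments.csv", index=False)
        neurons.to_csv(out / "neurons.csv", index=False)
        _comparisons_frame(comparisons).to_csv(out / "comparisons.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "segments": segments,
        "neurons": neurons,
        "comparisons": comparisons,
        "manifest": manifest,
    }


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["coherence"] = asdict(config.coherence)
    d["sfc"] = asdict(config.sfc)
    return d


def _comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        row = {
            "measure": c.measure,
            "band": c.band,
            "unit_type": c.unit_type,
            "state": c.state,
            "test": c.test,
            "F": c.f_statistic,
            "df1": c.df[0],
            "df2": c.df[1],
            "p": c.p_value,
        }
        for (g1, g2), p in c.pairwise_p.items():
            row[f"p_{g1}_vs_{g2}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
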