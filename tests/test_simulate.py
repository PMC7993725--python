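"""Synthetic-data generator: LFP spectra, coupled spike trains, group studies."""

import numpy as np
import pytest

import spikefield as sf
from spikefield.io import StateInterval
from spikefield.simulate import UnitSpec, CouplingSpec, SessionConfig


def _lfp_config(**kw):
    defaults = dict(duration=60.0, band_amplitudes={}, noise_scale=0.0, seed=1)
    defaults.update(kw)
    return SessionConfig(**defaults)


class TestGenerateLfp:
    def test_single_band_psd_peaks_inside_band(self):
        cfg = _lfp_config(band_amplitudes={"beta": 50.0})
        lfp = sf.generate_lfp(cfg)
        spec = sf.multitaper_psd(lfp.samples, lfp.fs, nw=5, k=9)
        peak = spec.frequencies[np.argmax(spec.power)]
        assert 12.0 <= peak < 30.0

    def test_all_zero_amplitudes_give_silence(self):
        lfp = sf.generate_lfp(_lfp_config())
        assert np.all(lfp.samples == 0)

    def test_one_over_f_slope_matches_periodogram_oracle(self):
        # oracle: plain DFT periodogram of the same realisation, log-log fit
        cfg = _lfp_config(duration=120.0, noise_scale=20.0, noise_exponent=1.0)
        lfp = sf.generate_lfp(cfg)
        x = lfp.samples
        pxx = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(x.size, d=1.0 / lfp.fs)
        sel = (freqs >= 2.0) & (freqs <= 100.0)
        # bin the noisy periodogram into 40 log-spaced bins before fitting
        edges = np.geomspace(2.0, 100.0, 41)
        idx = np.digitize(freqs[sel], edges)
        logf, logp = [], []
        for b in range(1, 41):
            m = idx == b
            if m.sum() > 0:
                logf.append(np.log10(freqs[sel][m].mean()))
                logp.append(np.log10(pxx[sel][m].mean()))
        slope = np.polyfit(logf, logp, 1)[0]
        assert abs(slope + 1.0) < 0.15

    def test_determinism_bit_identical(self):
        cfg = sf.default_session_config(seed=9)
        a, _ = sf.generate_session(cfg)
        b, _ = sf.generate_session(cfg)
        np.testing.assert_array_equal(a.lfp["lfp0"].samples, b.lfp["lfp0"].samples)
        for uid in a.units:
            np.testing.assert_array_equal(
                a.units[uid].timestamps, b.units[uid].timestamps
            )
            np.testing.assert_array_equal(
                a.units[uid].waveforms, b.units[uid].waveforms
            )

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            SessionConfig(duration=0.0)

    def test_overlapping_states_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SessionConfig(duration=50.0,
                          states=(("rest", 0.0, 30.0), ("locomotion", 20.0, 40.0)))


def _one_unit_session(kappa, seed, duration=100.0, rate=10.0, shape=1.0,
                      band="beta"):
    unit = UnitSpec(
        unit_type="A", mean_rate=rate, isi_regularity=shape,
        coupling={"rest": (CouplingSpec(band, kappa),)},
    )
    cfg = SessionConfig(
        duration=duration, units=(unit,),
        states=(("rest", 0.0, duration),), seed=seed,
    )
    return sf.generate_session(cfg)


class TestCoupledSpikeTrain:
    def test_uncoupled_poisson_count(self):
        session, _ = _one_unit_session(kappa=0.0, seed=21, rate=10.0)
        n = session.units["u00"].n_spikes
        # 100 s at 10 Hz: within 3 SD of 1000 under Poisson
        assert abs(n - 1000) < 3 * np.sqrt(1000) + 1

    def test_strong_coupling_centres_phases_on_preferred(self):
        session, _ = _one_unit_session(kappa=5.0, seed=22)
        seg = sf.Segment(0.0, 100.0, "rest", "s")
        res = sf.gated_phaselock(session, "u00", seg, "beta")
        # oracle: exhaustive complex-sum circular mean of the angles
        mean = np.angle(np.exp(1j * res.angles).sum())
        assert abs(mean) < 0.2
        assert abs(res.mean_angle - mean) < 1e-12

    def test_resultant_increases_with_kappa_same_field(self):
        rs = {}
        for kappa in (0.0, 2.0):
            session, _ = _one_unit_session(kappa=kappa, seed=23)
            seg = sf.Segment(0.0, 100.0, "rest", "s")
            rs[kappa] = sf.gated_phaselock(
                session, "u00", seg, "beta"
            ).resultant_length
        assert rs[2.0] > rs[0.0]

    @pytest.mark.parametrize("kappa", [0.0, 1.0, 2.0])
    def test_realised_rate_within_15_percent(self, kappa):
        session, _ = _one_unit_session(kappa=kappa, seed=24, rate=12.0)
        rate = session.units["u00"].n_spikes / 100.0
        assert abs(rate - 12.0) / 12.0 < 0.15

    def test_hard_refractory_never_violated(self):
        for seed in range(5):
            session, _ = _one_unit_session(kappa=2.0, seed=seed, rate=30.0)
            isi = np.diff(session.units["u00"].timestamps)
            assert isi.min() >= 0.002

    def test_empty_state_interval_list_rejected(self):
        lfp = sf.LfpChannel(np.zeros(1000), 1000.0)
        with pytest.raises(ValueError, match="state interval"):
            sf.generate_coupled_spike_train(lfp, UnitSpec(), [], rng=0)

    def test_regular_unit_has_concentrated_isis(self):
        # gamma shape 1 = Poisson (CV 1); shape 8 -> CV ~ 1/sqrt(8)
        _, cv = {}, {}
        for shape in (1.0, 8.0):
            session, _ = _one_unit_session(kappa=0.0, seed=25, rate=8.0,
                                           shape=shape)
            isi = np.diff(session.units["u00"].timestamps)
            cv[shape] = isi.std() / isi.mean()
        assert cv[8.0] < 0.6 < cv[1.0]


class TestCouplingRecoveryMini:
    def test_resultant_monotone_in_kappa(self):
        # averaged over 3 seeds; the full 10-seed sweep with coherence and
        # SFC runs in the acceptance suite
        kappas = (0.0, 0.5, 1.0, 2.0)
        means = []
        for kappa in kappas:
            vals = []
            for seed in range(3):
                session, _ = _one_unit_session(kappa=kappa, seed=30 + seed,
                                               duration=60.0)
                seg = sf.Segment(0.0, 60.0, "rest", "s")
                vals.append(
                    sf.gated_phaselock(session, "u00", seg, "beta").resultant_length
                )
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestGroupStudy:
    def test_unknown_group_rejected(self):
        template = sf.default_session_config(duration=70.0)
        with pytest.raises(ValueError, match="unknown group"):
            sf.generate_group_study(template, {"sham": {}}, 1)

    def test_zero_replicates_yield_empty_bundle(self):
        template = sf.default_session_config(duration=70.0)
        study = sf.generate_group_study(
            template, {"control": {}, "lesioned": {}}, 0
        )
        assert all(v == [] for v in study.values())

    def test_effect_multiplier_recorded_in_truth(self):
        template = sf.default_session_config(
            duration=70.0, n_type_a=1, n_type_b=0, kappa=0.5
        )
        study = sf.generate_group_study(
            template,
            {"control": {}, "lesioned": {("A", "rest", "beta"): 3.0}},
            n_per_group=1, seed=5,
        )
        k_ctrl = study["control"][0][1]["units"]["u00"]["coupling"]["rest"]["beta"]["kappa"]
        k_les = study["lesioned"][0][1]["units"]["u00"]["coupling"]["rest"]["beta"]["kappa"]
        assert k_ctrl == pytest.approx(0.5)
        assert k_les == pytest.approx(1.5)

    def test_lesioned_effect_orders_group_sfc(self):
        # mini version of the end-to-end direction check (3 sessions/group)
        template = sf.default_session_config(
            duration=80.0, n_type_a=2, n_type_b=0, kappa=0.5
        )
        study = sf.generate_group_study(
            template,
            {"control": {}, "lesioned": {("A", "rest", "beta"): 3.0}},
            n_per_group=3, seed=17,
        )
        means = {}
        for group, reps in study.items():
            vals = []
            for session, _ in reps:
                for uid in session.units:
                    res = sf.sfc_for_unit_segment(
                        session, uid, sf.Segment(5.0, 10.0, "rest", "s"), rng=1
                    )
                    if res is not None:
                        vals.append(res.band_means["beta"])
            means[group] = np.mean(vals)
        assert means["lesioned"] > means["control"]
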