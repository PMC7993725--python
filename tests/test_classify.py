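"""Spike-train cleaning, waveform sorting, and Type A/B classification."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import spikefield as sf
from spikefield.classify import (
    clean_spike_train,
    cluster_separation_test,
    isi_histogram,
    snr,
    snr_filter,
    sort_waveforms,
)
from spikefield.simulate import make_waveform_template


def _train(times, waveforms=None):
    return sf.SpikeTrain(np.asarray(times, dtype=float), waveforms=waveforms)


class TestCleaning:
    def test_short_isi_removes_later_spike(self):
        cleaned, log = clean_spike_train(_train([1.000, 1.0015, 1.010]))
        np.testing.assert_allclose(cleaned.timestamps, [1.000, 1.010])
        assert log.n_isi_removed == 1

    def test_no_violations_is_identity(self):
        cleaned, log = clean_spike_train(_train([0.1, 0.2, 0.3]))
        np.testing.assert_array_equal(cleaned.timestamps, [0.1, 0.2, 0.3])
        assert log.n_isi_removed == log.n_artifact_removed == 0

    def test_burst_keeps_only_first_spike(self):
        burst = 1.0 + 0.001 * np.arange(5)
        cleaned, _ = clean_spike_train(_train(burst))
        # oracle: brute-force pairwise scan — no surviving pair closer than 2 ms
        t = cleaned.timestamps
        assert all(abs(a - b) >= 0.002 for i, a in enumerate(t) for b in t[:i])
        np.testing.assert_allclose(t, [1.0])

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 10, 500))
        t = t[np.concatenate([[True], np.diff(t) > 0])]
        once, _ = clean_spike_train(_train(t))
        twice, log = clean_spike_train(once)
        np.testing.assert_array_equal(once.timestamps, twice.timestamps)
        assert log.n_isi_removed == 0

    def test_cross_channel_artifact_removed(self):
        # a spike present on all other channels within +-0.5 ms is an artifact
        t = [1.0, 2.0, 3.0]
        others = [np.array([2.0001, 8.0]), np.array([1.9997, 9.0])]
        cleaned, log = clean_spike_train(
            _train(t), other_channel_trains=others
        )
        np.testing.assert_allclose(cleaned.timestamps, [1.0, 3.0])
        assert log.n_artifact_removed == 1


class TestSnr:
    def test_keep_above_threshold(self):
        wf = np.tile([50.0, -50.0], (10, 1))  # peak-to-trough 100
        assert snr(wf, noise_rms=20.0) == pytest.approx(2.5)
        assert snr_filter(_train(np.arange(10) * 0.1 + 0.1, wf), 20.0)

    def test_drop_below_threshold(self):
        wf = np.tile([30.0, -30.0], (10, 1))  # peak-to-trough 60 -> SNR 1.5
        assert not snr_filter(_train(np.arange(10) * 0.1 + 0.1, wf), 20.0)

    def test_boundary_snr_exactly_two_is_dropped(self):
        wf = np.tile([40.0, -40.0], (10, 1))  # SNR exactly 2
        assert not snr_filter(_train(np.arange(10) * 0.1 + 0.1, wf), 20.0)

    def test_zero_noise_rejected(self):
        with pytest.raises(ValueError):
            snr(np.ones((3, 4)), 0.0)


class TestSortWaveforms:
    def _two_template_cohort(self, n_each=60, noise=4.0, seed=0):
        rng = np.random.default_rng(seed)
        a = make_waveform_template("A")
        b = make_waveform_template("B")
        wfs = np.concatenate([
            a[None, :] + noise * rng.standard_normal((n_each, a.size)),
            b[None, :] + noise * rng.standard_normal((n_each, b.size)),
        ])
        truth = np.array([0] * n_each + [1] * n_each)
        return wfs, truth

    def test_recovers_planted_clusters(self):
        wfs, truth = self._two_template_cohort()
        labels, _, _ = sort_waveforms(wfs, 2)
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_single_cluster_case(self):
        wfs, _ = self._two_template_cohort(n_each=10)
        labels, _, _ = sort_waveforms(wfs, 1)
        assert np.all(labels == labels[0])

    def test_deterministic_given_seed(self):
        wfs, _ = self._two_template_cohort()
        l1, _, _ = sort_waveforms(wfs, 2)
        l2, _, _ = sort_waveforms(wfs, 2)
        np.testing.assert_array_equal(l1, l2)

    def test_degenerate_waveforms_fall_back_to_one_cluster(self):
        wfs = np.tile(make_waveform_template("A"), (25, 1))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            labels, _, _ = sort_waveforms(wfs, 2)
        assert np.all(labels == 0)


class TestClusterSeparation:
    def test_gross_separation_is_highly_significant(self, rng):
        a = rng.standard_normal((80, 3))
        b = rng.standard_normal((80, 3)) + 10.0
        scores = np.vstack([a, b])
        labels = np.array([0] * 80 + [1] * 80)
        f, p, distinct = cluster_separation_test(scores, labels)
        assert p < 1e-6 and distinct and f > 100

    def test_permutation_null_calibration(self, rng):
        # with labels random, rejections at alpha=0.05 should run near 5%
        scores = rng.standard_normal((60, 3))
        rejections = 0
        n_perm = 300
        for _ in range(n_perm):
            labels = rng.permutation([0] * 30 + [1] * 30)
            _, p, _ = cluster_separation_test(scores, labels)
            rejections += p < 0.05
        assert 0.01 <= rejections / n_perm <= 0.10

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="two clusters"):
            cluster_separation_test(np.zeros((10, 3)), np.zeros(10))

    def test_tiny_cluster_rejected(self):
        scores = np.random.default_rng(1).standard_normal((12, 3))
        labels = np.array([0] * 10 + [1] * 2)  # 2 < dims+1
        with pytest.raises(ValueError, match="singular"):
            cluster_separation_test(scores, labels)


class TestTroughToPeak:
    def test_sample_grid_arithmetic(self):
        # symmetric extrema so parabolic refinement lands on the grid
        w = np.zeros(32)
        w[9], w[10], w[11] = -50.0, -80.0, -50.0
        w[14], w[15], w[16] = 30.0, 40.0, 30.0
        assert sf.trough_to_peak(w, 20000.0) == pytest.approx(0.25)

    def test_type_b_template_recovers_construction_value(self):
        w = make_waveform_template("B")
        assert sf.trough_to_peak(w, 20000.0) == pytest.approx(0.60, abs=0.05)

    def test_interpolated_matches_dense_oversampling_oracle(self):
        # oracle: evaluate the analytic template on a 100x finer grid
        fine_fs = 2_000_000.0
        fine = make_waveform_template("A", wf_fs=fine_fs)
        i_tr = np.argmin(fine)
        i_pk = i_tr + np.argmax(fine[i_tr:])
        oracle_ms = (i_pk - i_tr) / fine_fs * 1000.0
        coarse = make_waveform_template("A")
        assert abs(sf.trough_to_peak(coarse, 20000.0) - oracle_ms) < 0.05

    def test_monotone_waveform_rejected(self):
        with pytest.raises(ValueError):
            sf.trough_to_peak(np.arange(10.0)[::-1], 20000.0)


class TestClassifyUnits:
    def test_cohort_members_classified_by_construction(self, rng):
        dur = np.concatenate([rng.normal(0.25, 0.03, 10), rng.normal(0.60, 0.05, 8)])
        rate = np.concatenate([rng.lognormal(np.log(12), 0.3, 10),
                               rng.lognormal(np.log(4), 0.3, 8)])
        labels = sf.classify_units(dur, rate)
        assert labels[:10] == ["A"] * 10
        assert labels[10:] == ["B"] * 8

    def test_single_unit_fallback_boundary(self):
        assert sf.classify_unit(0.25, 12.0) == "A"
        assert sf.classify_unit(0.60, 4.0) == "B"

    def test_invariant_to_unit_ordering(self, rng):
        dur = np.concatenate([rng.normal(0.25, 0.03, 7), rng.normal(0.60, 0.05, 7)])
        rate = np.concatenate([rng.lognormal(np.log(12), 0.3, 7),
                               rng.lognormal(np.log(4), 0.3, 7)])
        labels = sf.classify_units(dur, rate)
        perm = rng.permutation(14)
        permuted = sf.classify_units(dur[perm], rate[perm])
        assert [labels[i] for i in perm] == permuted

    def test_homogeneous_cohort_gets_single_label(self, rng):
        dur = rng.normal(0.25, 0.02, 12)
        rate = rng.lognormal(np.log(12), 0.2, 12)
        assert sf.classify_units(dur, rate) == ["A"] * 12


class TestIsiHistogram:
    def test_regular_spiking_occupies_one_bin(self):
        t = np.arange(100) * 0.1
        counts, edges = isi_histogram(_train(t), bin_width=0.008, max_isi=0.5)
        assert counts.sum() == 99
        occupied = np.nonzero(counts)[0]
        assert occupied.size == 1
        assert edges[occupied[0]] <= 0.1 < edges[occupied[0] + 1]

    def test_poisson_isis_are_exponential(self):
        rng = np.random.default_rng(8)
        lam = 10.0
        t = np.cumsum(rng.exponential(1 / lam, 2000))
        counts, edges = isi_histogram(_train(t), bin_width=0.01, max_isi=0.5)
        # analytic exponential law per bin (tail mass folded into last bin)
        cdf = 1 - np.exp(-lam * edges)
        probs = np.diff(cdf)
        probs[-1] += 1 - cdf[-1]
        expected = probs * counts.sum()
        keep = expected > 5  # chi-square validity
        chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_counts_conserved(self, rng):
        t = np.sort(rng.uniform(0, 50, 300))
        counts, _ = isi_histogram(_train(t))
        assert counts.sum() == 299

    def test_under_two_spikes_empty(self):
        counts, _ = isi_histogram(_train([1.0]))
        assert counts.sum() == 0
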