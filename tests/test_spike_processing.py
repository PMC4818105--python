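"""Spike detection, latency measurement, clustering, and response labelling."""

import numpy as np
import pytest

import elstim as el
from elstim.errors import DegenerateClusterError, InvalidParameterError


def _trace_with_spikes(peak_times_ms, sample_rate=25_000.0, dur_s=0.05, amp=20.0):
    """Resting potential -60 mV with triangular spike waveforms inserted."""
    n = int(dur_s * sample_rate)
    v = np.full(n, -60.0)
    half = 10  # samples of rise/fall
    for t in peak_times_ms:
        i = int(round(t * 1e-3 * sample_rate))
        for k in range(-half, half + 1):
            v[i + k] = max(v[i + k], -60.0 + (amp + 60.0) * (1 - abs(k) / half))
    return v


class TestDetectSpikes:
    def test_flat_trace_detects_nothing(self):
        trace = el.MembraneTrace(np.full(1000, -60.0))
        assert el.detect_spikes(trace, threshold=0.0).spike_times.size == 0

    def test_inserted_spikes_found_at_peaks_despite_artefacts(self):
        """Three inserted spikes at 10/20/30 ms are recovered at the peak
        sample; artefact pulses inside the blank windows are erased."""
        sr = 25_000.0
        v = _trace_with_spikes([10.0, 20.0, 30.0], sample_rate=sr)
        onsets = np.array([0.005, 0.015, 0.025])  # s
        blank = 0.0015
        for onset in onsets:  # inject huge artefacts inside blank windows
            i0 = int(onset * sr)
            v[i0 + 2 : i0 + 20] = 200.0
        trace = el.MembraneTrace(v, sample_rate=sr, stimulus_onsets=onsets, blank_duration=blank)
        spikes = el.detect_spikes(trace, threshold=0.0)
        assert spikes.spike_times.size == 3
        np.testing.assert_allclose(spikes.spike_times, [0.010, 0.020, 0.030], atol=1.5 / sr)

    def test_plateau_yields_single_spike_at_first_maximal_sample(self):
        v = np.full(100, -60.0)
        v[40:45] = 10.0  # 5-sample plateau
        trace = el.MembraneTrace(v, sample_rate=1000.0)
        spikes = el.detect_spikes(trace, threshold=0.0)
        assert spikes.spike_times.size == 1
        assert spikes.spike_times[0] == pytest.approx(40 / 1000.0)

    def test_artefact_only_trace_is_empty_above_blank_value(self):
        sr = 25_000.0
        v = np.full(500, -60.0)
        onsets = np.array([0.004, 0.012])
        for onset in onsets:
            i0 = int(onset * sr)
            v[i0 : i0 + 10] = 150.0
        trace = el.MembraneTrace(v, sample_rate=sr, stimulus_onsets=onsets, blank_duration=0.0005)
        assert el.detect_spikes(trace, threshold=0.0).spike_times.size == 0


class TestComputeLatencies:
    def test_hand_examples_with_boundary_convention(self):
        spikes = el.SpikeTrain(np.array([0.002, 0.1019]))
        lists, dropped = el.compute_latencies(spikes, np.array([0.0, 0.1]))
        assert dropped == 0
        np.testing.assert_allclose(lists[0], [2.0])
        np.testing.assert_allclose(lists[1], [1.9])
        # spike exactly at an offset gets latency 0 on that offset
        lists, _ = el.compute_latencies(el.SpikeTrain(np.array([0.1])), np.array([0.0, 0.1]))
        assert lists[0].size == 0 and lists[1][0] == pytest.approx(0.0)

    def test_spikes_before_first_offset_dropped_and_counted(self):
        lists, dropped = el.compute_latencies(
            el.SpikeTrain(np.array([0.01, 0.21])), np.array([0.1, 0.2])
        )
        assert dropped == 1
        np.testing.assert_allclose(lists[1], [10.0])

    def test_matches_brute_force_assignment(self):
        rng = np.random.default_rng(42)
        offsets = np.sort(rng.uniform(0, 10, 200))
        offsets = offsets[np.diff(offsets, prepend=-1) > 1e-6]
        spikes = np.sort(rng.uniform(0, 10.5, 1000))
        lists, dropped = el.compute_latencies(el.SpikeTrain(spikes), offsets)
        # brute force: all-pairs latest-offset-at-or-before
        expected = [[] for _ in offsets]
        exp_dropped = 0
        for t in spikes:
            j = None
            for i, o in enumerate(offsets):
                if o <= t:
                    j = i
            if j is None:
                exp_dropped += 1
            else:
                expected[j].append((t - offsets[j]) * 1e3)
        assert dropped == exp_dropped
        for got, exp in zip(lists, expected):
            np.testing.assert_allclose(got, exp)


class TestClusterLatencies:
    def test_short_and_long_gaussian_clusters_recovered(self):
        """Bimodal latencies (direct ~1.95 ms, network ~12 ms) are separated
        with < 1% misassignment; mean errors stay within the sampling error of
        500 draws per cluster."""
        rng = np.random.default_rng(0)
        a = rng.normal(1.95, 0.3, 500)
        b = rng.normal(12.0, 2.0, 500)
        cl = el.cluster_latencies(np.concatenate([a, b]), k=2, seed=0)
        assert abs(cl.means[0] - 1.95) <= 0.15
        assert abs(cl.means[1] - 12.0) <= 0.30
        truth = np.r_[np.zeros(500, int), np.ones(500, int)]
        assert (cl.assignments != truth).mean() < 0.01
        lo, hi = cl.short_window
        assert lo == pytest.approx(cl.means[0] - 2 * cl.sds[0], abs=1e-9)

    def test_identical_latencies_single_degenerate_cluster(self):
        cl = el.cluster_latencies(np.full(10, 3.0), k=1)
        assert cl.means[0] == pytest.approx(3.0)
        assert cl.sds[0] == 0.0
        assert cl.short_window == (3.0, 3.0)

    def test_perfectly_separated_values_split_exactly(self):
        cl = el.cluster_latencies(np.array([1.0, 1, 1, 10, 10, 10]), k=2, seed=1)
        np.testing.assert_allclose(cl.means, [1.0, 10.0])
        np.testing.assert_array_equal(cl.assignments, [0, 0, 0, 1, 1, 1])

    def test_relabelled_clusters_are_order_invariant(self):
        rng = np.random.default_rng(3)
        lat = np.concatenate([rng.normal(2, 0.3, 80), rng.normal(9, 1.0, 80)])
        c1 = el.cluster_latencies(lat, k=2, seed=0)
        perm = rng.permutation(lat.size)
        c2 = el.cluster_latencies(lat[perm], k=2, seed=0)
        np.testing.assert_allclose(np.sort(c1.means), np.sort(c2.means), atol=1e-9)
        np.testing.assert_array_equal(c1.assignments[perm], c2.assignments)

    def test_too_few_distinct_values_raise(self):
        with pytest.raises(DegenerateClusterError):
            el.cluster_latencies(np.array([1.0, 1.0, 1.0]), k=2)

    def test_choose_k_heuristic(self):
        rng = np.random.default_rng(5)
        bimodal = np.concatenate([rng.normal(2, 0.3, 100), rng.normal(12, 1.5, 100)])
        unimodal = rng.normal(2, 0.3, 200)
        assert el.choose_k(bimodal) == 2
        assert el.choose_k(unimodal) == 1


class TestLabelResponses:
    clusters = el.LatencyClusters(
        k=2,
        means=np.array([1.95, 8.0]),
        sds=np.array([0.35, 1.0]),
        assignments=np.zeros(1, int),
        short_window=(0.9, 3.0),
    )

    def test_short_and_long_window_assignment(self):
        resp = el.label_responses(
            [np.array([1.8]), np.array([7.9]), np.array([]), np.array([1.8, 7.9])],
            self.clusters,
        )
        np.testing.assert_array_equal(resp.short, [1, 0, 0, 1])
        np.testing.assert_array_equal(resp.long, [0, 1, 0, 1])

    def test_duplicate_latencies_do_not_double_count(self):
        resp = el.label_responses([np.array([2.0, 2.0, 2.0])], self.clusters)
        assert resp.short.sum() == 1

    def test_long_labels_need_two_clusters(self):
        one = el.LatencyClusters(
            k=1, means=np.array([2.0]), sds=np.array([0.3]),
            assignments=np.zeros(1, int), short_window=(1.4, 2.6),
        )
        with pytest.raises(InvalidParameterError):
            el.label_responses([np.array([2.0])], one, want_long=True)
        resp = el.label_responses([np.array([2.0])], one, want_long=False)
        assert resp.long is None

    def test_simulated_labels_recovered_from_latencies(self):
        """Round trip through the simulator: cluster the pooled latencies, then
        re-label presentations; agreement with the generative labels is >= 99%
        at the default 4+ SD cluster separation."""
        array = el.default_array()
        cell = el.make_cell(array, [1.75, 1.75], seed=2)
        ens = el.sample_white_noise(4000, 20, 120.0, seed=3)
        rec = el.simulate_responses(cell, ens, seed=4)
        pooled = np.concatenate([l for l in rec.responses.latencies if l.size])
        clusters = el.cluster_latencies(pooled, k=2, seed=0)
        relabelled = el.label_responses(rec.responses.latencies, clusters)
        agree_short = (relabelled.short == rec.responses.short).mean()
        agree_long = (relabelled.long == rec.responses.long).mean()
        assert agree_short >= 0.99
        assert agree_long >= 0.99
        # recovered cluster means match the generative latency means
        assert abs(clusters.means[0] - cell.latency_short[0]) <= 0.2
        assert abs(clusters.means[1] - cell.latency_long[0]) <= 0.2
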