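"""Cross-correlogram construction, central-bin z-scores, and labeling."""

import numpy as np
import pytest

import der
from der import (
    CCGMatrix,
    ClusterMeta,
    DERConfig,
    ZMatrix,
    central_z,
    compute_ccg_matrix,
    label_suspicious_pairs,
    run_part3,
)
from der.errors import ConfigError
from conftest import make_channels, make_session

CHANNELS = make_channels(n_bundles=2, bundle_size=2)


def brute_force_ccg(session, t_bin_us=500, n_bins=81):
    """Independent all-pairs oracle via the full lag matrix."""
    cluster_ids = np.array(sorted(session.clusters), dtype=np.int64)
    K = len(cluster_ids)
    half = (n_bins - 1) // 2
    t_max = (t_bin_us * n_bins) // 2
    t = session.timestamp_us
    cl = np.searchsorted(cluster_ids, session.cluster_id.astype(np.int64))
    n = len(t)
    raw = np.zeros((K, K, n_bins), dtype=np.int64)
    lag = t[None, :] - t[:, None]                       # lag[i, j] = t_j - t_i
    later = np.triu(np.ones((n, n), dtype=bool), k=1)   # j after i in sort order
    ok = later & (lag < t_max) & (cl[:, None] != cl[None, :])
    ii, jj = np.nonzero(ok)
    bins = half + (lag[ii, jj] + t_bin_us // 2) // t_bin_us
    for i, j, b in zip(ii, jj, bins):
        raw[cl[i], cl[j], b] += 1
    return raw + raw.transpose(1, 0, 2)[:, :, ::-1]


def random_session(rng, n_clusters=5, n_spikes=200, duration_us=10_000_000):
    events = []
    for c in range(n_clusters):
        times = rng.integers(0, duration_us, size=n_spikes)
        events += [(int(t), c % 4, c, 50.0) for t in times]
    return make_session(events, channels=CHANNELS, duration_us=duration_us)


class TestCCGConstruction:
    def test_single_pair_lands_in_central_bin(self):
        session = make_session([(1000, 0, 0, 50.0), (1100, 1, 1, 50.0)],
                               channels=CHANNELS)
        ccg = compute_ccg_matrix(session)
        assert ccg.counts[0, 1, ccg.central_bin] == 1
        assert ccg.counts.sum() == 2  # the same pair mirrored
        assert ccg.counts[1, 0, ccg.central_bin] == 1

    def test_skew_symmetry_on_random_fixture(self):
        session = random_session(np.random.default_rng(0))
        ccg = compute_ccg_matrix(session)
        assert np.array_equal(ccg.counts,
                              ccg.counts.transpose(1, 0, 2)[:, :, ::-1])

    def test_streaming_equals_bruteforce(self):
        rng = np.random.default_rng(1)
        session = random_session(rng)
        ccg = compute_ccg_matrix(session)
        assert np.array_equal(ccg.counts, brute_force_ccg(session))

    def test_diagonal_excluded(self):
        session = make_session([(1000, 0, 0, 50.0), (1100, 0, 0, 50.0)],
                               channels=CHANNELS)
        ccg = compute_ccg_matrix(session)
        assert ccg.counts.sum() == 0

    def test_even_bin_count_rejected(self):
        session = make_session([(1000, 0, 0, 50.0)], channels=CHANNELS)
        with pytest.raises(ConfigError):
            compute_ccg_matrix(session, n_bins=80)


class TestCentralZ:
    def _ccg(self, counts_pair):
        counts = np.zeros((2, 2, 81), dtype=np.int64)
        counts[0, 1] = counts_pair
        counts[1, 0] = counts_pair[::-1]
        return CCGMatrix(counts=counts, t_bin_us=500, n_bins=81,
                         cluster_ids=np.array([0, 1]))

    def test_flat_correlogram_scores_zero(self):
        z = central_z(self._ccg(np.full(81, 4)))
        assert z.z[0, 1] == 0.0
        assert not z.degenerate.any()

    def test_arithmetic_forced_case(self):
        # other bins: forty 1s and forty 3s -> mean 2, std 1; central 10 -> z 8
        pair = np.empty(81, dtype=np.int64)
        pair[:40] = 1
        pair[41:] = 3
        pair[40] = 10
        z = central_z(self._ccg(pair))
        assert z.z[0, 1] == pytest.approx(8.0)

    def test_degenerate_flagged_as_suspicious(self):
        pair = np.zeros(81, dtype=np.int64)
        pair[40] = 3
        z = central_z(self._ccg(pair))
        assert z.degenerate[0, 1]
        assert z.suspicious(z_thr=1e9)[0, 1]


def two_cluster_session(class_a, class_b, same_bundle, n_coincident=4,
                        amp_a=80.0, amp_b=50.0):
    """Two clusters with coincident spikes (|dt| = 100 us) plus lone spikes."""
    ch_b = 1 if same_bundle else 2
    events = []
    for k in range(n_coincident):
        t = 1_000_000 * (k + 1)
        events.append((t, 0, 0, amp_a))
        events.append((t + 100, ch_b, 1, amp_b))
    events.append((8_000_000, 0, 0, amp_a))       # non-coincident extras
    events.append((8_500_000, ch_b, 1, amp_b))
    clusters = {
        0: ClusterMeta(cluster_id=0, channel_id=0, class_label=class_a,
                       extraction_threshold_uV=10.0),
        1: ClusterMeta(cluster_id=1, channel_id=ch_b, class_label=class_b,
                       extraction_threshold_uV=10.0),
    }
    return make_session(events, clusters=clusters, channels=CHANNELS)


def forced_z():
    return ZMatrix(z=np.array([[0.0, 6.0], [6.0, 0.0]]),
                   degenerate=np.zeros((2, 2), dtype=bool),
                   cluster_ids=np.array([0, 1]))


class TestLabeling:
    def _flagged(self, session):
        records = label_suspicious_pairs(session, forced_z(), z_thr=5.0)
        idx = session.index_of([r.event_id for r in records]) \
            if records else np.zeros(0, dtype=int)
        return records, set(session.cluster_id[idx].tolist())

    def test_artifact_pair_labels_both_clusters(self):
        session = two_cluster_session("artifact", "SU", same_bundle=True)
        records, clusters = self._flagged(session)
        assert clusters == {0, 1}
        assert len(records) == 8  # 4 coincidences x 2 events
        assert all(r.rules == ("table3_case1",) for r in records)

    def test_different_bundles_labels_both(self):
        session = two_cluster_session("SU", "SU", same_bundle=False)
        records, clusters = self._flagged(session)
        assert clusters == {0, 1}
        assert all(r.rules == ("table3_case2",) for r in records)

    def test_su_mu_same_bundle_labels_only_mu(self):
        session = two_cluster_session("SU", "MU", same_bundle=True)
        records, clusters = self._flagged(session)
        assert clusters == {1}
        assert len(records) == 4
        assert all(r.rules == ("table3_case3",) for r in records)

    def test_same_class_same_bundle_labels_lower_snr_cluster(self):
        # amp 80 vs 50 at threshold 10: cluster 1 has the lower mean SNR
        session = two_cluster_session("SU", "SU", same_bundle=True)
        records, clusters = self._flagged(session)
        assert clusters == {1}
        assert all(r.rules == ("table3_case4",) for r in records)

    def test_only_central_bin_coincidences_labeled(self):
        # spikes 400 us apart are outside the +/-250 us central bin
        session = two_cluster_session("artifact", "SU", same_bundle=True)
        shifted = session.with_timestamps(
            session.timestamp_us + 300 * (session.cluster_id == 1))
        records = label_suspicious_pairs(shifted, forced_z(), 5.0)
        assert records == []


class TestRunPart3:
    def test_duplicated_unit_lower_snr_twin_flagged(self, small_contaminated):
        session, truth = small_contaminated
        records = run_part3(session, DERConfig())
        flagged = {r.event_id for r in records}
        twin_ids = session.event_id[truth.tag == "duplicated_unit"]
        caught = sum(1 for e in twin_ids if int(e) in flagged)
        assert caught / len(twin_ids) >= 0.95

    def test_independent_low_rate_clusters_stay_below_threshold(self):
        # six independent Poisson units at <= 2 Hz over 25 minutes
        rng = np.random.default_rng(123)
        duration_us = 1_500_000_000
        events = []
        for c, rate in enumerate(np.linspace(0.3, 2.0, 6)):
            n = rng.poisson(rate * 1500)
            for t in rng.integers(0, duration_us, size=n):
                events.append((int(t), c % 4, c, 50.0))
        session = make_session(events, channels=CHANNELS,
                               duration_us=duration_us)
        ccg = compute_ccg_matrix(session)
        zm = central_z(ccg)
        assert not zm.suspicious(5.0).any()

    def test_single_cluster_session_is_empty(self):
        session = make_session([(1000 * k, 0, 0, 50.0) for k in range(10)],
                               channels=CHANNELS)
        assert run_part3(session, DERConfig()) == []

    def test_flagged_fraction_monotone_in_z_thr(self, small_contaminated):
        session, _ = small_contaminated
        ccg = compute_ccg_matrix(session)
        zm = central_z(ccg)
        sizes = [len(label_suspicious_pairs(session, zm, z)) for z in
                 (2.0, 5.0, 10.0, 50.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_z_of_flagged_pairs_drops_after_removal(self, small_contaminated):
        session, _ = small_contaminated
        cfg = DERConfig()
        ccg = compute_ccg_matrix(session)
        zm = central_z(ccg)
        suspicious = np.argwhere(np.triu(zm.suspicious(cfg.z_thr), k=1))
        assert len(suspicious)
        records = label_suspicious_pairs(session, zm, cfg.z_thr)
        flagged = {r.event_id for r in records}
        keep = ~np.isin(session.event_id,
                        np.fromiter(flagged, np.int64, len(flagged)))
        cleaned = session.subset(keep)
        zm2 = central_z(compute_ccg_matrix(cleaned))
        assert np.array_equal(zm2.cluster_ids, zm.cluster_ids)
        inf = 1e12
        for a, b in suspicious:
            z_before = inf if zm.degenerate[a, b] else zm.z[a, b]
            z_after = inf if zm2.degenerate[a, b] else zm2.z[a, b]
            assert z_after <= z_before + 1e-9
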