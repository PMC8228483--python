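"""Data model invariants and container round trips."""

import dataclasses

import h5py
import numpy as np
import pytest
from scipy.io import savemat

import der
from der import (
    DERConfig,
    DetectionRecord,
    SessionData,
    read_channel_map,
    read_combinato,
    read_detections,
    read_session,
    read_waveclus,
    write_channel_map,
    write_cleaned_session,
    write_detections,
    write_session,
)
from der.errors import (
    ConfigError,
    FormatError,
    ReferentialIntegrityError,
    ShapeError,
)
from conftest import make_channels, make_session, spike_waveform


@pytest.fixture
def channel_map_file(tmp_path):
    path = tmp_path / "map.csv"
    write_channel_map(make_channels(), path)
    return path


class TestSessionData:
    def test_events_sorted_by_time_then_channel_then_id(self):
        session = make_session([
            (500, 1, 1, 50.0), (100, 0, 0, 50.0), (500, 0, 0, 50.0),
        ])
        assert session.timestamp_us.tolist() == [100, 500, 500]
        assert session.channel_id.tolist() == [0, 0, 1]

    def test_polarity_contradiction_rejected(self):
        session = make_session([(0, 0, 0, 60.0)])
        with pytest.raises(ShapeError):
            SessionData(
                event_id=session.event_id, channel_id=session.channel_id,
                cluster_id=session.cluster_id, timestamp_us=session.timestamp_us,
                polarity=-session.polarity, waveforms=session.waveforms,
                clusters=session.clusters, channels=session.channels,
                duration_us=session.duration_us)

    def test_unresolved_cluster_rejected(self):
        session = make_session([(0, 0, 0, 60.0)])
        with pytest.raises(ReferentialIntegrityError):
            SessionData(
                event_id=session.event_id, channel_id=session.channel_id,
                cluster_id=session.cluster_id + 99,
                timestamp_us=session.timestamp_us, polarity=session.polarity,
                waveforms=session.waveforms, clusters=session.clusters,
                channels=session.channels, duration_us=session.duration_us)

    def test_mean_snr_is_mean_event_snr(self):
        session = make_session([(0, 0, 0, 50.0), (1000, 0, 0, 70.0)],
                               threshold=10.0)
        # event SNRs 5 and 7
        assert session.clusters[0].mean_snr == pytest.approx(6.0, rel=1e-5)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            DERConfig(n_bins=80).validate()
        with pytest.raises(ConfigError):
            DERConfig(z_thr=-1).validate()
        assert DERConfig().validate().n_bins == 81

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = DERConfig(z_thr=4.0, detect_same_channel=False)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert DERConfig.from_yaml(path) == cfg


class TestSessionContainer:
    def test_empty_container_round_trip(self, tmp_path, channel_map_file):
        session = make_session([])
        path = tmp_path / "s.h5"
        write_session(session, path)
        back = read_session(path, channel_map_file)
        assert back.n_events == 0
        assert back.duration_us == session.duration_us

    def test_simulator_round_trip_is_exact(self, tmp_path, small_clean):
        session, _ = small_clean
        path = tmp_path / "s.h5"
        map_path = tmp_path / "map.csv"
        write_session(session, path)
        write_channel_map(session.channels, map_path)
        back = read_session(path, map_path)
        assert np.array_equal(back.event_id, session.event_id)
        assert np.array_equal(back.timestamp_us, session.timestamp_us)
        assert np.array_equal(back.cluster_id, session.cluster_id)
        assert np.array_equal(back.polarity, session.polarity)
        assert np.array_equal(back.waveforms, session.waveforms)
        assert back.clusters.keys() == session.clusters.keys()
        for cid in session.clusters:
            assert dataclasses.asdict(back.clusters[cid]) == pytest.approx(
                dataclasses.asdict(session.clusters[cid]))

    def test_narrow_waveforms_rejected(self, tmp_path, channel_map_file):
        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.attrs["duration_us"] = 1000
            g = f.create_group("channels/0")
            g.create_dataset("event_ids", data=np.arange(2))
            g.create_dataset("timestamps_us", data=np.array([0, 10]))
            g.create_dataset("cluster_ids", data=np.zeros(2, np.int32))
            g.create_dataset("polarity", data=np.ones(2, np.int8))
            g.create_dataset("waveforms", data=np.ones((2, 48)))
        with pytest.raises(ShapeError):
            read_session(path, channel_map_file)

    def test_missing_dataset_names_path(self, tmp_path, channel_map_file):
        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.attrs["duration_us"] = 1000
            g = f.create_group("channels/0")
            g.create_dataset("event_ids", data=np.arange(1))
        with pytest.raises(FormatError, match="channels/0"):
            read_session(path, channel_map_file)

    def test_unresolved_cluster_id_rejected(self, tmp_path, channel_map_file):
        session = make_session([(0, 0, 0, 60.0)])
        path = tmp_path / "s.h5"
        write_session(session, path)
        with h5py.File(path, "r+") as f:
            del f["clusters/0"]
        with pytest.raises(ReferentialIntegrityError):
            read_session(path, channel_map_file)

    def test_channel_map_spanning_hemispheres_rejected(self, tmp_path):
        path = tmp_path / "map.csv"
        path.write_text("channel_id,bundle_id,hemisphere,region\n"
                        "0,LA,left,A\n1,LA,right,A\n")
        with pytest.raises(FormatError):
            read_channel_map(path)


class TestDetectionExport:
    def test_empty_records_header_only(self, tmp_path):
        session = make_session([(0, 0, 0, 60.0)])
        path = tmp_path / "det.csv"
        write_detections([], session, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("event_id,channel_id")

    def test_multi_part_record_is_single_row_with_union(self, tmp_path):
        session = make_session([(0, 0, 0, 60.0)])
        rec = DetectionRecord(event_id=0,
                              detected_by=frozenset({"part1", "part3"}),
                              rules=("part1_median", "table3_case2"))
        path = tmp_path / "det.csv"
        write_detections([rec], session, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2
        assert "part1|part3" in lines[1]

    def test_round_trip_preserves_records(self, tmp_path):
        events = [(i * 1000, 0, 0, 60.0) for i in range(5)]
        session = make_session(events)
        records = [
            DetectionRecord(event_id=i, detected_by=frozenset({"part1"}),
                            rules=("part1_median",),
                            retained_event_id=None if i % 2 else i + 1)
            for i in range(4)
        ]
        path = tmp_path / "det.csv"
        write_detections(records, session, path)
        assert read_detections(path) == records

    def test_unknown_event_id_rejected(self, tmp_path):
        session = make_session([(0, 0, 0, 60.0)])
        rec = DetectionRecord(event_id=99, detected_by=frozenset({"part1"}),
                              rules=("r",))
        with pytest.raises(ReferentialIntegrityError):
            write_detections([rec], session, tmp_path / "det.csv")


class TestCleanedSession:
    def test_no_records_is_identity(self, tmp_path, channel_map_file):
        session = make_session([(0, 0, 0, 60.0), (5000, 1, 1, 70.0)])
        path = tmp_path / "clean.h5"
        cleaned = write_cleaned_session(session, [], path)
        assert cleaned.n_events == session.n_events
        map_path = tmp_path / "m.csv"
        write_channel_map(session.channels, map_path)
        back = read_session(path, map_path)
        assert np.array_equal(back.event_id, session.event_id)

    def test_all_flagged_leaves_metadata(self, tmp_path):
        session = make_session([(0, 0, 0, 60.0), (5000, 1, 1, 70.0)])
        records = [DetectionRecord(event_id=i, detected_by=frozenset({"part1"}),
                                   rules=("r",)) for i in (0, 1)]
        cleaned = write_cleaned_session(session, records, tmp_path / "c.h5")
        assert cleaned.n_events == 0
        assert set(cleaned.clusters) == set(session.clusters)

    def test_count_drops_by_exactly_the_flagged_set(self, tmp_path,
                                                    small_contaminated):
        session, truth = small_contaminated
        dup_ids = session.event_id[truth.tag == "duplicated_unit"][:100]
        records = [DetectionRecord(event_id=int(e),
                                   detected_by=frozenset({"part3"}),
                                   rules=("r",)) for e in dup_ids]
        cleaned = write_cleaned_session(session, records, tmp_path / "c.h5")
        assert cleaned.n_events == session.n_events - 100


class TestSorterAdapters:
    def test_combinato_style_import(self, tmp_path, channel_map_file):
        path = tmp_path / "data_ch0.h5"
        wf = np.tile(spike_waveform(50.0), (3, 1)).astype(np.float32)
        with h5py.File(path, "w") as f:
            f.attrs["threshold"] = 12.0
            g = f.create_group("pos")
            g.create_dataset("spikes", data=wf)
            g.create_dataset("times", data=np.array([1.0, 2.5, 10.0]))  # ms
            g.create_dataset("classes", data=np.array([0, 0, 1]))
            g.create_dataset("types", data=np.array([2, -1]))  # SU, artifact
        session = read_combinato({0: str(path)}, channel_map_file)
        assert session.n_events == 3
        assert session.timestamp_us.tolist() == [1000, 2500, 10000]
        labels = sorted(m.class_label for m in session.clusters.values())
        assert labels == ["SU", "artifact"]
        assert all(m.extraction_threshold_uV == 12.0
                   for m in session.clusters.values())

    def test_waveclus_style_import(self, tmp_path, channel_map_file):
        path = tmp_path / "times_ch1.mat"
        wf = np.tile(spike_waveform(40.0), (4, 1))
        cluster_class = np.array([[0, 1.0], [1, 2.0], [1, 3.5], [2, 9.0]])
        savemat(path, {"cluster_class": cluster_class, "spikes": wf})
        session = read_waveclus({1: str(path)}, channel_map_file)
        assert session.n_events == 4
        assert session.timestamp_us.tolist() == [1000, 2000, 3500, 9000]
        # cluster 0 is unsorted -> artifact
        labels = {m.cluster_id: m.class_label for m in session.clusters.values()}
        assert sorted(labels.values()) == ["MU", "MU", "artifact"]
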