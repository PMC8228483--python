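"""Read and write the session container and the detection export.

HDF5 session layout (one group per channel, one group per cluster)::

    /                     attrs: duration_us
    /channels/<id>/
        event_ids     (N,)    int64
        timestamps_us (N,)    int64
        cluster_ids   (N,)    int32
        polarity      (N,)    int8     (+1 positive, -1 negative)
        waveforms     (N, 64) float32  (microvolts)
    /clusters/<id>        attrs: channel_id, class_label, polarity,
                                 extraction_threshold_uV, mean_snr

The channel map is a CSV with header ``channel_id,bundle_id,hemisphere,region``.
Detections are exported as a flat CSV, one row per flagged event, with
``detected_by`` and ``rules`` encoded as ``|``-joined sorted lists.

Thin adapters for Combinato-style and Wave_clus-style sorter outputs are
provided as optional importers; they map the essential arrays (spike shapes,
times, class assignment) into :class:`~der.model.SessionData` and take the
class labels as given.
"""

from __future__ import annotations

import csv
from typing import Dict, List, Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, ReferentialIntegrityError, ShapeError
from .model import (
    WAVEFORM_SAMPLES,
    ChannelInfo,
    ClusterMeta,
    DetectionRecord,
    SessionData,
)

DETECTION_COLUMNS = [
    "event_id", "channel_id", "cluster_id", "timestamp_us",
    "class_label", "detected_by", "rule", "retained_event_id",
]


# ---------------------------------------------------------------------------
# channel map
# ---------------------------------------------------------------------------

def read_channel_map(path) -> Dict[int, ChannelInfo]:
    df = pd.read_csv(path)
    required = {"channel_id", "bundle_id", "hemisphere", "region"}
    if not required <= set(df.columns):
        raise FormatError(
            f"channel map {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    channels = {}
    for row in df.itertuples(index=False):
        channels[int(row.channel_id)] = ChannelInfo(
            channel_id=int(row.channel_id),
            bundle_id=str(row.bundle_id),
            hemisphere=str(row.hemisphere),
            region="" if pd.isna(row.region) else str(row.region),
        )
    by_bundle: Dict[str, str] = {}
    for info in channels.values():
        hemi = by_bundle.setdefault(info.bundle_id, info.hemisphere)
        if hemi != info.hemisphere:
            raise FormatError(
                f"bundle {info.bundle_id} spans both hemispheres in {path}"
            )
    return channels


def write_channel_map(channels: Dict[int, ChannelInfo], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["channel_id", "bundle_id", "hemisphere", "region"])
        for cid in sorted(channels):
            info = channels[cid]
            w.writerow([info.channel_id, info.bundle_id, info.hemisphere, info.region])


# ---------------------------------------------------------------------------
# HDF5 session container
# ---------------------------------------------------------------------------

def write_session(session: SessionData, path) -> None:
    """Write a session to the documented HDF5 layout (channel map not included)."""
    with h5py.File(path, "w") as f:
        f.attrs["duration_us"] = session.duration_us
        chans = f.create_group("channels")
        for ch in sorted(session.channels):
            mask = session.channel_id == ch
            g = chans.create_group(str(ch))
            g.create_dataset("event_ids", data=session.event_id[mask])
            g.create_dataset("timestamps_us", data=session.timestamp_us[mask])
            g.create_dataset("cluster_ids", data=session.cluster_id[mask])
            g.create_dataset("polarity", data=session.polarity[mask])
            g.create_dataset("waveforms", data=session.waveforms[mask])
        cl = f.create_group("clusters")
        for cid in sorted(session.clusters):
            meta = session.clusters[cid]
            g = cl.create_group(str(cid))
            g.attrs["channel_id"] = meta.channel_id
            g.attrs["class_label"] = meta.class_label
            g.attrs["polarity"] = meta.polarity
            g.attrs["extraction_threshold_uV"] = meta.extraction_threshold_uV
            g.attrs["mean_snr"] = -1.0 if meta.mean_snr is None else meta.mean_snr


def read_session(path, channel_map) -> SessionData:
    """Read a session container plus its CSV channel map.

    Raises :class:`FormatError` on a missing dataset (naming its path),
    :class:`ShapeError` if waveforms are not 64 samples wide, and
    :class:`ReferentialIntegrityError` if an id does not resolve.
    """
    channels = read_channel_map(channel_map)
    ev_id: List[np.ndarray] = []
    ch_id: List[np.ndarray] = []
    cl_id: List[np.ndarray] = []
    ts: List[np.ndarray] = []
    pol: List[np.ndarray] = []
    wf: List[np.ndarray] = []
    clusters: Dict[int, ClusterMeta] = {}
    with h5py.File(path, "r") as f:
        if "duration_us" not in f.attrs:
            raise FormatError(f"{path}: missing root attribute 'duration_us'")
        duration_us = int(f.attrs["duration_us"])
        if "channels" not in f:
            raise FormatError(f"{path}: missing group /channels")
        for name, g in f["channels"].items():
            for ds in ("event_ids", "timestamps_us", "cluster_ids",
                       "polarity", "waveforms"):
                if ds not in g:
                    raise FormatError(f"{path}: missing dataset /channels/{name}/{ds}")
            w = np.asarray(g["waveforms"])
            if w.ndim != 2 or w.shape[1] != WAVEFORM_SAMPLES:
                raise ShapeError(
                    f"{path}: /channels/{name}/waveforms has shape {w.shape}, "
                    f"expected (n, {WAVEFORM_SAMPLES})"
                )
            ev_id.append(np.asarray(g["event_ids"], dtype=np.int64))
            ts.append(np.asarray(g["timestamps_us"], dtype=np.int64))
            cl_id.append(np.asarray(g["cluster_ids"], dtype=np.int32))
            pol.append(np.asarray(g["polarity"], dtype=np.int8))
            wf.append(w.astype(np.float32))
            ch_id.append(np.full(len(w), int(name), dtype=np.int32))
        if "clusters" in f:
            for name, g in f["clusters"].items():
                snr = float(g.attrs.get("mean_snr", -1.0))
                clusters[int(name)] = ClusterMeta(
                    cluster_id=int(name),
                    channel_id=int(g.attrs["channel_id"]),
                    class_label=str(g.attrs["class_label"]),
                    polarity=str(g.attrs.get("polarity", "positive")),
                    extraction_threshold_uV=float(g.attrs["extraction_threshold_uV"]),
                    mean_snr=None if snr < 0 else snr,
                )

    def cat(parts, dtype, width=None):
        if not parts:
            shape = (0,) if width is None else (0, width)
            return np.zeros(shape, dtype=dtype)
        return np.concatenate(parts)

    return SessionData(
        event_id=cat(ev_id, np.int64),
        channel_id=cat(ch_id, np.int32),
        cluster_id=cat(cl_id, np.int32),
        timestamp_us=cat(ts, np.int64),
        polarity=cat(pol, np.int8),
        waveforms=cat(wf, np.float32, WAVEFORM_SAMPLES),
        clusters=clusters,
        channels=channels,
        duration_us=duration_us,
    )


def write_cleaned_session(session: SessionData, records: Sequence[DetectionRecord],
                          path) -> SessionData:
    """Write a copy of the session with every flagged event removed.

    Cluster and channel metadata are preserved even for clusters that lose
    all their events.  Returns the cleaned in-memory session.
    """
    flagged = {rec.event_id for rec in records}
    if flagged:
        session.index_of(flagged)  # referential check
    keep = ~np.isin(session.event_id, np.fromiter(flagged, dtype=np.int64,
                                                  count=len(flagged)))
    cleaned = session.subset(keep)
    write_session(cleaned, path)
    return cleaned


# ---------------------------------------------------------------------------
# detection export
# ---------------------------------------------------------------------------

def write_detections(records: Sequence[DetectionRecord], session: SessionData,
                     path) -> None:
    """Export detections as CSV, one row per flagged event.

    Rows are ordered by (timestamp, event_id); ``detected_by`` and ``rule``
    are ``|``-joined sorted lists.
    """
    ids = [rec.event_id for rec in records]
    idx = session.index_of(ids) if ids else np.zeros(0, dtype=np.int64)
    classes = session.event_class
    rows = []
    for rec, i in zip(records, idx):
        rows.append({
            "event_id": rec.event_id,
            "channel_id": int(session.channel_id[i]),
            "cluster_id": int(session.cluster_id[i]),
            "timestamp_us": int(session.timestamp_us[i]),
            "class_label": classes[i],
            "detected_by": "|".join(sorted(rec.detected_by)),
            "rule": "|".join(sorted(rec.rules)),
            "retained_event_id": "" if rec.retained_event_id is None
                                 else rec.retained_event_id,
        })
    rows.sort(key=lambda r: (r["timestamp_us"], r["event_id"]))
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=DETECTION_COLUMNS)
        w.writeheader()
        w.writerows(rows)


def read_detections(path) -> List[DetectionRecord]:
    df = pd.read_csv(path)
    if list(df.columns) != DETECTION_COLUMNS:
        raise FormatError(f"{path}: unexpected detection columns {list(df.columns)}")
    records = []
    for row in df.itertuples(index=False):
        retained = row.retained_event_id
        records.append(DetectionRecord(
            event_id=int(row.event_id),
            detected_by=frozenset(str(row.detected_by).split("|")),
            rules=tuple(str(row.rule).split("|")),
            retained_event_id=None if pd.isna(retained) else int(retained),
        ))
    return records


# ---------------------------------------------------------------------------
# sorter adapters (optional importers)
# ---------------------------------------------------------------------------

def read_combinato(data_files: Dict[int, str], channel_map,
                   duration_us: Optional[int] = None) -> SessionData:
    """Import Combinato-style per-channel HDF5 outputs.

    ``data_files`` maps channel id -> HDF5 file expected to contain, for each
    present sign ``pos``/``neg``: ``<sign>/spikes`` (N, 64), ``<sign>/times``
    (ms, float), ``<sign>/classes`` (per-event cluster index within the sign)
    and ``<sign>/types`` (per-cluster class code: -1 artifact, 1 MU, 2 SU),
    plus an optional root attribute ``threshold`` (extraction threshold, uV).
    Cluster ids are renumbered globally; timestamps are converted to integer
    microseconds.
    """
    channels = read_channel_map(channel_map)
    type_map = {-1: "artifact", 0: "artifact", 1: "MU", 2: "SU"}
    ev, ch, cl, ts, pol, wf = [], [], [], [], [], []
    clusters: Dict[int, ClusterMeta] = {}
    next_cluster = 0
    next_event = 0
    for channel_id, fname in sorted(data_files.items()):
        with h5py.File(fname, "r") as f:
            thr = float(f.attrs.get("threshold", 1.0))
            for sign, p in (("pos", 1), ("neg", -1)):
                if sign not in f:
                    continue
                g = f[sign]
                for ds in ("spikes", "times", "classes", "types"):
                    if ds not in g:
                        raise FormatError(f"{fname}: missing dataset /{sign}/{ds}")
                spikes = np.asarray(g["spikes"], dtype=np.float32)
                if spikes.ndim != 2 or spikes.shape[1] != WAVEFORM_SAMPLES:
                    raise ShapeError(
                        f"{fname}: /{sign}/spikes has shape {spikes.shape}")
                times_us = np.round(np.asarray(g["times"], dtype=np.float64)
                                    * 1000.0).astype(np.int64)
                classes = np.asarray(g["classes"], dtype=np.int64)
                types = np.asarray(g["types"], dtype=np.int64)
                local_ids = {}
                for local, tcode in enumerate(types):
                    local_ids[local] = next_cluster
                    clusters[next_cluster] = ClusterMeta(
                        cluster_id=next_cluster,
                        channel_id=channel_id,
                        class_label=type_map.get(int(tcode), "artifact"),
                        polarity="positive" if p > 0 else "negative",
                        extraction_threshold_uV=thr,
                    )
                    next_cluster += 1
                n = len(spikes)
                ev.append(np.arange(next_event, next_event + n, dtype=np.int64))
                next_event += n
                ch.append(np.full(n, channel_id, dtype=np.int32))
                cl.append(np.array([local_ids[int(c)] for c in classes],
                                   dtype=np.int32))
                ts.append(times_us)
                pol.append(np.full(n, p, dtype=np.int8))
                wf.append(spikes)

    all_ts = np.concatenate(ts) if ts else np.zeros(0, dtype=np.int64)
    if duration_us is None:
        duration_us = int(all_ts.max()) + 1 if len(all_ts) else 1
    return SessionData(
        event_id=np.concatenate(ev) if ev else np.zeros(0, np.int64),
        channel_id=np.concatenate(ch) if ch else np.zeros(0, np.int32),
        cluster_id=np.concatenate(cl) if cl else np.zeros(0, np.int32),
        timestamp_us=all_ts,
        polarity=np.concatenate(pol) if pol else np.zeros(0, np.int8),
        waveforms=np.concatenate(wf) if wf else np.zeros((0, WAVEFORM_SAMPLES),
                                                         np.float32),
        clusters=clusters,
        channels=channels,
        duration_us=duration_us,
    )


def read_waveclus(times_files: Dict[int, str], channel_map,
                  duration_us: Optional[int] = None) -> SessionData:
    """Import Wave_clus-style ``times_*.mat`` files (one per channel).

    Each file is expected to hold ``cluster_class`` (N, 2: cluster index and
    spike time in ms; cluster 0 = unsorted, treated as artifact) and
    ``spikes`` (N, 64).  Class labels: cluster 0 -> artifact, others -> MU
    (Wave_clus does not assign SU/MU; relabel via ``SessionData.clusters``
    if curation information exists).
    """
    from scipy.io import loadmat

    channels = read_channel_map(channel_map)
    ev, ch, cl, ts, pol, wf = [], [], [], [], [], []
    clusters: Dict[int, ClusterMeta] = {}
    next_cluster = 0
    next_event = 0
    for channel_id, fname in sorted(times_files.items()):
        mat = loadmat(fname)
        for key in ("cluster_class", "spikes"):
            if key not in mat:
                raise FormatError(f"{fname}: missing variable '{key}'")
        cc = np.asarray(mat["cluster_class"], dtype=np.float64)
        spikes = np.asarray(mat["spikes"], dtype=np.float32)
        if spikes.ndim != 2 or spikes.shape[1] != WAVEFORM_SAMPLES:
            raise ShapeError(f"{fname}: spikes has shape {spikes.shape}")
        local = cc[:, 0].astype(np.int64)
        times_us = np.round(cc[:, 1] * 1000.0).astype(np.int64)
        local_ids = {}
        for lc in sorted(set(local.tolist())):
            local_ids[lc] = next_cluster
            clusters[next_cluster] = ClusterMeta(
                cluster_id=next_cluster,
                channel_id=channel_id,
                class_label="artifact" if lc == 0 else "MU",
                polarity="positive",
                extraction_threshold_uV=1.0,
            )
            next_cluster += 1
        n = len(spikes)
        peaks = spikes[np.arange(n), np.argmax(np.abs(spikes), axis=1)]
        ev.append(np.arange(next_event, next_event + n, dtype=np.int64))
        next_event += n
        ch.append(np.full(n, channel_id, dtype=np.int32))
        cl.append(np.array([local_ids[int(c)] for c in local], dtype=np.int32))
        ts.append(times_us)
        pol.append(np.where(peaks >= 0, 1, -1).astype(np.int8))
        wf.append(spikes)
    # mixed polarity is possible inside wave_clus clusters
    for cid, meta in clusters.items():
        meta.polarity = "mixed"

    all_ts = np.concatenate(ts) if ts else np.zeros(0, dtype=np.int64)
    if duration_us is None:
        duration_us = int(all_ts.max()) + 1 if len(all_ts) else 1
    return SessionData(
        event_id=np.concatenate(ev) if ev else np.zeros(0, np.int64),
        channel_id=np.concatenate(ch) if ch else np.zeros(0, np.int32),
        cluster_id=np.concatenate(cl) if cl else np.zeros(0, np.int32),
        timestamp_us=all_ts,
        polarity=np.concatenate(pol) if pol else np.zeros(0, np.int8),
        waveforms=np.concatenate(wf) if wf else np.zeros((0, WAVEFORM_SAMPLES),
                                                         np.float32),
        clusters=clusters,
        channels=channels,
        duration_us=duration_us,
    )
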