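"""Session data model for spike-sorted microwire recordings.

A *session* is the output of a spike sorter run on one recording: per-event
waveforms (64 samples spanning 2 ms), integer-microsecond timestamps, a
polarity flag, and a cluster assignment, plus per-cluster class labels
(single unit / multi-unit / artifact) and a channel -> bundle -> hemisphere
map.  Events are stored column-wise in numpy arrays so that sessions with
millions of events stay cheap to scan; :class:`SpikeEvent` is a per-event
view used for convenience and testing.

Timestamps are integer microseconds throughout: all detection windows of the
algorithm (50 us, 650 us, 500 us bins) are integer multiples of 1 us, so
window membership never depends on float rounding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigError, ReferentialIntegrityError, ShapeError

#: Number of samples per extracted waveform (2 ms at 32 kHz sorter output).
WAVEFORM_SAMPLES = 64

#: Provenance labels for the parts of the algorithm.
PART1 = "part1"
PART2_SAME_CHANNEL = "part2_same_channel"
PART2_SAME_BUNDLE = "part2_same_bundle"
PART3 = "part3"
ALL_PARTS = (PART1, PART2_SAME_CHANNEL, PART2_SAME_BUNDLE, PART3)

CLASS_LABELS = ("SU", "MU", "artifact")
POLARITIES = ("positive", "negative")


def polarity_sign(polarity: str) -> int:
    if polarity == "positive":
        return 1
    if polarity == "negative":
        return -1
    raise ValueError(f"unknown polarity {polarity!r}")


@dataclass(frozen=True)
class ChannelInfo:
    """One microwire: which bundle it belongs to and where that bundle sits."""

    channel_id: int
    bundle_id: str
    hemisphere: str  # "left" | "right"
    region: str = ""

    def __post_init__(self):
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be left/right, got {self.hemisphere!r}")


@dataclass
class ClusterMeta:
    """One sorted cluster with its operator-assigned class label.

    ``mean_snr`` is the mean over member events of
    ``|peak amplitude| / extraction threshold``; it is filled in at session
    construction when not provided.
    """

    cluster_id: int
    channel_id: int
    class_label: str  # "SU" | "MU" | "artifact"
    polarity: str = "positive"  # "positive" | "negative" | "mixed"
    extraction_threshold_uV: float = 1.0
    mean_snr: Optional[float] = None

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if self.polarity not in ("positive", "negative", "mixed"):
            raise ValueError(f"cluster polarity must be positive/negative/mixed")
        if not self.extraction_threshold_uV > 0:
            raise ValueError("extraction_threshold_uV must be positive")


@dataclass(frozen=True)
class SpikeEvent:
    """Per-event view (one row of the columnar store)."""

    event_id: int
    channel_id: int
    cluster_id: int
    timestamp_us: int
    polarity: str
    waveform_uV: np.ndarray

    @property
    def peak_amplitude_uV(self) -> float:
        w = self.waveform_uV
        return float(w[int(np.argmax(np.abs(w)))])


@dataclass(frozen=True)
class DetectionRecord:
    """One flagged event with full provenance.

    ``detected_by`` is the set of algorithm parts that flagged the event;
    an event flagged by several parts has exactly one record carrying the
    union.  ``rules`` lists the rule-table cases that fired (e.g.
    ``table2_case1``).  ``retained_event_id`` names the kept counterpart for
    pairwise rules, or ``None`` when every member of a group is labeled.
    """

    event_id: int
    detected_by: frozenset
    rules: tuple
    retained_event_id: Optional[int] = None

    def __post_init__(self):
        if not self.detected_by:
            raise ValueError("detected_by must be nonempty")
        unknown = set(self.detected_by) - set(ALL_PARTS)
        if unknown:
            raise ValueError(f"unknown parts {unknown}")


@dataclass
class DERConfig:
    """All tunable parameters of the algorithm with their published defaults.

    Distances are Euclidean distances between selected orthonormal-Haar
    coefficients and therefore live in microvolts.
    """

    no_sim: int = 3                      # min events per cross-bundle window
    dt_cross_bundle_us: int = 50         # Part I coincidence window
    d_thr_cross_bundle: float = 14.6     # Part I median-distance threshold (uV)
    dt_same_channel_us: int = 650        # Part II biphasic window
    dt_same_bundle_us: int = 50          # Part II same-bundle window
    d_thr_same_bundle: float = 8.4       # Part II pairwise-distance threshold (uV)
    t_bin_us: int = 500                  # Part III correlogram bin width
    n_bins: int = 81                     # Part III correlogram bins (odd)
    z_thr: float = 5.0                   # Part III central-bin z threshold
    n_feature_dims: int = 10             # wavelet dimensions kept by KS selection
    wavelet_levels: int = 5              # Haar decomposition depth
    invert_negative_polarity: bool = True   # mirror negative events before featurizing
    detect_same_channel: bool = True        # off switch for bipolar montages

    def validate(self) -> "DERConfig":
        for name in ("no_sim", "dt_cross_bundle_us", "d_thr_cross_bundle",
                     "dt_same_channel_us", "dt_same_bundle_us", "d_thr_same_bundle",
                     "t_bin_us", "n_bins", "z_thr", "n_feature_dims",
                     "wavelet_levels"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_bins % 2 == 0:
            raise ConfigError("n_bins must be odd so the central bin is well defined")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "DERConfig":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DERConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


class SessionData:
    """A complete spike-sorted session in columnar form.

    Events are globally sorted by ``timestamp_us`` with ties broken by
    ``(channel_id, event_id)`` so that every sweep over the session is
    deterministic.
    """

    def __init__(
        self,
        event_id: np.ndarray,
        channel_id: np.ndarray,
        cluster_id: np.ndarray,
        timestamp_us: np.ndarray,
        polarity: np.ndarray,
        waveforms: np.ndarray,
        clusters: Mapping[int, ClusterMeta],
        channels: Mapping[int, ChannelInfo],
        duration_us: int,
        validate: bool = True,
    ):
        n = len(event_id)
        self.event_id = np.asarray(event_id, dtype=np.int64)
        self.channel_id = np.asarray(channel_id, dtype=np.int32)
        self.cluster_id = np.asarray(cluster_id, dtype=np.int32)
        self.timestamp_us = np.asarray(timestamp_us, dtype=np.int64)
        self.polarity = np.asarray(polarity, dtype=np.int8)  # +1 / -1
        wf = np.asarray(waveforms, dtype=np.float32)
        self.waveforms = wf.reshape(n, -1) if n else wf.reshape(0, WAVEFORM_SAMPLES)
        self.clusters = dict(clusters)
        self.channels = dict(channels)
        self.duration_us = int(duration_us)

        order = np.lexsort((self.event_id, self.channel_id, self.timestamp_us))
        if not np.array_equal(order, np.arange(n)):
            for name in ("event_id", "channel_id", "cluster_id",
                         "timestamp_us", "polarity"):
                setattr(self, name, getattr(self, name)[order])
            self.waveforms = self.waveforms[order]

        if validate:
            self._validate()
        self._fill_mean_snr()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        n = self.n_events
        if self.waveforms.shape != (n, WAVEFORM_SAMPLES):
            raise ShapeError(
                f"waveforms must be (n, {WAVEFORM_SAMPLES}), got {self.waveforms.shape}"
            )
        if n and len(np.unique(self.event_id)) != n:
            raise ReferentialIntegrityError("event_id values must be unique")
        if n and (self.timestamp_us.min() < 0 or self.timestamp_us.max() >= self.duration_us):
            raise ShapeError("timestamps must lie in [0, duration_us)")
        missing_cl = set(np.unique(self.cluster_id).tolist()) - set(self.clusters)
        if missing_cl:
            raise ReferentialIntegrityError(f"unresolved cluster ids {sorted(missing_cl)}")
        missing_ch = set(np.unique(self.channel_id).tolist()) - set(self.channels)
        if missing_ch:
            raise ReferentialIntegrityError(f"unresolved channel ids {sorted(missing_ch)}")
        for meta in self.clusters.values():
            if meta.channel_id not in self.channels:
                raise ReferentialIntegrityError(
                    f"cluster {meta.cluster_id} references unknown channel {meta.channel_id}"
                )
        if n:
            peaks = self.peak_amplitude_uV
            bad = np.sign(peaks).astype(np.int8) * self.polarity < 0
            if bad.any():
                raise ShapeError(
                    f"{int(bad.sum())} events whose polarity flag contradicts the "
                    "sign of their peak amplitude"
                )

    def _fill_mean_snr(self) -> None:
        if all(m.mean_snr is not None for m in self.clusters.values()):
            return
        means = {}
        if self.n_events:
            uniq, inv = np.unique(self.cluster_id, return_inverse=True)
            sums = np.bincount(inv, weights=self.event_snr)
            counts = np.bincount(inv)
            means = {int(u): float(s / c)
                     for u, s, c in zip(uniq, sums, counts)}
        for cid, meta in self.clusters.items():
            if meta.mean_snr is None:
                meta.mean_snr = means.get(cid, 0.0)

    # -- derived columns --------------------------------------------------

    @property
    def n_events(self) -> int:
        return len(self.event_id)

    @property
    def peak_amplitude_uV(self) -> np.ndarray:
        """Signed extremum of each waveform."""
        cache = self.__dict__.setdefault("_derived", {})
        if "peak" not in cache:
            if self.n_events == 0:
                cache["peak"] = np.zeros(0, dtype=np.float32)
            else:
                idx = np.argmax(np.abs(self.waveforms), axis=1)
                cache["peak"] = self.waveforms[np.arange(self.n_events), idx]
        return cache["peak"]

    def _mapped(self, key: str, ids: np.ndarray, lut: dict) -> np.ndarray:
        cache = self.__dict__.setdefault("_derived", {})
        if key not in cache:
            uniq, inverse = np.unique(ids, return_inverse=True)
            values = np.array([lut[int(u)] for u in uniq], dtype=object)
            cache[key] = values[inverse] if len(ids) else np.zeros(0, dtype=object)
        return cache[key]

    @property
    def event_snr(self) -> np.ndarray:
        """Per-event SNR: |peak amplitude| / cluster extraction threshold."""
        cache = self.__dict__.setdefault("_derived", {})
        if "snr" not in cache:
            thr = self._mapped(
                "thr", self.cluster_id,
                {cid: m.extraction_threshold_uV for cid, m in self.clusters.items()},
            ).astype(np.float64) if self.n_events else np.zeros(0)
            cache["snr"] = np.abs(self.peak_amplitude_uV) / np.where(thr > 0, thr, 1.0)
        return cache["snr"]

    @property
    def event_class(self) -> np.ndarray:
        """Per-event cluster class label (SU/MU/artifact)."""
        return self._mapped("class", self.cluster_id,
                            {cid: m.class_label for cid, m in self.clusters.items()})

    @property
    def event_bundle(self) -> np.ndarray:
        return self._mapped("bundle", self.channel_id,
                            {cid: i.bundle_id for cid, i in self.channels.items()})

    @property
    def event_hemisphere(self) -> np.ndarray:
        return self._mapped("hemisphere", self.channel_id,
                            {cid: i.hemisphere for cid, i in self.channels.items()})

    # -- access -----------------------------------------------------------

    def event(self, index: int) -> SpikeEvent:
        return SpikeEvent(
            event_id=int(self.event_id[index]),
            channel_id=int(self.channel_id[index]),
            cluster_id=int(self.cluster_id[index]),
            timestamp_us=int(self.timestamp_us[index]),
            polarity="positive" if self.polarity[index] > 0 else "negative",
            waveform_uV=self.waveforms[index],
        )

    def index_of(self, event_ids: Iterable[int]) -> np.ndarray:
        """Row indices of the given event ids (raises if any is unknown)."""
        wanted = np.asarray(list(event_ids), dtype=np.int64)
        order = np.argsort(self.event_id)
        pos = np.searchsorted(self.event_id, wanted, sorter=order)
        if len(self.event_id) == 0 or (pos >= len(order)).any():
            raise ReferentialIntegrityError("unknown event id")
        idx = order[np.minimum(pos, len(order) - 1)]
        if not np.array_equal(self.event_id[idx], wanted):
            raise ReferentialIntegrityError("unknown event id")
        return idx

    def subset(self, mask: np.ndarray) -> "SessionData":
        """New session containing only the events selected by ``mask``."""
        return SessionData(
            event_id=self.event_id[mask],
            channel_id=self.channel_id[mask],
            cluster_id=self.cluster_id[mask],
            timestamp_us=self.timestamp_us[mask],
            polarity=self.polarity[mask],
            waveforms=self.waveforms[mask],
            clusters={k: dataclasses.replace(v) for k, v in self.clusters.items()},
            channels=self.channels,
            duration_us=self.duration_us,
            validate=False,
        )

    def with_timestamps(self, timestamp_us: np.ndarray) -> "SessionData":
        """New session with replaced timestamps (re-sorted)."""
        return SessionData(
            event_id=self.event_id,
            channel_id=self.channel_id,
            cluster_id=self.cluster_id,
            timestamp_us=timestamp_us,
            polarity=self.polarity,
            waveforms=self.waveforms,
            clusters={k: dataclasses.replace(v) for k, v in self.clusters.items()},
            channels=self.channels,
            duration_us=self.duration_us,
            validate=False,
        )


def merge_detections(*record_lists: Sequence[DetectionRecord]) -> list:
    """Merge per-part detection records into one record per event.

    ``detected_by`` becomes the union across parts; rules are concatenated
    (deduplicated, sorted); the retained counterpart of the first part (in
    the canonical part order) that names one is kept.
    """
    by_event: dict = {}
    for records in record_lists:
        for rec in records:
            prev = by_event.get(rec.event_id)
            if prev is None:
                by_event[rec.event_id] = rec
            else:
                retained = prev.retained_event_id
                if retained is None:
                    retained = rec.retained_event_id
                by_event[rec.event_id] = DetectionRecord(
                    event_id=rec.event_id,
                    detected_by=prev.detected_by | rec.detected_by,
                    rules=tuple(sorted(set(prev.rules) | set(rec.rules))),
                    retained_event_id=retained,
                )
    return [by_event[k] for k in sorted(by_event)]
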