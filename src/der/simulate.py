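"""Ground-truth synthetic sessions: Poisson units, templates, contamination.

The generator emulates the statistics of the simulated benchmark used to
estimate the algorithm's false-positive rate: 80 individually simulated
channels in bundles of 8, each channel carrying one 5 Hz multi-unit plus 1
to 19 single units with rates drawn uniformly from 0.1-2 Hz (2 to 20
neurons per channel), homogeneous Poisson spike trains over a ~25 minute
session, and template-plus-Gaussian-noise waveforms.

Waveform templates are a two-lobe difference-of-Gaussians family spanning
realistic peak-to-trough times of 300-900 us, with peak amplitudes of
40-150 uV.  Units fire independently; refractoriness and overlapping-spike
superposition are not modeled.

Contamination is injected on top with per-event ground-truth tags so that
detection recall and false positives can be measured exactly:

* ``cross-bundle artifact trains`` — one Poisson noise source emitting the
  same template near-simultaneously on several channels across >= 2
  bundles (events land in per-channel merged artifact clusters),
* ``duplicated units`` — a single unit's spike train copied with small
  jitter and an attenuated template onto a second channel of its bundle,
* ``biphasic double extractions`` — a polarity-flipped twin of an event on
  the same channel, delayed by the template's peak-to-trough time (twin
  events land in the channel's merged artifact cluster),
* ``line-noise clusters`` — a strictly periodic 50 Hz artifact train on one
  channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import SimulationSpecError
from .model import (
    WAVEFORM_SAMPLES,
    ChannelInfo,
    ClusterMeta,
    SessionData,
)

#: ground-truth origin tags
TAG_CLEAN = "clean"
TAG_ARTIFACT_TRAIN = "cross_bundle_train"
TAG_DUPLICATED_UNIT = "duplicated_unit"
TAG_BIPHASIC_TWIN = "biphasic_twin"
TAG_LINE_NOISE = "line_noise"

_REGIONS = ["A", "AH", "EC", "PH", "PHC", "I", "TP", "OF", "AC", "SM"]


@dataclass
class ContaminationSpec:
    """Rates and shapes of the injected duplicate/artifact contamination."""

    n_artifact_trains: int = 0
    artifact_train_rate_hz: float = 2.0
    artifact_train_channels: int = 4      # channels hit per source
    artifact_train_bundles: int = 2       # bundles those channels span
    artifact_train_jitter_us: int = 4     # per-channel timing jitter (+/-)

    n_duplicated_units: int = 0
    duplicate_jitter_us: int = 20         # spike-time jitter on the twin (+/-)
    duplicate_attenuation: float = 0.8    # template scale on the twin channel

    n_biphasic_channels: int = 0
    biphasic_prob: float = 0.8            # per-event probability of a twin
    biphasic_max_ptt_us: float = 600.0    # only narrow spikes double-extract

    n_line_noise_clusters: int = 0
    line_noise_freq_hz: float = 50.0

    @classmethod
    def none(cls) -> "ContaminationSpec":
        return cls()

    @classmethod
    def default(cls) -> "ContaminationSpec":
        """The canonical contaminated benchmark configuration."""
        return cls(n_artifact_trains=2, n_duplicated_units=3,
                   n_biphasic_channels=4, n_line_noise_clusters=1)


@dataclass
class SimulationSpec:
    """Full description of one synthetic session."""

    n_channels: int = 80
    bundle_size: int = 8
    duration_s: float = 1500.0
    su_per_channel: Tuple[int, int] = (1, 19)   # inclusive range
    su_rate_range_hz: Tuple[float, float] = (0.1, 2.0)
    mu_rate_hz: float = 5.0
    amplitude_range_uV: Tuple[float, float] = (40.0, 150.0)
    peak_trough_range_us: Tuple[float, float] = (300.0, 900.0)
    noise_sd_uV: float = 2.0
    extraction_sigma: float = 5.0               # threshold = sigma * noise sd
    contamination: ContaminationSpec = field(default_factory=ContaminationSpec.none)
    seed: int = 0

    def validate(self) -> "SimulationSpec":
        if self.n_channels <= 0 or self.bundle_size <= 0:
            raise SimulationSpecError("channel and bundle counts must be positive")
        if self.n_channels % self.bundle_size != 0:
            raise SimulationSpecError("bundle_size must divide n_channels")
        if self.duration_s <= 0:
            raise SimulationSpecError("duration must be positive")
        if not (0 < self.su_rate_range_hz[0] <= self.su_rate_range_hz[1]):
            raise SimulationSpecError("SU rates must be positive and ordered")
        if self.mu_rate_hz <= 0:
            raise SimulationSpecError("MU rate must be positive")
        if self.su_per_channel[0] < 0 or self.su_per_channel[0] > self.su_per_channel[1]:
            raise SimulationSpecError("SU count range must be ordered and nonnegative")
        total_rate = self.n_channels * (
            self.mu_rate_hz + self.su_per_channel[1] * self.su_rate_range_hz[1])
        if total_rate * self.duration_s > 5e8:
            raise SimulationSpecError("spec implies an unrepresentable event count")
        if self.noise_sd_uV < 0:
            raise SimulationSpecError("noise sd must be nonnegative")
        return self


@dataclass
class GroundTruth:
    """Per-event origin tags, aligned with the session's event order."""

    event_id: np.ndarray      # (N,) int64, session order
    tag: np.ndarray           # (N,) object: TAG_* constants
    source_event_id: np.ndarray  # (N,) int64; twin's original event, else -1
    source_id: np.ndarray     # (N,) int64; contamination source index, else -1

    def mask(self, tag: str) -> np.ndarray:
        return self.tag == tag

    @property
    def clean(self) -> np.ndarray:
        return self.tag == TAG_CLEAN


def make_template(rng: np.random.Generator,
                  amplitude_range_uV=(40.0, 150.0),
                  peak_trough_range_us=(300.0, 900.0),
                  polarity: int = 1) -> Tuple[np.ndarray, float]:
    """One two-lobe spike template; returns (64 samples, peak-to-trough us).

    Difference of two Gaussian lobes: a sharp main peak near sample 20 (the
    usual sorter alignment point) and a broader opposite trough delayed by
    the peak-to-trough time.
    """
    dt_us = 2000.0 / WAVEFORM_SAMPLES
    t = np.arange(WAVEFORM_SAMPLES) * dt_us
    t_peak = 20 * dt_us
    ptt = float(rng.uniform(*peak_trough_range_us))
    amp = float(rng.uniform(*amplitude_range_uV))
    trough_ratio = float(rng.uniform(0.3, 0.6))
    sigma_peak = float(rng.uniform(80.0, 150.0))
    sigma_trough = float(rng.uniform(150.0, 300.0))
    w = amp * (np.exp(-0.5 * ((t - t_peak) / sigma_peak) ** 2)
               - trough_ratio * np.exp(-0.5 * ((t - t_peak - ptt) / sigma_trough) ** 2))
    return polarity * w, ptt


def _poisson_train(rng: np.random.Generator, rate_hz: float,
                   duration_us: int) -> np.ndarray:
    n = rng.poisson(rate_hz * duration_us * 1e-6)
    return np.sort(rng.integers(0, duration_us, size=n, dtype=np.int64))


class _Builder:
    """Accumulates event columns while ids are being assigned."""

    def __init__(self, duration_us: int, noise_sd: float,
                 rng: np.random.Generator):
        self.duration_us = duration_us
        self.noise_sd = noise_sd
        self.rng = rng
        self.ts: List[np.ndarray] = []
        self.ch: List[np.ndarray] = []
        self.cl: List[np.ndarray] = []
        self.pol: List[np.ndarray] = []
        self.wf: List[np.ndarray] = []
        self.tag: List[np.ndarray] = []
        self.src_event: List[np.ndarray] = []
        self.src_id: List[np.ndarray] = []
        self.row_offset = 0

    def add(self, times: np.ndarray, channel: int, cluster: int,
            template: np.ndarray, tag: str, source_id: int = -1,
            source_rows: Optional[np.ndarray] = None) -> np.ndarray:
        """Append one block of events sharing a template; returns row ids."""
        inside = (times >= 0) & (times < self.duration_us)
        times = times[inside]
        if source_rows is not None:
            source_rows = np.asarray(source_rows)[inside]
        n = len(times)
        noise = self.rng.normal(0.0, self.noise_sd,
                                size=(n, WAVEFORM_SAMPLES)) if self.noise_sd else 0.0
        w = template[None, :] + noise
        pol = 1 if template[np.argmax(np.abs(template))] >= 0 else -1
        self.ts.append(times.astype(np.int64))
        self.ch.append(np.full(n, channel, dtype=np.int32))
        self.cl.append(np.full(n, cluster, dtype=np.int32))
        self.pol.append(np.full(n, pol, dtype=np.int8))
        self.wf.append(np.asarray(w, dtype=np.float32))
        self.tag.append(np.full(n, tag, dtype=object))
        self.src_id.append(np.full(n, source_id, dtype=np.int64))
        if source_rows is None:
            self.src_event.append(np.full(n, -1, dtype=np.int64))
        else:
            self.src_event.append(np.asarray(source_rows, dtype=np.int64))
        rows = np.arange(self.row_offset, self.row_offset + n, dtype=np.int64)
        self.row_offset += n
        return rows


def simulate_session(spec: SimulationSpec) -> Tuple[SessionData, GroundTruth]:
    """Build a synthetic session plus exact ground truth, deterministically.

    The same spec (including seed) always produces a bit-identical session.
    Row ids assigned during construction become the final ``event_id``
    values, so ground-truth tags survive the global time sort.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    duration_us = int(round(spec.duration_s * 1e6))
    n_bundles = spec.n_channels // spec.bundle_size

    channels: Dict[int, ChannelInfo] = {}
    for b in range(n_bundles):
        hemi = "left" if b < (n_bundles + 1) // 2 else "right"
        region = _REGIONS[b % len(_REGIONS)]
        bundle_id = ("L" if hemi == "left" else "R") + region
        for k in range(spec.bundle_size):
            ch = b * spec.bundle_size + k
            channels[ch] = ChannelInfo(channel_id=ch, bundle_id=bundle_id,
                                       hemisphere=hemi, region=region)

    threshold = spec.extraction_sigma * max(spec.noise_sd_uV, 1e-3)
    builder = _Builder(duration_us, spec.noise_sd_uV, rng)
    clusters: Dict[int, ClusterMeta] = {}
    templates: Dict[int, Tuple[np.ndarray, float]] = {}
    su_clusters_by_channel: Dict[int, List[int]] = {ch: [] for ch in channels}
    artifact_cluster: Dict[int, int] = {}   # merged artifact cluster per channel
    next_cluster = 0

    def new_cluster(channel: int, label: str, polarity: str = "positive") -> int:
        nonlocal next_cluster
        cid = next_cluster
        next_cluster += 1
        clusters[cid] = ClusterMeta(
            cluster_id=cid, channel_id=channel, class_label=label,
            polarity=polarity, extraction_threshold_uV=threshold)
        return cid

    def get_artifact_cluster(channel: int) -> int:
        if channel not in artifact_cluster:
            artifact_cluster[channel] = new_cluster(channel, "artifact", "mixed")
        return artifact_cluster[channel]

    # -- clean units ------------------------------------------------------
    for ch in sorted(channels):
        mu = new_cluster(ch, "MU")
        templates[mu] = make_template(rng, spec.amplitude_range_uV,
                                      spec.peak_trough_range_us)
        builder.add(_poisson_train(rng, spec.mu_rate_hz, duration_us),
                    ch, mu, templates[mu][0], TAG_CLEAN)
        n_su = int(rng.integers(spec.su_per_channel[0],
                                spec.su_per_channel[1] + 1))
        for _ in range(n_su):
            su = new_cluster(ch, "SU")
            templates[su] = make_template(rng, spec.amplitude_range_uV,
                                          spec.peak_trough_range_us)
            rate = float(rng.uniform(*spec.su_rate_range_hz))
            builder.add(_poisson_train(rng, rate, duration_us),
                        ch, su, templates[su][0], TAG_CLEAN)
            su_clusters_by_channel[ch].append(su)

    # -- contamination ----------------------------------------------------
    cont = spec.contamination
    bundle_channels: Dict[str, List[int]] = {}
    for ch, info in channels.items():
        bundle_channels.setdefault(info.bundle_id, []).append(ch)
    bundle_list = sorted(bundle_channels)
    source_counter = 0

    for _ in range(cont.n_artifact_trains):
        if len(bundle_list) < cont.artifact_train_bundles:
            raise SimulationSpecError("not enough bundles for an artifact train")
        chosen_bundles = rng.choice(len(bundle_list),
                                    size=cont.artifact_train_bundles,
                                    replace=False)
        pool = np.concatenate([
            np.sort(np.asarray(bundle_channels[bundle_list[i]]))
            for i in chosen_bundles
        ])
        # at least one channel per chosen bundle, rest drawn from the pool
        picks = [int(rng.choice(bundle_channels[bundle_list[i]]))
                 for i in chosen_bundles]
        remaining = [c for c in pool if c not in picks]
        extra = cont.artifact_train_channels - len(picks)
        if extra > 0:
            picks += [int(c) for c in
                      rng.choice(remaining, size=extra, replace=False)]
        template, _ = make_template(rng, spec.amplitude_range_uV,
                                    spec.peak_trough_range_us)
        base_times = _poisson_train(rng, cont.artifact_train_rate_hz, duration_us)
        for ch in picks:
            jitter = rng.integers(-cont.artifact_train_jitter_us,
                                  cont.artifact_train_jitter_us + 1,
                                  size=len(base_times))
            builder.add(base_times + jitter, ch, get_artifact_cluster(ch),
                        template, TAG_ARTIFACT_TRAIN, source_id=source_counter)
        source_counter += 1

    duplicable = [(ch, su) for ch in sorted(channels)
                  for su in su_clusters_by_channel[ch]
                  if len(bundle_channels[channels[ch].bundle_id]) > 1]
    n_dup = min(cont.n_duplicated_units, len(duplicable))
    dup_choices = rng.choice(len(duplicable), size=n_dup, replace=False) \
        if n_dup else []
    for pick in dup_choices:
        ch, su = duplicable[int(pick)]
        twin_channel = int(rng.choice(
            [c for c in bundle_channels[channels[ch].bundle_id] if c != ch]))
        # replay the unit's spikes: rows of the original cluster
        block = next(i for i, cls in enumerate(builder.cl)
                     if cls.size and cls[0] == su)
        src_times = builder.ts[block]
        src_rows = np.arange(sum(len(x) for x in builder.ts[:block]),
                             sum(len(x) for x in builder.ts[:block]) + len(src_times),
                             dtype=np.int64)
        jitter = rng.integers(-cont.duplicate_jitter_us,
                              cont.duplicate_jitter_us + 1, size=len(src_times))
        twin_template = cont.duplicate_attenuation * templates[su][0]
        twin_cluster = new_cluster(twin_channel, "SU")
        templates[twin_cluster] = (twin_template, templates[su][1])
        keep = (src_times + jitter >= 0) & (src_times + jitter < duration_us)
        builder.add((src_times + jitter)[keep], twin_channel, twin_cluster,
                    twin_template, TAG_DUPLICATED_UNIT,
                    source_id=source_counter, source_rows=src_rows[keep])
        source_counter += 1

    if cont.n_biphasic_channels:
        narrow = [(ch, su) for ch in sorted(channels)
                  for su in su_clusters_by_channel[ch]
                  if templates[su][1] <= cont.biphasic_max_ptt_us]
        chosen: Dict[int, int] = {}
        for ch, su in narrow:
            if len(chosen) >= cont.n_biphasic_channels:
                break
            chosen.setdefault(ch, su)
        for ch, su in chosen.items():
            block = next(i for i, cls in enumerate(builder.cl)
                         if cls.size and cls[0] == su)
            src_times = builder.ts[block]
            src_rows = np.arange(sum(len(x) for x in builder.ts[:block]),
                                 sum(len(x) for x in builder.ts[:block]) + len(src_times),
                                 dtype=np.int64)
            picked = rng.random(len(src_times)) < cont.biphasic_prob
            delay = int(round(templates[su][1]))
            twin_template = -templates[su][0]
            builder.add(src_times[picked] + delay, ch, get_artifact_cluster(ch),
                        twin_template, TAG_BIPHASIC_TWIN,
                        source_id=source_counter,
                        source_rows=src_rows[picked])
            source_counter += 1

    for _ in range(cont.n_line_noise_clusters):
        ch = int(rng.integers(0, spec.n_channels))
        period_us = 1e6 / cont.line_noise_freq_hz
        start = float(rng.uniform(0, period_us))
        times = np.round(np.arange(start, duration_us, period_us)).astype(np.int64)
        template, _ = make_template(rng, spec.amplitude_range_uV,
                                    spec.peak_trough_range_us)
        builder.add(times, ch, get_artifact_cluster(ch), template,
                    TAG_LINE_NOISE, source_id=source_counter)
        source_counter += 1

    # -- assemble ---------------------------------------------------------
    n = builder.row_offset
    session = SessionData(
        event_id=np.arange(n, dtype=np.int64),
        channel_id=np.concatenate(builder.ch) if n else np.zeros(0, np.int32),
        cluster_id=np.concatenate(builder.cl) if n else np.zeros(0, np.int32),
        timestamp_us=np.concatenate(builder.ts) if n else np.zeros(0, np.int64),
        polarity=np.concatenate(builder.pol) if n else np.zeros(0, np.int8),
        waveforms=np.concatenate(builder.wf) if n
        else np.zeros((0, WAVEFORM_SAMPLES), np.float32),
        clusters=clusters,
        channels=channels,
        duration_us=duration_us,
        validate=False,
    )
    tags = np.concatenate(builder.tag) if n else np.zeros(0, dtype=object)
    src_event = np.concatenate(builder.src_event) if n else np.zeros(0, np.int64)
    src_id = np.concatenate(builder.src_id) if n else np.zeros(0, np.int64)
    # event ids were assigned in construction (row) order; re-align the tags
    # with the time-sorted session
    inverse = session.event_id  # session rows carry their construction ids
    truth = GroundTruth(
        event_id=session.event_id.copy(),
        tag=tags[inverse],
        source_event_id=src_event[inverse],
        source_id=src_id[inverse],
    )
    return session, truth
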