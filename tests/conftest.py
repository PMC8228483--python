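"""Shared fixtures: hand-built micro-sessions and reusable simulations."""

from __future__ import annotations

import numpy as np
import pytest

from der import (
    ChannelInfo,
    ClusterMeta,
    ContaminationSpec,
    FeatureBasis,
    SessionData,
    SimulationSpec,
    simulate_session,
)
from der.model import WAVEFORM_SAMPLES


def make_channels(n_bundles: int = 2, bundle_size: int = 2) -> dict:
    """Channel map: bundles L00, L01, ... on the left, R.. on the right."""
    channels = {}
    for b in range(n_bundles):
        hemi = "left" if b < (n_bundles + 1) // 2 else "right"
        bundle = f"{'L' if hemi == 'left' else 'R'}{b:02d}"
        for k in range(bundle_size):
            ch = b * bundle_size + k
            channels[ch] = ChannelInfo(channel_id=ch, bundle_id=bundle,
                                       hemisphere=hemi, region=bundle)
    return channels


def spike_waveform(amplitude: float = 80.0, peak: int = 20,
                   width: int = 3) -> np.ndarray:
    """A simple positive spike-like bump."""
    w = np.zeros(WAVEFORM_SAMPLES)
    x = np.arange(WAVEFORM_SAMPLES)
    w += amplitude * np.exp(-0.5 * ((x - peak) / width) ** 2)
    return w


def make_session(events, clusters=None, channels=None, duration_us=10_000_000,
                 default_class="SU", threshold=10.0):
    """Build a session from (timestamp_us, channel, cluster, waveform) tuples.

    ``waveform`` may be an array or a scalar peak amplitude (signed; the
    sign sets the polarity).
    """
    channels = channels if channels is not None else make_channels()
    rows = []
    for i, (t, ch, cl, wf) in enumerate(events):
        if np.isscalar(wf):
            w = spike_waveform(abs(float(wf))) * (1 if wf >= 0 else -1)
        else:
            w = np.asarray(wf, dtype=float)
        pol = 1 if w[np.argmax(np.abs(w))] >= 0 else -1
        rows.append((i, t, ch, cl, pol, w))
    if clusters is None:
        cluster_ids = sorted({cl for _, _, _, cl, _, _ in rows})
        clusters = {}
        for cl in cluster_ids:
            ch = next(r[2] for r in rows if r[3] == cl)
            clusters[cl] = ClusterMeta(cluster_id=cl, channel_id=ch,
                                       class_label=default_class,
                                       extraction_threshold_uV=threshold)
    return SessionData(
        event_id=np.array([r[0] for r in rows], dtype=np.int64),
        channel_id=np.array([r[2] for r in rows], dtype=np.int32),
        cluster_id=np.array([r[3] for r in rows], dtype=np.int32),
        timestamp_us=np.array([r[1] for r in rows], dtype=np.int64),
        polarity=np.array([r[4] for r in rows], dtype=np.int8),
        waveforms=np.array([r[5] for r in rows]) if rows
        else np.zeros((0, WAVEFORM_SAMPLES)),
        clusters=clusters,
        channels=channels,
        duration_us=duration_us,
    )


def identity_basis(k: int = 10) -> FeatureBasis:
    """A fixed basis over the first k coefficients, for hand fixtures."""
    return FeatureBasis(selected_dims=np.arange(k),
                        ks_statistics=np.zeros(WAVEFORM_SAMPLES),
                        n_events_fit=2 * k)


@pytest.fixture(scope="session")
def small_contaminated():
    """A small contaminated simulation shared by several tests."""
    spec = SimulationSpec(n_channels=16, duration_s=120.0, su_per_channel=(1, 4),
                          contamination=ContaminationSpec.default(), seed=7)
    return simulate_session(spec)


@pytest.fixture(scope="session")
def small_clean():
    """A small clean simulation (no contamination)."""
    spec = SimulationSpec(n_channels=16, duration_s=120.0, su_per_channel=(1, 4),
                          seed=5)
    return simulate_session(spec)
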