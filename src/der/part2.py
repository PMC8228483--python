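"""Part II — duplicate events within one bundle.

Two mechanisms are handled:

* **Same channel, biphasic double extraction** — a biphasic spike whose
  positive and negative lobes both cross the extraction thresholds is
  extracted twice with opposite polarity.  Any two opposite-polarity events
  on one channel within 650 us (a classical peak-to-trough spike duration)
  form a candidate pair.  Pairing is greedy nearest-in-time so one event
  cannot wipe out a whole train.
* **Same bundle, different channels** — overlapping recording volumes of
  neighboring microwires record one physical event on two wires.  Any pair
  of events on different channels of one bundle within 50 us whose shape
  distance is <= 8.4 uV is a duplicate pair (a per-pair criterion, unlike
  Part I's median rule).

Which event of a pair survives follows the cluster-class rule table:

========  ==========================================  =========================
Case      combination                                 labeled as artifact
========  ==========================================  =========================
1         artifact x (SU or MU), same channel         the artifact-cluster event
2         artifact x (SU or MU), same bundle          both events
3         SU x MU                                     the MU event
4         same class (incl. artifact x artifact)      the lower event-SNR event
========  ==========================================  =========================

Event SNR is ``|peak amplitude| / extraction threshold`` of the event's
cluster.  Case-4 ties label the later event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .features import FeatureBasis, selected_coeffs
from .model import (
    PART2_SAME_BUNDLE,
    PART2_SAME_CHANNEL,
    DERConfig,
    DetectionRecord,
    SessionData,
)

KIND_SAME_CHANNEL = "same_channel_biphasic"
KIND_SAME_BUNDLE = "same_bundle"


@dataclass(frozen=True)
class DuplicatePair:
    """Two events suspected to be one physical event."""

    event_a: int                 # earlier event id
    event_b: int                 # later event id
    index_a: int                 # session row indices
    index_b: int
    kind: str                    # KIND_SAME_CHANNEL | KIND_SAME_BUNDLE
    dt_us: int
    distance: Optional[float] = None   # shape distance (same-bundle only)


def detect_biphasic_same_channel(session: SessionData,
                                 dt_us: int = 650) -> List[DuplicatePair]:
    """Opposite-polarity pairs within ``dt_us`` on one channel.

    Each event is paired at most once, with its nearest-in-time
    opposite-polarity partner; on ties the earlier candidate pair wins.
    Either polarity order (positive first or negative first) is accepted.
    """
    pairs: List[DuplicatePair] = []
    t = session.timestamp_us
    pol = session.polarity
    for ch in sorted(session.channels):
        idx = np.nonzero(session.channel_id == ch)[0]
        if len(idx) < 2:
            continue
        tt = t[idx]
        hi = np.searchsorted(tt, tt + dt_us, side="right")
        candidates = []
        for a in range(len(idx)):
            for b in range(a + 1, hi[a]):
                if pol[idx[a]] != pol[idx[b]]:
                    candidates.append((int(tt[b] - tt[a]), a, b))
        candidates.sort()
        used = np.zeros(len(idx), dtype=bool)
        for dt, a, b in candidates:
            if used[a] or used[b]:
                continue
            used[a] = used[b] = True
            pairs.append(DuplicatePair(
                event_a=int(session.event_id[idx[a]]),
                event_b=int(session.event_id[idx[b]]),
                index_a=int(idx[a]), index_b=int(idx[b]),
                kind=KIND_SAME_CHANNEL, dt_us=dt,
            ))
    pairs.sort(key=lambda p: (p.index_a, p.index_b))
    return pairs


def detect_same_bundle_duplicates(session: SessionData, features: np.ndarray,
                                  basis: FeatureBasis, dt_us: int = 50,
                                  d_thr: float = 8.4) -> List[DuplicatePair]:
    """Similar-shape pairs within ``dt_us`` on different channels of a bundle."""
    pairs: List[DuplicatePair] = []
    t = session.timestamp_us
    ch = session.channel_id
    bundles = sorted({info.bundle_id for info in session.channels.values()})
    sel = selected_coeffs(features, basis) if session.n_events else None
    bundle_of = session.event_bundle
    for bundle in bundles:
        idx = np.nonzero(bundle_of == bundle)[0]
        if len(idx) < 2:
            continue
        tt = t[idx]
        hi = np.searchsorted(tt, tt + dt_us, side="right")
        for a in range(len(idx)):
            for b in range(a + 1, hi[a]):
                ia, ib = idx[a], idx[b]
                if ch[ia] == ch[ib]:
                    continue
                d = float(np.linalg.norm(sel[ia] - sel[ib]))
                if d <= d_thr:
                    pairs.append(DuplicatePair(
                        event_a=int(session.event_id[ia]),
                        event_b=int(session.event_id[ib]),
                        index_a=int(ia), index_b=int(ib),
                        kind=KIND_SAME_BUNDLE, dt_us=int(tt[b] - tt[a]),
                        distance=d,
                    ))
    pairs.sort(key=lambda p: (p.index_a, p.index_b))
    return pairs


def resolve_pair(pair: DuplicatePair,
                 session: SessionData) -> Tuple[Tuple[int, ...], Optional[int], str]:
    """Apply the rule table to one pair.

    Returns ``(labeled_event_ids, retained_event_id, rule)``; Case 2 labels
    both events and retains none.
    """
    meta_a = session.clusters[int(session.cluster_id[pair.index_a])]
    meta_b = session.clusters[int(session.cluster_id[pair.index_b])]
    cls_a, cls_b = meta_a.class_label, meta_b.class_label

    if {cls_a, cls_b} == {"artifact"}:
        pass  # artifact x artifact: fall through to the Case-4 SNR rule
    elif "artifact" in (cls_a, cls_b):
        if pair.kind == KIND_SAME_CHANNEL:
            labeled = pair.event_a if cls_a == "artifact" else pair.event_b
            retained = pair.event_b if cls_a == "artifact" else pair.event_a
            return (labeled,), retained, "table2_case1"
        return (pair.event_a, pair.event_b), None, "table2_case2"

    if cls_a != cls_b:  # SU x MU
        labeled = pair.event_a if cls_a == "MU" else pair.event_b
        retained = pair.event_b if cls_a == "MU" else pair.event_a
        return (labeled,), retained, "table2_case3"

    snr = session.event_snr
    snr_a = float(snr[pair.index_a])
    snr_b = float(snr[pair.index_b])
    if snr_a < snr_b:
        return (pair.event_a,), pair.event_b, "table2_case4"
    if snr_b < snr_a:
        return (pair.event_b,), pair.event_a, "table2_case4"
    # tie: label the later event
    return (pair.event_b,), pair.event_a, "table2_case4"


def run_part2(session: SessionData, config: DERConfig,
              features: Optional[np.ndarray] = None,
              basis: Optional[FeatureBasis] = None) -> List[DetectionRecord]:
    """Run both Part-II detectors and resolve every pair."""
    if features is None or basis is None:
        from .features import fit_feature_basis, session_features
        features = session_features(
            session, levels=config.wavelet_levels,
            invert_negative=config.invert_negative_polarity)
        basis = fit_feature_basis(features, k=config.n_feature_dims)

    per_event: dict = {}

    def add(event_id, part, rule, retained):
        key = event_id
        prev = per_event.get(key)
        if prev is None:
            per_event[key] = (set([part]), {rule}, retained)
        else:
            prev[0].add(part)
            prev[1].add(rule)

    pair_lists = []
    if config.detect_same_channel:
        pair_lists.append((PART2_SAME_CHANNEL,
                           detect_biphasic_same_channel(
                               session, config.dt_same_channel_us)))
    pair_lists.append((PART2_SAME_BUNDLE,
                       detect_same_bundle_duplicates(
                           session, features, basis,
                           config.dt_same_bundle_us,
                           config.d_thr_same_bundle)))
    for part, pairs in pair_lists:
        for pair in pairs:
            labeled, retained, rule = resolve_pair(pair, session)
            for e in labeled:
                add(e, part, rule, retained)

    return [
        DetectionRecord(event_id=e, detected_by=frozenset(parts),
                        rules=tuple(sorted(rules)), retained_event_id=retained)
        for e, (parts, rules, retained) in sorted(per_event.items())
    ]
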