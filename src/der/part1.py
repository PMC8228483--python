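"""Part I — simultaneous similar-shape events across microwire bundles.

External noise (mains interference, movement, instruments near the patient)
is picked up by wires in several bundles at once and can be extracted as
spike-like events by the sorter.  Part I flags groups of at least ``no_sim``
events that fall inside a short coincidence window, span two or more
bundles, and whose *median* pairwise shape distance is below the Part-I
threshold.  All members of such a group are labeled: none of them can be
trusted to be the "real" one.

Window semantics: one candidate window ``[t, t + dt]`` (boundary inclusive)
is anchored at every event; flagged sets are the union over all windows that
pass the count, bundle, and median-distance criteria.  Anchored windows are
deterministic and avoid unbounded single-linkage chaining of events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.spatial.distance import pdist

from .features import FeatureBasis, selected_coeffs
from .model import PART1, DERConfig, DetectionRecord, SessionData

RULE_MEDIAN = "part1_median"


@dataclass(frozen=True)
class CoincidenceWindow:
    """Events within ``[t_anchor, t_anchor + dt]`` of an anchor event."""

    anchor_event_id: int
    member_event_ids: tuple      # in time order, anchor first
    member_indices: tuple        # session row indices of the members
    bundle_count: int


def find_coincidence_windows(session: SessionData, dt_us: int,
                             no_sim: int) -> List[CoincidenceWindow]:
    """All anchored windows holding >= ``no_sim`` events in >= 2 bundles.

    A single left-to-right sweep over the time-sorted events; cost is
    O(n * max window occupancy).
    """
    t = session.timestamp_us
    n = len(t)
    if n == 0:
        return []
    bundles = session.event_bundle
    hi = np.searchsorted(t, t + dt_us, side="right")
    windows = []
    for i in np.nonzero(hi - np.arange(n) >= no_sim)[0]:
        members = np.arange(i, hi[i])
        n_bundles = len(set(bundles[members]))
        if n_bundles >= 2:
            windows.append(CoincidenceWindow(
                anchor_event_id=int(session.event_id[i]),
                member_event_ids=tuple(int(e) for e in session.event_id[members]),
                member_indices=tuple(int(j) for j in members),
                bundle_count=n_bundles,
            ))
    return windows


def evaluate_window(window: CoincidenceWindow, features: np.ndarray,
                    basis: FeatureBasis, d_thr: float) -> List[int]:
    """Label all members if the median pairwise shape distance is < ``d_thr``.

    The median runs over *all* unordered member pairs, including pairs on
    the same bundle inside a cross-bundle window.
    """
    idx = np.asarray(window.member_indices)
    sel = selected_coeffs(features[idx], basis)
    distances = pdist(sel)
    if float(np.median(distances)) < d_thr:
        return list(window.member_event_ids)
    return []


def run_part1(session: SessionData, config: DERConfig,
              features: Optional[np.ndarray] = None,
              basis: Optional[FeatureBasis] = None) -> List[DetectionRecord]:
    """Run Part I and return one record per flagged event.

    ``features``/``basis`` may be precomputed (the pipeline shares them
    across parts); otherwise they are fitted here from the whole session.
    """
    if features is None or basis is None:
        from .features import fit_feature_basis, session_features
        features = session_features(
            session, levels=config.wavelet_levels,
            invert_negative=config.invert_negative_polarity)
        basis = fit_feature_basis(features, k=config.n_feature_dims)
    flagged: set = set()
    for window in find_coincidence_windows(session, config.dt_cross_bundle_us,
                                           config.no_sim):
        flagged.update(evaluate_window(window, features, basis,
                                       config.d_thr_cross_bundle))
    return [
        DetectionRecord(event_id=e, detected_by=frozenset({PART1}),
                        rules=(RULE_MEDIAN,), retained_event_id=None)
        for e in sorted(flagged)
    ]
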