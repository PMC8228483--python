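"""Orchestrate Parts I-III, merge provenance, and summarize.

The three parts run independently on the *original* event set (never on a
sequentially pruned one) and their detections are merged per event
afterwards; this is what makes the per-part overlap partition (the Venn
breakdown of which parts caught which events) well defined.  Detections are
labels — removal is a separate, opt-in step
(:func:`der.io.write_cleaned_session`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .features import FeatureBasis, fit_feature_basis, session_features
from .model import (
    ALL_PARTS,
    PART1,
    PART3,
    DERConfig,
    DetectionRecord,
    SessionData,
    merge_detections,
)
from .part1 import run_part1
from .part2 import run_part2
from .part3 import run_part3

CLASSES = ("SU", "MU", "artifact")
#: Venn partition runs over the three algorithm parts (II's two detectors
#: are one part there, but are reported separately in the fraction table).
VENN_PARTS = ("part1", "part2", "part3")


@dataclass
class DERReport:
    """Per-class and per-part detection summary of one pipeline run."""

    total_events: int
    totals_per_class: Dict[str, int]
    flagged_per_part_class: Dict[str, Dict[str, int]]
    flagged_fraction_per_part_class: Dict[str, Dict[str, float]]
    venn_partition: Dict[str, int]          # "part1|part3" -> count
    flagged_total: int
    config: dict
    feature_basis: Optional[dict] = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _venn_key(parts: frozenset) -> str:
    collapsed = {PART1 if p == PART1 else PART3 if p == PART3 else "part2"
                 for p in parts}
    return "|".join(p for p in VENN_PARTS if p in collapsed)


def summarize(records: Sequence[DetectionRecord], session: SessionData,
              config: Optional[DERConfig] = None,
              basis: Optional[FeatureBasis] = None) -> DERReport:
    """Build the per-class / per-part / overlap report for merged records."""
    classes = session.event_class
    totals = {c: int((classes == c).sum()) for c in CLASSES}
    id_class = dict(zip(session.event_id.tolist(), classes))

    flagged_counts = {p: {c: 0 for c in CLASSES} for p in ALL_PARTS}
    venn: Dict[str, int] = {}
    for rec in records:
        cls = id_class[rec.event_id]
        for part in rec.detected_by:
            flagged_counts[part][cls] += 1
        key = _venn_key(rec.detected_by)
        venn[key] = venn.get(key, 0) + 1

    fractions = {
        p: {c: (flagged_counts[p][c] / totals[c] if totals[c] else 0.0)
            for c in CLASSES}
        for p in ALL_PARTS
    }
    return DERReport(
        total_events=session.n_events,
        totals_per_class=totals,
        flagged_per_part_class=flagged_counts,
        flagged_fraction_per_part_class=fractions,
        venn_partition=dict(sorted(venn.items())),
        flagged_total=len(records),
        config=(config or DERConfig()).to_dict(),
        feature_basis=None if basis is None else {
            "selected_dims": [int(d) for d in basis.selected_dims],
            "n_events_fit": basis.n_events_fit,
        },
    )


def run_der(session: SessionData, config: Optional[DERConfig] = None
            ) -> Tuple[List[DetectionRecord], DERReport]:
    """Run the full three-part algorithm on one session.

    The wavelet feature basis is fitted once on all events of the session
    and shared by Parts I and II.  Returns the merged per-event records
    (union of ``detected_by`` across parts) and the summary report.
    """
    config = (config or DERConfig()).validate()
    if session.n_events:
        features = session_features(session, levels=config.wavelet_levels,
                                    invert_negative=config.invert_negative_polarity)
        basis = fit_feature_basis(features, k=config.n_feature_dims)
        rec1 = run_part1(session, config, features, basis)
        rec2 = run_part2(session, config, features, basis)
    else:
        basis = None
        rec1, rec2 = [], []
    rec3 = run_part3(session, config)
    records = merge_detections(rec1, rec2, rec3)
    report = summarize(records, session, config, basis)
    return records, report
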