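"""Label duplicate spike events in a contaminated session and summarize.

Builds a small synthetic session (16 microwires in two bundles, 2 minutes)
with injected contamination — a cross-bundle artifact train, duplicated
units, biphasic double extractions, and a line-noise cluster — then runs
the three-part detection pipeline and prints what each part caught.
"""

import collections

from der import ContaminationSpec, SimulationSpec, run_der, simulate_session

spec = SimulationSpec(n_channels=16, duration_s=120.0, su_per_channel=(1, 4),
                      contamination=ContaminationSpec.default(), seed=7)
session, truth = simulate_session(spec)
print(f"session: {session.n_events} events, {len(session.clusters)} clusters, "
      f"{session.duration_us / 1e6:.0f} s")
print("injected:", dict(collections.Counter(truth.tag.tolist())))

records, report = run_der(session)
pct = 100.0 * len(records) / session.n_events
print(f"\nflagged {len(records)} events ({pct:.2f}% of all spikes)")
print("flagged per part x class:")
for part, per_class in report.flagged_per_part_class.items():
    print(f"  {part:20s} {per_class}")
print("overlap partition (which parts caught the same events):")
for cell, count in report.venn_partition.items():
    print(f"  {cell:20s} {count}")

# how well the flags line up with the injected ground truth
by_event = {r.event_id: r.detected_by for r in records}
for tag in ("cross_bundle_train", "biphasic_twin", "duplicated_unit"):
    ids = session.event_id[truth.tag == tag]
    hits = sum(1 for e in ids if int(e) in by_event)
    print(f"recall on {tag}: {hits / len(ids):.1%}")
# A flagged fraction near the injected contamination fraction, with high
# per-type recall, means the pipeline is catching what was planted without
# eating the clean single-unit spikes.
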