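"""Screen cluster pairs by the central bin of their cross-correlogram.

A unit picked up by two microwires produces two clusters that fire
together within microseconds; their cross-correlogram piles up in the
central (zero-lag) bin. This example duplicates a unit onto a neighboring
wire, computes all pairwise correlograms in one streaming pass, and shows
the central-bin z-scores that expose the duplicate.
"""

import numpy as np

from der import (
    ContaminationSpec,
    DERConfig,
    SimulationSpec,
    central_z,
    compute_ccg_matrix,
    label_suspicious_pairs,
    simulate_session,
)

contamination = ContaminationSpec(n_duplicated_units=2)
spec = SimulationSpec(n_channels=8, duration_s=300.0, su_per_channel=(2, 4),
                      contamination=contamination, seed=31)
session, truth = simulate_session(spec)

ccg = compute_ccg_matrix(session, t_bin_us=500, n_bins=81)
zm = central_z(ccg)
K = len(zm.cluster_ids)
iu = np.triu_indices(K, k=1)
z = np.where(zm.degenerate, np.inf, zm.z)[iu]
print(f"{K} clusters -> {len(z)} cluster pairs")
print(f"median central-bin z: {np.median(z[np.isfinite(z)]):.2f}")
top = np.argsort(z)[-4:][::-1]
for k in top:
    a, b = iu[0][k], iu[1][k]
    print(f"  pair ({zm.cluster_ids[a]}, {zm.cluster_ids[b]}): "
          f"z = {z[k]:.1f}, central count = "
          f"{ccg.counts[a, b, ccg.central_bin]}")

records = label_suspicious_pairs(session, zm, z_thr=DERConfig().z_thr)
flagged = {r.event_id for r in records}
twin_ids = set(session.event_id[truth.tag == "duplicated_unit"].tolist())
print(f"events flagged: {len(records)}; "
      f"duplicated-unit spikes among them: {len(flagged & twin_ids)}"
      f" of {len(twin_ids)}")
# Independent pairs hover near z = 0; the duplicated unit's pair stands out
# by orders of magnitude, and only the lower-SNR twin's spikes are labeled.
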