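"""Refit the shape-distance threshold from a session's own pair populations.

The published thresholds (14.6 uV across bundles, 8.4 uV within a bundle)
depend on the amplifier chain. This example rebuilds the ROC calibration:
coincident artifact pairs (the "real" duplicates) against non-coincident
cross-hemisphere pairs (the surrogate), swept in 0.1 uV steps.
"""

from der import (
    ContaminationSpec,
    SimulationSpec,
    fit_feature_basis,
    operating_point,
    roc_curve,
    sample_pair_distances,
    session_features,
    simulate_session,
    sweep_time_windows,
)

spec = SimulationSpec(n_channels=16, duration_s=300.0, su_per_channel=(1, 4),
                      contamination=ContaminationSpec.default(), seed=17)
session, _ = simulate_session(spec)
features = session_features(session)
basis = fit_feature_basis(features)
print(f"feature basis: wavelet dims {basis.selected_dims.tolist()}")

real = sample_pair_distances(session, features, basis, "artifact_pairs",
                             "coincident_cross_bundle", n_pairs=5000,
                             dt_us=50, seed=1)
surr = sample_pair_distances(session, features, basis, "artifact_pairs",
                             "noncoincident_cross_hemisphere", n_pairs=5000,
                             dt_us=50, seed=2)
import numpy as np

print(f"median distance, coincident cross-bundle pairs: "
      f"{np.median(real):.1f} uV")
print(f"median distance, cross-hemisphere surrogate pairs: "
      f"{np.median(surr):.1f} uV")

roc = roc_curve(real, surr)
print(f"AUC {roc.auc:.3f}; operating point d_thr = "
      f"{operating_point(roc):.1f} uV")

best_dt, curves = sweep_time_windows(session, features, basis,
                                     grid=[32, 50, 100, 500], n_pairs=3000,
                                     seed=3)
for dt in sorted(curves):
    print(f"  window {dt:4d} us -> AUC {curves[dt].auc:.3f}")
print(f"selected coincidence window: {best_dt} us")
# The operating point is the distance threshold closest to perfect
# sensitivity and specificity; it replaces the published default when the
# recording chain differs from the one the default was fitted on.
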