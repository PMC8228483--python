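"""Show that coincidence excess vanishes in a circular-shift surrogate.

Pools all channels into 0.5 ms bins and compares the contaminated original
against a surrogate in which every cluster is rotated by an independent
random offset — the null model for "how much simultaneity would occur by
chance".
"""

from der import (
    ContaminationSpec,
    SimulationSpec,
    bin_coincidence_histogram,
    circular_shift_surrogate,
    simulate_session,
)

contamination = ContaminationSpec(n_artifact_trains=1,
                                  artifact_train_rate_hz=8.0,
                                  artifact_train_channels=16,
                                  artifact_train_bundles=2)
spec = SimulationSpec(n_channels=16, duration_s=300.0,
                      contamination=contamination, seed=2027)
session, _ = simulate_session(spec)
surrogate = circular_shift_surrogate(session, seed=2028)

orig = bin_coincidence_histogram(session, bin_us=500)
surr = bin_coincidence_histogram(surrogate, bin_us=500)

thr = orig.five_sigma_threshold
print(f"original: mean {orig.mean:.3f} events/bin, mean+5sigma = {thr:.2f}")
print(f"bins above threshold, original : {(orig.counts > thr).sum()}")
print(f"bins above threshold, surrogate: {(surr.counts > thr).sum()}")
print("proportion of bins holding k events (k=0..8):")
for label, h in (("original", orig), ("surrogate", surr)):
    row = ", ".join(f"{p:.2e}" for p in h.fill_proportions[:9])
    print(f"  {label:9s} {row}")
# The artifact train loads single bins with up to 16 simultaneous events;
# rotating each cluster independently destroys that synchrony, so no
# surrogate bin exceeds the original's 5-sigma line.
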