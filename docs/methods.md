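# Methods

This note documents the detection model, the numerical choices behind it,
what the synthetic-data generator does and does not emulate, and the known
limitations. It is the design record for maintainers; the README covers
usage.

## The detection problem

A spike-sorted microwire session consists of extracted events (64 samples
spanning 2 ms, in µV, with integer-µs timestamps and a polarity flag),
grouped into clusters that an operator or sorter has labeled single unit
(SU), multi-unit (MU) or artifact. Bundles of eight wires share a location
and reference wire, so one physical event — neural or not — can be
extracted several times: on wires of several bundles (external noise picked
up everywhere, or a spike on the shared reference appearing mirrored on
referenced channels), on neighboring wires of one bundle (overlapping
recording volumes), or twice on one wire with opposite polarity (a biphasic
waveform crossing both extraction thresholds). The task is to label every
event that is plausibly a duplicate extraction of another, keeping the best
representative where one exists.

Class labels are taken as given input and never recomputed; a merged
mixed-polarity artifact cluster per channel is permitted (it is how
Combinato-style pipelines store artifacts) but not required.

## Shape features

Waveform similarity is measured in a wavelet domain. Each 64-sample
waveform is decomposed by a five-level **orthonormal** Haar DWT into 64
coefficients, packed `[A5(2), D5(2), D4(4), D3(8), D2(16), D1(32)]`.
Orthonormality matters: energy is conserved, so coefficients — and the
Euclidean distances between them — stay on the µV scale of the waveforms,
which is what makes fixed numeric thresholds (14.6, 8.4) physically
meaningful. The transform is delegated to PyWavelets (`haar`,
`mode="periodization"`), which is exact for dyadic lengths; the test suite
checks it against an explicitly constructed dense 64×64 orthonormal Haar
matrix, energy conservation, and invertibility at 1e−9 relative.

Dimensionality is reduced to the 10 coefficients whose distribution across
events deviates most from a normal distribution — multimodality marks
coefficients that separate distinct waveform shapes rather than noise.
Each coefficient is z-scored across events and scored by the one-sample
Kolmogorov–Smirnov statistic against N(0,1); the 10 largest statistics win,
ties broken toward the lower coefficient index. Exactly constant
coefficients score 0 and are never selected. The basis is fitted **once per
session on all events pooled across channels**: the distances it supports
are cross-channel comparisons, so they must live in one shared subspace.

Negative-polarity waveforms are sign-inverted before the transform
(configurable, default on), so that a reference-wire artifact — which
appears mirrored on referenced channels — matches its positive twin.

## Part I — cross-bundle coincidence windows

One candidate window `[t, t + Δt]` (Δt = 50 µs, boundary inclusive) is
anchored at every event. A window is a detection candidate if it holds
≥ `no_sim = 3` events spanning ≥ 2 bundles. For each candidate the median
over **all** unordered pairwise shape distances (same-bundle pairs
included) is compared with `d_thr = 14.6`; strictly below threshold, every
member is labeled (none can be trusted). Flags are the union over windows.
Anchored windows make the sweep deterministic and O(n · window occupancy),
and avoid the unbounded chaining that single-linkage "clusters of
coincidences" would produce. Overlapping windows are evaluated
independently; the union of labels makes merge order irrelevant.

## Part II — within-bundle duplicates

*Same channel.* Opposite-polarity pairs within 650 µs — the classical
peak-to-trough duration bound below which biphasic (interneuron-like)
waveforms live. Matching is greedy nearest-in-time with each event used at
most once, so a train of spikes cannot be annihilated by a single partner;
either polarity order is accepted.

*Same bundle.* Pairs on different channels of one bundle within 50 µs with
shape distance ≤ 8.4 (a per-pair criterion, unlike Part I's median; every
qualifying pair is resolved independently).

Retention rules (Case numbers as used in the detection records):
artifact × unit on one channel labels the artifact event (Case 1);
artifact × unit within a bundle labels both (Case 2); SU × MU labels the MU
event (Case 3); same class labels the lower event-SNR member (Case 4),
where event SNR = |peak| / extraction threshold. Artifact × artifact pairs
(possible with merged artifact clusters) are resolved by the Case-4 SNR
rule; exact SNR ties label the later event. `detect_same_channel: false`
disables the biphasic screen for bipolar montages, where channel
subtraction manufactures opposite-polarity twins wholesale.

## Part III — cross-correlogram screening

All pairwise cross-correlograms (81 bins × 500 µs, lags to
t_max = ½·t_bin·n_bins = 20.25 ms) are built in one pass over the
time-ordered events: each event looks forward up to t_max at events of
other clusters; the matrix is completed afterwards through the skew
symmetry `C[i,j,b] = C[j,i,n−1−b]`. Bin b covers lags
`[(b−40−½)·t_bin, (b−40+½)·t_bin)`; the central bin is `[−250, +250) µs`.
Autocorrelations are excluded — same-cluster duplicates are Part II's
domain. The implementation chunks the forward pairs and accumulates with
`bincount`; the tests pin it to an independent all-pairs oracle.

The central bin is scored as `z = (c₀ − μ)/σ` with μ, σ (population SD)
from the 80 other bins. Pairs with `z > 5` have their coincident spikes
(|Δt| strictly < 250 µs) labeled by the second rule table: artifact × unit
labels both sides' coincident events (Case 1); different bundles labels
both (Case 2 — with no shared anatomy, neither side has a claim to the
event); SU × MU in one bundle labels the MU side (Case 3); same class in
one bundle labels the lower *mean-SNR cluster*'s coincident spikes
(Case 4). Degenerate correlograms (σ = 0 with a central excess) are given
an effective z of +∞: a pair that fires only simultaneously is the
archetypal duplicate. Labeling is a single pass; z is not recomputed after
removal (residual isolated super-threshold pairs are expected, and the
tests assert only that removal never increases a flagged pair's z).

A deliberate property worth knowing: for very sparse cluster pairs (a few
dozen spikes each) the baseline σ estimated from 80 mostly-empty bins is
tiny, and one or two chance coincidences produce z well above 5. The
per-pair false-flag probability is small (~2·10⁻³ on shifted data), but
the number of cluster pairs grows quadratically with cluster count, so the
*pooled* false-positive percentage of Part III scales with cluster density:
at ~2 clusters/channel (typical curated recordings) it is of order 0.01%,
at ~10 clusters/channel (the dense synthetic benchmark below) of order
0.1%. `scripts/acceptance.py` measures it at the dense benchmark scale; we
chose to keep the published z-rule rather than add an unpublished
minimum-count guard.

## Pipeline semantics

Parts run independently on the unpruned event set and are merged per event
(union of `detected_by`, rules concatenated), so the Venn partition over
{Part I, Part II, Part III} is well defined and per-part counts equal the
sums of the partition cells containing that part. Detections are labels;
`write_cleaned_session` is the explicit removal step — studies of genuine
coincident firing may want the labels but not the deletion. All removal
windows are narrow (0.05 / 0.65 / 0.5 ms), so longer-lag asymmetries in
cross-correlograms survive cleaning.

## Threshold calibration

The distance thresholds transfer poorly across amplifier chains, so they
can be refitted per session. Real population: coincident pairs of the
relevant classes (artifact pairs across bundles for Part I; SU/MU pairs
within a bundle for Part II). Surrogate population: pairs of the same
classes from *different hemispheres*, not coincident — two wires in
different hemispheres cannot share a physical source. Both are sampled
uniformly with replacement (default 10,000 pairs, seeded). Sweeping the
threshold from 0 to the largest observed distance in steps of 0.1 yields
sensitivity/specificity per step (distance ≤ threshold counts as positive);
AUC is the trapezoidal integral, and the operating point is the threshold
minimizing the Euclidean distance to (0,1), ties toward the smaller
(more conservative) threshold. The coincidence window itself is chosen by
maximizing AUC over a grid (32 µs–1 ms); windows within 0.001 AUC of the
maximum are ties and the largest tied window wins — a wider window costs
nothing when separation is equal. Calibration is per session; pooling
across sessions is out of scope.

## Surrogates and coincidence diagnostics

The null model for synchrony is the cluster-wise circular shift: each
cluster's spike train is rotated by an independent offset uniform on
[0, duration), modulo the duration. Event counts, rates and ISI structure
(up to one wrap gap) are preserved exactly; all cross-cluster timing is
destroyed. The pooled coincidence histogram bins all events (all channels)
into fixed 0.5 ms bins anchored at t = 0 and reports the bin-count
distribution and a mean+5σ exceedance threshold computed over *all* bins of
the session, empty ones included. Note the scale-dependence: the 5σ line
only separates original from surrogate when contamination inflates the
original's σ; in a long, lightly contaminated session the surrogate's
extreme bins approach the line simply because there are millions of bins.
The suppression test therefore uses a short, heavily contaminated session
(16 channels, 300 s, an 8 Hz artifact train across both bundles) — the
regime the diagnostic is for.

## The synthetic-data generator

The generator emulates the reference benchmark used to estimate the
false-positive rate: 80 channels in 10 bundles (5 per hemisphere), ~25
minutes, one 5 Hz multi-unit plus 1–19 single units per channel (2–20
neurons/channel) with SU rates uniform on 0.1–2 Hz — giving ~70% SU spikes
and a ~15.8 Hz mean channel rate. Trains are homogeneous Poisson
(refractoriness not modeled). Waveforms are a per-cluster
difference-of-Gaussians template — sharp positive lobe aligned near sample
20, broader trough delayed by a peak-to-trough time drawn from 300–900 µs,
peak amplitude 40–150 µV — plus i.i.d. Gaussian sample noise.

Defaults chosen here (not dictated by the benchmark) and why:

- **noise_sd_uV = 2.** Fixed by energy analysis before any tuning: two
  extractions of one physical event differ by independent noise in each of
  the 10 selected orthonormal coefficients, so their expected distance is
  √(2·10·σ²) ≈ 8.9 µV at σ = 2 — consistent with the published thresholds
  (shared-source pairs must sit below 14.6 µV cross-bundle and near
  8.4 µV within a bundle, as real duplicate pairs evidently do).
- **extraction threshold = 5 × noise SD** (10 µV), the standard sorter
  setting; with 40–150 µV templates this yields event SNRs of 4–15.
- **Contamination defaults** (all off unless requested;
  `ContaminationSpec.default()` is the canonical contaminated benchmark):
  2 artifact trains at 2 Hz, each emitting one template on 4 channels
  across 2 bundles with ±4 µs jitter (well inside the 50 µs window);
  3 duplicated units — a single unit's train copied with ±20 µs jitter
  (inside the 250 µs central bin) and a ×0.8-attenuated template onto a
  second channel of its bundle, so the twin is the lower-SNR cluster;
  biphasic twins on 4 channels — narrow-spike (peak-to-trough ≤ 600 µs)
  units emit a polarity-flipped twin delayed by their peak-to-trough time
  with probability 0.8 per event, landing in the channel's merged artifact
  cluster (double extraction only happens to waveforms whose trough fits
  inside the 650 µs screen, hence the narrowness condition); one 50 Hz
  line-noise artifact cluster.

Ground truth tags every event (`clean`, `cross_bundle_train`,
`duplicated_unit`, `biphasic_twin`, `line_noise`) with the source event for
twins, so recall and false positives are exactly measurable.

What the generator does **not** emulate: bursting and refractoriness,
non-stationary rates, overlapping-spike superposition on one wire,
electrode drift, genuine synaptic synchrony, and the heavy-tailed artifact
menagerie of a real ward. Passing the recovery tests therefore shows the
detection logic is correct under the stated statistics, not that real-data
percentages will match; on real recordings the class composition and
cluster density dominate the flagged fractions.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on micro-fixtures (2–6 clusters) and small
simulations (16 channels, 120–300 s). The recovery benchmark runs at the
full default scale (80 channels, 25 min, ~1.9 M events; a few minutes of
CPU). The acceptance script runs the clean benchmark plus surrogate shift
once (~1–2 min). The specificity unit test uses 32 channels × 600 s at 1–4
SU/channel — real-recording-like cluster density, where the <0.1% flagged
expectation applies (see the scale note in the Part III section).

## Known limitations

- Part III's pooled false-positive rate grows with cluster density
  (quadratic pair count); on dense sessions consider raising `z_thr` or
  post-filtering sparse pairs.
- The 650 µs biphasic screen assumes referential montages; switch it off
  for bipolar recordings.
- Calibration needs both hemispheres implanted (the surrogate population is
  cross-hemispheric) and enough labeled artifacts or SU/MU coincidences.
- Thresholds refitted on a single session inherit that session's artifact
  mix; the published defaults were fitted on a large multi-session pool.
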