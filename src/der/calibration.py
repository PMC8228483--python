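"""Re-derive the similarity and z thresholds from a user's own session.

The published distance thresholds (14.6 uV cross-bundle, 8.4 uV within a
bundle) were fitted on one lab's amplifier chain; other gains and montages
need a refit.  The procedure compares two pair populations drawn from the
session itself:

* a *real* population — pairs of events of the relevant classes that occur
  within the coincidence window (across bundles for Part I, within one
  bundle for Part II), and
* a *surrogate* population — pairs of the same classes from different
  hemispheres that do **not** occur within the window (two wires in
  different hemispheres cannot record the same physical source).

Sweeping a distance threshold in steps of 0.1 over both distance
distributions yields an ROC curve; the operating point is the threshold
closest to the ideal corner (0, 1).  The coincidence window itself is
selected by maximizing the AUC over a grid of candidate windows, preferring
the larger window when AUCs tie within a tolerance (a larger window loses
nothing when separation is equal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import CalibrationError
from .features import FeatureBasis, selected_coeffs
from .model import DERConfig, SessionData
from .part3 import central_z, compute_ccg_matrix, label_suspicious_pairs

POPULATIONS = ("artifact_pairs", "su_mu_pairs")
RELATIONS = ("coincident_cross_bundle", "coincident_same_bundle",
             "noncoincident_cross_hemisphere")


@dataclass(frozen=True)
class ROCResult:
    """One ROC sweep over a distance-threshold grid."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    operating_threshold: float


def _population_mask(session: SessionData, population: str) -> np.ndarray:
    classes = session.event_class
    if population == "artifact_pairs":
        return classes == "artifact"
    if population == "su_mu_pairs":
        return (classes == "SU") | (classes == "MU")
    raise CalibrationError(f"unknown population {population!r}")


def sample_pair_distances(session: SessionData, features: np.ndarray,
                          basis: FeatureBasis, population: str,
                          relation: str, n_pairs: int = 10_000,
                          dt_us: int = 50,
                          seed: Optional[int] = None) -> np.ndarray:
    """Distances of ``n_pairs`` event pairs sampled (with replacement).

    ``population`` restricts both pair members by cluster class;
    ``relation`` selects coincident pairs (within ``dt_us``, across bundles
    or within one bundle on different channels) or the non-coincident
    different-hemisphere surrogate pairs.
    """
    if population not in POPULATIONS:
        raise CalibrationError(f"population must be one of {POPULATIONS}")
    if relation not in RELATIONS:
        raise CalibrationError(f"relation must be one of {RELATIONS}")
    if n_pairs == 0:
        return np.zeros(0)
    rng = np.random.default_rng(seed)
    mask = _population_mask(session, population)
    if not mask.any():
        raise CalibrationError(f"session has no events for {population!r}")
    sel = selected_coeffs(features, basis)

    if relation == "noncoincident_cross_hemisphere":
        hemi = session.event_hemisphere
        left = np.nonzero(mask & (hemi == "left"))[0]
        right = np.nonzero(mask & (hemi == "right"))[0]
        if len(left) == 0 or len(right) == 0:
            raise CalibrationError(
                f"{population!r} needs events in both hemispheres")
        out = np.empty(n_pairs)
        filled = 0
        t = session.timestamp_us
        while filled < n_pairs:
            m = n_pairs - filled
            a = rng.choice(left, size=m)
            b = rng.choice(right, size=m)
            ok = np.abs(t[a] - t[b]) > dt_us
            k = int(ok.sum())
            if k:
                out[filled:filled + k] = np.linalg.norm(
                    sel[a[ok]] - sel[b[ok]], axis=1)
                filled += k
        return out

    pairs = _coincident_candidate_pairs(session, mask, relation, dt_us)
    if len(pairs) == 0:
        raise CalibrationError(
            f"no coincident {population!r} pairs within {dt_us} us")
    pick = rng.integers(0, len(pairs), size=n_pairs)
    a = pairs[pick, 0]
    b = pairs[pick, 1]
    return np.linalg.norm(sel[a] - sel[b], axis=1)


def _coincident_candidate_pairs(session: SessionData, mask: np.ndarray,
                                relation: str, dt_us: int) -> np.ndarray:
    """All in-population event-index pairs with |dt| <= dt_us and the
    required bundle relation (n, 2)."""
    idx = np.nonzero(mask)[0]
    t = session.timestamp_us[idx]
    bundle = session.event_bundle[idx]
    channel = session.channel_id[idx]
    hi = np.searchsorted(t, t + dt_us, side="right")
    out: List[Tuple[int, int]] = []
    for a in range(len(idx)):
        for b in range(a + 1, hi[a]):
            if relation == "coincident_cross_bundle":
                if bundle[a] != bundle[b]:
                    out.append((idx[a], idx[b]))
            else:  # coincident_same_bundle
                if bundle[a] == bundle[b] and channel[a] != channel[b]:
                    out.append((idx[a], idx[b]))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def roc_curve(real: Sequence[float], surrogate: Sequence[float],
              step: float = 0.1) -> ROCResult:
    """Sweep a distance threshold from 0 to the largest observed distance.

    A real-population distance at or below the threshold is a true
    positive; a surrogate distance at or below it is a false positive.
    AUC is the trapezoidal integral of the (FPR, TPR) curve.
    """
    real = np.asarray(real, dtype=np.float64)
    surrogate = np.asarray(surrogate, dtype=np.float64)
    if len(real) == 0 or len(surrogate) == 0:
        raise CalibrationError("both populations must be nonempty")
    top = float(max(real.max(), surrogate.max()))
    thresholds = np.arange(0.0, top + step, step)
    sens = np.array([(real <= thr).mean() for thr in thresholds])
    spec = np.array([(surrogate > thr).mean() for thr in thresholds])
    fpr = 1.0 - spec
    # curve runs from (0,0) toward (1,1); close both ends for the integral
    xs = np.concatenate(([0.0], fpr, [1.0]))
    ys = np.concatenate(([0.0], sens, [1.0]))
    order = np.argsort(xs, kind="stable")
    auc = float(np.trapezoid(ys[order], xs[order]))
    dist = np.hypot(fpr, 1.0 - sens)
    best = int(np.argmin(dist))  # argmin takes the first == smallest threshold
    return ROCResult(thresholds=thresholds, sensitivity=sens,
                     specificity=spec, auc=auc,
                     operating_threshold=float(thresholds[best]))


def operating_point(roc: ROCResult) -> float:
    """Threshold whose (1 - specificity, sensitivity) is closest to (0, 1)."""
    dist = np.hypot(1.0 - roc.specificity, 1.0 - roc.sensitivity)
    return float(roc.thresholds[int(np.argmin(dist))])


DEFAULT_WINDOW_GRID_US = (32, 50, 100, 200, 500, 1000)


def sweep_time_windows(session: SessionData, features: np.ndarray,
                       basis: FeatureBasis, population: str = "artifact_pairs",
                       relation: str = "coincident_cross_bundle",
                       grid: Iterable[int] = DEFAULT_WINDOW_GRID_US,
                       n_pairs: int = 10_000, seed: Optional[int] = None,
                       auc_tolerance: float = 0.001
                       ) -> Tuple[int, Dict[int, ROCResult]]:
    """AUC for each candidate coincidence window; returns (best_dt, curves).

    The best window maximizes AUC; windows within ``auc_tolerance`` of the
    maximum are treated as ties and the *largest* tied window wins.
    """
    grid = sorted(set(int(g) for g in grid))
    if not grid:
        raise CalibrationError("window grid must be nonempty")
    results: Dict[int, ROCResult] = {}
    rng = np.random.default_rng(seed)
    for dt in grid:
        sub = int(rng.integers(0, 2**31 - 1))
        real = sample_pair_distances(session, features, basis, population,
                                     relation, n_pairs, dt, seed=sub)
        surr = sample_pair_distances(session, features, basis, population,
                                     "noncoincident_cross_hemisphere",
                                     n_pairs, dt, seed=sub + 1)
        results[dt] = roc_curve(real, surr)
    best_auc = max(r.auc for r in results.values())
    tied = [dt for dt in grid if results[dt].auc >= best_auc - auc_tolerance]
    return max(tied), results


def z_threshold_study(session: SessionData, z_grid: Sequence[float],
                      config: Optional[DERConfig] = None) -> Dict[str, np.ndarray]:
    """Fraction of each class flagged by Part III at each z threshold.

    Returns a mapping with ``z_thr`` and per-class flagged fractions
    (``SU``, ``MU``, ``artifact``); each fraction is non-increasing in z.
    The correlogram matrix is computed once and re-thresholded.
    """
    config = config or DERConfig()
    ccg = compute_ccg_matrix(session, config.t_bin_us, config.n_bins)
    zm = central_z(ccg)
    classes = session.event_class
    totals = {c: max(int((classes == c).sum()), 1) for c in ("SU", "MU", "artifact")}
    rows = {"z_thr": np.asarray(z_grid, dtype=np.float64)}
    fractions = {c: [] for c in ("SU", "MU", "artifact")}
    id_class = dict(zip(session.event_id.tolist(), classes))
    for z_thr in z_grid:
        records = label_suspicious_pairs(session, zm, z_thr, config.t_bin_us)
        counts = {c: 0 for c in ("SU", "MU", "artifact")}
        for rec in records:
            counts[id_class[rec.event_id]] += 1
        for c in ("SU", "MU", "artifact"):
            fractions[c].append(counts[c] / totals[c])
    for c in ("SU", "MU", "artifact"):
        rows[c] = np.asarray(fractions[c])
    return rows
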