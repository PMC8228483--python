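"""Part III — suspicious zero-lag cross-correlations between clusters.

For every unordered pair of clusters a cross-correlogram of spike-time lags
is built (81 bins of 500 us by default, lags up to t_max = half bin-width
times bin-count = 20.25 ms).  Independent units produce a flat correlogram;
duplicate recordings of one unit, or a shared artifact source, concentrate
counts at zero lag.  The central bin is scored as a z-value against the
mean and standard deviation of all other bins; pairs whose central z
exceeds the threshold have their coincident (central-bin) spikes labeled
according to the cluster-class rule table:

========  ==========================================  ===========================
Case      combination                                 labeled as artifact
========  ==========================================  ===========================
1         artifact x (SU or MU)                       all coincident events (both)
2         two clusters in different bundles           all coincident events (both)
3         SU x MU in the same bundle                  the MU coincident spikes
4         same class in the same bundle               the lower mean-SNR cluster's
                                                      coincident spikes
========  ==========================================  ===========================

The correlogram construction loops once over the time-ordered events and
only looks forward up to t_max; the matrix is completed afterwards via the
skew symmetry ``counts[i, j, b] == counts[j, i, n_bins - 1 - b]``.
Autocorrelations (the diagonal) are excluded: same-cluster coincidences are
Part II's domain.

Degenerate correlograms — zero variance outside the central bin but a
central count above the mean — are treated as suspicious: a pair that fires
*only* simultaneously is the archetypal duplicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .errors import ConfigError
from .model import PART3, DERConfig, DetectionRecord, SessionData

_CHUNK = 200_000


@dataclass(frozen=True)
class CCGMatrix:
    """All pairwise cross-correlograms of one session."""

    counts: np.ndarray           # (K, K, n_bins) int64
    t_bin_us: int
    n_bins: int
    cluster_ids: np.ndarray      # (K,) cluster id per matrix row

    @property
    def central_bin(self) -> int:
        return (self.n_bins - 1) // 2


@dataclass(frozen=True)
class ZMatrix:
    """Central-bin z-scores with degenerate-correlogram flags."""

    z: np.ndarray                # (K, K) float
    degenerate: np.ndarray       # (K, K) bool: std 0 but central above mean
    cluster_ids: np.ndarray

    def suspicious(self, z_thr: float) -> np.ndarray:
        """Boolean matrix of pairs above threshold.

        Degenerate pairs behave as ``z = +inf``: suspicious at every finite
        threshold.
        """
        return np.where(self.degenerate, np.inf, self.z) > z_thr


def compute_ccg_matrix(session: SessionData, t_bin_us: int = 500,
                       n_bins: int = 81) -> CCGMatrix:
    """Streaming construction of the full cross-correlogram matrix.

    Bin ``b`` covers lags ``[(b - h - 1/2) * t_bin, (b - h + 1/2) * t_bin)``
    with ``h = (n_bins - 1) / 2``; the central bin collects lags in
    ``[-t_bin/2, +t_bin/2)``.
    """
    if n_bins % 2 == 0:
        raise ConfigError("n_bins must be odd")
    cluster_ids = np.array(sorted(session.clusters), dtype=np.int64)
    K = len(cluster_ids)
    raw = np.zeros(K * K * n_bins, dtype=np.int64)
    t = session.timestamp_us
    n = len(t)
    half = (n_bins - 1) // 2
    t_max = (t_bin_us * n_bins) // 2
    # cluster_ids is sorted, so row index = searchsorted position
    cl = np.searchsorted(cluster_ids, session.cluster_id.astype(np.int64))

    hi = np.searchsorted(t, t + t_max, side="left")  # forward lag < t_max
    counts_fwd = hi - np.arange(n) - 1
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        c = counts_fwd[start:stop]
        total = int(c.sum())
        if total == 0:
            continue
        src = np.repeat(np.arange(start, stop), c)
        # target offsets 1..c within each source's forward window
        offs = np.arange(total) - np.repeat(np.cumsum(c) - c, c) + 1
        tgt = src + offs
        keep = cl[src] != cl[tgt]
        src, tgt = src[keep], tgt[keep]
        if len(src) == 0:
            continue
        lag = t[tgt] - t[src]
        b = half + (lag + t_bin_us // 2) // t_bin_us
        flat = (cl[src] * K + cl[tgt]) * n_bins + b
        raw += np.bincount(flat, minlength=raw.size)
    raw = raw.reshape(K, K, n_bins)
    counts = raw + raw.transpose(1, 0, 2)[:, :, ::-1]
    return CCGMatrix(counts=counts, t_bin_us=t_bin_us, n_bins=n_bins,
                     cluster_ids=cluster_ids)


def central_z(ccg: CCGMatrix) -> ZMatrix:
    """Z-score of the central bin against the mean/std of all other bins.

    ``z = 0`` for a perfectly flat correlogram; a zero-variance correlogram
    with a central excess is flagged degenerate (suspicious at any
    threshold).
    """
    if ccg.n_bins < 3:
        raise ConfigError("need at least 3 bins to z-score the central bin")
    cb = ccg.central_bin
    central = ccg.counts[:, :, cb].astype(np.float64)
    others = np.delete(ccg.counts, cb, axis=2).astype(np.float64)
    mean = others.mean(axis=2)
    std = others.std(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(std > 0, (central - mean) / np.where(std > 0, std, 1.0), 0.0)
    degenerate = (std == 0) & (central > mean)
    K = len(ccg.cluster_ids)
    z[np.arange(K), np.arange(K)] = 0.0
    degenerate[np.arange(K), np.arange(K)] = False
    return ZMatrix(z=z, degenerate=degenerate, cluster_ids=ccg.cluster_ids)


def _coincident_pairs(ta: np.ndarray, tb: np.ndarray,
                      half_bin_us: int) -> Tuple[np.ndarray, np.ndarray]:
    """Indices (into ta, tb) of all pairs with |dt| < half_bin_us."""
    lo = np.searchsorted(tb, ta - half_bin_us + 1, side="left")
    hi = np.searchsorted(tb, ta + half_bin_us, side="left")
    counts = hi - lo
    src = np.repeat(np.arange(len(ta)), counts)
    total = int(counts.sum())
    offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    tgt = np.repeat(lo, counts) + offs
    return src, tgt


def label_suspicious_pairs(session: SessionData, zmatrix: ZMatrix,
                           z_thr: float = 5.0,
                           t_bin_us: int = 500) -> List[DetectionRecord]:
    """Label coincident spikes of every cluster pair above the z threshold.

    Coincidence means a spike-time difference strictly below half the bin
    width (the central correlogram bin).  Each event is labeled at most
    once; the rule recorded is the first (lowest-numbered) case that fired
    for it.
    """
    suspicious = zmatrix.suspicious(z_thr)
    cluster_ids = zmatrix.cluster_ids
    half_bin = t_bin_us // 2
    # group event rows by cluster, preserving time order within each cluster
    order = np.argsort(session.cluster_id, kind="stable")
    cl_sorted = session.cluster_id[order]
    starts = np.searchsorted(cl_sorted, cluster_ids, side="left")
    ends = np.searchsorted(cl_sorted, cluster_ids, side="right")
    idx_by_cluster: Dict[int, np.ndarray] = {
        int(c): order[starts[k]:ends[k]] for k, c in enumerate(cluster_ids)
    }
    bundle_of_cluster = {
        int(cid): session.channels[meta.channel_id].bundle_id
        for cid, meta in session.clusters.items()
    }
    flagged: Dict[int, str] = {}  # event_id -> rule

    def mark(indices: np.ndarray, rule: str):
        for i in indices:
            e = int(session.event_id[i])
            if e not in flagged:
                flagged[e] = rule

    for a, b in np.argwhere(np.triu(suspicious, k=1)):
        ca, cb = int(cluster_ids[a]), int(cluster_ids[b])
        ia, ib = idx_by_cluster[ca], idx_by_cluster[cb]
        src, tgt = _coincident_pairs(session.timestamp_us[ia],
                                     session.timestamp_us[ib], half_bin)
        if len(src) == 0:
            continue
        co_a = ia[np.unique(src)]
        co_b = ib[np.unique(tgt)]
        meta_a = session.clusters[ca]
        meta_b = session.clusters[cb]
        classes = {meta_a.class_label, meta_b.class_label}
        same_bundle = bundle_of_cluster[ca] == bundle_of_cluster[cb]
        if "artifact" in classes and classes != {"artifact"}:
            mark(co_a, "table3_case1")
            mark(co_b, "table3_case1")
        elif not same_bundle:
            mark(co_a, "table3_case2")
            mark(co_b, "table3_case2")
        elif classes == {"SU", "MU"}:
            mu = co_a if meta_a.class_label == "MU" else co_b
            mark(mu, "table3_case3")
        else:
            # same class in the same bundle: lower mean-SNR cluster loses
            lower = co_a if (meta_a.mean_snr or 0) <= (meta_b.mean_snr or 0) \
                else co_b
            mark(lower, "table3_case4")

    return [
        DetectionRecord(event_id=e, detected_by=frozenset({PART3}),
                        rules=(rule,), retained_event_id=None)
        for e, rule in sorted(flagged.items())
    ]


def run_part3(session: SessionData, config: DERConfig) -> List[DetectionRecord]:
    """Single-pass Part III: correlograms, z-scores, rule-table labeling."""
    ccg = compute_ccg_matrix(session, config.t_bin_us, config.n_bins)
    zm = central_z(ccg)
    return label_suspicious_pairs(session, zm, config.z_thr, config.t_bin_us)


def export_z_matrix(zmatrix: ZMatrix, path) -> None:
    """Write the central-bin z matrix as CSV (cluster ids as header/index)."""
    import pandas as pd

    df = pd.DataFrame(zmatrix.z, index=zmatrix.cluster_ids,
                      columns=zmatrix.cluster_ids)
    df.to_csv(path, index_label="cluster_id")
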