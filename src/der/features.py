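"""Wavelet shape features and the similarity distance used by Parts I and II.

Every 64-sample waveform is decomposed with a five-level *orthonormal* Haar
discrete wavelet transform into 64 coefficients, ordered
``[A5 (2), D5 (2), D4 (4), D3 (8), D2 (16), D1 (32)]``.  Orthonormality
keeps the coefficients on the microvolt scale of the waveforms (energy is
conserved), so the fixed numeric distance thresholds of the algorithm are
meaningful physical quantities.

Dimensionality is then reduced to the ``k`` (default 10) coefficients whose
distribution across all events of the session deviates most from a normal
distribution, quantified by a one-sample Kolmogorov-Smirnov statistic on the
per-coefficient z-scores.  Deviation from normality marks coefficients that
carry structured (multi-modal) shape information rather than noise — the
same selection idea the upstream sorters use for clustering.  Shape
similarity of two events is the Euclidean distance of their selected
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import stats

from .errors import CalibrationError, ShapeError
from .model import WAVEFORM_SAMPLES, SessionData

_WAVELET = "haar"
_MODE = "periodization"  # exact orthonormal transform for dyadic lengths


@dataclass(frozen=True)
class FeatureBasis:
    """The selected discriminative wavelet dimensions of one session."""

    selected_dims: np.ndarray     # (k,) coefficient indices, by descending KS
    ks_statistics: np.ndarray     # (64,) per-coefficient deviation scores
    n_events_fit: int

    def __post_init__(self):
        dims = np.asarray(self.selected_dims)
        if len(np.unique(dims)) != len(dims):
            raise ValueError("selected dimensions must be distinct")
        if dims.size and (dims.min() < 0 or dims.max() >= WAVEFORM_SAMPLES):
            raise ValueError("selected dimensions must lie in [0, 64)")


def haar_dwt(waveform: np.ndarray, levels: int = 5) -> np.ndarray:
    """Orthonormal Haar coefficients of one 64-sample waveform."""
    w = np.asarray(waveform, dtype=np.float64)
    if w.shape != (WAVEFORM_SAMPLES,):
        raise ShapeError(f"waveform must have {WAVEFORM_SAMPLES} samples, "
                         f"got shape {w.shape}")
    return haar_dwt_matrix(w[None, :], levels=levels)[0]


def haar_dwt_matrix(waveforms: np.ndarray, levels: int = 5) -> np.ndarray:
    """Row-wise orthonormal Haar transform of an (n, 64) waveform matrix."""
    w = np.asarray(waveforms, dtype=np.float64)
    if w.ndim != 2 or w.shape[1] != WAVEFORM_SAMPLES:
        raise ShapeError(f"waveforms must be (n, {WAVEFORM_SAMPLES}), "
                         f"got shape {w.shape}")
    coeffs = pywt.wavedec(w, _WAVELET, level=levels, mode=_MODE, axis=1)
    return np.concatenate(coeffs, axis=1)


def inverse_haar(coeffs: np.ndarray, levels: int = 5) -> np.ndarray:
    """Inverse of :func:`haar_dwt` (row-wise for 2-D input)."""
    c = np.asarray(coeffs, dtype=np.float64)
    squeeze = c.ndim == 1
    if squeeze:
        c = c[None, :]
    if c.shape[1] != WAVEFORM_SAMPLES:
        raise ShapeError(f"expected {WAVEFORM_SAMPLES} coefficients")
    widths = [WAVEFORM_SAMPLES >> levels]
    widths += [WAVEFORM_SAMPLES >> lv for lv in range(levels, 0, -1)]
    parts = np.split(c, np.cumsum(widths)[:-1], axis=1)
    out = pywt.waverec(parts, _WAVELET, mode=_MODE, axis=1)
    return out[0] if squeeze else out


def session_features(session: SessionData, levels: int = 5,
                     invert_negative: bool = True) -> np.ndarray:
    """Wavelet coefficients for every event of a session, time order.

    With ``invert_negative`` (the default), negative-polarity waveforms are
    sign-inverted before the transform so a mirrored artifact (e.g. a spike
    picked up on the reference wire) matches its positive twin.
    """
    w = session.waveforms.astype(np.float64)
    if invert_negative and session.n_events:
        # polarity is +1/-1: positive rows unchanged, negative rows mirrored
        w = w * session.polarity[:, None].astype(np.float64)
    return haar_dwt_matrix(w, levels=levels)


def fit_feature_basis(coeff_matrix: np.ndarray, k: int = 10) -> FeatureBasis:
    """Select the ``k`` most non-normal coefficient dimensions.

    Each coefficient is z-scored across events and compared with a standard
    normal via the one-sample KS statistic; the ``k`` largest statistics win
    (ties broken toward the lower index).  Coefficients that are constant
    across events score 0 and are never selected ahead of varying ones.
    """
    c = np.asarray(coeff_matrix, dtype=np.float64)
    if c.ndim != 2:
        raise ShapeError("coefficient matrix must be 2-D (events x coefficients)")
    n, d = c.shape
    if n < 2 * k:
        raise CalibrationError(
            f"need at least {2 * k} events to fit a {k}-dimensional basis, "
            f"got {n}; provide more events or lower k"
        )
    ks = np.zeros(d)
    sd = c.std(axis=0)
    mean = c.mean(axis=0)
    constant = np.ptp(c, axis=0) == 0
    for j in range(d):
        if constant[j] or sd[j] == 0:
            continue
        z = (c[:, j] - mean[j]) / sd[j]
        ks[j] = stats.kstest(z, "norm").statistic
    # stable ordering: descending statistic, ascending index on ties
    order = np.lexsort((np.arange(d), -ks))
    return FeatureBasis(selected_dims=order[:k].copy(), ks_statistics=ks,
                        n_events_fit=n)


def selected_coeffs(coeff_matrix: np.ndarray, basis: FeatureBasis) -> np.ndarray:
    """Restrict a coefficient matrix to the basis dimensions."""
    return np.asarray(coeff_matrix)[:, basis.selected_dims]


def shape_distance(a: np.ndarray, b: np.ndarray, basis: FeatureBasis) -> float:
    """Euclidean distance of two events' selected wavelet coefficients (uV)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return float(np.linalg.norm(a[basis.selected_dims] - b[basis.selected_dims]))
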