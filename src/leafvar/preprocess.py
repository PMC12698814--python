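"""Chemometric preprocessing of leaf reflectance spectra.

Sensor splice correction, spectral-range trimming, per-species local-outlier
screening, standard normal variate (SNV) scaling, Savitzky-Golay smoothing /
derivatives, and the feature augmentation used for spectra-to-trait
calibration (raw + SNV + first/second derivatives + SNV-then-derivative).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import LocalOutlierFactor

from .synthetic import SpectraMatrix

SENSOR_JUNCTIONS = (1000, 1800)
SPLICE_MATCH_REGIONS = ((750, 1000), (1800, 1950))


# ---------------------------------------------------------------------------
# Splice correction
# ---------------------------------------------------------------------------


def _fit_line(wl: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row least-squares line fit; returns (intercept, slope)."""
    x = wl - wl.mean()
    slope = (y * x).sum(axis=-1) / (x**2).sum()
    intercept = y.mean(axis=-1)
    return intercept, slope


def _edge_prediction(wl: np.ndarray, values: np.ndarray, lo: int, hi: int, at: float) -> np.ndarray:
    """Extrapolate a short linear fit over wavelengths [lo, hi] to ``at``."""
    sel = (wl >= lo) & (wl <= hi)
    if sel.sum() < 2:
        raise ValueError("not enough wavelengths near junction for splice fit")
    wsel = wl[sel].astype(float)
    intercept, slope = _fit_line(wsel, values[..., sel])
    return intercept + slope * (at - wsel.mean())


def splice_correct(
    spectra: SpectraMatrix,
    junctions: tuple[int, int] = SENSOR_JUNCTIONS,
    match_regions: tuple[tuple[int, int], tuple[int, int]] = SPLICE_MATCH_REGIONS,
    fit_width: int = 20,
) -> SpectraMatrix:
    """Remove per-sensor reflectance steps at the sensor junctions.

    The middle sensor (SWIR1) is the anchor.  For each junction the offset of
    the outer sensor is estimated as the difference between short linear
    extrapolations of the two sides to the junction midpoint, and the whole
    outer sensor is shifted additively by that offset.  The estimation
    windows are capped to the configured match regions, so values outside
    them are shifted by a constant only and within-sensor band shapes are
    preserved exactly.
    """
    wl = spectra.wavelengths
    j1, j2 = junctions
    if wl[0] > j1 or wl[-1] <= j2:
        raise ValueError("junctions outside available wavelength range")
    v = spectra.values.copy()

    # VNIR (<= j1) against SWIR1 (j1+1 .. j2)
    lo1 = max(match_regions[0][0], j1 - fit_width)
    vnir_pred = _edge_prediction(wl, v, lo1, j1, j1 + 0.5)
    swir1_pred = _edge_prediction(wl, v, j1 + 1, j1 + 1 + fit_width, j1 + 0.5)
    v[:, wl <= j1] += (swir1_pred - vnir_pred)[:, None]

    # SWIR2 (>= j2+1) against SWIR1
    hi2 = min(match_regions[1][1], j2 + 1 + fit_width)
    swir2_pred = _edge_prediction(wl, v, j2 + 1, hi2, j2 + 0.5)
    swir1b_pred = _edge_prediction(wl, v, j2 - fit_width, j2, j2 + 0.5)
    v[:, wl >= j2 + 1] += (swir1b_pred - swir2_pred)[:, None]

    out = spectra.copy()
    out.values = v
    out.spliced = True
    return out


def junction_discontinuity(spectra: SpectraMatrix, junction: int = 1000) -> np.ndarray:
    """|r(j) - r(j+1)| per leaf, a diagnostic of residual splice steps."""
    wl = spectra.wavelengths
    i = int(np.where(wl == junction)[0][0])
    return np.abs(spectra.values[:, i + 1] - spectra.values[:, i])


# ---------------------------------------------------------------------------
# Trimming and outlier screening
# ---------------------------------------------------------------------------


def trim_range(spectra: SpectraMatrix, low: int = 400, high: int = 2500) -> SpectraMatrix:
    """Retain wavelengths in [low, high] inclusive (drops noisy sensor edges)."""
    if low >= high:
        raise ValueError("low must be < high")
    wl = spectra.wavelengths
    sel = (wl >= low) & (wl <= high)
    if not sel.any():
        raise ValueError("trim range retains no wavelengths")
    out = SpectraMatrix(
        list(spectra.leaf_ids), wl[sel], spectra.values[:, sel], spectra.spliced, True
    )
    return out


def lof_outliers(
    spectra: SpectraMatrix,
    groups: pd.Series | np.ndarray | list,
    n_neighbors: int = 20,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Local outlier factor per spectrum, computed within each group.

    ``groups`` assigns every leaf to a group (typically its species); LOF is
    computed separately per group on the raw reflectance rows.  A leaf is
    flagged iff its LOF score exceeds ``threshold`` (inliers score about 1).
    Returns a frame with leaf_id, group, lof and outlier columns, in the
    input row order.
    """
    groups = np.asarray(groups)
    if len(groups) != len(spectra.leaf_ids):
        raise ValueError("groups length must match number of spectra")
    scores = np.empty(len(groups))
    for g in pd.unique(groups):
        idx = np.where(groups == g)[0]
        if len(idx) <= n_neighbors:
            raise ValueError(
                f"group {g!r} has {len(idx)} spectra; needs > n_neighbors={n_neighbors}"
            )
        lof = LocalOutlierFactor(n_neighbors=n_neighbors)
        lof.fit(spectra.values[idx])
        scores[idx] = -lof.negative_outlier_factor_
    return pd.DataFrame(
        {
            "leaf_id": spectra.leaf_ids,
            "group": groups,
            "lof": scores,
            "outlier": scores > threshold,
        }
    )


# ---------------------------------------------------------------------------
# SNV, Savitzky-Golay, augmentation
# ---------------------------------------------------------------------------


def snv(values: np.ndarray) -> np.ndarray:
    """Standard normal variate: center and scale each spectrum to SD 1."""
    values = np.asarray(values, float)
    mean = values.mean(axis=-1, keepdims=True)
    sd = values.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant spectrum has zero variance; SNV undefined")
    return (values - mean) / sd


def sg_filter(
    values: np.ndarray, window: int = 51, polyorder: int = 2, deriv: int = 0
) -> np.ndarray:
    """Savitzky-Golay smoothing/derivative, valid region only.

    Derivatives are per 1-nm step.  The ``(window - 1) // 2`` points at each
    edge, where the fit window would be truncated, are dropped, so the output
    has ``n - window + 1`` points.
    """
    values = np.asarray(values, float)
    n = values.shape[-1]
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if n < window:
        raise ValueError("spectrum shorter than filter window")
    full = savgol_filter(values, window, polyorder, deriv=deriv, delta=1.0, axis=-1)
    half = (window - 1) // 2
    return full[..., half : n - half]


def augment_features(values: np.ndarray, window: int = 51, polyorder: int = 2) -> np.ndarray:
    """Chemometric feature augmentation for calibration models.

    Concatenates five channels, each trimmed to the Savitzky-Golay valid
    region of length ``n - window + 1``: raw reflectance, SNV, first and
    second SG derivatives, and the first SG derivative of the SNV spectrum.
    A 2501-point spectrum therefore yields 5 x 2451 = 12255 features.
    """
    values = np.asarray(values, float)
    half = (window - 1) // 2
    interior = slice(half, values.shape[-1] - half)
    z = snv(values)
    channels = [
        values[..., interior],
        z[..., interior],
        sg_filter(values, window, polyorder, deriv=1),
        sg_filter(values, window, polyorder, deriv=2),
        sg_filter(z, window, polyorder, deriv=1),
    ]
    return np.concatenate(channels, axis=-1)


class SpectralFeatureAugmenter(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer wrapping :func:`augment_features`."""

    def __init__(self, window: int = 51, polyorder: int = 2):
        self.window = window
        self.polyorder = polyorder

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("expected a 2-d array of spectra")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return augment_features(np.asarray(X, float), self.window, self.polyorder)

    def get_feature_names_out(self, input_features=None):
        n = self.n_features_in_ - self.window + 1
        names = []
        for ch in ("raw", "snv", "sg1", "sg2", "snv_sg1"):
            names += [f"{ch}_{i}" for i in range(n)]
        return np.asarray(names)
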