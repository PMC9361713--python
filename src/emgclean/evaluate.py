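"""Filtering-performance features in the time and frequency domains.

Time-domain features compare median windowed-RMS amplitudes between an
unfiltered signal (Xin) and a filtered one (Xout), split by contamination
region (subscript 0: noise-only; 1: EMG-contaminated):

    GL    = 20·log10(Xout0' / Xin0')   effect of filtering where no EMG
    GH    = 20·log10(Xout1' / Xin1')   effect of filtering inside bursts
    GXin  = 20·log10(Xin1'  / Xin0')   burst-to-background ratio, before
    GXout = 20·log10(Xout1' / Xout0')  burst-to-background ratio, after

where X' is the median of per-window RMS over non-overlapping 1 s windows
tiled over the concatenated samples of the region.  A good canceller gives
GH < 0 (bursts attenuated) with GL ≈ 0 (background preserved).

Sweeping the soft-threshold multiplier k from 0.1 to 2.0 turns GL and GH
into feature vectors; the normalized Euclidean distance between the two
vectors quantifies how contaminated a channel is (identical curves ⇒
uncontaminated).

Frequency-domain features are the median frequency and its power, read off
a Yule-Walker autoregressive PSD (order 10) evaluated on a fine grid, for
the full signal and for each canonical EEG band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import signal as sps
from statsmodels.regression.linear_model import yule_walker

from .decompose import Method, decompose
from .reference import estimate_thresholds, make_emg_reference
from .synth import EEG_BANDS
from .types import ContaminationMask, TimeSeries

__all__ = [
    "Region",
    "TimeFeatures",
    "FeatureCurve",
    "SpectralFeatures",
    "region_rms_median",
    "time_features",
    "feature_curve",
    "normalized_distance",
    "ar_spectrum",
    "median_frequency",
    "band_features",
    "DEFAULT_K_GRID",
]


class Region(str, Enum):
    NOISE = "noise"
    EMG = "emg"


DEFAULT_K_GRID = np.round(np.arange(0.1, 2.01, 0.1), 10)


@dataclass(frozen=True)
class TimeFeatures:
    GL: float
    GH: float
    GXin: float
    GXout: float
    window_s: float
    medians: dict[str, float]


@dataclass(frozen=True)
class FeatureCurve:
    k_grid: np.ndarray
    GL_of_k: np.ndarray
    GH_of_k: np.ndarray


@dataclass(frozen=True)
class SpectralFeatures:
    f: np.ndarray
    pxx: np.ndarray
    fmed: float
    p_at_fmed: float
    band: str = "full"


def region_rms_median(
    x: TimeSeries,
    mask: ContaminationMask,
    region: Region | str,
    window_s: float = 1.0,
) -> float:
    """Median of per-window RMS over the selected contamination region.

    Windows are tiled over the *concatenated* samples of the region, so
    bursts shorter than the window still contribute; a trailing partial
    window is discarded.
    """
    region = Region(region)
    if mask.n != x.n:
        raise ValueError("mask length must match the signal")
    sel = mask.flags if region is Region.EMG else ~mask.flags
    samples = x.samples[sel]
    w = int(round(window_s * x.fs))
    n_win = samples.size // w
    if n_win < 1:
        raise ValueError(
            f"{region.value} region ({samples.size} samples) shorter than one "
            f"{window_s} s window ({w} samples)"
        )
    windows = samples[: n_win * w].reshape(n_win, w)
    rms = np.sqrt(np.mean(windows**2, axis=1))
    return float(np.median(rms))


def time_features(
    xin: TimeSeries,
    xout: TimeSeries,
    mask: ContaminationMask,
    window_s: float = 1.0,
) -> TimeFeatures:
    """GL, GH, GXin, GXout from the four region RMS medians."""
    m = {
        "Xin0": region_rms_median(xin, mask, Region.NOISE, window_s),
        "Xin1": region_rms_median(xin, mask, Region.EMG, window_s),
        "Xout0": region_rms_median(xout, mask, Region.NOISE, window_s),
        "Xout1": region_rms_median(xout, mask, Region.EMG, window_s),
    }
    def db(a, b):
        return 20.0 * np.log10(a / b)
    return TimeFeatures(
        GL=db(m["Xout0"], m["Xin0"]),
        GH=db(m["Xout1"], m["Xin1"]),
        GXin=db(m["Xin1"], m["Xin0"]),
        GXout=db(m["Xout1"], m["Xout0"]),
        window_s=window_s,
        medians=m,
    )


def feature_curve(
    x: TimeSeries,
    method: Method | str,
    mask: ContaminationMask,
    k_grid: np.ndarray = DEFAULT_K_GRID,
    params: dict | None = None,
    window_s: float = 1.0,
) -> FeatureCurve:
    """GL(k) and GH(k) for the soft-threshold sweep.

    The decomposition is computed once; each k rescales the per-component
    noise SDs into thresholds and rebuilds the reference, which plays the
    role of the filtered signal (xout) against the raw input (xin).
    """
    k_grid = np.asarray(k_grid, dtype=float)
    comps = decompose(x, method, params)
    gl = np.empty(k_grid.size)
    gh = np.empty(k_grid.size)
    if comps.method is Method.EMD_PCA:
        # k-independent reconstruction: constant curves
        ref = TimeSeries(comps.components.sum(axis=0), x.fs)
        tf = time_features(x, ref, mask, window_s)
        gl[:] = tf.GL
        gh[:] = tf.GH
        return FeatureCurve(k_grid, gl, gh)
    base = estimate_thresholds(comps, mask, k=1.0)
    for j, k in enumerate(k_grid):
        ref = np.zeros(x.n)
        for comp, sd in zip(comps.components, base.t):
            t = k * sd
            ref += np.sign(comp) * np.maximum(np.abs(comp) - t, 0.0)
        tf = time_features(x, TimeSeries(ref, x.fs), mask, window_s)
        gl[j] = tf.GL
        gh[j] = tf.GH
    return FeatureCurve(k_grid, gl, gh)


def normalized_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Bounded contamination metric d = ‖u−v‖₂ / (‖u‖₂ + ‖v‖₂) ∈ [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("feature vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu + nv == 0:
        return 0.0
    return float(np.linalg.norm(u - v) / (nu + nv))


def ar_spectrum(
    x: TimeSeries, order: int = 10, df: float = 0.01
) -> SpectralFeatures:
    """Yule-Walker autoregressive PSD on the grid f = 0, df, ..., fs/2.

    AR coefficients come from the biased (MLE) autocovariances via
    Levinson-Durbin; the one-sided PSD is σ²/fs·|A(f)|⁻² with interior
    frequencies doubled, so the grid integral approximates the signal
    variance.
    """
    if np.ptp(x.samples) == 0:
        raise ValueError("constant signal: autocorrelation is singular")
    rho, sigma = yule_walker(x.samples, order=order, method="mle")
    f = np.arange(0.0, x.fs / 2 + df / 2, df)
    _, h = sps.freqz(1.0, np.r_[1.0, -rho], worN=f, fs=x.fs)
    pxx = (sigma**2 / x.fs) * np.abs(h) ** 2
    pxx[1:] *= 2.0
    if f[-1] == x.fs / 2:
        pxx[-1] /= 2.0
    fmed, p_at = median_frequency(f, pxx)
    return SpectralFeatures(f=f, pxx=pxx, fmed=fmed, p_at_fmed=p_at)


def median_frequency(f: np.ndarray, pxx: np.ndarray) -> tuple[float, float]:
    """Smallest grid frequency at which the cumulative PSD reaches half its total."""
    pxx = np.asarray(pxx, dtype=float)
    total = pxx.sum()
    if total <= 0:
        raise ValueError("spectrum has no positive mass")
    cum = np.cumsum(pxx)
    i = int(np.searchsorted(cum, total / 2.0))
    return float(f[i]), float(pxx[i])


def band_features(
    x: TimeSeries,
    order: int = 10,
    df: float = 0.01,
    bands: dict[str, tuple[float, float]] | None = None,
) -> dict[str, SpectralFeatures]:
    """Median frequency and its power for the full signal and each EEG band.

    Each band is isolated by a zero-phase 4th-order Butterworth band-pass
    before the AR spectrum is fit.
    """
    if x.fs / 2 <= 70:
        raise ValueError("sampling rate too low to resolve the gamma band")
    bands = bands or EEG_BANDS
    out: dict[str, SpectralFeatures] = {}
    full = ar_spectrum(x, order, df)
    out["full"] = full
    for name, (lo, hi) in bands.items():
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=x.fs, output="sos")
        xb = TimeSeries(sps.sosfiltfilt(sos, x.samples), x.fs)
        sf = ar_spectrum(xb, order, df)
        out[name] = SpectralFeatures(
            f=sf.f, pxx=sf.pxx, fmed=sf.fmed, p_at_fmed=sf.p_at_fmed, band=name
        )
    return out
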