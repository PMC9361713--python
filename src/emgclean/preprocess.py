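"""Detrending and amplitude-outlier replacement.

Trend removal precedes decomposition: electrode-impedance drift and
cable/skin motion put slow additive components into both EEG and EMG
channels.  The non-linear trend is a windowed-median curve re-sampled by
monotone piecewise-cubic (PCHIP) interpolation.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

from .types import ContaminationMask, TimeSeries

__all__ = [
    "remove_linear_trend",
    "estimate_nonlinear_trend",
    "remove_nonlinear_trend",
    "replace_outliers",
]


def remove_linear_trend(x: TimeSeries) -> TimeSeries:
    """Subtract the least-squares straight line from the signal."""
    if x.n < 2:
        raise ValueError("need at least 2 samples to fit a line")
    return x.with_samples(sps.detrend(x.samples, type="linear"))


def estimate_nonlinear_trend(x: TimeSeries, window_ms: float = 20.0) -> TimeSeries:
    """Windowed-median trend, PCHIP-interpolated back to every sample.

    Medians are taken over non-overlapping rectangular windows (default
    20 ms — 100 samples at 5 kHz); a trailing partial window is kept as its
    own window so no samples are discarded.  Anchors sit at window centres;
    the first/last medians are held constant to the record edges so the
    evaluation never extrapolates.
    """
    w = int(round(window_ms / 1000.0 * x.fs))
    if w < 1:
        raise ValueError("window must contain at least 1 sample")
    if w > x.n:
        raise ValueError(f"window ({w} samples) longer than signal ({x.n})")
    n = x.n
    starts = np.arange(0, n, w)
    centers = []
    medians = []
    for s in starts:
        e = min(s + w, n)
        centers.append((s + e - 1) / 2.0)
        medians.append(np.median(x.samples[s:e]))
    centers = np.asarray(centers, dtype=float)
    medians = np.asarray(medians, dtype=float)
    # hold edge medians constant out to the record boundaries
    if centers[0] > 0:
        centers = np.r_[0.0, centers]
        medians = np.r_[medians[0], medians]
    if centers[-1] < n - 1:
        centers = np.r_[centers, float(n - 1)]
        medians = np.r_[medians, medians[-1]]
    if centers.size == 1:
        trend = np.full(n, medians[0])
    else:
        trend = PchipInterpolator(centers, medians)(np.arange(n, dtype=float))
    return x.with_samples(trend)


def remove_nonlinear_trend(x: TimeSeries, window_ms: float = 20.0) -> TimeSeries:
    """Subtract the windowed-median PCHIP trend."""
    return x.with_samples(x.samples - estimate_nonlinear_trend(x, window_ms).samples)


def replace_outliers(
    x: TimeSeries,
    mask: ContaminationMask,
    k_sd: float = 10.0,
    seed: int = 0,
) -> TimeSeries:
    """Replace extreme samples by standard-normal draws.

    Thresholds are mean ± ``k_sd``·SD of the samples in the EMG-contaminated
    (mask-high) regions; any sample of the whole record falling outside them
    is replaced by a seeded draw from N(0, 1).  Note the replacements are
    literally unit-normal — they are *not* rescaled to the signal's
    amplitude, so on a µV-scale channel they are near-zero insertions.
    """
    if mask.n != x.n:
        raise ValueError("mask length must match the signal")
    high = mask.high_samples_of(x.samples)
    if high.size < 2:
        raise ValueError("mask must contain at least 2 high samples to set thresholds")
    mu = high.mean()
    sd = high.std()
    lo, hi = mu - k_sd * sd, mu + k_sd * sd
    out = x.samples.copy()
    bad = (out < lo) | (out > hi)
    if bad.any():
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
        out[bad] = rng.standard_normal(int(bad.sum()))
    return x.with_samples(out)
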