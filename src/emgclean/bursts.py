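"""Automatic EMG burst detection: from raw channel to binary contamination mask.

The detector mirrors the de-noising front end: detrend, decompose by EMD,
soft-threshold the components against statistics from a known noise-only
window, sum, take a moving-RMS energy envelope, binarize against the
envelope's noise statistics, and clean the binary signal morphologically.
It is normally run on a simultaneously recorded EMG channel, but works on
the contaminated EEG itself when no EMG channel exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .decompose import decompose
from .preprocess import remove_linear_trend, remove_nonlinear_trend
from .reference import estimate_thresholds, soft_threshold
from .types import ContaminationMask, TimeSeries

__all__ = ["BurstDetectorOptions", "energy_envelope", "detect_emg_bursts"]


@dataclass(frozen=True)
class BurstDetectorOptions:
    """Detector tuning.

    Defaults assume contraction-protocol timing: the shortest burst is
    0.5 s and inter-burst gaps are at least 2 s.  Gap merging (200 ms) runs
    before the duration filter so a burst briefly dipping under the level
    is never discarded piecewise; the 400 ms minimum duration then rejects
    sub-burst noise excursions — the moving-RMS envelope widens true bursts,
    never shortens them, so every real contraction survives the floor.
    ``threshold_c`` sets the binarization level at
    mean + c·SD of the envelope over the noise window; the level is floored
    at ``level_floor_frac`` of the envelope's 95th percentile, because
    soft-thresholding can null the noise window almost perfectly while
    leaving residual wiggle elsewhere — without the floor the level would
    collapse toward zero on a clean channel.  The floor scales with the
    envelope, so the mask stays invariant to amplitude scaling, and on a
    burst-free record the 95th percentile is itself noise-level so the
    noise-window rule still dominates.
    """

    envelope_window_ms: float = 100.0
    threshold_c: float = 3.0
    level_floor_frac: float = 0.1
    min_duration_ms: float = 400.0
    merge_gap_ms: float = 200.0
    soft_k: float = 1.5
    detrend_window_ms: float = 20.0
    max_components: int = 10


def energy_envelope(x: TimeSeries, window_ms: float = 100.0) -> TimeSeries:
    """Centered moving root-mean-square of the signal."""
    w = int(round(window_ms / 1000.0 * x.fs))
    if w < 1:
        raise ValueError("envelope window must contain at least 1 sample")
    if w > x.n:
        raise ValueError("envelope window longer than the signal")
    ms = uniform_filter1d(x.samples**2, size=w, mode="nearest")
    return x.with_samples(np.sqrt(np.maximum(ms, 0.0)))


def _merge_gaps(flags: np.ndarray, max_gap: int) -> np.ndarray:
    out = flags.copy()
    mask = ContaminationMask(~out, 1.0)
    for i0, i1 in mask.intervals:
        if i0 > 0 and i1 < out.size and (i1 - i0) < max_gap:
            out[i0:i1] = True
    return out


def _drop_short(flags: np.ndarray, min_len: int) -> np.ndarray:
    out = flags.copy()
    mask = ContaminationMask(out, 1.0)
    for i0, i1 in mask.intervals:
        if (i1 - i0) < min_len:
            out[i0:i1] = False
    return out


def detect_emg_bursts(
    x: TimeSeries,
    noise_window: tuple[float, float],
    opts: BurstDetectorOptions | None = None,
) -> ContaminationMask:
    """Detect EMG activity and return a per-sample contamination mask.

    ``noise_window`` is a (start_s, end_s) interval known to contain only
    baseline activity; it anchors both the component thresholds and the
    envelope binarization level.
    """
    opts = opts or BurstDetectorOptions()
    t0, t1 = noise_window
    i0, i1 = int(round(t0 * x.fs)), int(round(t1 * x.fs))
    if not (0 <= i0 < i1 <= x.n):
        raise ValueError("noise window must lie within the record")
    if (t1 - t0) < 0.1:
        raise ValueError("noise window must be at least 0.1 s long")

    y = remove_linear_trend(x)
    y = remove_nonlinear_trend(y, opts.detrend_window_ms)
    comps = decompose(y, "emd", {"max_components": opts.max_components})
    # dummy all-low mask; thresholds come from the explicit noise window
    dummy = ContaminationMask(np.zeros(x.n, dtype=bool), x.fs)
    tv = estimate_thresholds(comps, dummy, k=opts.soft_k, noise_window=(i0, i1))
    denoised = np.zeros(x.n)
    for comp, t in zip(comps.components, tv.t):
        denoised += soft_threshold(comp, t)

    env = energy_envelope(TimeSeries(denoised, x.fs), opts.envelope_window_ms)
    # trim half an envelope window off each end so burst energy adjacent to
    # the noise window cannot leak into its statistics
    half = int(round(opts.envelope_window_ms / 2000.0 * x.fs))
    j0 = min(i0 + half, i1 - 1)
    j1 = max(i1 - half, j0 + 1)
    noise_env = env.samples[j0:j1]
    level = noise_env.mean() + opts.threshold_c * noise_env.std()
    level = max(level, opts.level_floor_frac * np.percentile(env.samples, 95))
    flags = env.samples > level

    flags = _merge_gaps(flags, int(round(opts.merge_gap_ms / 1000.0 * x.fs)))
    flags = _drop_short(flags, int(round(opts.min_duration_ms / 1000.0 * x.fs)))
    return ContaminationMask(flags, x.fs)
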