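"""Soft-thresholded component reconstruction: the EMG and EEG reference signals.

Each decomposition component is shrunk toward zero by a threshold set from
its own amplitude over the noise-only (mask-low) region — t_m = k·SD_m,
with k = 1.5 as the conventional default.  Summing the shrunk components
yields the EMG reference: a version of the contaminated channel with the
low-amplitude EEG background largely suppressed and the bursts preserved.
Subtracting it from the contaminated channel yields the EEG reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decompose import ComponentSet, Method, decompose
from .types import ContaminationMask, TimeSeries

__all__ = [
    "ThresholdVector",
    "estimate_thresholds",
    "soft_threshold",
    "make_emg_reference",
    "make_eeg_reference",
]


@dataclass(frozen=True)
class ThresholdVector:
    """Per-component soft thresholds t_m = k · SD(component m | noise region)."""

    t: np.ndarray
    k: float
    noise_source: np.ndarray  # (m, 2) sample intervals used as the noise region

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        if np.any(self.t < 0):
            raise ValueError("thresholds must be nonnegative")


def estimate_thresholds(
    c: ComponentSet,
    mask: ContaminationMask,
    k: float = 1.5,
    noise_window: tuple[int, int] | None = None,
) -> ThresholdVector:
    """Thresholds from component SDs over the noise region.

    By default all mask-low samples are pooled; ``noise_window`` restricts
    the statistics to one explicit sample interval instead.
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    if mask.n != c.n:
        raise ValueError("mask length must match components")
    if noise_window is not None:
        i0, i1 = noise_window
        sel = np.zeros(c.n, dtype=bool)
        sel[i0:i1] = True
        source = np.array([[i0, i1]])
    else:
        sel = ~mask.flags
        source = ContaminationMask(sel, mask.fs).intervals
    if sel.sum() < 2:
        raise ValueError("need at least 2 noise samples to estimate thresholds")
    sds = c.components[:, sel].std(axis=1)
    return ThresholdVector(k * sds, k, source)


def soft_threshold(c_m: np.ndarray, t_m: float) -> np.ndarray:
    """Elementwise shrinkage sign(c)·max(|c| − t, 0)."""
    if t_m < 0:
        raise ValueError("threshold must be nonnegative")
    c_m = np.asarray(c_m, dtype=float)
    return np.sign(c_m) * np.maximum(np.abs(c_m) - t_m, 0.0)


def _thresholded_sum(c: ComponentSet, tv: ThresholdVector) -> np.ndarray:
    out = np.zeros(c.n)
    for comp, t in zip(c.components, tv.t):
        out += soft_threshold(comp, t)
    return out


def make_emg_reference(
    x: TimeSeries,
    method: Method | str,
    mask: ContaminationMask,
    k: float = 1.5,
    params: dict | None = None,
    components: ComponentSet | None = None,
) -> TimeSeries:
    """Decompose, shrink, and reconstruct the EMG reference signal.

    For EMD-PCA the retained principal-axis components already form the
    de-noised reconstruction, so no thresholding is applied.  A
    pre-computed ``components`` set may be passed to amortize the
    decomposition across several k values.
    """
    c = components if components is not None else decompose(x, method, params)
    if c.method is Method.EMD_PCA:
        return TimeSeries(c.components.sum(axis=0), x.fs)
    tv = estimate_thresholds(c, mask, k)
    return TimeSeries(_thresholded_sum(c, tv), x.fs)


def make_eeg_reference(contaminated: TimeSeries, emg_ref: TimeSeries) -> TimeSeries:
    """EEG reference = contaminated − EMG reference.

    The sign convention keeps EEG polarity in the reference; the quadratic
    adaptive filters downstream are indifferent to it.
    """
    if contaminated.n != emg_ref.n:
        raise ValueError("length mismatch between contaminated signal and reference")
    return contaminated.with_samples(contaminated.samples - emg_ref.samples)
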