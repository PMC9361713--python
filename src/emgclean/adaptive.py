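"""Adaptive noise cancellation: LMS, NLMS, RLS, and batch FIR Wiener filtering.

The canceller drives an FIR filter with the reference signal and adapts its
taps so the output tracks the contaminated (desired) channel.  Which signal
is "the cleaned EEG" depends on the reference kind: with an EMG reference
the filter predicts the contamination and the *error* d − y is the cleaned
signal; with an EEG reference the filter tracks the EEG-like reference and
its *output* y is the cleaned signal.

Default tap counts (10; 4 for NLMS) and the 1e-7 step scale follow common
settings for µV-scale EEG.  RLS and Wiener have no step size: the 1e-7
scale enters RLS as the inverse-correlation initialization δ, and the
Wiener solution is step-free.  The RLS forgetting factor defaults to
0.9999: burst-gated references leave long stretches with almost no
excitation, and a shorter memory lets the inverse-correlation matrix wind
up during the quiet gaps and destabilize the taps at burst onsets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy.linalg import solve_toeplitz

from .types import TimeSeries

__all__ = [
    "FilterMethod",
    "ReferenceKind",
    "FilterConfig",
    "FilterResult",
    "adaptive_filter",
    "clean_eeg",
]


class FilterMethod(str, Enum):
    LMS = "lms"
    NLMS = "nlms"
    RLS = "rls"
    WIENER = "wiener"


class ReferenceKind(str, Enum):
    EMG_REF = "emg"
    EEG_REF = "eeg"


@dataclass(frozen=True)
class FilterConfig:
    method: FilterMethod = FilterMethod.RLS
    order: int | None = None  # default 10; NLMS defaults to 4
    step: float = 1e-7  # LMS step µ
    nlms_step: float = 0.1  # normalized step for NLMS
    nlms_eps: float = 1e-7
    rls_forgetting: float = 0.9999
    rls_delta: float = 1e-7
    reference_kind: ReferenceKind = ReferenceKind.EEG_REF

    def __post_init__(self):
        object.__setattr__(self, "method", FilterMethod(self.method))
        object.__setattr__(self, "reference_kind", ReferenceKind(self.reference_kind))
        if self.order is not None and self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.step <= 0 or self.nlms_step <= 0:
            raise ValueError("step sizes must be positive")
        if not (0 < self.rls_forgetting <= 1):
            raise ValueError("RLS forgetting factor must lie in (0, 1]")

    @property
    def effective_order(self) -> int:
        if self.order is not None:
            return self.order
        return 4 if self.method is FilterMethod.NLMS else 10


@dataclass(frozen=True)
class FilterResult:
    output: TimeSeries  # filter output y
    error: TimeSeries  # d - y
    weights: np.ndarray  # final taps
    cleaned: TimeSeries  # selected per reference kind


def _tap_matrix(ref: np.ndarray, order: int) -> np.ndarray:
    """(n, order) matrix of tap-delay vectors [x_i, x_{i-1}, ..], zero-padded."""
    padded = np.r_[np.zeros(order - 1), ref]
    return sliding_window_view(padded, order)[:, ::-1]


def _run_lms(d, ref, order, mu):
    X = _tap_matrix(ref, order)
    w = np.zeros(order)
    y = np.empty_like(d)
    for i in range(d.size):
        xi = X[i]
        y[i] = w @ xi
        e = d[i] - y[i]
        w += 2.0 * mu * e * xi
    return y, w


def _run_nlms(d, ref, order, mu, eps):
    X = _tap_matrix(ref, order)
    w = np.zeros(order)
    y = np.empty_like(d)
    for i in range(d.size):
        xi = X[i]
        y[i] = w @ xi
        e = d[i] - y[i]
        w += (mu / (eps + xi @ xi)) * e * xi
    return y, w


def _run_rls(d, ref, order, lam, delta):
    X = _tap_matrix(ref, order)
    w = np.zeros(order)
    P = np.eye(order) / delta
    y = np.empty_like(d)
    inv_lam = 1.0 / lam
    for i in range(d.size):
        xi = X[i]
        y[i] = w @ xi
        Px = P @ xi
        denom = lam + xi @ Px
        gain = Px / denom
        if not np.all(np.isfinite(gain)):
            raise FloatingPointError(
                f"RLS gain became non-finite at sample {i}; "
                "consider a larger rls_delta or forgetting factor"
            )
        e = d[i] - y[i]
        w = w + gain * e
        P = (P - np.outer(gain, Px)) * inv_lam
    return y, w


def _run_wiener(d, ref, order):
    n = d.size
    # biased auto-/cross-correlation estimates, lags 0..order-1
    r = np.array([ref[: n - k] @ ref[k:] for k in range(order)]) / n
    p = np.array([d[k:] @ ref[: n - k] for k in range(order)]) / n
    if r[0] == 0:
        w = np.zeros(order)
    else:
        w = solve_toeplitz((r, r), p)
    y = sps.lfilter(w, 1.0, ref)
    return y, w


def adaptive_filter(
    desired: TimeSeries, reference: TimeSeries, cfg: FilterConfig
) -> FilterResult:
    """Run one canceller over the whole record.

    All methods start from zero taps with zero-padded history, so results
    are deterministic.  ``output + error == desired`` exactly.
    """
    d = desired.samples
    x = reference.samples
    if d.size != x.size:
        raise ValueError("desired and reference must have equal length")
    order = cfg.effective_order
    if d.size < order:
        raise ValueError("record shorter than the filter order")
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite input samples")

    if cfg.method is FilterMethod.LMS:
        y, w = _run_lms(d, x, order, cfg.step)
    elif cfg.method is FilterMethod.NLMS:
        y, w = _run_nlms(d, x, order, cfg.nlms_step, cfg.nlms_eps)
    elif cfg.method is FilterMethod.RLS:
        y, w = _run_rls(d, x, order, cfg.rls_forgetting, cfg.rls_delta)
    else:
        y, w = _run_wiener(d, x, order)

    e = d - y
    cleaned = e if cfg.reference_kind is ReferenceKind.EMG_REF else y
    fs = desired.fs
    return FilterResult(
        output=TimeSeries(y, fs),
        error=TimeSeries(e, fs),
        weights=w,
        cleaned=TimeSeries(cleaned, fs),
    )


def clean_eeg(
    contaminated: TimeSeries, reference: TimeSeries, cfg: FilterConfig
) -> TimeSeries:
    """Cleaned EEG from one adaptive-cancellation pass (see module docstring)."""
    return adaptive_filter(contaminated, reference, cfg).cleaned
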