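"""Core containers: uniformly sampled signals and binary contamination masks.

Amplitudes are in microvolts throughout the package; sampling rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude values in microvolts.
    fs : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray) -> "TimeSeries":
        """Same sampling rate, new sample values."""
        return TimeSeries(samples, self.fs)


@dataclass(frozen=True)
class ContaminationMask:
    """Per-sample binary labels: high = EMG activity, low = noise-only.

    The interval view lists maximal high runs as half-open sample ranges
    ``[start, end)``.
    """

    flags: np.ndarray
    fs: float

    def __post_init__(self):
        flags = np.asarray(self.flags).astype(bool)
        object.__setattr__(self, "flags", flags)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if flags.ndim != 1:
            raise ValueError("flags must be one-dimensional")

    @property
    def n(self) -> int:
        return self.flags.size

    @property
    def n_high(self) -> int:
        return int(self.flags.sum())

    @property
    def intervals(self) -> np.ndarray:
        """(m, 2) array of half-open high runs in samples."""
        f = np.r_[False, self.flags, False].astype(np.int8)
        d = np.diff(f)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        return np.column_stack([starts, ends])

    @property
    def intervals_s(self) -> np.ndarray:
        """High runs in seconds."""
        return self.intervals / self.fs

    @classmethod
    def from_intervals(
        cls, intervals_s, n: int, fs: float
    ) -> "ContaminationMask":
        """Build a mask from (start_s, end_s) pairs over an n-sample record."""
        flags = np.zeros(n, dtype=bool)
        for start_s, end_s in intervals_s:
            i0 = max(0, int(np.round(start_s * fs)))
            i1 = min(n, int(np.round(end_s * fs)))
            if i1 > i0:
                flags[i0:i1] = True
        return cls(flags, fs)

    def high_samples_of(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x)[self.flags]

    def low_samples_of(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x)[~self.flags]
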