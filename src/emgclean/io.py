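"""File I/O: delimited-text signals and masks, EDF reading, JSON sidecars.

The canonical on-disk signal format is two-column delimited text
(time_s, amplitude_uV).  Masks round-trip both as interval files
(start_s, end_s) and as per-sample 0/1 columns.  EDF recordings are read
through mne when the optional dependency is present.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .types import ContaminationMask, TimeSeries

__all__ = [
    "read_signal",
    "write_signal",
    "read_mask",
    "write_mask",
    "write_sidecar",
]


def write_signal(x: TimeSeries, path: str | Path, delimiter: str = ",") -> None:
    """Write (time_s, amplitude) rows; full float precision."""
    path = Path(path)
    data = np.column_stack([x.times, x.samples])
    header = f"time_s{delimiter}amplitude_uV"
    np.savetxt(path, data, delimiter=delimiter, header=header, fmt="%.17g")


def _read_text_signal(path: Path, delimiter: str) -> TimeSeries:
    try:
        data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed signal file {path}: {exc}") from exc
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected (time_s, amplitude) columns")
    t, v = data[:, 0], data[:, 1]
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples to infer the sampling rate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12) or dt[0] <= 0:
        raise ValueError(f"{path}: time column is not uniformly increasing")
    return TimeSeries(v, 1.0 / dt[0])


def _read_edf_signal(path: Path, channel: str | int | None) -> TimeSeries:
    import mne  # optional dependency; imported lazily

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = raw.ch_names
    if channel is None:
        if len(names) != 1:
            raise ValueError(
                f"{path} holds {len(names)} channels {names}; pass an explicit channel"
            )
        channel = names[0]
    if isinstance(channel, int):
        channel = names[channel]
    data = raw.get_data(picks=[channel])[0] * 1e6  # volts -> microvolts
    return TimeSeries(data, float(raw.info["sfreq"]))


def read_signal(
    path: str | Path,
    fmt: str | None = None,
    delimiter: str = ",",
    channel: str | int | None = None,
) -> TimeSeries:
    """Read a signal from delimited text or EDF (format inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "text"
    if fmt == "edf":
        return _read_edf_signal(path, channel)
    return _read_text_signal(path, delimiter)


def write_mask(mask: ContaminationMask, path: str | Path, style: str = "intervals") -> None:
    """Write a mask as (start_s, end_s, label) intervals or a per-sample 0/1 column."""
    path = Path(path)
    if style == "intervals":
        iv = mask.intervals_s
        rows = np.column_stack([iv, np.ones(len(iv))]) if len(iv) else np.empty((0, 3))
        np.savetxt(path, rows, delimiter=",", header="start_s,end_s,label", fmt="%.17g")
    elif style == "samples":
        np.savetxt(path, mask.flags.astype(int), fmt="%d", header=f"fs={mask.fs}")
    else:
        raise ValueError(f"unknown mask style {style!r}")


def read_mask(
    path: str | Path,
    n: int | None = None,
    fs: float | None = None,
    style: str = "intervals",
) -> ContaminationMask:
    path = Path(path)
    if style == "intervals":
        if n is None or fs is None:
            raise ValueError("interval masks need the record length n and fs")
        data = np.loadtxt(path, delimiter=",", ndmin=2)
        iv = data[:, :2] if data.size else np.empty((0, 2))
        return ContaminationMask.from_intervals(iv, n, fs)
    if style == "samples":
        if fs is None:
            with open(path) as fh:
                first = fh.readline()
            if first.startswith("#") and "fs=" in first:
                fs = float(first.split("fs=")[1])
            else:
                raise ValueError("per-sample mask file lacks an fs header; pass fs")
        flags = np.loadtxt(path).astype(bool)
        return ContaminationMask(flags, fs)
    raise ValueError(f"unknown mask style {style!r}")


def write_sidecar(path: str | Path, payload: dict) -> None:
    """JSON sidecar recording seeds and parameters next to a data file."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
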