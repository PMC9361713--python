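"""End-to-end orchestration: detrend, mask, decompose, reference, cancel, score.

`run_pipeline` wires the stages together for one contaminated channel and
writes every artefact (cleaned signal, reference, mask, feature tables) plus
a JSON report that records all parameters and seeds, so a run is exactly
reproducible from its report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as eio
from .adaptive import FilterConfig, ReferenceKind, adaptive_filter
from .bursts import BurstDetectorOptions, detect_emg_bursts
from .decompose import Method, decompose
from .evaluate import band_features, time_features
from .preprocess import remove_linear_trend, remove_nonlinear_trend, replace_outliers
from .reference import make_eeg_reference, make_emg_reference
from .types import ContaminationMask, TimeSeries

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    signal_path: str
    out_dir: str
    emg_path: str | None = None  # separate EMG channel for burst detection
    mask_path: str | None = None  # ground-truth / precomputed interval mask
    method: str = "ssa"
    decomp_params: dict = field(default_factory=dict)
    k: float = 1.5
    filter: FilterConfig = field(default_factory=FilterConfig)
    noise_window: tuple[float, float] = (0.0, 2.0)
    detrend_window_ms: float = 20.0
    outlier_k_sd: float = 10.0
    spectral_df: float = 0.1
    seed: int = 0
    compute_band_features: bool = True


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full cleaning chain and return the run report.

    Stage order: linear + non-linear detrend, outlier replacement, burst
    detection (skipped when a mask file is supplied), decomposition,
    soft-thresholded reconstruction into the EMG reference (skipped for
    EMD-PCA, whose principal-axis reconstruction is already de-noised),
    optional EEG-reference formation, adaptive cancellation, and feature
    evaluation.  Any stage failure is re-raised with a stage tag.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _config_record(cfg), "stages": []}

    def stage(name):
        report["stages"].append(name)
        return name

    try:
        stage("read")
        x = eio.read_signal(cfg.signal_path)

        stage("detrend")
        x = remove_linear_trend(x)
        x = remove_nonlinear_trend(x, cfg.detrend_window_ms)

        stage("mask")
        if cfg.mask_path is not None:
            mask = eio.read_mask(cfg.mask_path, n=x.n, fs=x.fs)
            report["mask_source"] = "file"
        else:
            probe_path = cfg.emg_path or cfg.signal_path
            probe = eio.read_signal(probe_path)
            mask = detect_emg_bursts(probe, cfg.noise_window, BurstDetectorOptions())
            report["mask_source"] = "emg_channel" if cfg.emg_path else "contaminated_eeg"

        stage("outliers")
        x = replace_outliers(x, mask, cfg.outlier_k_sd, seed=cfg.seed)

        stage("reference")
        method = Method(cfg.method)
        params = dict(cfg.decomp_params)
        if method is Method.EEMD:
            params.setdefault("seed", cfg.seed)
        emg_ref = make_emg_reference(x, method, mask, cfg.k, params)
        report["soft_thresholding_applied"] = method is not Method.EMD_PCA
        if cfg.filter.reference_kind is ReferenceKind.EEG_REF:
            reference = make_eeg_reference(x, emg_ref)
        else:
            reference = emg_ref

        stage("adaptive_filter")
        result = adaptive_filter(x, reference, cfg.filter)
        cleaned = result.cleaned

        stage("evaluate")
        tf = time_features(x, cleaned, mask)
        report["time_features"] = {
            "GL_db": tf.GL,
            "GH_db": tf.GH,
            "GXin_db": tf.GXin,
            "GXout_db": tf.GXout,
            "medians_uV": tf.medians,
        }
        if cfg.compute_band_features:
            spectral = {}
            for role, sig in (("raw", x), ("filtered", cleaned)):
                per_band = band_features(sig, df=cfg.spectral_df)
                spectral[role] = {
                    name: {"fmed_hz": sf.fmed, "p_at_fmed": sf.p_at_fmed}
                    for name, sf in per_band.items()
                }
            report["spectral_features"] = spectral

        stage("write")
        eio.write_signal(cleaned, out_dir / "cleaned.csv")
        eio.write_signal(emg_ref, out_dir / "emg_reference.csv")
        eio.write_mask(mask, out_dir / "mask_intervals.csv")
        report["outputs"] = {
            name: _sha256(out_dir / name)
            for name in ("cleaned.csv", "emg_reference.csv", "mask_intervals.csv")
        }
        report["final_weights"] = result.weights.tolist()
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    except Exception as exc:
        failed = report["stages"][-1] if report["stages"] else "init"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc


def _config_record(cfg: RunConfig) -> dict:
    rec = {
        "signal_path": cfg.signal_path,
        "emg_path": cfg.emg_path,
        "mask_path": cfg.mask_path,
        "method": cfg.method,
        "decomp_params": cfg.decomp_params,
        "k": cfg.k,
        "noise_window": list(cfg.noise_window),
        "detrend_window_ms": cfg.detrend_window_ms,
        "outlier_k_sd": cfg.outlier_k_sd,
        "spectral_df": cfg.spectral_df,
        "seed": cfg.seed,
        "filter": {
            "method": cfg.filter.method.value,
            "order": cfg.filter.effective_order,
            "step": cfg.filter.step,
            "nlms_step": cfg.filter.nlms_step,
            "rls_forgetting": cfg.filter.rls_forgetting,
            "rls_delta": cfg.filter.rls_delta,
            "reference_kind": cfg.filter.reference_kind.value,
        },
    }
    return rec
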