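"""Single-channel signal decompositions used to build reference signals.

Six methods share one interface: EMD, ensemble EMD (EEMD), singular
spectrum analysis (SSA), circulant SSA (CiSSA), multilevel discrete wavelet
decomposition, and EMD followed by a principal-axis rotation of the IMF
stack (EMD-PCA).  Components are equal-length time series; for the complete
transforms (EMD with its residual, SSA/CiSSA with all components, wavelet
with all level bands) the components sum back to the input.

Parameter conventions follow common practice for EEG de-noising: at most
10 components; PCHIP-interpolated envelopes for EMD/EEMD sifting; 5
ensemble members for EEMD; SSA window length 100 with an 80% explained-
variance retention rule; coif5 mother wavelet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import PchipInterpolator

from .types import TimeSeries

__all__ = [
    "Method",
    "ComponentSet",
    "decompose",
    "explained_variance",
    "emd",
]


class Method(str, Enum):
    EMD = "emd"
    EEMD = "eemd"
    SSA = "ssa"
    CISSA = "cissa"
    WAVELET = "wavelet"
    EMD_PCA = "emd-pca"


MAX_COMPONENTS = 10


@dataclass
class ComponentSet:
    """Ordered components of a decomposed signal.

    ``components`` is an (M, n) array.  ``residual`` holds whatever part of
    the input is not carried by the components (EMD's final monotone
    remainder; the discarded part for variance-truncated methods) so that
    ``components.sum(0) + residual`` reconstructs the input for the complete
    transforms.
    """

    components: np.ndarray
    method: Method
    fs: float
    params: dict[str, Any] = field(default_factory=dict)
    explained_variance: np.ndarray | None = None
    residual: np.ndarray | None = None

    @property
    def m(self) -> int:
        return self.components.shape[0]

    @property
    def n(self) -> int:
        return self.components.shape[1]

    def reconstruct(self, include_residual: bool = True) -> np.ndarray:
        out = self.components.sum(axis=0)
        if include_residual and self.residual is not None:
            out = out + self.residual
        return out


# --------------------------------------------------------------------------
# EMD


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    rises = d > 0
    falls = d < 0
    maxima = np.flatnonzero(rises[:-1] & falls[1:]) + 1
    minima = np.flatnonzero(falls[:-1] & rises[1:]) + 1
    return maxima, minima


def _mirrored(idx: np.ndarray, val: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Reflect up to two extrema past each record edge to anchor the envelope."""
    k = min(2, idx.size)
    left_i = -idx[:k][::-1]
    left_v = val[:k][::-1]
    right_i = 2 * (n - 1) - idx[-k:][::-1]
    right_v = val[-k:][::-1]
    ii = np.r_[left_i, idx, right_i]
    vv = np.r_[left_v, val, right_v]
    keep = np.r_[True, np.diff(ii) > 0]
    return ii[keep], vv[keep]


def _envelope(idx: np.ndarray, x: np.ndarray) -> np.ndarray:
    ii, vv = _mirrored(idx, x[idx], x.size)
    return PchipInterpolator(ii, vv)(np.arange(x.size, dtype=float))


def emd(
    x: np.ndarray,
    max_imfs: int = MAX_COMPONENTS,
    sd_stop: float = 0.2,
    max_sifts: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical mode decomposition by sifting with PCHIP envelopes.

    Returns ``(imfs, residual)`` with ``imfs.sum(0) + residual == x`` exactly
    (the procedure is telescoping).  Sifting of each mode stops when the
    normalized change ``sum((h_prev-h)^2)/sum(h_prev^2)`` drops below
    ``sd_stop`` or after ``max_sifts`` iterations; extraction stops when the
    remainder has fewer than two maxima or minima, or at ``max_imfs`` modes.
    """
    x = np.asarray(x, dtype=np.float64)
    residual = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        h = residual
        for _ in range(max_sifts):
            maxima, minima = _local_extrema(h)
            if maxima.size < 2 or minima.size < 2:
                break
            mean_env = 0.5 * (_envelope(maxima, h) + _envelope(minima, h))
            h_new = h - mean_env
            denom = np.sum(h * h)
            if denom == 0:
                h = h_new
                break
            sd = np.sum((h - h_new) ** 2) / denom
            h = h_new
            if sd < sd_stop:
                break
        imfs.append(h)
        residual = residual - h
    if not imfs:
        return np.empty((0, x.size)), residual
    return np.vstack(imfs), residual


def _decompose_emd(x: np.ndarray, fs: float, params: dict) -> ComponentSet:
    imfs, residual = emd(
        x,
        max_imfs=params.get("max_components", MAX_COMPONENTS),
        sd_stop=params.get("sd_stop", 0.2),
        max_sifts=params.get("max_sifts", 100),
    )
    return ComponentSet(imfs, Method.EMD, fs, dict(params), residual=residual)


def _decompose_eemd(x: np.ndarray, fs: float, params: dict) -> ComponentSet:
    """Ensemble EMD: average IMFs over noise-perturbed sifting runs."""
    n_ens = params.get("n_ensembles", 5)
    noise_sd = params.get("noise_sd", 0.2) * np.std(x)
    max_imfs = params.get("max_components", MAX_COMPONENTS)
    seed = params.get("seed", 0)
    runs = []
    for j in range(n_ens):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5, j]))
        noise = noise_sd * rng.standard_normal(x.size)
        imfs, res = emd(x + noise, max_imfs=max_imfs)
        runs.append((imfs, res))
    m = max(imfs.shape[0] for imfs, _ in runs)
    comp = np.zeros((m, x.size))
    residual = np.zeros(x.size)
    for imfs, res in runs:
        comp[: imfs.shape[0]] += imfs
        residual += res
    comp /= n_ens
    residual /= n_ens
    return ComponentSet(comp, Method.EEMD, fs, dict(params), residual=residual)


# --------------------------------------------------------------------------
# SSA / CiSSA


def _hankelize_rank1(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Diagonal-average the rank-1 matrix outer(a, b) into a series.

    Anti-diagonal sums of an outer product are the full linear convolution
    of the two vectors; dividing by the anti-diagonal lengths gives the
    averaged series.
    """
    counts = np.convolve(np.ones(a.size), np.ones(b.size))
    return np.convolve(a, b) / counts


def _decompose_ssa(x: np.ndarray, fs: float, params: dict) -> ComponentSet:
    L = params.get("window", 100)
    var_target = params.get("var_target", 0.8)
    n = x.size
    if L >= n:
        raise ValueError(f"SSA window ({L}) must be shorter than the signal ({n})")
    X = sliding_window_view(x, L).T  # (L, K)
    S = X @ X.T
    eigvals, eigvecs = np.linalg.eigh(S)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    shares = eigvals / total if total > 0 else np.zeros_like(eigvals)
    cum = np.cumsum(shares)
    m = int(np.searchsorted(cum, var_target) + 1)
    m = min(m, L)
    comps = np.empty((m, n))
    for i in range(m):
        u = eigvecs[:, i]
        comps[i] = _hankelize_rank1(u, X.T @ u)
    residual = x - comps.sum(axis=0)
    ev = np.r_[shares[:m], max(0.0, 1.0 - cum[m - 1])]
    # the unexplained remainder is carried as a final component so that
    # reconstruction-based stages can use the full sum
    comps = np.vstack([comps, residual])
    return ComponentSet(comps, Method.SSA, fs, dict(params), explained_variance=ev)


def _decompose_cissa(x: np.ndarray, fs: float, params: dict) -> ComponentSet:
    """Circulant SSA: frequency-indexed subspace components.

    The lagged second-moment matrix is replaced by its circulant
    approximation, whose eigenvectors are Fourier vectors; conjugate
    frequency pairs (k, L−k) are combined so every component is real.  The
    L/2+1 frequency bins are then merged down to at most ``max_components``
    groups by repeatedly folding the smallest-energy group into its
    smaller-energy adjacent neighbour.
    """
    L = params.get("window", 100)
    max_comp = params.get("max_components", MAX_COMPONENTS)
    n = x.size
    if L >= n:
        raise ValueError(f"CiSSA window ({L}) must be shorter than the signal ({n})")
    X = sliding_window_view(x, L).T  # (L, K)
    F = np.fft.fft(np.eye(L), axis=0) / np.sqrt(L)  # columns are Fourier vectors
    proj = F.conj().T @ X  # (L, K) frequency-domain rows
    n_bins = L // 2 + 1
    counts = np.convolve(np.ones(L), np.ones(X.shape[1]))
    bin_series = np.empty((n_bins, n))
    for k in range(n_bins):
        # anti-diagonal averaging of the rank-<=2 matrix via convolution
        s = np.convolve(F[:, k], proj[k])
        partner = (L - k) % L
        if partner != k:
            s = s + np.convolve(F[:, partner], proj[partner])
        bin_series[k] = s.real / counts
    energies = (bin_series**2).sum(axis=1)
    # adjacency-preserving merge down to the component cap
    groups: list[list[int]] = [[k] for k in range(n_bins)]
    g_energy = list(energies)
    while len(groups) > max_comp:
        i = int(np.argmin(g_energy))
        neighbors = [j for j in (i - 1, i + 1) if 0 <= j < len(groups)]
        j = min(neighbors, key=lambda q: g_energy[q])
        lo, hi = sorted((i, j))
        groups[lo] = groups[lo] + groups[hi]
        g_energy[lo] = g_energy[lo] + g_energy[hi]
        del groups[hi], g_energy[hi]
    comps = np.vstack([bin_series[g].sum(axis=0) for g in groups])
    total = comps.var(axis=1).sum()
    ev = comps.var(axis=1) / total if total > 0 else None
    return ComponentSet(comps, Method.CISSA, fs, dict(params), explained_variance=ev)


# --------------------------------------------------------------------------
# Wavelet


def _decompose_wavelet(x: np.ndarray, fs: float, params: dict) -> ComponentSet:
    wavelet = params.get("wavelet", "coif5")
    max_comp = params.get("max_components", MAX_COMPONENTS)
    max_level = pywt.dwt_max_level(x.size, wavelet)
    level = min(max_comp - 1, max_level)
    if level < 1:
        raise ValueError("signal too short for one wavelet level")
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    comps = np.empty((len(coeffs), x.size))
    for i in range(len(coeffs)):
        sel = [c if j == i else np.zeros_like(c) for j, c in enumerate(coeffs)]
        comps[i] = pywt.waverec(sel, wavelet, mode="symmetric")[: x.size]
    # order bands from finest detail to the approximation
    comps = comps[::-1]
    return ComponentSet(comps, Method.WAVELET, fs, dict(params, level=level))


# --------------------------------------------------------------------------
# EMD-PCA


def _decompose_emd_pca(x: np.ndarray, fs: float, params: dict) -> ComponentSet:
    """EMD followed by a principal-axis rotation of the IMF stack.

    Axes of the uncentered second-moment matrix of the IMFs are retained in
    descending variance order until they cover ``var_target`` of the total;
    each returned component is the retained axis's contribution to the IMF
    sum, so the components sum to a de-noised reconstruction directly
    (no thresholding stage is needed for this method).
    """
    var_target = params.get("var_target", 0.8)
    imfs, residual = emd(x, max_imfs=params.get("max_components", MAX_COMPONENTS))
    if imfs.shape[0] == 0:
        raise ValueError("EMD produced no IMFs; cannot rotate")
    S = imfs @ imfs.T / imfs.shape[1]
    eigvals, eigvecs = np.linalg.eigh(S)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    shares = eigvals / total if total > 0 else np.zeros_like(eigvals)
    cum = np.cumsum(shares)
    m = int(np.searchsorted(cum, var_target) + 1)
    m = min(m, imfs.shape[0])
    comps = np.empty((m, x.size))
    ones = np.ones(imfs.shape[0])
    for i in range(m):
        v = eigvecs[:, i]
        comps[i] = (ones @ v) * (v @ imfs)
    discarded = imfs.sum(axis=0) - comps.sum(axis=0)
    return ComponentSet(
        comps,
        Method.EMD_PCA,
        fs,
        dict(params),
        explained_variance=shares[:m],
        residual=residual + discarded,
    )


# --------------------------------------------------------------------------


_DISPATCH = {
    Method.EMD: _decompose_emd,
    Method.EEMD: _decompose_eemd,
    Method.SSA: _decompose_ssa,
    Method.CISSA: _decompose_cissa,
    Method.WAVELET: _decompose_wavelet,
    Method.EMD_PCA: _decompose_emd_pca,
}


def decompose(
    x: TimeSeries, method: Method | str, params: dict | None = None
) -> ComponentSet:
    """Decompose a signal by the chosen method.

    ``params`` overrides per-method defaults: ``max_components`` (10),
    ``window`` (100, SSA/CiSSA), ``var_target`` (0.8, SSA/EMD-PCA),
    ``n_ensembles`` (5) / ``noise_sd`` (0.2·SD) / ``seed`` (EEMD),
    ``wavelet`` ('coif5').
    """
    method = Method(method)
    return _DISPATCH[method](x.samples, x.fs, dict(params or {}))


def explained_variance(c: ComponentSet) -> np.ndarray:
    """Per-component explained-variance fractions.

    Defined for SSA (eigenvalue shares, plus the residual component's
    remainder), CiSSA (component variance shares) and EMD-PCA (principal-axis
    shares); the raw EMD/EEMD/wavelet transforms have no variance-ordering
    notion and raise.
    """
    if c.m < 1:
        raise ValueError("empty component set")
    if c.explained_variance is None:
        raise NotImplementedError(
            f"explained variance is not defined for method {c.method.value!r}"
        )
    return np.asarray(c.explained_variance)
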