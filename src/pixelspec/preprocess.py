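"""Spectral and spatial preprocessing of masked hyperspectral cubes.

Four families are implemented, matching the comparison the pipeline is built
around:

* **MA** — per-pixel moving-average (boxcar) smoothing of each spectrum over
  an odd number of adjacent bands.  Cheap, but wide windows flatten genuine
  absorption features along with the noise.
* **MF** — per-band spatial median filter of each gray-scale image.  Spreads
  values among neighbouring pixels; it does not suppress spectral noise the
  way averaging does, and it dims bright foreground objects as the window
  grows (background zeros bleed into the window near bean edges).
* **WT** — per-pixel wavelet shrinkage: multilevel DWT, soft-threshold the
  detail coefficients (universal or SURE rule), reconstruct.
* **EMD** — per-pixel empirical mode decomposition: sift the spectrum into
  intrinsic mode functions (IMFs), threshold the first (noise-dominated)
  IMFs, and reconstruct from thresholded IMFs + remaining IMFs + residual.

All methods keep the background exactly zero and preserve spectrum length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter

from .cube_io import BeanLabelMap, HyperCube

METHODS = ("none", "MA", "MF", "WT", "EMD")


@dataclass
class PreprocessConfig:
    method: str = "none"
    ma_points: int = 7
    mf_window: int = 3
    wt_wavelet: str = "db4"
    wt_level: int = 4
    wt_threshold_rule: str = "universal"   # or "sure"
    emd_n_noise_imfs: int = 1
    emd_threshold_rule: str = "universal"
    emd_threshold_mode: str = "soft"       # or "hard"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method '{self.method}', expected one of {METHODS}")
        for name, v in (("ma_points", self.ma_points), ("mf_window", self.mf_window)):
            if v < 3 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {v}")
        if self.wt_threshold_rule not in ("universal", "sure"):
            raise ValueError("wt_threshold_rule must be 'universal' or 'sure'")
        if self.emd_threshold_rule != "universal":
            raise ValueError("emd_threshold_rule must be 'universal'")
        if self.emd_threshold_mode not in ("soft", "hard"):
            raise ValueError("emd_threshold_mode must be 'soft' or 'hard'")


# ---------------------------------------------------------------------------
# Moving average
# ---------------------------------------------------------------------------

def moving_average(spectrum: np.ndarray, points: int) -> np.ndarray:
    """Centered boxcar mean over ``points`` bands (odd), length-preserving.

    Near the ends the window shrinks symmetrically (at index i the half-width
    is min(H, i, n-1-i)), so no extrapolated values enter the mean.  Accepts
    a single spectrum or a 2-D batch (n_spectra x bands, smoothing along the
    last axis).
    """
    x = np.asarray(spectrum, dtype=np.float64)
    n = x.shape[-1]
    if points % 2 == 0 or points < 3:
        raise ValueError(f"points must be odd and >= 3, got {points}")
    if points > n:
        raise ValueError(f"window of {points} points exceeds {n} bands")
    H = (points - 1) // 2
    cs = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1
    )
    out = np.empty_like(x)
    # interior: full window
    out[..., H:n - H] = (cs[..., 2 * H + 1:] - cs[..., :n - 2 * H]) / (2 * H + 1)
    # shrinking symmetric edges
    for i in range(H):
        h = i
        out[..., i] = (cs[..., i + h + 1] - cs[..., i - h]) / (2 * h + 1)
        j = n - 1 - i
        out[..., j] = (cs[..., j + h + 1] - cs[..., j - h]) / (2 * h + 1)
    return out.astype(np.asarray(spectrum).dtype, copy=False)


# ---------------------------------------------------------------------------
# Median filter
# ---------------------------------------------------------------------------

def median_filter_band(image: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel spatial median over a window x window neighbourhood.

    Borders use reflect padding.  Applied independently to every band by
    :func:`median_filter_cube`.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    return median_filter(np.asarray(image), size=window, mode="reflect")


def median_filter_cube(cube: HyperCube, window: int) -> HyperCube:
    out = np.empty_like(cube.data)
    for b in range(cube.n_bands):
        out[:, :, b] = median_filter_band(cube.data[:, :, b], window)
    return HyperCube(data=out, wavelengths=cube.wavelengths, meta=dict(cube.meta))


# ---------------------------------------------------------------------------
# Wavelet shrinkage
# ---------------------------------------------------------------------------

def _mad_sigma(d: np.ndarray) -> np.ndarray:
    """Noise sd estimate from the median absolute deviation, along last axis."""
    return np.median(np.abs(d), axis=-1) / 0.6745


def _soft(c: np.ndarray, thr: np.ndarray) -> np.ndarray:
    return np.sign(c) * np.maximum(np.abs(c) - thr, 0.0)


def _sure_threshold(d: np.ndarray, sigma: float) -> float:
    """Stein's unbiased risk minimising threshold for one detail level."""
    if sigma <= 0:
        return 0.0
    z = (d / sigma) ** 2
    z_sorted = np.sort(z)
    n = z.size
    cum = np.cumsum(z_sorted)
    # risk of thresholding at t^2 = z_sorted[k]: n - 2(k+1) + cum[k] + (n-k-1) z_sorted[k]
    k = np.arange(n)
    risk = n - 2.0 * (k + 1) + cum + (n - k - 1) * z_sorted
    best = int(np.argmin(risk))
    return sigma * float(np.sqrt(z_sorted[best]))


def wavelet_denoise(spectrum: np.ndarray, wavelet: str = "db4", level: int = 4,
                    rule: str = "universal",
                    threshold: float | None = None) -> np.ndarray:
    """Multilevel DWT shrinkage of one spectrum (or a 2-D batch).

    Detail coefficients at every level are soft-thresholded; the threshold is
    the universal rule sigma*sqrt(2 ln n) (sigma from the MAD of the finest
    details) or the per-level SURE minimiser.  ``threshold`` overrides the
    rule with a fixed value (0 gives the perfect-reconstruction identity).
    """
    x = np.asarray(spectrum, dtype=np.float64)
    n = x.shape[-1]
    if 2 ** level > n:
        raise ValueError(f"level {level} too deep for {n}-band spectrum")
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric", axis=-1)
    if threshold is not None:
        thr = np.asarray(float(threshold))
        sigma = None
    else:
        sigma = _mad_sigma(coeffs[-1])
        thr = sigma * np.sqrt(2.0 * np.log(n))
    new = [coeffs[0]]
    for d in coeffs[1:]:
        if threshold is None and rule == "sure":
            if x.ndim == 1:
                t = _sure_threshold(d, float(sigma))
            else:
                t = np.array([_sure_threshold(d[i], float(sigma[i]))
                              for i in range(d.shape[0])])[..., None]
            new.append(_soft(d, t))
        else:
            t = thr if x.ndim == 1 else np.asarray(thr)[..., None]
            new.append(_soft(d, t))
    rec = pywt.waverec(new, wavelet, mode="symmetric", axis=-1)
    rec = rec[..., :n]
    return rec.astype(np.asarray(spectrum).dtype, copy=False)


# ---------------------------------------------------------------------------
# Empirical mode decomposition
# ---------------------------------------------------------------------------

def _extrema_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus collapse to one)."""
    dx = np.diff(x)
    s = np.sign(dx)
    # carry the previous non-zero slope across flats
    nz = s != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    idx = np.where(nz, np.arange(s.size), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, s[np.clip(idx, 0, None)], 0)
    turn = np.diff(filled)
    maxima = np.where(turn < 0)[0] + 1
    minima = np.where(turn > 0)[0] + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray | None:
    """Cubic-spline envelope through the extrema, mirrored at the ends."""
    if idx.size < 2:
        return None
    n = x.size
    t = idx.astype(np.float64)
    v = x[idx]
    # mirror the first/last extremum about the signal boundaries
    ts, vs = list(t), list(v)
    if t[0] > 0:
        ts.insert(0, -t[0])
        vs.insert(0, v[0])
    if t[-1] < n - 1:
        ts.append(2 * (n - 1) - t[-1])
        vs.append(v[-1])
    spline = CubicSpline(ts, vs)
    return spline(np.arange(n))


def emd(spectrum: np.ndarray, max_imfs: int = 12, max_siftings: int = 50,
        sd_tol: float = 0.2) -> tuple[list[np.ndarray], np.ndarray]:
    """Sift a 1-D signal into intrinsic mode functions plus a residual.

    Sifting stops per IMF when the normalised squared change between
    consecutive siftings drops below ``sd_tol`` (the classical SD criterion)
    or after ``max_siftings`` iterations (best effort, with a warning).
    Decomposition stops when the residual has fewer than 4 extrema.  By
    construction ``sum(imfs) + residual`` equals the input to rounding error.
    """
    x = np.asarray(spectrum, dtype=np.float64)
    imfs: list[np.ndarray] = []
    r = x.copy()
    for _ in range(max_imfs):
        maxima, minima = _extrema_indices(r)
        if maxima.size + minima.size < 4:
            break
        h = r.copy()
        converged = False
        for _sift in range(max_siftings):
            up = _envelope(h, maxima)
            lo = _envelope(h, minima)
            if up is None or lo is None:
                converged = True
                break
            mean_env = 0.5 * (up + lo)
            h_new = h - mean_env
            denom = float(np.sum(h * h)) + 1e-300
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            maxima, minima = _extrema_indices(h)
            if sd < sd_tol:
                converged = True
                break
        if not converged:
            warnings.warn("EMD sifting did not converge; using best effort",
                          stacklevel=2)
        imfs.append(h)
        r = r - h
        maxima, minima = _extrema_indices(r)
        if maxima.size + minima.size < 4:
            break
    return imfs, r


def emd_denoise(spectrum: np.ndarray, n_noise_imfs: int = 1,
                mode: str = "soft") -> np.ndarray:
    """EMD shrinkage: threshold the first (noise-dominated) IMFs and rebuild.

    The universal threshold sigma*sqrt(2 ln n) is applied samplewise to each
    of the first ``n_noise_imfs`` IMFs, with sigma from the IMF's MAD; the
    remaining IMFs and the residual pass through unchanged.  Spectra with
    fewer than 4 extrema carry no oscillatory mode and are returned as-is.
    """
    x = np.asarray(spectrum, dtype=np.float64)
    imfs, res = emd(x)
    if not imfs:
        return np.asarray(spectrum).copy()
    n = x.size
    out = res.copy()
    for j, imf in enumerate(imfs):
        if j < n_noise_imfs:
            sigma = float(_mad_sigma(imf))
            thr = sigma * np.sqrt(2.0 * np.log(n))
            if mode == "soft":
                out += _soft(imf, thr)
            else:
                out += np.where(np.abs(imf) > thr, imf, 0.0)
        else:
            out += imf
    return out.astype(np.asarray(spectrum).dtype, copy=False)


def emd_denoise_batch(X: np.ndarray, n_noise_imfs: int = 1,
                      mode: str = "soft") -> np.ndarray:
    return np.stack([emd_denoise(row, n_noise_imfs, mode) for row in X])


# ---------------------------------------------------------------------------
# Cube-level dispatch
# ---------------------------------------------------------------------------

def preprocess_cube(cube: HyperCube, lmap: BeanLabelMap,
                    cfg: PreprocessConfig) -> HyperCube:
    """Apply the configured method to a masked cube.

    Spectral methods (MA, WT, EMD) act on foreground pixel spectra only, so
    the background stays exactly 0.  The spatial method (MF) filters every
    gray-scale band and then re-applies the mask, since values bleed across
    the bean boundary inside the median window.
    """
    if cfg.method == "none":
        return HyperCube(data=cube.data.copy(), wavelengths=cube.wavelengths,
                         meta=dict(cube.meta))
    if cfg.method == "MF":
        filtered = median_filter_cube(cube, cfg.mf_window)
        filtered.data[lmap.mask == 0] = 0
        return filtered
    rr, cc = np.nonzero(lmap.mask)
    X = np.asarray(cube.data[rr, cc, :], dtype=np.float64)
    if cfg.method == "MA":
        Xp = moving_average(X, cfg.ma_points)
    elif cfg.method == "WT":
        Xp = wavelet_denoise(X, cfg.wt_wavelet, cfg.wt_level, cfg.wt_threshold_rule)
    elif cfg.method == "EMD":
        Xp = emd_denoise_batch(X, cfg.emd_n_noise_imfs, cfg.emd_threshold_mode)
    else:  # pragma: no cover — config validation forbids this
        raise ValueError(f"unknown method '{cfg.method}'")
    out = np.zeros_like(cube.data)
    out[rr, cc, :] = Xp.astype(cube.data.dtype, copy=False)
    return HyperCube(data=out, wavelengths=cube.wavelengths, meta=dict(cube.meta))


def preprocess_spectra(X: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Apply a spectral method to an ``n x bands`` matrix of spectra.

    MF is spatial and has no meaning on extracted spectra; request it at the
    cube level instead.
    """
    if cfg.method == "none":
        return np.asarray(X).copy()
    if cfg.method == "MF":
        raise ValueError("MF is a spatial filter; apply it with preprocess_cube")
    if cfg.method == "MA":
        return moving_average(X, cfg.ma_points)
    if cfg.method == "WT":
        return wavelet_denoise(X, cfg.wt_wavelet, cfg.wt_level, cfg.wt_threshold_rule)
    return emd_denoise_batch(np.atleast_2d(X), cfg.emd_n_noise_imfs,
                             cfg.emd_threshold_mode)
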