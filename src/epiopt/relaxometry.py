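"""Voxel-wise T2* mapping from multi-echo gradient-echo magnitude data.

The signal of a spoiled GRE acquisition sampled at several echo times
decays mono-exponentially, ``S(TE) = S0 * exp(-TE/T2*)``, provided the
voxel is a single compartment and macroscopic field gradients are
negligible.  The default fitter is a weighted log-linear regression
(weights proportional to the squared signal, which makes log-domain least
squares equivalent to signal-domain least squares to first order in the
noise); an optional Levenberg-Marquardt refinement in signal space is
available via ``method="nonlin"``.

Echoes that have sunk below three times the background noise level are
excluded from the fit when a noise-floor estimate is supplied.  No Rician
bias correction is applied: the intended operating regime is magnitude
SNR >= 10, where Gaussian statistics are adequate.

Fits with r^2 < 0.8 or T2* outside [1, 2000] ms are flagged invalid rather
than propagated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import nibabel as nib
import numpy as np
from scipy.optimize import curve_fit

from .exceptions import EmptyROIError

__all__ = [
    "MultiEchoSeries",
    "T2StarMap",
    "FitResult",
    "ROIStats",
    "fit_monoexp_voxel",
    "map_t2star",
    "roi_stats",
]

R2_MIN = 0.8
T2_BOUNDS = (1.0, 2000.0)


@dataclass
class MultiEchoSeries:
    """4-D magnitude data (x, y, z, echo) with its echo-time axis."""

    data: np.ndarray
    echo_times: np.ndarray
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, echo)")
        if self.data.shape[-1] != self.echo_times.size:
            raise ValueError("echo axis length must match number of echo times")
        if np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times.size)

    @classmethod
    def from_nifti(cls, path, echo_times) -> "MultiEchoSeries":
        img = nib.load(str(path))
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=float), np.asarray(echo_times),
                   voxel_dims=vox)

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.voxel_dims) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))


class FitResult(NamedTuple):
    s0: float
    t2star: float
    r_squared: float
    valid: bool


class ROIStats(NamedTuple):
    mean: float
    sd: float
    n_voxels: int


@dataclass
class T2StarMap:
    """Voxel-wise T2* fit results; invalid voxels are NaN and flagged."""

    t2star: np.ndarray
    s0: np.ndarray
    r_squared: np.ndarray
    valid_mask: np.ndarray
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.voxel_dims) + [1.0])
        nib.save(nib.Nifti1Image(self.t2star.astype(np.float32), affine),
                 str(path))


def _loglin_fit(signal: np.ndarray, te: np.ndarray, include: np.ndarray):
    """Weighted log-linear fit per row.

    signal: (n, e); te: (e,); include: (n, e) boolean.  Returns s0, t2star,
    n_used arrays; non-decaying rows get t2star = inf.
    """
    w = np.where(include, signal**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(include & (signal > 0), np.log(np.maximum(signal, 1e-300)), 0.0)
    sw = w.sum(axis=1)
    swx = (w * te).sum(axis=1)
    swy = (w * y).sum(axis=1)
    swxx = (w * te**2).sum(axis=1)
    swxy = (w * te * y).sum(axis=1)
    denom = sw * swxx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (sw * swxy - swx * swy) / denom
        intercept = (swy - slope * swx) / sw
    s0 = np.exp(intercept)
    # slopes indistinguishable from zero (T2* > 1e9 ms) count as non-decaying
    with np.errstate(divide="ignore"):
        t2 = np.where(slope < -1e-9, -1.0 / slope, np.inf)
    return s0, t2, include.sum(axis=1)


def _r_squared(signal, te, include, s0, t2):
    with np.errstate(over="ignore", invalid="ignore"):
        pred = s0[:, None] * np.exp(-te[None, :] / t2[:, None])
    resid = np.where(include, signal - pred, 0.0)
    n_used = include.sum(axis=1)
    mean = np.where(n_used > 0,
                    np.where(include, signal, 0.0).sum(axis=1) / np.maximum(n_used, 1),
                    0.0)
    sstot = np.where(include, (signal - mean[:, None])**2, 0.0).sum(axis=1)
    ssres = (resid**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ssres / sstot
    r2 = np.where(sstot > 0, r2, np.nan)  # constant signal: undefined
    return np.clip(r2, 0.0, 1.0)


def _fit_rows(signal: np.ndarray, te: np.ndarray, method: str,
              noise_floor: float | None):
    """Fit S0*exp(-TE/T2*) row-wise; returns (s0, t2, r2, valid)."""
    n, e = signal.shape
    if e < 3:
        raise ValueError("mono-exponential fit needs at least 3 echoes")
    include = signal > 0
    if noise_floor is not None:
        include &= signal >= 3.0 * noise_floor
    enough = include.sum(axis=1) >= 3

    s0, t2, _ = _loglin_fit(signal, te, include)
    decaying = np.isfinite(t2) & (t2 > 0)

    if method == "nonlin":
        rows = np.flatnonzero(enough & decaying)
        for i in rows:
            m = include[i]
            try:
                popt, _ = curve_fit(
                    lambda x, a, t: a * np.exp(-x / t),
                    te[m], signal[i, m], p0=[s0[i], t2[i]],
                    bounds=([0.0, 1e-3], [np.inf, 1e5]), maxfev=200)
                s0[i], t2[i] = popt
            except RuntimeError:
                decaying[i] = False
    elif method != "loglin":
        raise ValueError(f"unknown fit method {method!r}")

    r2 = _r_squared(signal, te, include, s0, np.where(decaying, t2, np.inf))
    valid = (enough & decaying & np.isfinite(r2) & (r2 >= R2_MIN)
             & (t2 >= T2_BOUNDS[0]) & (t2 <= T2_BOUNDS[1]))
    return s0, t2, r2, valid


def fit_monoexp_voxel(signal: Sequence[float], echo_times: Sequence[float],
                      method: str = "loglin",
                      noise_floor: float | None = None) -> FitResult:
    """Fit one voxel's decay; invalid fits are flagged, not raised.

    A non-decaying or constant signal yields ``valid=False`` with
    ``t2star = inf`` / ``nan`` rather than an exception, so callers can mask.
    """
    s = np.atleast_2d(np.asarray(signal, dtype=float))
    te = np.asarray(echo_times, dtype=float)
    if s.shape[1] != te.size:
        raise ValueError("signal and echo_times length mismatch")
    if np.any(s < 0):
        raise ValueError("magnitude signal must be non-negative")
    s0, t2, r2, valid = _fit_rows(s, te, method, noise_floor)
    return FitResult(float(s0[0]), float(t2[0]),
                     float(r2[0]) if np.isfinite(r2[0]) else float("nan"),
                     bool(valid[0]))


def map_t2star(series: MultiEchoSeries, mask: np.ndarray | None = None,
               method: str = "loglin",
               noise_floor: float | None = None) -> T2StarMap:
    """Voxel-wise T2* map inside ``mask`` (everything, if None)."""
    shape = series.data.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} != spatial shape {shape}")

    t2map = np.full(shape, np.nan)
    s0map = np.full(shape, np.nan)
    r2map = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    idx = np.flatnonzero(mask.ravel())
    if idx.size:
        rows = series.data.reshape(-1, series.n_echoes)[idx]
        s0, t2, r2, ok = _fit_rows(rows, series.echo_times, method, noise_floor)
        flat = t2map.ravel(); flat[idx] = np.where(ok, t2, np.nan)
        flat = s0map.ravel(); flat[idx] = np.where(ok, s0, np.nan)
        flat = r2map.ravel(); flat[idx] = r2
        flat = valid.ravel(); flat[idx] = ok
    return T2StarMap(t2map, s0map, r2map, valid, series.voxel_dims)


def roi_stats(t2map: T2StarMap, roi_mask: np.ndarray) -> ROIStats:
    """Mean / sample SD / count of valid T2* values inside an ROI."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != t2map.t2star.shape:
        raise ValueError("ROI mask shape mismatch")
    sel = roi_mask & t2map.valid_mask
    n = int(sel.sum())
    if n == 0:
        raise EmptyROIError("ROI contains no valid T2* voxels")
    vals = t2map.t2star[sel]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return ROIStats(float(np.mean(vals)), sd, n)
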