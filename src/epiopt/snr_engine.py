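"""Pseudo-multiple-replica SNR, temporal SNR, and noise decomposition.

Two complementary SNR measurements for EPI time series:

* **pSNR** — from a *single* acquisition plus the receiver noise covariance
  Ψ, many synthetic replicas are formed by adding properly scaled and
  correlated complex Gaussian noise to k-space and reconstructing each
  (inverse FFT + root-sum-of-squares coil combination).  Replicas differ
  only by thermal noise, so voxel-wise mean/SD over replicas estimates the
  thermal-noise-limited SNR.
* **tSNR** — voxel-wise mean over temporal SD of a repeated-acquisition
  time series; includes physiological fluctuations and system instability
  on top of thermal noise.

Because physiological noise adds variance in quadrature, the two combine
into the physiological-to-thermal noise ratio

    σP/σT = sqrt((pSNR/tSNR)^2 − 1),

defined only where pSNR >= tSNR (elsewhere the argument is negative purely
through sampling noise and the ratio is flagged NaN, never imaginary).
σP/σT < 1 means thermal-noise dominance.

Conventions: Ψ is the covariance of circular complex noise, E[n n^H] = Ψ
(real and imaginary parts each carry Ψ/2); reconstruction uses centered
orthonormal 2-D FFTs so white k-space noise maps to white image noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from .exceptions import EmptyROIError

__all__ = [
    "KSpaceSeries",
    "EPITimeSeries",
    "SNRSummary",
    "fft2c",
    "ifft2c",
    "reconstruct_rss",
    "pseudo_replica_snr",
    "temporal_snr",
    "noise_ratio",
    "summarize_snr",
]


def fft2c(img: np.ndarray, axes=(-3, -2)) -> np.ndarray:
    """Centered orthonormal 2-D FFT (image -> k-space)."""
    x = np.fft.ifftshift(img, axes=axes)
    x = np.fft.fft2(x, axes=axes, norm="ortho")
    return np.fft.fftshift(x, axes=axes)


def ifft2c(ksp: np.ndarray, axes=(-3, -2)) -> np.ndarray:
    """Centered orthonormal 2-D inverse FFT (k-space -> image)."""
    x = np.fft.ifftshift(ksp, axes=axes)
    x = np.fft.ifft2(x, axes=axes, norm="ortho")
    return np.fft.fftshift(x, axes=axes)


@dataclass
class KSpaceSeries:
    """Multi-coil Cartesian k-space with its coil noise covariance Ψ.

    ``data`` has shape (coil, kx, ky, slice) for a single acquisition or
    (coil, kx, ky, slice, rep) for a time series.
    """

    data: np.ndarray
    noise_cov: np.ndarray
    te: float | None = None
    tr: float | None = None
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.noise_cov = np.asarray(self.noise_cov)
        if self.data.ndim not in (4, 5):
            raise ValueError("k-space must be (coil, kx, ky, slice[, rep])")
        nc = self.data.shape[0]
        if self.noise_cov.shape != (nc, nc):
            raise ValueError("noise covariance must be (n_coils, n_coils)")
        if not np.allclose(self.noise_cov, self.noise_cov.conj().T):
            raise ValueError("noise covariance must be Hermitian")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_reps(self) -> int:
        return self.data.shape[4] if self.data.ndim == 5 else 1

    def rep(self, i: int = 0) -> np.ndarray:
        """Single-acquisition k-space volume (coil, kx, ky, slice)."""
        return self.data[..., i] if self.data.ndim == 5 else self.data

    def to_hdf5(self, path, attrs: Mapping | None = None) -> None:
        with h5py.File(str(path), "w") as f:
            f.create_dataset("data", data=self.data.astype(np.complex64))
            f.create_dataset("noise_cov", data=self.noise_cov.astype(np.complex128))
            if self.te is not None:
                f.attrs["te_ms"] = self.te
            if self.tr is not None:
                f.attrs["tr_ms"] = self.tr
            f.attrs["voxel_dims_mm"] = np.asarray(self.voxel_dims)
            for k, v in (attrs or {}).items():
                f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "KSpaceSeries":
        with h5py.File(str(path), "r") as f:
            return cls(
                data=f["data"][()],
                noise_cov=f["noise_cov"][()],
                te=float(f.attrs["te_ms"]) if "te_ms" in f.attrs else None,
                tr=float(f.attrs["tr_ms"]) if "tr_ms" in f.attrs else None,
                voxel_dims=tuple(f.attrs.get("voxel_dims_mm", (1.0, 1.0, 1.0))),
            )


@dataclass
class EPITimeSeries:
    """Reconstructed 4-D magnitude time series (x, y, z, t)."""

    data: np.ndarray
    tr: float | None = None
    te: float | None = None
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("time series must be 4-D (x, y, z, t)")

    @property
    def n_reps(self) -> int:
        return self.data.shape[-1]


def reconstruct_rss(kspace_vol: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares reconstruction of one (coil, kx, ky, slice) volume."""
    coil_imgs = ifft2c(kspace_vol, axes=(1, 2))
    return np.sqrt(np.sum(np.abs(coil_imgs) ** 2, axis=0))


def draw_correlated_noise(rng: np.random.Generator, chol: np.ndarray,
                          shape: tuple[int, ...]) -> np.ndarray:
    """Circular complex Gaussian noise with E[n n^H] = chol @ chol^H.

    ``shape`` is the per-coil sample shape; output is (n_coils,) + shape.
    """
    nc = chol.shape[0]
    iid = (rng.standard_normal((nc,) + shape)
           + 1j * rng.standard_normal((nc,) + shape)) / np.sqrt(2.0)
    return np.einsum("ab,b...->a...", chol, iid)


def pseudo_replica_snr(kspace: KSpaceSeries, n_replicas: int = 128,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Voxel-wise pseudo-multiple-replica SNR map from one acquisition.

    Adds ``n_replicas`` independent correlated-noise realizations (drawn
    through the Cholesky factor of Ψ) to the k-space data, reconstructs
    each, and returns mean/SD over the replicas.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_replicas < 2:
        raise ValueError("need at least 2 replicas")
    if n_replicas < 8:
        warnings.warn("fewer than 8 replicas gives an unstable SD estimate",
                      stacklevel=2)
    try:
        chol = np.linalg.cholesky(kspace.noise_cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("noise covariance must be positive-definite") from exc

    base = kspace.rep(0).astype(np.complex128)
    acc = None
    acc2 = None
    for _ in range(n_replicas):
        noise = draw_correlated_noise(rng, chol, base.shape[1:])
        img = reconstruct_rss(base + noise)
        if acc is None:
            acc = img.copy()
            acc2 = img ** 2
        else:
            acc += img
            acc2 += img ** 2
    mean = acc / n_replicas
    var = (acc2 - n_replicas * mean ** 2) / (n_replicas - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sd > 0, mean / sd, np.inf)
    return snr


def temporal_snr(timeseries, detrend: bool = False) -> np.ndarray:
    """Voxel-wise temporal SNR: mean / temporal SD over repetitions.

    Accepts an :class:`EPITimeSeries` or a bare (x, y, z, t) array.  Voxels
    with zero temporal variance are flagged infinite.  Optional linear
    detrending removes a per-voxel linear drift before the SD (off by
    default; the phantom has no drift).
    """
    data = timeseries.data if isinstance(timeseries, EPITimeSeries) else \
        np.asarray(timeseries, dtype=float)
    if data.ndim != 4:
        raise ValueError("time series must be 4-D (x, y, z, t)")
    n = data.shape[-1]
    if n < 8:
        raise ValueError("need at least 8 repetitions for a temporal SD")
    mean = data.mean(axis=-1)
    if detrend:
        t = np.arange(n) - (n - 1) / 2.0
        slope = (data * t).sum(axis=-1) / (t ** 2).sum()
        resid = data - mean[..., None] - slope[..., None] * t
        sd = np.sqrt((resid ** 2).sum(axis=-1) / (n - 2))
    else:
        sd = data.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sd > 0, mean / sd, np.inf)


def noise_ratio(psnr, tsnr):
    """Physiological-to-thermal noise ratio sqrt((pSNR/tSNR)^2 − 1).

    NaN where pSNR < tSNR (sampling noise would make the ratio imaginary)
    and where tSNR is zero or not finite.
    """
    p = np.asarray(psnr, dtype=float)
    t = np.asarray(tsnr, dtype=float)
    if np.any(t == 0):
        raise ZeroDivisionError("tSNR contains zeros")
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = (p / t) ** 2 - 1.0
        out = np.where((arg >= 0) & np.isfinite(arg), np.sqrt(np.abs(arg)),
                       np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass
class SNRSummary:
    """Voxel-wise maps plus per-ROI SNR and noise-ratio statistics.

    The table reports, per ROI, both Eq.-of-means and mean-of-voxel-ratios
    variants of the noise decomposition:

    * ``ratio_of_means`` — the ratio computed from ROI-mean pSNR and tSNR;
    * ``voxel_ratio_mean`` — mean of the voxel-wise ratio map over the ROI
      (NaN voxels excluded; their fraction is ``ratio_defined_frac``).
    """

    psnr_map: np.ndarray
    tsnr_map: np.ndarray
    ratio_map: np.ndarray
    table: pd.DataFrame
    n_replicas: int | None = None
    n_repeats: int | None = None


def summarize_snr(psnr_map: np.ndarray, tsnr_map: np.ndarray,
                  roi_masks: Mapping[str, np.ndarray],
                  n_replicas: int | None = None,
                  n_repeats: int | None = None) -> SNRSummary:
    """Per-ROI mean ± SD of pSNR, tSNR and the noise ratio."""
    psnr_map = np.asarray(psnr_map, dtype=float)
    tsnr_map = np.asarray(tsnr_map, dtype=float)
    ratio_map = noise_ratio(psnr_map, tsnr_map)
    rows = []
    for name, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != psnr_map.shape:
            raise ValueError(f"ROI {name!r} shape mismatch")
        n = int(mask.sum())
        if n == 0:
            raise EmptyROIError(f"ROI {name!r} is empty")
        p = psnr_map[mask]
        t = tsnr_map[mask]
        r = ratio_map[mask]
        defined = np.isfinite(r)
        rows.append({
            "roi": name,
            "n_voxels": n,
            "psnr_mean": float(np.mean(p)),
            "psnr_sd": float(np.std(p, ddof=1)) if n > 1 else 0.0,
            "tsnr_mean": float(np.mean(t)),
            "tsnr_sd": float(np.std(t, ddof=1)) if n > 1 else 0.0,
            "ratio_of_means": float(noise_ratio(np.mean(p), np.mean(t))),
            "voxel_ratio_mean": float(np.nanmean(r)) if defined.any() else float("nan"),
            "ratio_defined_frac": float(defined.mean()),
        })
    table = pd.DataFrame(rows).set_index("roi")
    return SNRSummary(psnr_map, tsnr_map, ratio_map, table,
                      n_replicas=n_replicas, n_repeats=n_repeats)
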