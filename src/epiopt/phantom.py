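"""Digital brain-like phantom and forward simulation of GRE acquisitions.

The phantom replaces volunteer data with a fully controlled object: a
white-matter ellipsoid core inside a gray-matter ellipsoidal shell, with a
"visual cortex" patch carved out of the posterior part of the shell.  Each
compartment carries its own proton density and mid-field relaxation
parameters (defaults: T1 = 717.2 ms everywhere; T2* = 86.3 ms GM, 77.9 ms
WM, 78.5 ms visual cortex).

Two forward models are provided:

* ``simulate_megre`` — image-domain multi-echo GRE magnitude series for
  T2* mapping (spoiled steady state × mono-exponential decay + noise);
* ``simulate_epi_timeseries`` — multi-coil EPI k-space time series with
  correlated thermal noise and an optional two-term physiological signal
  model.  Per repetition the image is

      S · (1 + λ_const·g_t + λ_bold · TE·e^{−TE/T2*} · h_t)

  with g, h unit-variance AR(1) processes (independent per voxel): a
  signal-proportional non-BOLD term and a BOLD-like term whose amplitude
  carries the TE weighting of susceptibility contrast, so the injected
  physiological-to-thermal ratio grows as TE approaches T2*.  The analytic
  per-voxel σP, σT and σP/σT ground truth is returned alongside the data.

Sampling is ideal Cartesian (no trajectory effects, no decay during the
readout), so the forward model is exactly inverted by the FFT + RSS
reconstruction in :mod:`epiopt.snr_engine`.  The simulated signal includes
the voxel-volume factor, so at fixed k-space noise larger voxels yield
proportionally higher baseline SNR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .efficiency import RelaxationParams, steady_state_signal
from .exceptions import InvalidConfigError
from .relaxometry import MultiEchoSeries
from .sequence_model import EPIProtocol
from .snr_engine import KSpaceSeries, draw_correlated_noise, fft2c

__all__ = [
    "PhantomSpec",
    "TissuePhantom",
    "EPIGroundTruth",
    "make_tissue_phantom",
    "synthesize_coils",
    "simulate_megre",
    "simulate_epi_timeseries",
    "calibrate_lambda",
    "ground_truth_summary",
]

_GM = RelaxationParams(717.2, 86.3, "gray matter")
_WM = RelaxationParams(717.2, 77.9, "white matter")
_VC = RelaxationParams(717.2, 78.5, "visual cortex")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue, coil and noise description of the digital phantom.

    ``target_psnr`` sets the thermal noise level as the GM-mean
    thermal-only SNR of the reconstructed image; alternatively
    ``thermal_sigma`` fixes the k-space noise scale directly (takes
    precedence when set).  ``lambda_const`` and ``lambda_bold`` are the
    amplitudes of the two physiological terms (the BOLD-like term
    multiplies TE·e^{−TE/T2*} in ms, so useful values are ~1e-3).
    """

    shape: tuple[int, int, int] = (48, 48, 12)
    voxel_size: float = 4.0                      # mm, isotropic
    outer_frac: tuple[float, float, float] = (0.82, 0.88, 0.80)
    wm_frac: float = 0.62                        # WM core relative to outer
    vc_posterior_frac: float = 0.30              # posterior GM band -> VC
    gm: RelaxationParams = _GM
    wm: RelaxationParams = _WM
    vc: RelaxationParams = _VC
    pd_gm: float = 0.80
    pd_wm: float = 0.70
    pd_vc: float = 0.80
    n_coils: int = 16
    coil_coupling: float = 0.10                  # off-diagonal of Ψ
    target_psnr: float = 50.0
    thermal_sigma: float | None = None
    lambda_const: float = 0.0
    lambda_bold: float = 0.0
    ar_coeff: float = 0.7
    seed: int = 20230

    @property
    def voxel_dims(self) -> tuple[float, float, float]:
        return (self.voxel_size,) * 3

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size ** 3


@dataclass
class TissuePhantom:
    """Tissue masks and parameter volumes produced from a PhantomSpec."""

    spec: PhantomSpec
    masks: dict[str, np.ndarray]       # 'gm', 'wm', 'vc' — pairwise disjoint
    t1_map: np.ndarray
    t2star_map: np.ndarray
    pd_map: np.ndarray

    @property
    def brain_mask(self) -> np.ndarray:
        return self.masks["gm"] | self.masks["wm"] | self.masks["vc"]


def _ellipsoid(shape, semiaxes, center=None) -> np.ndarray:
    if center is None:
        center = [(n - 1) / 2.0 for n in shape]
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return r2 <= 1.0


def make_tissue_phantom(spec: PhantomSpec) -> TissuePhantom:
    """Deterministic tissue geometry and parameter volumes.

    Raises :class:`InvalidConfigError` if any compartment is empty (e.g.,
    a zero-thickness GM shell) or exceeds the grid.
    """
    shape = tuple(int(n) for n in spec.shape)
    semi_outer = [f * n / 2.0 for f, n in zip(spec.outer_frac, shape)]
    if any(a >= n / 2.0 for a, n in zip(semi_outer, shape)):
        raise InvalidConfigError("outer compartment exceeds the grid")
    outer = _ellipsoid(shape, semi_outer)
    inner = _ellipsoid(shape, [spec.wm_frac * a for a in semi_outer])
    shell = outer & ~inner

    # posterior band of the shell (+y direction) becomes the VC patch
    y = np.arange(shape[1])[None, :, None]
    y_cut = shape[1] * (1.0 - spec.vc_posterior_frac)
    vc = shell & np.broadcast_to(y >= y_cut, shape)
    gm = shell & ~vc
    wm = inner

    for name, m in (("wm", wm), ("gm", gm), ("vc", vc)):
        if not m.any():
            raise InvalidConfigError(f"compartment {name!r} is empty")

    t1 = np.zeros(shape)
    t2s = np.zeros(shape)
    pd = np.zeros(shape)
    for m, relax, w in ((gm, spec.gm, spec.pd_gm), (wm, spec.wm, spec.pd_wm),
                        (vc, spec.vc, spec.pd_vc)):
        t1[m] = relax.t1
        t2s[m] = relax.t2star
        pd[m] = w
    return TissuePhantom(spec, {"gm": gm, "wm": wm, "vc": vc}, t1, t2s, pd)


def synthesize_coils(n_coils: int, shape, rho: float = 0.10,
                     radius_frac: float = 1.05,
                     width_frac: float = 0.75):
    """Smooth complex coil sensitivities and the coil noise covariance Ψ.

    Coils are Gaussian lobes centered on a circle around the in-plane FOV
    with linear phase ramps; ``n_coils == 1`` yields a uniform sensitivity.
    Ψ has unit diagonal and constant off-diagonal coupling ``rho``
    (requires −1/(n−1) < rho < 1 for positive-definiteness).
    """
    if n_coils < 1:
        raise InvalidConfigError("n_coils must be >= 1")
    if abs(rho) >= 1:
        raise InvalidConfigError("|coil coupling| must be < 1")
    shape = tuple(int(n) for n in shape)
    nx, ny = shape[0], shape[1]
    if n_coils == 1:
        sens = np.ones((1,) + shape, dtype=complex)
        return sens, np.eye(1, dtype=complex)
    if rho <= -1.0 / (n_coils - 1):
        raise InvalidConfigError("coupling makes Ψ non-positive-definite")

    x = np.arange(nx)[:, None] - (nx - 1) / 2.0
    y = np.arange(ny)[None, :] - (ny - 1) / 2.0
    r = radius_frac * max(nx, ny) / 2.0
    width = width_frac * max(nx, ny)
    sens2d = np.empty((n_coils, nx, ny), dtype=complex)
    for c in range(n_coils):
        th = 2.0 * math.pi * c / n_coils
        cx, cy = r * math.cos(th), r * math.sin(th)
        mag = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * width ** 2)))
        phase = 2.0 * math.pi * (x * math.cos(th) + y * math.sin(th)) / (4.0 * max(nx, ny))
        sens2d[c] = mag * np.exp(1j * phase)
    sens = np.repeat(sens2d[:, :, :, None], shape[2], axis=3)
    psi = np.full((n_coils, n_coils), complex(rho))
    np.fill_diagonal(psi, 1.0)
    return sens, psi


def steady_state_image(phantom: TissuePhantom, te: float, tr: float,
                       flip_deg: float) -> np.ndarray:
    """Noiseless voxel signal PD·V·f(α,TR,T1)·exp(−TE/T2*) (zero outside)."""
    m = phantom.brain_mask
    out = np.zeros(phantom.spec.shape)
    ss = steady_state_signal(tr, phantom.t1_map[m], flip_deg)
    out[m] = (phantom.pd_map[m] * phantom.spec.voxel_volume * ss
              * np.exp(-te / phantom.t2star_map[m]))
    return out


def simulate_megre(phantom: TissuePhantom, echo_times, flip: float = 32.0,
                   tr: float = 97.25, snr: float = 100.0,
                   seed: int | None = None) -> MultiEchoSeries:
    """Image-domain multi-echo GRE magnitude series for T2* mapping.

    ``snr`` sets the first-echo GM-mean signal over the additive Gaussian
    noise SD; ``snr=inf`` (or None) gives noiseless data.
    """
    echo_times = np.asarray(echo_times, dtype=float)
    if np.any(np.diff(echo_times) <= 0):
        raise InvalidConfigError("echo times must be strictly increasing")
    spec = phantom.spec
    vols = np.stack([steady_state_image(phantom, te, tr, flip)
                     for te in echo_times], axis=-1)
    if snr is not None and np.isfinite(snr):
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        s_ref = vols[..., 0][phantom.masks["gm"]].mean()
        vols = np.abs(vols + rng.normal(0.0, s_ref / snr, size=vols.shape))
    return MultiEchoSeries(vols, echo_times, voxel_dims=spec.voxel_dims)


@dataclass
class EPIGroundTruth:
    """Analytic per-voxel truth for one simulated EPI run."""

    ideal_image: np.ndarray   # noiseless RSS magnitude
    sigma_t: np.ndarray       # thermal noise SD in the RSS image
    sigma_p: np.ndarray       # physiological fluctuation SD
    ratio: np.ndarray         # σP/σT (NaN outside the object)
    bold_weight: float        # TE·e^{−TE/T2*} at the GM T2*, ms


def _thermal_sigma_for_target(signal_coils, psi, rss, gm_mask, target):
    """k-space noise scale giving GM-mean thermal SNR = target."""
    quad = np.einsum("a...,ab,b...->...", signal_coils.conj(), psi,
                     signal_coils).real
    with np.errstate(divide="ignore", invalid="ignore"):
        unit_sigma = np.sqrt(quad / 2.0) / rss      # σT per unit k-space σ
    return float(np.mean(rss[gm_mask] / unit_sigma[gm_mask]) / target)


def _sigma_t_map(signal_coils, psi, rss, sigma_k):
    """Linearized RSS-magnitude thermal noise SD per voxel."""
    quad = np.einsum("a...,ab,b...->...", signal_coils.conj(), psi,
                     signal_coils).real
    with np.errstate(divide="ignore", invalid="ignore"):
        out = sigma_k * np.sqrt(quad / 2.0) / rss
    return np.where(rss > 0, out, np.nan)


def _ar1(rng, rho, shape, n_steps):
    """Unit-variance AR(1) field, independent across voxels: (..., t)."""
    out = np.empty(shape + (n_steps,))
    out[..., 0] = rng.standard_normal(shape)
    scale = math.sqrt(1.0 - rho ** 2)
    for t in range(1, n_steps):
        out[..., t] = rho * out[..., t - 1] + scale * rng.standard_normal(shape)
    return out


def simulate_epi_timeseries(phantom: TissuePhantom, protocol: EPIProtocol,
                            n_repeats: int = 64, seed: int | None = None
                            ) -> tuple[KSpaceSeries, EPIGroundTruth]:
    """Multi-coil EPI k-space time series plus analytic noise ground truth."""
    spec = phantom.spec
    shape = tuple(spec.shape)
    if tuple(protocol.matrix_inplane) != shape[:2]:
        raise InvalidConfigError(
            f"protocol matrix {protocol.matrix_inplane} does not match "
            f"phantom grid {shape[:2]}")
    if n_repeats < 1:
        raise InvalidConfigError("n_repeats must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    s0 = steady_state_image(phantom, protocol.te, protocol.tr,
                            protocol.flip_angle)
    sens, psi0 = synthesize_coils(spec.n_coils, shape, spec.coil_coupling)
    signal_coils = sens * s0[None]
    rss = np.sqrt(np.sum(np.abs(signal_coils) ** 2, axis=0))

    if spec.thermal_sigma is not None:
        sigma_k = float(spec.thermal_sigma)
    else:
        sigma_k = _thermal_sigma_for_target(signal_coils, psi0, rss,
                                            phantom.masks["gm"],
                                            spec.target_psnr)
    noise_cov = sigma_k ** 2 * psi0
    chol = sigma_k * np.linalg.cholesky(psi0)

    # BOLD-like weighting uses each voxel's own T2*
    with np.errstate(divide="ignore", invalid="ignore"):
        w_map = np.where(phantom.t2star_map > 0,
                         protocol.te * np.exp(-protocol.te
                                              / np.maximum(phantom.t2star_map, 1e-9)),
                         0.0)
    lam_c, lam_b = spec.lambda_const, spec.lambda_bold
    has_physio = (lam_c != 0.0) or (lam_b != 0.0)
    if has_physio:
        g = _ar1(rng, spec.ar_coeff, shape, n_repeats)
        h = _ar1(rng, spec.ar_coeff, shape, n_repeats)

    data = np.empty((spec.n_coils,) + shape + (n_repeats,), dtype=np.complex64)
    for t in range(n_repeats):
        img = s0
        if has_physio:
            img = s0 * (1.0 + lam_c * g[..., t] + lam_b * w_map * h[..., t])
        ksp = fft2c(sens * img[None], axes=(1, 2))
        ksp += draw_correlated_noise(rng, chol, shape)
        data[..., t] = ksp

    sigma_t = _sigma_t_map(signal_coils, psi0, rss, sigma_k)
    sigma_p = rss * np.sqrt(lam_c ** 2 + (lam_b * w_map) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(rss > 0, sigma_p / sigma_t, np.nan)
    gt = EPIGroundTruth(
        ideal_image=rss, sigma_t=sigma_t, sigma_p=sigma_p, ratio=ratio,
        bold_weight=float(protocol.te * math.exp(-protocol.te / spec.gm.t2star)),
    )
    series = KSpaceSeries(data, noise_cov, te=protocol.te, tr=protocol.tr,
                          voxel_dims=spec.voxel_dims)
    return series, gt


def ground_truth_summary(gt: EPIGroundTruth, roi_masks: Mapping[str, np.ndarray]
                         ) -> dict[str, float]:
    """ROI-level σP/σT from the analytic maps, via the same ratio-of-means
    functional used for estimated maps (Eq.-5 identity on ROI-mean SNRs)."""
    out = {}
    for name, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        p = np.mean(gt.ideal_image[mask] / gt.sigma_t[mask])
        t = np.mean(gt.ideal_image[mask]
                    / np.sqrt(gt.sigma_t[mask] ** 2 + gt.sigma_p[mask] ** 2))
        out[name] = math.sqrt(max((p / t) ** 2 - 1.0, 0.0))
    return out


def calibrate_lambda(phantom: TissuePhantom, protocol: EPIProtocol,
                     target_ratio: float, mode: str = "const") -> float:
    """λ giving a GM ROI-level σP/σT equal to ``target_ratio``.

    Solves on the analytic ground truth (no simulation), using the
    ratio-of-ROI-means summary.  ``mode`` selects which physiological term
    carries the fluctuation ('const' or 'bold').
    """
    if target_ratio < 0:
        raise InvalidConfigError("target ratio must be non-negative")
    if target_ratio == 0:
        return 0.0
    spec = phantom.spec
    s0 = steady_state_image(phantom, protocol.te, protocol.tr,
                            protocol.flip_angle)
    sens, psi0 = synthesize_coils(spec.n_coils, spec.shape, spec.coil_coupling)
    signal_coils = sens * s0[None]
    rss = np.sqrt(np.sum(np.abs(signal_coils) ** 2, axis=0))
    if spec.thermal_sigma is not None:
        sigma_k = float(spec.thermal_sigma)
    else:
        sigma_k = _thermal_sigma_for_target(signal_coils, psi0, rss,
                                            phantom.masks["gm"],
                                            spec.target_psnr)
    sigma_t = _sigma_t_map(signal_coils, psi0, rss, sigma_k)
    gm = phantom.masks["gm"]
    if mode == "const":
        weight = np.ones_like(rss)
    elif mode == "bold":
        with np.errstate(divide="ignore", invalid="ignore"):
            weight = protocol.te * np.exp(-protocol.te
                                          / np.maximum(phantom.t2star_map, 1e-9))
    else:
        raise InvalidConfigError(f"unknown mode {mode!r}")

    p_bar = np.mean(rss[gm] / sigma_t[gm])

    def f(lam):
        sp = lam * weight[gm] * rss[gm]
        t_bar = np.mean(rss[gm] / np.sqrt(sigma_t[gm] ** 2 + sp ** 2))
        return math.sqrt(max((p_bar / t_bar) ** 2 - 1.0, 0.0)) - target_ratio

    hi = 10.0 / max(np.mean(weight[gm]), 1e-12) \
        * float(np.mean(sigma_t[gm] / rss[gm]))
    return float(brentq(f, 0.0, hi, xtol=1e-12))
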