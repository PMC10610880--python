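"""T2* contrast efficiency: the figure of merit for GRE-EPI at mid-field.

The BOLD-weighted image SNR of a spoiled gradient-echo EPI acquisition is

    SNR_BOLD ∝ Δx·Δy·Δz · TE · sqrt(TAD) · f(α, TR, T1) · exp(−TE/T2*)

where ``f`` is the spoiled steady-state term ``(1−E)·sin α / (1 − E·cos α)``
with ``E = exp(−TR/T1)``, and TAD is the readout duration (longer readouts
average more of the thermal noise).  Acquiring N images in a run of fixed
total duration TS = N·TR multiplies SNR by sqrt(N), which motivates the
*contrast efficiency*

    η_T2* = SNR_BOLD / sqrt(TR)

as the quantity to maximize when the scan time, not the image count, is
fixed.  With TR free, the optimum is TE = T2*; when TR must grow with TE
(multi-slice coverage forces TR ≥ n_slices·(TE + c)), the 1/sqrt(TR)
penalty moves the optimum to TE < T2*.

All SNR values are in arbitrary units (proportionality constant K = 1);
only ratios are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .exceptions import InvalidConfigError
from .sequence_model import EPIProtocol

__all__ = [
    "RelaxationParams",
    "EfficiencyCurve",
    "ernst_angle",
    "ernst_angle_int",
    "steady_state_signal",
    "snr_bold",
    "timeseries_snr",
    "contrast_efficiency",
    "optimize_te",
]


@dataclass(frozen=True)
class RelaxationParams:
    """Longitudinal (T1) and effective transverse (T2*) relaxation, ms."""

    t1: float
    t2star: float
    tissue_label: str = ""

    def __post_init__(self):
        if self.t1 <= 0 or self.t2star <= 0:
            raise ValueError("T1 and T2* must be strictly positive")


def ernst_angle(tr, t1) -> float:
    """Ernst angle arccos(exp(−TR/T1)) in degrees (vectorized)."""
    tr = np.asarray(tr, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if np.any(tr <= 0) or np.any(t1 <= 0):
        raise ValueError("TR and T1 must be strictly positive")
    out = np.degrees(np.arccos(np.exp(-tr / t1)))
    return float(out) if out.ndim == 0 else out


def ernst_angle_int(tr, t1):
    """Ernst angle rounded to the nearest integer degree."""
    out = np.rint(ernst_angle(tr, t1)).astype(int)
    return int(out) if np.ndim(out) == 0 else out


def steady_state_signal(tr, t1, flip_deg):
    """Spoiled GRE steady-state term (1−E)·sinα / (1 − E·cosα), E = e^{−TR/T1}."""
    e1 = np.exp(-np.asarray(tr, dtype=float) / np.asarray(t1, dtype=float))
    a = np.radians(np.asarray(flip_deg, dtype=float))
    out = (1.0 - e1) * np.sin(a) / (1.0 - e1 * np.cos(a))
    return float(out) if np.ndim(out) == 0 else out


def snr_bold(protocol: EPIProtocol, relaxation: RelaxationParams) -> float:
    """BOLD-weighted SNR of one EPI acquisition (arbitrary units, K = 1)."""
    if not 0.0 < protocol.flip_angle <= 90.0:
        raise ValueError("flip angle must be in (0, 90] degrees")
    ss = steady_state_signal(protocol.tr, relaxation.t1, protocol.flip_angle)
    return (protocol.voxel_volume * protocol.te * math.sqrt(protocol.tad)
            * ss * math.exp(-protocol.te / relaxation.t2star))


def timeseries_snr(snr: float, n_images: int) -> float:
    """SNR after averaging an N-image time series with uncorrelated noise."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    return math.sqrt(n_images) * snr


def contrast_efficiency(snr, tr):
    """T2* contrast efficiency η = SNR_BOLD / sqrt(TR) (vectorized)."""
    tr = np.asarray(tr, dtype=float)
    if np.any(tr <= 0):
        raise ValueError("TR must be strictly positive")
    out = np.asarray(snr, dtype=float) / np.sqrt(tr)
    return float(out) if out.ndim == 0 else out


@dataclass
class EfficiencyCurve:
    """η_T2* evaluated over a TE grid, with its argmax.

    ``snr_bold`` and ``eta`` are in arbitrary units.  ``te_opt`` is the TE
    maximizing η; on a discrete grid, exact ties resolve to the smaller TE.
    """

    te_grid: np.ndarray
    tr_grid: np.ndarray
    flip_grid: np.ndarray
    snr_bold: np.ndarray
    eta: np.ndarray
    te_opt: float
    relaxation: RelaxationParams
    mode: str = "grid"

    @property
    def eta_max(self) -> float:
        return float(np.max(self.eta))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "te_ms": self.te_grid,
            "tr_ms": self.tr_grid,
            "flip_deg": self.flip_grid,
            "snr_bold": self.snr_bold,
            "eta": self.eta,
        })


def _argmax_smallest(te: np.ndarray, eta: np.ndarray) -> float:
    """Index of the maximum, breaking (near-machine) ties toward smaller TE."""
    top = np.flatnonzero(eta >= eta.max() * (1.0 - 1e-12))
    return float(te[top[0]])


def optimize_te(
    te_grid: Sequence[float] | None = None,
    protocols: Sequence[EPIProtocol] | None = None,
    relaxation: RelaxationParams | None = None,
    mode: str = "grid",
    tr_fn: Callable[[float], float] | None = None,
    template: EPIProtocol | None = None,
    te_bounds: tuple[float, float] = (1.0, 300.0),
    n_samples: int = 601,
) -> EfficiencyCurve:
    """Find the efficiency-optimal echo time.

    Grid mode evaluates η at each supplied per-TE protocol (TE, TR and flip
    angle all vary along the grid, as on a scanner where TR is the minimum
    for the slice coverage and the flip angle the Ernst angle for that TR).
    Continuous mode maximizes η(TE) with TR given by ``tr_fn`` and the exact
    Ernst angle at each TR, using bounded scalar optimization; the returned
    curve is densely sampled over ``te_bounds``.
    """
    if relaxation is None:
        raise InvalidConfigError("relaxation parameters are required")

    if mode == "grid":
        if not protocols:
            raise InvalidConfigError("grid mode needs a non-empty protocol list")
        te = np.array([p.te for p in protocols], dtype=float)
        if te_grid is not None and not np.allclose(te, np.asarray(te_grid, float)):
            raise InvalidConfigError("te_grid does not match protocol TEs")
        if te.size == 0:
            raise InvalidConfigError("empty TE grid")
        if np.any(np.diff(te) <= 0):
            raise InvalidConfigError("TE grid must be strictly increasing")
        snr = np.array([snr_bold(p, relaxation) for p in protocols])
        tr = np.array([p.tr for p in protocols], dtype=float)
        fa = np.array([p.flip_angle for p in protocols], dtype=float)
        eta = contrast_efficiency(snr, tr)
        return EfficiencyCurve(te, tr, fa, snr, np.asarray(eta),
                               _argmax_smallest(te, np.asarray(eta)),
                               relaxation, mode="grid")

    if mode == "continuous":
        if tr_fn is None:
            raise InvalidConfigError("continuous mode needs tr_fn(TE) -> TR")
        tad = template.tad if template is not None else 1.0
        volume = template.voxel_volume if template is not None else 1.0

        def eta_of(te: float) -> float:
            tr = tr_fn(te)
            alpha = ernst_angle(tr, relaxation.t1)
            ss = steady_state_signal(tr, relaxation.t1, alpha)
            s = (volume * te * math.sqrt(tad) * ss
                 * math.exp(-te / relaxation.t2star))
            return s / math.sqrt(tr)

        res = minimize_scalar(lambda x: -eta_of(x), bounds=te_bounds,
                              method="bounded",
                              options={"xatol": 1e-8})
        te_opt = float(res.x)
        te = np.linspace(te_bounds[0], te_bounds[1], n_samples)
        tr = np.array([tr_fn(x) for x in te], dtype=float)
        fa = ernst_angle(tr, relaxation.t1)
        ss = steady_state_signal(tr, relaxation.t1, fa)
        snr = volume * te * math.sqrt(tad) * ss * np.exp(-te / relaxation.t2star)
        eta = contrast_efficiency(snr, tr)
        return EfficiencyCurve(te, tr, np.asarray(fa), snr, np.asarray(eta),
                               te_opt, relaxation, mode="continuous")

    raise InvalidConfigError(f"unknown mode {mode!r}")
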