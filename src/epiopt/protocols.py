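"""Reference 0.5 T protocol families and tissue relaxation constants.

The two built-in EPI families are the 3.4 mm and 4.0 mm isotropic
single-shot GRE-EPI protocols of a head-only 0.5 T system: nine echo times
from 25 to 105 ms in 10 ms steps, each run at the minimum TR for its slice
coverage with the flip angle set to the Ernst angle for gray matter.

Relaxation constants are 0.5–0.55 T gray/white-matter values: GM T1
717.2 ms; T2* 86.3 ms (GM), 77.9 ms (WM), 78.5 ms (visual cortex).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .efficiency import RelaxationParams
from .sequence_model import EPIProtocol, build_protocol, calibrate_overhead

__all__ = [
    "GM", "WM", "VISUAL_CORTEX", "GM_NOMINAL",
    "ProtocolFamily", "FAMILY_3P4MM", "FAMILY_4P0MM",
    "reference_families", "MEGRE_ECHO_TIMES",
]

# gray matter T1 at 0.55 T; T2* values measured at 0.5 T (means over ROIs)
GM = RelaxationParams(t1=717.2, t2star=86.3, tissue_label="gray matter")
WM = RelaxationParams(t1=717.2, t2star=77.9, tissue_label="white matter")
VISUAL_CORTEX = RelaxationParams(t1=717.2, t2star=78.5,
                                 tissue_label="visual cortex")
#: GM with the rounded nominal T2* = 86 ms used for protocol optimization.
GM_NOMINAL = RelaxationParams(t1=717.2, t2star=86.0, tissue_label="gray matter")

#: 26-echo multi-echo GRE grid for T2* mapping: TE1 = 5 ms, spacing 3.4 ms.
MEGRE_ECHO_TIMES = tuple(5.0 + 3.4 * k for k in range(26))


@dataclass(frozen=True)
class ProtocolFamily:
    """A TE series of otherwise-identical EPI protocols (one resolution)."""

    name: str
    voxel_size: float                 # isotropic, mm
    fov_inplane: float                # mm
    matrix: int                       # in-plane matrix (square)
    etl: int
    n_slices: int
    acq_bandwidth: float              # Hz
    te_grid: tuple[float, ...]        # ms
    tr_grid: tuple[float, ...]        # ms
    flip_grid: tuple[int, ...]        # degrees
    prep_time: float = 3.0

    @property
    def per_slice_overhead(self) -> float:
        """Per-slice timing overhead c (ms) calibrated from the TR table."""
        return calibrate_overhead(self.te_grid, self.tr_grid,
                                  self.n_slices).overhead

    def protocols(self) -> list[EPIProtocol]:
        """One validated :class:`EPIProtocol` per grid row."""
        return [
            build_protocol({
                "fov_inplane": self.fov_inplane,
                "matrix_inplane": self.matrix,
                "slice_thickness": self.voxel_size,
                "etl": self.etl,
                "n_slices": self.n_slices,
                "acq_bandwidth": self.acq_bandwidth,
                "te": te,
                "tr": tr,
                "flip_angle": fa,
                "prep_time": self.prep_time,
            })
            for te, tr, fa in zip(self.te_grid, self.tr_grid, self.flip_grid)
        ]


_TE_GRID = tuple(np.arange(25.0, 106.0, 10.0))

FAMILY_3P4MM = ProtocolFamily(
    name="3.4mm",
    voxel_size=3.4,
    fov_inplane=240.0,
    matrix=70,
    etl=70,
    n_slices=38,
    acq_bandwidth=160e3,
    te_grid=_TE_GRID,
    tr_grid=(1738, 2119, 2499, 2879, 3259, 3639, 4019, 4399, 4779),
    flip_grid=(85, 87, 88, 89, 89, 90, 90, 90, 90),
)

FAMILY_4P0MM = ProtocolFamily(
    name="4.0mm",
    voxel_size=4.0,
    fov_inplane=240.0,
    matrix=60,
    etl=60,
    n_slices=32,
    acq_bandwidth=160e3,
    te_grid=_TE_GRID,
    tr_grid=(1386, 1706, 2026, 2346, 2666, 2986, 3306, 3626, 3946),
    flip_grid=(82, 85, 87, 88, 89, 89, 89, 90, 90),
)


def reference_families() -> dict[str, ProtocolFamily]:
    """The two built-in 0.5 T EPI protocol families, keyed by name."""
    return {f.name: f for f in (FAMILY_3P4MM, FAMILY_4P0MM)}
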