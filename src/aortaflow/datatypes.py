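"""Core containers for velocity-encoded cine data and derived indices.

Conventions used throughout the package:

* arrays are ``(rows, cols, frames)``; row 0 is the image top, which is the
  12 o'clock direction of the vessel cross-section; columns increase to the
  right (3 o'clock);
* velocity is through-plane in cm/s with positive = forward (head-ward) flow;
* all geometry is physical — pixel spacing in mm, frame interval in ms —
  and no downstream operation accepts pixel-only coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np


@dataclass
class VelocityCine:
    """A 2D+t through-plane velocity stack of one vessel cross-section.

    Parameters
    ----------
    velocity:
        ``(rows, cols, frames)`` array in cm/s, positive = forward flow.
    pixel_spacing:
        ``(row_mm, col_mm)`` physical pixel size.
    frame_interval:
        time between cine phases, ms.
    venc:
        velocity-encoding limit in cm/s, metadata only; when present every
        stored speed must not exceed it (no aliased values).
    """

    velocity: np.ndarray
    pixel_spacing: tuple[float, float]
    frame_interval: float
    venc: Optional[float] = None

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim != 3:
            raise ValueError(
                f"velocity must be (rows, cols, frames); got shape {self.velocity.shape}"
            )
        r_mm, c_mm = self.pixel_spacing
        if r_mm <= 0 or c_mm <= 0:
            raise ValueError(f"pixel spacing must be positive; got {self.pixel_spacing}")
        if self.frame_interval <= 0:
            raise ValueError(f"frame_interval must be positive; got {self.frame_interval}")
        if self.venc is not None and np.abs(self.velocity).max() > self.venc + 1e-9:
            raise ValueError(
                f"|velocity| exceeds VENC={self.venc} cm/s "
                f"(max {np.abs(self.velocity).max():.3f})"
            )

    @property
    def frame_count(self) -> int:
        return self.velocity.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Frame mid-times in ms, frame 0 at t = 0."""
        return np.arange(self.frame_count) * self.frame_interval

    @property
    def pixel_area_cm2(self) -> float:
        r_mm, c_mm = self.pixel_spacing
        return (r_mm * c_mm) / 100.0


@dataclass
class MaskSeries:
    """Per-frame binary lumen masks on the same grid as the velocity cine."""

    mask: np.ndarray  # (rows, cols, frames), bool

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be (rows, cols, frames); got shape {self.mask.shape}")
        counts = self.mask.sum(axis=(0, 1))
        if (counts == 0).any():
            empty = int(np.argmax(counts == 0))
            raise ValueError(f"mask frame {empty} has no foreground pixel")

    @property
    def frame_count(self) -> int:
        return self.mask.shape[2]

    def frame(self, i: int) -> np.ndarray:
        return self.mask[:, :, i]


def check_grid_match(cine: VelocityCine, masks: MaskSeries) -> None:
    """Fail loudly when mask and velocity grids disagree."""
    if cine.velocity.shape != masks.mask.shape:
        raise ValueError(
            f"mask shape {masks.mask.shape} does not match velocity shape "
            f"{cine.velocity.shape}"
        )


@dataclass
class Centreline:
    """Ordered 3D polyline of the aortic path, mm."""

    points: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"centreline must be (n, 3); got shape {self.points.shape}")
        if self.points.shape[0] < 2:
            raise ValueError("centreline needs at least 2 points")
        seg = np.diff(self.points, axis=0)
        if (np.linalg.norm(seg, axis=1) == 0).any():
            raise ValueError("centreline has duplicate consecutive points")


@dataclass
class FlowCurve:
    """Per-frame flow rates over one cardiac cycle.

    ``backward_rate`` stores the magnitude of retrograde flow (>= 0);
    the net rate is ``forward_rate - backward_rate``.
    """

    time: np.ndarray  # ms
    forward_rate: np.ndarray  # mL/s, >= 0
    backward_rate: np.ndarray  # mL/s magnitude, >= 0
    frame_interval: float  # ms

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.forward_rate = np.asarray(self.forward_rate, dtype=float)
        self.backward_rate = np.asarray(self.backward_rate, dtype=float)
        n = len(self.time)
        if len(self.forward_rate) != n or len(self.backward_rate) != n:
            raise ValueError("time, forward_rate, backward_rate must have equal length")
        if (self.forward_rate < -1e-12).any() or (self.backward_rate < -1e-12).any():
            raise ValueError("rates are stored as non-negative magnitudes")

    @property
    def net_rate(self) -> np.ndarray:
        return self.forward_rate - self.backward_rate


@dataclass(frozen=True)
class SystolicWindow:
    """Inclusive frame-index range covering systole."""

    first_frame: int
    last_frame: int

    def __post_init__(self) -> None:
        if self.first_frame > self.last_frame:
            raise ValueError(
                f"empty systolic window [{self.first_frame}, {self.last_frame}]"
            )
        if self.first_frame < 0:
            raise ValueError("window starts before frame 0")

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.first_frame, self.last_frame + 1)

    def __len__(self) -> int:
        return self.last_frame - self.first_frame + 1


@dataclass
class AorticFlowIndices:
    """Per-subject scalar outputs of the quantification pipeline.

    Angles are degrees in (-180, 180] clockwise from 12 o'clock; the
    rotational angle is NaN when no systolic frame passes the flow-
    displacement gate. Any index may be NaN when undefined.
    """

    ao_forward_flow: float = np.nan  # mL per cycle
    ao_backward_flow: float = np.nan  # mL per cycle (magnitude)
    ao_forward_flow_indexed: float = np.nan  # mL/m^2
    ao_max_area: float = np.nan  # cm^2
    ao_min_area: float = np.nan  # cm^2
    fd_savg: float = np.nan  # percent
    rotational_angle: float = np.nan  # degrees
    systolic_forward_flow: float = np.nan  # mL
    systolic_retrograde_flow: float = np.nan  # mL
    sfrr: float = np.nan  # percent
    pwv: float = np.nan  # m/s

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: canonical column order for cohort index tables
INDEX_COLUMNS = [
    "ao_forward_flow",
    "ao_backward_flow",
    "ao_forward_flow_indexed",
    "ao_max_area",
    "ao_min_area",
    "fd_savg",
    "rotational_angle",
    "systolic_forward_flow",
    "systolic_retrograde_flow",
    "sfrr",
    "pwv",
]

#: canonical subject-level metadata columns preceding the indices
SUBJECT_COLUMNS = ["subject_id", "group", "sex", "age", "bsa"]
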