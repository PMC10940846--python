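"""Per-frame and per-cycle aortic flow indices from a velocity cine.

The quantities computed here are the standard 2D phase-contrast flow
metrics for an aortic cross-section:

* per-pixel forward/backward flow rates and their cycle/systolic volumes;
* flow displacement (FD): the distance from the lumen centroid to the
  velocity-weighted centre of forward flow, normalised to the effective
  lumen diameter ``2*sqrt(A/pi)`` and expressed in percent; ``fd_savg``
  is its unweighted mean over the systolic window;
* rotational angle (RA): the clockwise angle from 12 o'clock of the
  displacement vector, only defined on frames whose FD exceeds a gate
  (default 12%) because the direction of a near-zero vector is noise;
* systolic flow reversal ratio: retrograde over forward systolic volume
  in percent;
* lumen area extrema over the cycle.

Systole is detected as the maximal contiguous run of frames around the
net-flow peak whose net rate stays above a fraction (default 10%) of the
peak; volumes use rectangular rate x frame-interval integration to match
the discrete cine phases.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Optional

import numpy as np

from .datatypes import (
    AorticFlowIndices,
    FlowCurve,
    MaskSeries,
    SystolicWindow,
    VelocityCine,
    check_grid_match,
)


def frame_flow_rates(cine: VelocityCine, masks: MaskSeries) -> FlowCurve:
    """Forward/backward flow rate per frame (mL/s) from in-mask pixels.

    Forward rate sums all positive in-mask velocities times the pixel
    area; the backward rate is the magnitude of the same sum over
    negative velocities.
    """
    check_grid_match(cine, masks)
    v = np.where(masks.mask, cine.velocity, 0.0)
    area = cine.pixel_area_cm2  # cm^2; v in cm/s -> rate in cm^3/s = mL/s
    forward = np.maximum(v, 0.0).sum(axis=(0, 1)) * area
    backward = np.maximum(-v, 0.0).sum(axis=(0, 1)) * area
    return FlowCurve(
        time=cine.times,
        forward_rate=forward,
        backward_rate=backward,
        frame_interval=cine.frame_interval,
    )


def detect_systole(curve: FlowCurve, fraction: float = 0.10) -> SystolicWindow:
    """Contiguous frames around the net-rate peak above ``fraction*peak``."""
    net = curve.net_rate
    peak_idx = int(np.argmax(net))
    peak = net[peak_idx]
    if peak <= 0:
        raise ValueError("flow curve has no positive net-rate peak")
    thresh = fraction * peak
    above = net >= thresh
    first = peak_idx
    while first > 0 and above[first - 1]:
        first -= 1
    last = peak_idx
    while last < len(net) - 1 and above[last + 1]:
        last += 1
    return SystolicWindow(first, last)


class CycleVolumes(NamedTuple):
    ao_forward_flow: float  # mL, whole cycle
    ao_backward_flow: float  # mL, whole cycle (magnitude)
    systolic_forward_flow: float  # mL, systolic window
    systolic_retrograde_flow: float  # mL, systolic window (magnitude)


def cycle_volumes(curve: FlowCurve, window: SystolicWindow) -> CycleVolumes:
    """Rectangular-sum volumes (rate x frame interval), in mL."""
    dt_s = curve.frame_interval / 1000.0
    sel = slice(window.first_frame, window.last_frame + 1)
    return CycleVolumes(
        ao_forward_flow=float(curve.forward_rate.sum() * dt_s),
        ao_backward_flow=float(curve.backward_rate.sum() * dt_s),
        systolic_forward_flow=float(curve.forward_rate[sel].sum() * dt_s),
        systolic_retrograde_flow=float(curve.backward_rate[sel].sum() * dt_s),
    )


def sfrr(systolic_retrograde_flow: float, systolic_forward_flow: float) -> float:
    """Systolic flow reversal ratio: retrograde / forward x 100 (percent).

    Undefined (NaN, with a warning) when there is no systolic forward flow.
    """
    if systolic_forward_flow <= 0:
        warnings.warn("sFRR undefined: no systolic forward flow", stacklevel=2)
        return np.nan
    return 100.0 * systolic_retrograde_flow / systolic_forward_flow


def _pixel_coords_mm(shape: tuple[int, int], spacing: tuple[float, float]):
    rows = np.arange(shape[0]) * spacing[0]
    cols = np.arange(shape[1]) * spacing[1]
    return np.meshgrid(rows, cols, indexing="ij")


def mask_centroid(mask: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    """Area centroid of the lumen mask, (row_mm, col_mm)."""
    rr, cc = _pixel_coords_mm(mask.shape, spacing)
    m = mask.astype(bool)
    n = m.sum()
    if n == 0:
        raise ValueError("empty mask")
    return np.array([rr[m].mean(), cc[m].mean()])


def centre_of_velocity(
    velocity: np.ndarray, mask: np.ndarray, spacing: tuple[float, float]
) -> Optional[np.ndarray]:
    """Forward-flow velocity-weighted mean pixel location, (row_mm, col_mm).

    Only positive (forward) velocities carry weight; returns None when no
    in-mask pixel flows forward.
    """
    w = np.where(mask, np.maximum(velocity, 0.0), 0.0)
    total = w.sum()
    if total <= 0:
        return None
    rr, cc = _pixel_coords_mm(mask.shape, spacing)
    return np.array([(w * rr).sum() / total, (w * cc).sum() / total])


def effective_diameter_mm(mask: np.ndarray, spacing: tuple[float, float]) -> float:
    """Diameter of the circle with the mask's area: ``2*sqrt(A/pi)``."""
    area_mm2 = mask.sum() * spacing[0] * spacing[1]
    return 2.0 * np.sqrt(area_mm2 / np.pi)


def flow_displacement(
    velocity: np.ndarray, mask: np.ndarray, spacing: tuple[float, float]
) -> float:
    """Flow displacement of one frame, percent of effective diameter.

    NaN when the centre of velocity is undefined (no forward flow).
    """
    cov = centre_of_velocity(velocity, mask, spacing)
    if cov is None:
        return np.nan
    centroid = mask_centroid(mask, spacing)
    return 100.0 * float(np.linalg.norm(cov - centroid)) / effective_diameter_mm(mask, spacing)


def _wrap_angle(deg: float) -> float:
    """Map an angle in degrees onto (-180, 180].

    Values within floating-point noise of -180 are snapped to +180 so a
    jet pointing exactly at 6 o'clock reports 180, not -180 + epsilon.
    """
    wrapped = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped <= -180.0 + 1e-9 else wrapped


def rotational_angle(
    velocity: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float],
    fd_gate: float = 12.0,
) -> float:
    """Clockwise angle of the displacement vector from 12 o'clock, degrees.

    0 deg points to the image top, +90 to the right (3 o'clock), 180 down,
    -90 to the left. NaN whenever the frame's flow displacement is below
    ``fd_gate`` percent, where the vector direction is dominated by noise.
    """
    fd = flow_displacement(velocity, mask, spacing)
    if not np.isfinite(fd) or fd < fd_gate:
        return np.nan
    cov = centre_of_velocity(velocity, mask, spacing)
    centroid = mask_centroid(mask, spacing)
    d_row, d_col = cov - centroid
    # image up is -row; clockwise from up goes toward +col
    return _wrap_angle(float(np.degrees(np.arctan2(d_col, -d_row))))


def fd_systolic_average(fd_per_frame: np.ndarray, window: SystolicWindow) -> float:
    """Unweighted mean of defined per-frame FD values over the window."""
    vals = np.asarray(fd_per_frame, dtype=float)[window.first_frame : window.last_frame + 1]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return np.nan
    return float(vals.mean())


def ra_summary(ra_per_frame: np.ndarray, window: SystolicWindow) -> float:
    """Circular mean of the defined gated angles in the window, degrees.

    Angles are averaged as unit vectors so that e.g. +170 and -170 average
    to 180, not 0. NaN when no frame in the window has a defined angle.
    """
    vals = np.asarray(ra_per_frame, dtype=float)[window.first_frame : window.last_frame + 1]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return np.nan
    rad = np.radians(vals)
    return _wrap_angle(float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))))


def area_extrema(masks: MaskSeries, spacing: tuple[float, float]) -> tuple[float, float]:
    """(max, min) lumen cross-sectional area over the cycle, cm^2."""
    areas_cm2 = masks.mask.sum(axis=(0, 1)) * spacing[0] * spacing[1] / 100.0
    return float(areas_cm2.max()), float(areas_cm2.min())


def index_by_bsa(value: float, bsa: float) -> float:
    """Index a volume by body surface area (mL -> mL/m^2)."""
    if bsa is None or not np.isfinite(bsa):
        return np.nan
    if bsa <= 0:
        raise ValueError(f"BSA must be positive; got {bsa}")
    return value / bsa


def quantify_bundle(
    cine: VelocityCine,
    masks: MaskSeries,
    fd_gate: float = 12.0,
    systole_fraction: float = 0.10,
    bsa: Optional[float] = None,
):
    """Run the full per-subject quantification on one cine bundle.

    Returns ``(AorticFlowIndices, per_frame)`` where ``per_frame`` is a
    dict of per-frame diagnostic arrays (time_ms, forward/backward rates,
    fd_pct, ra_deg).
    """
    check_grid_match(cine, masks)
    curve = frame_flow_rates(cine, masks)
    window = detect_systole(curve, fraction=systole_fraction)
    vols = cycle_volumes(curve, window)

    n = cine.frame_count
    fd = np.full(n, np.nan)
    ra = np.full(n, np.nan)
    for f in range(n):
        fd[f] = flow_displacement(cine.velocity[:, :, f], masks.frame(f), cine.pixel_spacing)
        ra[f] = rotational_angle(
            cine.velocity[:, :, f], masks.frame(f), cine.pixel_spacing, fd_gate=fd_gate
        )

    max_area, min_area = area_extrema(masks, cine.pixel_spacing)
    indices = AorticFlowIndices(
        ao_forward_flow=vols.ao_forward_flow,
        ao_backward_flow=vols.ao_backward_flow,
        ao_forward_flow_indexed=(
            index_by_bsa(vols.ao_forward_flow, bsa) if bsa is not None else np.nan
        ),
        ao_max_area=max_area,
        ao_min_area=min_area,
        fd_savg=fd_systolic_average(fd, window),
        rotational_angle=ra_summary(ra, window),
        systolic_forward_flow=vols.systolic_forward_flow,
        systolic_retrograde_flow=vols.systolic_retrograde_flow,
        sfrr=sfrr(vols.systolic_retrograde_flow, vols.systolic_forward_flow),
    )
    per_frame = {
        "time_ms": curve.time,
        "forward_rate_ml_s": curve.forward_rate,
        "backward_rate_ml_s": curve.backward_rate,
        "net_rate_ml_s": curve.net_rate,
        "fd_pct": fd,
        "ra_deg": ra,
        "systole_first": window.first_frame,
        "systole_last": window.last_frame,
    }
    return indices, per_frame
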