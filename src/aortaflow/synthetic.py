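"""Synthetic velocity-encoded cine generator with analytically known truth.

The generator emulates a 2D phase-contrast acquisition of an aortic
cross-section: a circular lumen on a Cartesian grid, a spatially smooth
forward jet whose centre can be displaced off the lumen centre by a
controlled fraction of the diameter, an optional near-wall retrograde
crescent opposite the jet whose amplitude is tuned by bisection so the
noiseless systolic flow-reversal ratio hits a requested target, a
raised-cosine systolic envelope over a 30-phase cycle, and additive
Gaussian velocity noise.

Ground truth for every index is computed by running the package's own
flow-metric operators on the noiseless field, so recovery tests are
self-consistent by construction; the jet geometry additionally makes the
continuum values (FD = 100 x displacement_fraction, RA = jet direction)
known in closed form when the jet is fully contained in the lumen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datatypes import Centreline, MaskSeries, VelocityCine
from .flow_metrics import quantify_bundle
from .pwv import WaveformPair, arc_length


@dataclass
class JetSpec:
    """Parameters of one synthetic cine bundle.

    ``displacement_fraction`` is the jet-centre offset as a fraction of
    the lumen diameter; ``displacement_direction`` is degrees clockwise
    from 12 o'clock (image up). ``reversal_target`` is the intended
    sFRR/100 of the noiseless field.
    """

    lumen_radius: float = 16.0  # mm
    grid_size: int = 64  # pixels per side
    pixel_spacing: float = 1.0  # mm (isotropic)
    n_frames: int = 30
    frame_interval: float = 40.0  # ms
    peak_velocity: float = 100.0  # cm/s
    displacement_fraction: float = 0.0  # of lumen diameter, in [0, 0.4]
    displacement_direction: float = 0.0  # degrees clockwise from 12 o'clock
    reversal_target: float = 0.0  # sFRR/100, in [0, 0.3]
    noise_sigma: float = 0.0  # cm/s
    seed: int = 0
    systole_fraction_of_cycle: float = 0.35  # raised-cosine support
    jet_radius_fraction: float = 0.8  # jet radius / lumen radius
    area_pulsation: float = 0.0  # fractional radius increase at peak systole
    venc: float = 200.0  # cm/s

    def __post_init__(self) -> None:
        if self.n_frames < 8:
            raise ValueError(f"n_frames must be >= 8; got {self.n_frames}")
        if not 0.0 <= self.displacement_fraction <= 0.4:
            raise ValueError(
                f"displacement_fraction must be in [0, 0.4]; got {self.displacement_fraction}"
            )
        if not 0.0 <= self.reversal_target <= 0.3:
            raise ValueError(f"reversal_target must be in [0, 0.3]; got {self.reversal_target}")
        if self.peak_velocity >= self.venc:
            raise ValueError("peak_velocity must stay below the VENC (no aliasing generated)")
        half_extent = (self.grid_size - 1) / 2.0 * self.pixel_spacing
        max_radius = self.lumen_radius * (1.0 + self.area_pulsation)
        if half_extent - max_radius < 2.0 * self.pixel_spacing:
            raise ValueError(
                f"grid {self.grid_size} too small: lumen radius {max_radius:.1f} mm "
                f"needs a >= 2-pixel margin at {self.pixel_spacing} mm spacing"
            )


@dataclass
class SyntheticTruth:
    """Noiseless-field target values for recovery tests.

    Flow-index truths are defined by the pipeline's own operators applied
    to the noiseless field; PWV truths are analytic.
    """

    fd_true: float = np.nan  # percent
    sfrr_true: float = np.nan  # percent
    ra_true: float = np.nan  # degrees
    forward_volume_true: float = np.nan  # mL
    transit_time_true: float = np.nan  # ms
    centreline_length_true: float = np.nan  # mm
    pwv_true: float = np.nan  # m/s


class ReversalInfeasibleError(ValueError):
    """Raised when no crescent amplitude can reach the requested sFRR."""

    def __init__(self, target_pct: float, achieved_pct: float):
        self.target_pct = target_pct
        self.achieved_pct = achieved_pct
        super().__init__(
            f"cannot reach sFRR target {target_pct:.1f}%; "
            f"achievable maximum is {achieved_pct:.1f}%"
        )


def _grid_mm(n: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    rows = np.arange(n) * spacing
    cols = np.arange(n) * spacing
    return np.meshgrid(rows, cols, indexing="ij")


def _direction_vector(direction_deg: float) -> np.ndarray:
    """(row, col) unit vector for a clockwise-from-12-o'clock angle."""
    rad = np.radians(direction_deg)
    # image up (12 o'clock) is -row; clockwise rotates toward +col
    return np.array([-np.cos(rad), np.sin(rad)])


def _jet_profile(
    rr: np.ndarray,
    cc: np.ndarray,
    centre: np.ndarray,
    radius: float,
    core_fraction: float = 0.6,
) -> np.ndarray:
    """Blunt jet profile: flat plateau with a raised-cosine taper to zero.

    Systolic flow in the ascending aorta is plug-like, so the profile is 1
    out to ``core_fraction * radius`` and falls as cos^2 to 0 at ``radius``;
    smooth, unimodal, and radially symmetric about the jet centre.
    """
    d = np.hypot(rr - centre[0], cc - centre[1])
    core = core_fraction * radius
    taper = np.cos(np.pi * (d - core) / (2.0 * (radius - core))) ** 2
    return np.where(d <= core, 1.0, np.where(d < radius, taper, 0.0))


def _crescent_profile(
    rr: np.ndarray,
    cc: np.ndarray,
    lumen_centre: np.ndarray,
    lumen_radius: float,
    direction_deg: float,
) -> np.ndarray:
    """Near-wall retrograde region opposite the jet, weights in [0, 1].

    Smooth in both the radial coordinate (peaking near 0.8 of the lumen
    radius) and the angular distance from the anti-jet direction
    (support +/- 75 degrees).
    """
    d_row = rr - lumen_centre[0]
    d_col = cc - lumen_centre[1]
    r = np.hypot(d_row, d_col)
    radial = np.where(
        (r > 0.5 * lumen_radius) & (r < lumen_radius),
        np.sin(np.pi * (r - 0.5 * lumen_radius) / (0.5 * lumen_radius)) ** 2,
        0.0,
    )
    anti = _direction_vector(direction_deg + 180.0)
    angle = np.arctan2(d_col, -d_row)  # clockwise from 12 o'clock
    anti_angle = np.arctan2(anti[1], -anti[0])
    dtheta = np.angle(np.exp(1j * (angle - anti_angle)))
    half_width = np.radians(75.0)
    angular = np.where(
        np.abs(dtheta) < half_width, np.cos(np.pi * dtheta / (2.0 * half_width)) ** 2, 0.0
    )
    return radial * angular


def _systolic_envelope(spec: JetSpec) -> np.ndarray:
    """Raised-cosine systolic envelope per frame, zero in diastole."""
    t = np.arange(spec.n_frames) * spec.frame_interval
    cycle = spec.n_frames * spec.frame_interval
    t_sys = spec.systole_fraction_of_cycle * cycle
    env = np.where(t < t_sys, np.sin(np.pi * t / t_sys) ** 2, 0.0)
    return env


def _noiseless_field(spec: JetSpec, crescent_amp: float) -> tuple[np.ndarray, np.ndarray]:
    """Build the (rows, cols, frames) noiseless velocity stack and masks."""
    n = spec.grid_size
    rr, cc = _grid_mm(n, spec.pixel_spacing)
    lumen_centre = np.array([(n - 1) / 2.0, (n - 1) / 2.0]) * spec.pixel_spacing
    offset = spec.displacement_fraction * 2.0 * spec.lumen_radius
    jet_centre = lumen_centre + offset * _direction_vector(spec.displacement_direction)
    jet = _jet_profile(rr, cc, jet_centre, spec.jet_radius_fraction * spec.lumen_radius)
    crescent = _crescent_profile(
        rr, cc, lumen_centre, spec.lumen_radius, spec.displacement_direction
    )
    spatial = spec.peak_velocity * jet - crescent_amp * crescent

    env = _systolic_envelope(spec)
    dist = np.hypot(rr - lumen_centre[0], cc - lumen_centre[1])
    if spec.area_pulsation > 0:
        radius_t = spec.lumen_radius * (1.0 + spec.area_pulsation * env)
        mask = dist[:, :, None] <= radius_t[None, None, :]
    else:
        mask = np.broadcast_to(
            (dist <= spec.lumen_radius)[:, :, None], (n, n, spec.n_frames)
        ).copy()
    velocity = spatial[:, :, None] * env[None, None, :]
    velocity = np.where(mask, velocity, 0.0)
    return velocity, mask


def _noiseless_sfrr(spec: JetSpec, crescent_amp: float) -> float:
    velocity, mask = _noiseless_field(spec, crescent_amp)
    cine = VelocityCine(
        velocity, (spec.pixel_spacing, spec.pixel_spacing), spec.frame_interval, venc=spec.venc
    )
    try:
        indices, _ = quantify_bundle(cine, MaskSeries(mask))
    except ValueError:
        # reversal so strong the net-flow peak vanishes: beyond any target
        return np.inf
    return indices.sfrr


def _solve_crescent_amplitude(spec: JetSpec, tol_pp: float = 0.1) -> float:
    """Bisection on the crescent amplitude to hit the sFRR target.

    sFRR is monotone increasing in the amplitude (forward volume can only
    shrink, retrograde volume grow), so bisection on [0, amp_max] is
    exact; amplitudes beyond ~2x the jet peak tip the net flow negative
    and the target is declared infeasible.
    """
    target_pct = 100.0 * spec.reversal_target
    if target_pct == 0.0:
        return 0.0
    lo, hi = 0.0, 2.0 * spec.peak_velocity
    sfrr_hi = _noiseless_sfrr(spec, hi)
    if np.isfinite(sfrr_hi) and sfrr_hi < target_pct:
        raise ReversalInfeasibleError(target_pct, sfrr_hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        val = _noiseless_sfrr(spec, mid)
        if abs(val - target_pct) < tol_pp / 4.0:
            return mid
        if val < target_pct:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_velocity_cine(spec: JetSpec) -> tuple[VelocityCine, MaskSeries, SyntheticTruth]:
    """Generate one synthetic cine bundle with stored noiseless truth.

    Returns the (noisy, when ``noise_sigma > 0``) cine, its mask series,
    and the truth block computed on the noiseless field with the
    package's own metric definitions.
    """
    amp = _solve_crescent_amplitude(spec)
    velocity, mask = _noiseless_field(spec, amp)
    masks = MaskSeries(mask)
    clean = VelocityCine(
        velocity, (spec.pixel_spacing, spec.pixel_spacing), spec.frame_interval, venc=spec.venc
    )
    indices, _ = quantify_bundle(clean, masks)
    # truth RA is the ungated jet direction: the 12% gate belongs to the
    # estimator, where near-zero displacement makes the angle noise-driven;
    # on the noiseless field the direction is exact at any displacement
    ungated, _ = quantify_bundle(clean, masks, fd_gate=0.0)
    ra_true = np.nan if spec.displacement_fraction == 0 else ungated.rotational_angle
    truth = SyntheticTruth(
        fd_true=indices.fd_savg,
        sfrr_true=indices.sfrr,
        ra_true=ra_true,
        forward_volume_true=indices.ao_forward_flow,
    )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = velocity + rng.normal(0.0, spec.noise_sigma, size=velocity.shape)
        noisy = np.clip(noisy, -spec.venc, spec.venc)
        cine = VelocityCine(
            noisy, (spec.pixel_spacing, spec.pixel_spacing), spec.frame_interval, venc=spec.venc
        )
    else:
        cine = clean
    return cine, masks, truth


def raised_cosine_pulse(t: np.ndarray, onset_ms: float, upstroke_ms: float, peak: float):
    """Analytic raised-cosine flow pulse: 0 before onset, peak at
    onset + upstroke, back to 0 at onset + 2*upstroke."""
    phase = (np.asarray(t, dtype=float) - onset_ms) / (2.0 * upstroke_ms)
    return np.where((phase >= 0) & (phase <= 1), peak * np.sin(np.pi * phase) ** 2, 0.0)


def make_pwv_pair(
    delay: float,
    centreline: Centreline,
    sampling_interval: float = 40.0,
    cycle_length: float = 1200.0,
    upstroke: float = 100.0,
    peak: float = 100.0,
    attenuation: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[WaveformPair, SyntheticTruth]:
    """Delayed ascending/descending waveform pair with analytic truth.

    The descending waveform is the ascending one shifted by ``delay`` ms
    (evaluated analytically, then sampled) and optionally attenuated, so
    the true transit time is exactly ``delay`` and the true PWV is the
    centreline arc length over the delay.
    """
    if delay <= 0:
        raise ValueError(f"delay must be positive; got {delay}")
    onset = sampling_interval  # keep the first sample below half-max
    if onset + delay + 2.0 * upstroke >= cycle_length:
        raise ValueError(
            f"delay {delay} ms not representable: pulse would leave the "
            f"{cycle_length} ms cycle"
        )
    t = np.arange(0.0, cycle_length, sampling_interval)
    asc = raised_cosine_pulse(t, onset, upstroke, peak)
    desc = attenuation * raised_cosine_pulse(t, onset + delay, upstroke, peak)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        asc = asc + rng.normal(0.0, noise_sigma, size=asc.shape)
        desc = desc + rng.normal(0.0, noise_sigma, size=desc.shape)
    pair = WaveformPair(time=t, ascending=asc, descending=desc)
    length = arc_length(centreline)
    truth = SyntheticTruth(
        transit_time_true=delay,
        centreline_length_true=length,
        pwv_true=length / delay,  # mm/ms == m/s
    )
    return pair, truth


@dataclass
class GroupSpec:
    """One cohort group: log-normal (median, IQR) per index."""

    name: str
    n_subjects: int
    indices: dict[str, tuple[float, float]]  # name -> (median, iqr)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"group '{self.name}' needs n_subjects >= 2; got {self.n_subjects}")
        for key, (med, iqr) in self.indices.items():
            if med <= 0 or iqr <= 0:
                raise ValueError(
                    f"group '{self.name}', index '{key}': median and IQR must be positive"
                )


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    seed: int = 0
    age_by_group: Optional[dict[str, tuple[float, float]]] = None  # mean, sd


def lognormal_sigma(median: float, iqr: float) -> float:
    """Log-sd of a log-normal with the given median and IQR.

    For X ~ LogNormal(mu, sigma), IQR = median * 2*sinh(z75*sigma) with
    z75 = 0.6744898 the 75th normal percentile, inverted in closed form.
    """
    z75 = 0.6744897501960817
    return float(np.arcsinh(iqr / (2.0 * median)) / z75)


def make_cohort(spec: CohortSpec) -> "pandas.DataFrame":
    """Subject-level index table with group labels, reproducible by seed.

    Index values are drawn from log-normal distributions (non-negative
    and right-skewed, matching the shape of real flow-index cohorts)
    parameterised by their median and IQR.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for group in spec.groups:
        age_mean, age_sd = (spec.age_by_group or {}).get(group.name, (55.0, 10.0))
        for _ in range(group.n_subjects):
            row = {
                "subject_id": f"S{sid:03d}",
                "group": group.name,
                "sex": "F" if rng.random() < 0.5 else "M",
                "age": float(np.round(rng.normal(age_mean, age_sd), 1)),
                "bsa": float(np.round(rng.normal(1.9, 0.2), 3)),
            }
            for key, (med, iqr) in group.indices.items():
                sigma = lognormal_sigma(med, iqr)
                row[key] = float(med * np.exp(sigma * rng.standard_normal()))
            rows.append(row)
            sid += 1
    return pd.DataFrame(rows)
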