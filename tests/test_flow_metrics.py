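"""Unit and property tests for the per-frame/per-cycle flow metrics."""

import numpy as np
import pytest

from aortaflow import JetSpec, MaskSeries, SystolicWindow, VelocityCine, make_velocity_cine
from aortaflow.flow_metrics import (
    area_extrema,
    centre_of_velocity,
    cycle_volumes,
    detect_systole,
    effective_diameter_mm,
    fd_systolic_average,
    flow_displacement,
    frame_flow_rates,
    index_by_bsa,
    mask_centroid,
    quantify_bundle,
    ra_summary,
    rotational_angle,
    sfrr,
)
from conftest import random_field


def uniform_bundle(value: float, n_pixels: int = 100):
    """n_pixels-pixel square mask at 1 mm x 1 mm, uniform velocity."""
    side = int(np.sqrt(n_pixels))
    v = np.zeros((side + 4, side + 4, 3))
    m = np.zeros_like(v, dtype=bool)
    m[2 : 2 + side, 2 : 2 + side, :] = True
    v[m] = value
    return VelocityCine(v, (1.0, 1.0), 40.0), MaskSeries(m)


class TestFrameFlowRates:
    def test_uniform_forward(self):
        cine, masks = uniform_bundle(+50.0)
        curve = frame_flow_rates(cine, masks)
        # 100 px x 0.01 cm^2 x 50 cm/s = 50 mL/s
        assert curve.forward_rate == pytest.approx([50.0] * 3)
        assert curve.backward_rate == pytest.approx([0.0] * 3)

    def test_uniform_backward(self):
        cine, masks = uniform_bundle(-20.0)
        curve = frame_flow_rates(cine, masks)
        assert curve.forward_rate == pytest.approx([0.0] * 3)
        assert curve.backward_rate == pytest.approx([20.0] * 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pixel_loop_oracle(self, seed):
        cine, masks = random_field(np.random.default_rng(seed))
        curve = frame_flow_rates(cine, masks)
        area = cine.pixel_area_cm2
        for f in range(cine.frame_count):
            fwd = bwd = 0.0
            for i in range(cine.velocity.shape[0]):
                for j in range(cine.velocity.shape[1]):
                    if masks.mask[i, j, f]:
                        v = cine.velocity[i, j, f]
                        fwd += max(v, 0.0) * area
                        bwd += max(-v, 0.0) * area
            assert curve.forward_rate[f] == pytest.approx(fwd, abs=1e-12)
            assert curve.backward_rate[f] == pytest.approx(bwd, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        cine, _ = uniform_bundle(10.0)
        bad = MaskSeries(np.ones((5, 5, 2), dtype=bool))
        with pytest.raises(ValueError, match="does not match"):
            frame_flow_rates(cine, bad)


class TestDetectSystole:
    def make_curve(self, net):
        net = np.asarray(net, dtype=float)
        fwd = np.maximum(net, 0.0)
        bwd = np.maximum(-net, 0.0)
        from aortaflow.datatypes import FlowCurve

        return FlowCurve(np.arange(len(net)) * 40.0, fwd, bwd, 40.0)

    def test_run_around_peak(self):
        curve = self.make_curve([0, 0, 30, 100, 60, 5, 0, 0])
        w = detect_systole(curve, fraction=0.10)
        assert (w.first_frame, w.last_frame) == (2, 4)

    def test_constant_curve_spans_cycle(self):
        curve = self.make_curve([10.0] * 8)
        w = detect_systole(curve)
        assert (w.first_frame, w.last_frame) == (0, 7)

    def test_raised_cosine_matches_analytic_support(self):
        t = np.arange(30) * 40.0
        t_sys = 400.0
        net = np.where(t < t_sys, np.sin(np.pi * t / t_sys) ** 2, 0.0) * 100
        curve = self.make_curve(net)
        w = detect_systole(curve, fraction=0.10)
        # analytic support of sin^2(pi t/T) >= 0.1: t/T in [0.1024, 0.8976]
        first_true = np.searchsorted(t, 0.1024 * t_sys)
        last_true = np.searchsorted(t, 0.8976 * t_sys, side="right") - 1
        assert abs(w.first_frame - first_true) <= 1
        assert abs(w.last_frame - last_true) <= 1

    def test_no_positive_peak_rejected(self):
        curve = self.make_curve([-5.0, -1.0, -2.0, 0.0, -4.0, -1.0, -1.0, -3.0])
        with pytest.raises(ValueError, match="no positive net-rate peak"):
            detect_systole(curve)


class TestCycleVolumes:
    def test_constant_window(self):
        from aortaflow.datatypes import FlowCurve

        # 50 mL/s over 300 ms window -> 15 mL
        curve = FlowCurve(np.arange(10) * 100.0, np.full(10, 50.0), np.zeros(10), 100.0)
        vols = cycle_volumes(curve, SystolicWindow(2, 4))
        assert vols.systolic_forward_flow == pytest.approx(15.0)
        assert vols.ao_forward_flow == pytest.approx(50.0)
        assert vols.systolic_retrograde_flow == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_rectangular_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cine, masks = random_field(rng)
        curve = frame_flow_rates(cine, masks)
        w = SystolicWindow(1, 4)
        vols = cycle_volumes(curve, w)
        dt = cine.frame_interval / 1000.0
        assert vols.ao_forward_flow == pytest.approx(sum(curve.forward_rate) * dt)
        assert vols.systolic_retrograde_flow == pytest.approx(
            sum(curve.backward_rate[1:5]) * dt
        )


class TestSfrr:
    def test_ratio(self):
        assert sfrr(4.0, 80.0) == pytest.approx(5.0)

    def test_zero_retrograde(self):
        assert sfrr(0.0, 80.0) == 0.0

    def test_zero_forward_is_missing_with_warning(self):
        with pytest.warns(UserWarning, match="sFRR undefined"):
            assert np.isnan(sfrr(1.0, 0.0))


class TestCentreOfVelocity:
    def test_uniform_disk_gives_centroid(self, centred_bundle):
        cine, masks, _ = centred_bundle
        f = 5  # mid-systole
        mask = masks.frame(f)
        uniform = np.where(mask, 30.0, 0.0)
        cov = centre_of_velocity(uniform, mask, cine.pixel_spacing)
        assert cov == pytest.approx(mask_centroid(mask, cine.pixel_spacing), abs=1e-9)

    def test_two_pixel_weighted_mean(self):
        v = np.zeros((1, 3))
        v[0, 0], v[0, 2] = 1.0, 3.0
        mask = np.ones((1, 3), dtype=bool)
        cov = centre_of_velocity(v, mask, (1.0, 1.0))
        assert cov[1] == pytest.approx(1.5)  # (0*1 + 2*3)/4 mm

    def test_negative_pixels_carry_no_weight(self):
        v = np.array([[2.0, -50.0, 2.0]])
        mask = np.ones((1, 3), dtype=bool)
        cov = centre_of_velocity(v, mask, (1.0, 1.0))
        assert cov[1] == pytest.approx(1.0)

    def test_no_forward_flow_undefined(self):
        v = -np.ones((4, 4))
        mask = np.ones((4, 4), dtype=bool)
        assert centre_of_velocity(v, mask, (1.0, 1.0)) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_weighted_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cine, masks = random_field(rng)
        v, m = cine.velocity[:, :, 0], masks.frame(0)
        cov = centre_of_velocity(v, m, cine.pixel_spacing)
        num = np.zeros(2)
        den = 0.0
        for i in range(v.shape[0]):
            for j in range(v.shape[1]):
                if m[i, j] and v[i, j] > 0:
                    w = v[i, j]
                    num += w * np.array([i * 1.2, j * 0.8])
                    den += w
        assert cov == pytest.approx(num / den, abs=1e-12)


class TestFlowDisplacement:
    def test_centred_jet_zero(self, centred_bundle):
        cine, masks, truth = centred_bundle
        assert truth.fd_true == pytest.approx(0.0, abs=1e-9)

    def test_definition_arithmetic(self):
        # single forward pixel at known distance from the mask centroid:
        # FD = 100 * distance / effective diameter
        n = 41
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        mask = np.hypot(rr - 20, cc - 20) <= 10.0
        v = np.zeros((n, n))
        v[20, 22] = 80.0  # 2 mm to the right of the centroid
        fd = flow_displacement(v, mask, (1.0, 1.0))
        d_eff = effective_diameter_mm(mask, (1.0, 1.0))
        centroid = mask_centroid(mask, (1.0, 1.0))
        dist = np.hypot(20.0 - centroid[0], 22.0 - centroid[1])
        assert fd == pytest.approx(100.0 * dist / d_eff)

    def test_noiseless_bundle_matches_truth(self, eccentric_bundle):
        cine, masks, truth = eccentric_bundle
        indices, _ = quantify_bundle(cine, masks)
        assert indices.fd_savg == pytest.approx(truth.fd_true, abs=1e-6)


class TestFdSystolicAverage:
    def test_constant(self):
        assert fd_systolic_average(np.full(10, 12.0), SystolicWindow(3, 7)) == 12.0

    def test_two_frame_mean(self):
        fd = np.array([np.nan, 10.0, 20.0, np.nan])
        assert fd_systolic_average(fd, SystolicWindow(1, 2)) == pytest.approx(15.0)

    def test_undefined_frames_drop_out(self):
        fd = np.array([np.nan, 10.0, np.nan, 20.0, np.nan])
        assert fd_systolic_average(fd, SystolicWindow(0, 4)) == pytest.approx(15.0)

    def test_all_undefined_missing(self):
        assert np.isnan(fd_systolic_average(np.full(5, np.nan), SystolicWindow(0, 4)))


def displaced_frame(direction_deg: float, fraction: float = 0.2):
    """One noiseless frame displaced toward the given clock direction."""
    cine, masks, _ = make_velocity_cine(
        JetSpec(displacement_fraction=fraction, displacement_direction=direction_deg)
    )
    f = 5
    return cine.velocity[:, :, f], masks.frame(f), cine.pixel_spacing


class TestRotationalAngle:
    @pytest.mark.parametrize(
        "direction, expected",
        [(0.0, 0.0), (90.0, 90.0), (180.0, 180.0), (-90.0, -90.0)],
        ids=["12oclock", "3oclock", "6oclock", "9oclock"],
    )
    def test_clock_conventions(self, direction, expected):
        v, m, spacing = displaced_frame(direction)
        ra = rotational_angle(v, m, spacing, fd_gate=12.0)
        assert ra == pytest.approx(expected, abs=1e-6)

    def test_below_gate_undefined(self):
        v, m, spacing = displaced_frame(90.0, fraction=0.05)  # FD ~ 5% < 12%
        assert np.isnan(rotational_angle(v, m, spacing, fd_gate=12.0))
        assert rotational_angle(v, m, spacing, fd_gate=0.0) == pytest.approx(90.0, abs=1e-6)


class TestRaSummary:
    def test_constant(self):
        assert ra_summary(np.full(6, 90.0), SystolicWindow(0, 5)) == pytest.approx(90.0)

    def test_circular_mean_wraps(self):
        ra = np.array([170.0, -170.0])
        assert ra_summary(ra, SystolicWindow(0, 1)) == pytest.approx(180.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_resultant_vector_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ra = rng.uniform(-180.0, 180.0, size=8)
        got = ra_summary(ra, SystolicWindow(0, 7))
        rad = np.radians(ra)
        expect = np.degrees(np.arctan2(np.sin(rad).sum(), np.cos(rad).sum()))
        assert got == pytest.approx(expect, abs=1e-9)

    def test_no_defined_angles_missing(self):
        assert np.isnan(ra_summary(np.full(6, np.nan), SystolicWindow(0, 5)))


class TestAreaExtrema:
    def test_constant_mask(self):
        m = np.zeros((40, 40, 3), dtype=bool)
        m[:35, :20, :] = True  # 700 px
        assert area_extrema(MaskSeries(m), (1.0, 1.0)) == pytest.approx((7.0, 7.0))

    def test_varying_mask(self):
        m = np.zeros((40, 40, 3), dtype=bool)
        for f, npx in enumerate([700, 800, 900]):
            m.reshape(-1, 3)[:npx, f] = True
        mx, mn = area_extrema(MaskSeries(m), (1.0, 1.0))
        assert (mx, mn) == pytest.approx((9.0, 7.0))

    def test_pulsatile_lumen_matches_schedule(self):
        spec = JetSpec(area_pulsation=0.1)
        cine, masks, _ = make_velocity_cine(spec)
        mx, mn = area_extrema(masks, cine.pixel_spacing)
        assert mx > mn
        # diastolic radius is the baseline lumen radius
        base_px = masks.mask[:, :, -1].sum()
        assert mn == pytest.approx(base_px * cine.pixel_area_cm2)


class TestIndexByBsa:
    def test_basic(self):
        assert index_by_bsa(70.0, 2.0) == 35.0

    def test_zero_bsa_rejected(self):
        with pytest.raises(ValueError, match="BSA"):
            index_by_bsa(70.0, 0.0)

    def test_round_trip(self):
        assert index_by_bsa(42.0 * 1.7, 1.7) == pytest.approx(42.0)


class TestInvariances:
    def test_scale_invariance(self, eccentric_bundle):
        """Multiplying velocities by k leaves FD/RA/sFRR fixed, scales flows."""
        cine, masks, _ = eccentric_bundle
        base, _ = quantify_bundle(cine, masks)
        k = 1.7
        scaled = VelocityCine(
            cine.velocity * k, cine.pixel_spacing, cine.frame_interval
        )
        got, _ = quantify_bundle(scaled, masks)
        assert got.fd_savg == pytest.approx(base.fd_savg, abs=1e-9)
        assert got.rotational_angle == pytest.approx(base.rotational_angle, abs=1e-9)
        assert got.sfrr == pytest.approx(base.sfrr, abs=1e-9)
        assert got.ao_forward_flow == pytest.approx(k * base.ao_forward_flow)
        assert got.systolic_retrograde_flow == pytest.approx(
            k * base.systolic_retrograde_flow
        )

    def test_rotation_equivariance(self, eccentric_bundle):
        """Rotating the field 90 degrees clockwise adds 90 to RA, keeps FD."""
        cine, masks, _ = eccentric_bundle
        base, _ = quantify_bundle(cine, masks)
        # np.rot90 with k=-1 rotates the image clockwise
        v_rot = np.stack(
            [np.rot90(cine.velocity[:, :, f], k=-1) for f in range(cine.frame_count)],
            axis=2,
        )
        m_rot = np.stack(
            [np.rot90(masks.frame(f), k=-1) for f in range(masks.frame_count)], axis=2
        )
        rot, _ = quantify_bundle(
            VelocityCine(v_rot, cine.pixel_spacing, cine.frame_interval), MaskSeries(m_rot)
        )
        assert rot.fd_savg == pytest.approx(base.fd_savg, abs=1e-6)
        expect = (base.rotational_angle + 90.0 + 180.0) % 360.0 - 180.0
        if expect == -180.0:
            expect = 180.0
        assert rot.rotational_angle == pytest.approx(expect, abs=1e-6)

    def test_grid_refinement_stability(self):
        """The same physical field at 2x resolution moves FD and sFRR < 0.5 pp."""
        coarse = JetSpec(
            grid_size=64, pixel_spacing=1.0,
            displacement_fraction=0.15, reversal_target=0.10,
        )
        fine = JetSpec(
            grid_size=128, pixel_spacing=0.5,
            displacement_fraction=0.15, reversal_target=0.10,
        )
        _, _, t_coarse = make_velocity_cine(coarse)
        _, _, t_fine = make_velocity_cine(fine)
        assert abs(t_coarse.fd_true - t_fine.fd_true) < 0.5
        assert abs(t_coarse.sfrr_true - t_fine.sfrr_true) < 0.5
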