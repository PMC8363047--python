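"""Eddy-current and nanoparticle sources, pulse schedules, compliance."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mnph
from mnph import (CLINICAL_HF_LIMIT, AMFExposure, BodyModel, MIONLoading,
                  Region, SLPModel, build_default_body, compliance_check,
                  eddy_field, power_factor, q_eddy, q_p_field,
                  region_volume, schedule_from_duty, voxelize, water_like)

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


@pytest.fixture(scope="module")
def torso():
    body = mnph.effective_body(build_default_body(0.02), 0.004)
    grid = voxelize(body, 0.004, merge_superficial=False)
    return body, grid



class TestQEddy:
    def test_hand_evaluated_value(self):
        # (sigma/2)(pi mu0 r f H)^2 at sigma=0.5, r=0.1 m, f=155 kHz,
        # H=3.03 kA/m
        assert q_eddy(0.5, 0.1, 1.55e5, 3.03e3) == pytest.approx(
            8594.26, rel=1e-4)

    def test_zeros(self):
        assert q_eddy(0.5, 0.1, 1.55e5, 0.0) == 0.0
        assert q_eddy(0.5, 0.0, 1.55e5, 3e3) == 0.0

    @given(sigma=positive, r=positive, f=positive, H=positive,
           a=st.floats(min_value=0.1, max_value=10.0))
    def test_quadratic_scaling_laws(self, sigma, r, f, H, a):
        base = q_eddy(sigma, r, f, H)
        for scaled in (q_eddy(sigma, a * r, f, H),
                       q_eddy(sigma, r, a * f, H),
                       q_eddy(sigma, r, f, a * H)):
            assert scaled == pytest.approx(a ** 2 * base, rel=1e-9)
        assert q_eddy(a * sigma, r, f, H) == pytest.approx(a * base,
                                                           rel=1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            q_eddy(-0.1, 0.1, 1e5, 1e3)


class TestEddyField:
    def test_zero_amplitude_gives_zero_field(self, torso):
        body, grid = torso
        q = eddy_field(grid, body, AMFExposure(0.0, 155e3))
        assert np.all(q == 0.0)

    def test_max_in_outermost_shell_for_uniform_sigma(self):
        body = BodyModel(regions=(
            Region("muscle", "cylinder", 0.1, (0.0, 0.0, 0.0),
                   water_like("muscle", electrical_conductivity=0.36),
                   precedence=0, axis="y", height=0.2),))
        grid = voxelize(body, 0.005)
        q = eddy_field(grid, body, AMFExposure(3e3, 155e3))
        xs, zs = grid.axis_centers(0), grid.axis_centers(2)
        r = np.sqrt(xs[:, None, None] ** 2 + zs[None, None, :] ** 2)
        r = np.broadcast_to(r, grid.shape)
        inside = grid.labels >= 0
        assert r[inside][np.argmax(q[inside])] == pytest.approx(
            r[inside].max())

    def test_central_tumor_sees_less_than_peripheral_pancreas(self, torso):
        # same electrical conductivity, but the tumor sits on the coil axis
        body, grid = torso
        q = eddy_field(grid, body, AMFExposure(3e3, 155e3))
        tumor = grid.region_mask("tumor") | grid.region_mask("mion")
        assert q[tumor].max() < q[grid.region_mask("pancreas")].max()


class TestSLPAndQp:
    def test_default_model_monotone_through_origin(self):
        slp = SLPModel.default()
        assert slp(0.0) == 0.0
        H = np.linspace(*slp.valid_range, 64)
        assert np.all(np.diff(slp.evaluate(H)) >= 0)

    def test_out_of_range_raises(self):
        slp = SLPModel.default()
        with pytest.raises(ValueError):
            slp.evaluate(slp.valid_range[1] * 1.01)

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            SLPModel(coefficients=(1.0, 0.0))       # SLP(0) != 0
        with pytest.raises(ValueError):
            SLPModel(coefficients=(0.0, -1e-3))     # decreasing

    def test_power_conservation_any_spacing(self, torso):
        _, grid = torso
        slp = SLPModel.default()
        exposure = AMFExposure(3e3, 155e3)
        loading = MIONLoading.for_tumor_radius(5.0, 0.02)
        q = q_p_field(grid, loading, slp, exposure)
        total = q.sum() * grid.voxel_volume
        expected = slp(3e3) * loading.total_fe_mg / 1000.0
        assert total == pytest.approx(expected, rel=1e-12)

    def test_smaller_fill_region_concentrates_power(self, torso):
        _, grid = torso
        slp = SLPModel.default()
        exposure = AMFExposure(3e3, 155e3)
        dose = MIONLoading.for_tumor_radius(5.0, 0.02)
        in_core = q_p_field(grid, dose, slp, exposure)
        whole = MIONLoading(dose.dose_density, dose.tumor_volume_cm3,
                            fill_region="tumor")
        in_shell = q_p_field(grid, whole, slp, exposure)
        # local rate scales inversely with fill volume ...
        assert in_core.max() > in_shell.max()
        ratio = region_volume(grid, "tumor") / region_volume(grid, "mion")
        assert in_core.max() / in_shell.max() == pytest.approx(ratio,
                                                               rel=1e-9)
        # ... but the total deposited power is conserved
        assert (in_core.sum() * grid.voxel_volume ==
                pytest.approx(in_shell.sum() * grid.voxel_volume, rel=1e-12))

    def test_zero_dose_zero_field(self, torso):
        _, grid = torso
        q = q_p_field(grid, MIONLoading(0.0, 33.5), SLPModel.default(),
                      AMFExposure(3e3, 155e3))
        assert np.all(q == 0.0)

    def test_total_fe_scales_with_volume(self):
        small = MIONLoading.for_tumor_radius(5.0, 0.01)
        large = MIONLoading.for_tumor_radius(5.0, 0.02)
        assert large.total_fe_mg == pytest.approx(8 * small.total_fe_mg)
        assert large.total_fe_mg == pytest.approx(5.0 * 33.5103, rel=1e-4)


class TestSchedule:
    def test_fifty_percent_symmetric_blocks(self):
        s = schedule_from_duty(50.0, on_block_s=30.0, total_on_s=1200.0)
        assert s.off_block_s == pytest.approx(30.0)

    def test_continuous_duty(self):
        s = schedule_from_duty(100.0, on_block_s=60.0, total_on_s=1200.0)
        assert s.off_block_s == 0.0
        assert s.elapsed_s == pytest.approx(1200.0)

    def test_quarter_duty_quadruples_elapsed_time(self):
        s = schedule_from_duty(25.0, on_block_s=600.0, total_on_s=1200.0)
        assert s.elapsed_s == pytest.approx(4800.0)

    @pytest.mark.parametrize("duty", [0.0, -5.0, 101.0])
    def test_invalid_duty(self, duty):
        with pytest.raises(ValueError):
            schedule_from_duty(duty, on_block_s=30.0, total_on_s=300.0)

    def test_on_time_must_tile_into_blocks(self):
        with pytest.raises(ValueError):
            schedule_from_duty(50.0, on_block_s=700.0, total_on_s=1200.0)

    @pytest.mark.parametrize("duty", [100.0, 50.0, 100.0 / 3.0, 25.0])
    def test_duty_roundtrip_from_blocks(self, duty):
        s = schedule_from_duty(duty, on_block_s=30.0, total_on_s=300.0)
        recon = 100.0 * s.on_block_s / (s.on_block_s + s.off_block_s)
        assert recon == pytest.approx(duty, rel=1e-3)

    def test_power_factor_phases(self):
        s = schedule_from_duty(50.0, on_block_s=30.0, total_on_s=300.0)
        assert power_factor(15.0, s) == 1.0
        assert power_factor(45.0, s) == 0.0
        always_on = schedule_from_duty(100.0, 30.0, 300.0)
        assert np.all(power_factor(np.linspace(0, 600, 101), always_on) == 1)

    @pytest.mark.parametrize("duty", [100.0, 50.0, 100.0 / 3.0, 25.0])
    def test_power_factor_time_average_equals_duty(self, duty):
        s = schedule_from_duty(duty, on_block_s=30.0, total_on_s=300.0)
        dt = 0.5  # divides both blocks for all tested duties
        t = np.arange(0, s.period_s, dt)
        avg = power_factor(t, s).mean()
        assert avg == pytest.approx(duty / 100.0, rel=1e-9)

    @pytest.mark.parametrize("duty", [100.0, 50.0, 100.0 / 3.0, 25.0])
    def test_cumulative_on_time_is_duty_invariant(self, duty):
        s = schedule_from_duty(duty, on_block_s=600.0, total_on_s=1200.0)
        dt = 1.0
        t = np.arange(0, s.elapsed_s, dt)
        assert power_factor(t, s).sum() * dt == pytest.approx(1200.0)


class TestCompliance:
    def test_zero_field_full_margin(self):
        res = compliance_check(0.0, 155e3)
        assert res.passed and res.margin == CLINICAL_HF_LIMIT

    def test_exactly_at_limit_fails(self):
        H = CLINICAL_HF_LIMIT / 1.55e5
        res = compliance_check(H, 1.55e5)
        assert res.product == pytest.approx(CLINICAL_HF_LIMIT)
        assert not res.passed  # strict inequality

    def test_limit_amplitude_at_155khz(self):
        assert CLINICAL_HF_LIMIT / 1.55e5 == pytest.approx(3.13e3, rel=5e-3)


class TestAmplitudeConvention:
    def test_peak_to_peak_is_halved(self):
        exp = AMFExposure.from_peak_to_peak(18e3, 160e3)
        assert exp.amplitude_peak == pytest.approx(9e3)
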