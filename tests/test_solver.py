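"""Bioheat solver: steady states, stability, closed forms, convergence."""

import numpy as np
import pytest

import mnph
from mnph import (ADIABATIC, AMFExposure, BoundaryCondition, BoundarySet,
                  MIONLoading, PennesSystem, SolverConfig, build_default_body,
                  heated_sphere_oracle, mms_case, schedule_from_duty,
                  simulate, steady_state_baseline, uniform_box_grid,
                  water_like)

INSULATED = BoundarySet.uniform(ADIABATIC)


def box_system(shape, spacing, props, blood, boundaries=INSULATED,
               rtol=1e-10, origin=(0.0, 0.0, 0.0), dt=1.0):
    grid = uniform_box_grid(shape, spacing, origin=origin)
    cfg = SolverConfig(time_step=dt, boundaries=boundaries, rtol=rtol)
    return grid, PennesSystem(grid, {"medium": props}, blood, cfg)


def grid_points(grid):
    xs, ys, zs = (grid.axis_centers(i) for i in range(3))
    return np.meshgrid(xs, ys, zs, indexing="ij")


class TestSteadyState:
    def test_insulated_no_metabolism_is_arterial(self, blood):
        props = water_like(perfusion=1e-3)
        _, system = box_system((6, 6, 6), 0.01, props, blood)
        T = system.steady_state()
        assert np.allclose(T, blood.arterial_temperature, atol=1e-8)

    def test_uniform_metabolic_heat_closed_form(self, blood):
        props = water_like(perfusion=1e-3, metabolic_rate=1000.0)
        _, system = box_system((6, 6, 6), 0.01, props, blood)
        T = system.steady_state()
        expected = blood.arterial_temperature + 1000.0 / (
            blood.perfusion_factor * props.perfusion)
        assert np.allclose(T, expected, rtol=1e-8)

    def test_insulated_unperfused_with_heat_has_no_steady_state(self, blood):
        props = water_like(metabolic_rate=100.0)
        _, system = box_system((4, 4, 4), 0.01, props, blood)
        with pytest.raises(mnph.SolverError):
            system.steady_state()

    def test_convective_surface_monotone_toward_core(self, blood):
        # 1-D slab, cooled at both x faces: temperature rises monotonically
        # from the surface to the core (discrete maximum principle)
        props = water_like(perfusion=1e-3, metabolic_rate=500.0)
        bc = BoundarySet(x=BoundaryCondition("convective", 10.0, 25.0),
                         y=ADIABATIC, z=ADIABATIC)
        _, system = box_system((80, 1, 1), 0.001, props, blood,
                               boundaries=bc)
        T = system.steady_state()
        half = T[:40]
        assert np.all(np.diff(half) > 0)
        assert T.max() <= blood.arterial_temperature + 500.0 / (
            blood.perfusion_factor * props.perfusion) + 1e-9


class TestTransient:
    def test_arterial_state_is_fixed_point(self, blood):
        props = water_like(perfusion=1e-3)
        _, system = box_system((6, 6, 6), 0.01, props, blood)
        T0 = np.full(system.n, blood.arterial_temperature)
        T1 = system.step(T0, 30.0)
        assert np.allclose(T1, T0, atol=1e-8)

    def test_uniform_perfused_heating_matches_closed_form(self, blood):
        # dT/dt closed form: T_b + (Q/g)(1 - exp(-g t / rho c)), g=rho_b c_b w
        props = water_like(perfusion=1e-2, density=1000.0,
                           specific_heat=3600.0)
        g = blood.perfusion_factor * props.perfusion
        tau = props.volumetric_heat_capacity / g
        Q = 5e4
        dt = tau / 200.0
        _, system = box_system((4, 4, 4), 0.01, props, blood, rtol=1e-12)
        T = np.full(system.n, blood.arterial_temperature)
        q = np.full(system.n, Q)
        t, worst = 0.0, 0.0
        prev = T[0]
        for _ in range(600):  # runs to 3 tau
            t += dt
            T = system.step(T, dt, q)
            exact = blood.arterial_temperature + Q / g * (1 - np.exp(-t / tau))
            worst = max(worst, abs(T[0] - exact)
                        / (exact - blood.arterial_temperature))
            assert T[0] > prev  # monotone approach, no overshoot
            prev = T[0]
        assert T[0] < blood.arterial_temperature + Q / g
        assert worst < 0.005

    def test_discrete_maximum_principle(self, blood, rng):
        # insulated, sourceless: extrema relax monotonically toward T_b
        props = water_like(perfusion=5e-3)
        _, system = box_system((8, 8, 8), 0.005, props, blood)
        T = rng.uniform(30.0, 40.0, size=system.n)
        lo, hi = T.min(), T.max()
        tb = blood.arterial_temperature
        for _ in range(20):
            T = system.step(T, 30.0)
            # new values are convex combinations of old values and T_b
            assert T.max() <= max(hi, tb) + 1e-9
            assert T.min() >= min(lo, tb) - 1e-9
            lo, hi = T.min(), T.max()
        # after many relaxation steps the field has contracted toward T_b
        assert max(abs(hi - tb), abs(lo - tb)) < 1.0

    def test_energy_bookkeeping_insulated_unperfused(self, blood, rng):
        # heat capacity x mean temperature rise == integral of source power
        props = water_like()
        grid, system = box_system((10, 10, 10), 0.005, props, blood,
                                  rtol=1e-12)
        q = rng.uniform(0, 1e5, size=system.n)
        T = np.full(system.n, 37.0)
        dt, steps = 5.0, 40
        for _ in range(steps):
            T = system.step(T, dt, q)
        v = grid.voxel_volume
        absorbed = (system.mass * (T - 37.0)).sum() * v
        delivered = q.sum() * v * dt * steps
        assert absorbed == pytest.approx(delivered, rel=0.01)


class TestVerificationOracles:
    def test_mms_spatial_order_two(self, blood, soft_tissue):
        L = 0.064
        case = mms_case((np.pi / L, 2 * np.pi / L, np.pi / L), 0.0, 1.0,
                        soft_tissue, blood)
        errs = []
        for n in (16, 32, 64):  # 4, 2, 1 mm
            grid, system = box_system((n, n, n), L / n, soft_tissue, blood)
            X, Y, Z = grid_points(grid)
            src = system.source_vector(case.source(X, Y, Z, 0.0))
            T = system.steady_state(q_ext=src)
            exact = case.temperature(X, Y, Z, 0.0)[system.active]
            errs.append(float(np.abs(T - exact).max()))
        assert errs[0] > errs[1] > errs[2]
        order = np.log2(errs[1] / errs[2])
        assert 1.9 <= order <= 2.1

    def test_mms_time_order_one(self, blood, soft_tissue):
        # time-only Richardson: compare against a small-dt reference so the
        # fixed spatial error cancels
        L = 0.064
        case = mms_case((np.pi / L,) * 3, 1e-3, 2.0, soft_tissue, blood)
        n = 16
        grid, system = box_system((n, n, n), L / n, soft_tissue, blood,
                                  rtol=1e-12)
        X, Y, Z = grid_points(grid)
        T0 = case.temperature(X, Y, Z, 0.0)[system.active]

        def run(dt, t_end=400.0):
            T = T0.copy()
            t = 0.0
            while t < t_end - 1e-9:
                t += dt
                T = system.step(T, dt,
                                system.source_vector(case.source(X, Y, Z, t)))
            return T

        ref = run(2.5)
        e40 = np.abs(run(40.0) - ref).max()
        e20 = np.abs(run(20.0) - ref).max()
        assert 0.9 <= np.log2(e40 / e20) <= 1.3

    def test_heated_sphere_profile(self, blood):
        Q, R, k, T_inf = 5e4, 0.01, 0.5, 20.0
        oracle = heated_sphere_oracle(Q, R, k, T_inf)
        # closed-form identities
        assert oracle(0.0) - T_inf == pytest.approx(Q * R ** 2 / (2 * k))
        assert (oracle(0.0) - T_inf) / (oracle(R) - T_inf) == \
            pytest.approx(1.5)
        assert oracle(0.0) == pytest.approx(oracle(1e-9), rel=1e-6)

        # conduction-only solve against the oracle, Dirichlet far field
        props = water_like(conductivity=k)
        bc = BoundaryCondition(
            "fixed",
            ambient=lambda x, y, z: oracle(np.sqrt(x * x + y * y + z * z)))
        n, half = 48, 0.03
        grid, system = box_system((n, n, n), 2 * half / n, props, blood,
                                  boundaries=BoundarySet.uniform(bc),
                                  rtol=1e-12, origin=(-half,) * 3)
        X, Y, Z = grid_points(grid)
        r = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)
        src = np.where(r <= R, 1.0, 0.0)
        src *= Q * (4 / 3 * np.pi * R ** 3) / (src.sum() * grid.voxel_volume)
        T = system.steady_state(q_ext=system.source_vector(src))
        rv = r[system.active]
        exact = oracle(rv)
        m = rv < 2 * R
        rel = np.abs(T[m] - exact[m]) / (exact[m] - T_inf)
        assert rel.max() < 0.02


class TestSimulate:
    def test_no_sources_flat_at_baseline(self):
        body = build_default_body(0.02)
        cfg = SolverConfig(time_step=60.0, spacing=0.008)
        sched = schedule_from_duty(100.0, on_block_s=300.0, total_on_s=300.0)
        res = simulate(body, AMFExposure(0.0, 155e3), sched,
                       loading=MIONLoading.for_tumor_radius(5.0, 0.02),
                       config=cfg)
        # SLP(0) = 0 and H = 0: every trace stays at the baseline
        assert np.allclose(res.tmax, res.tmax[0], atol=1e-6)
        assert np.allclose(res.tmin, res.tmin[0], atol=1e-6)

    def test_pulsed_trace_sawtooth(self):
        # 50% duty: muscle peak rises during on-blocks, falls during off
        body = build_default_body(0.02)
        cfg = SolverConfig(time_step=30.0, spacing=0.008)
        sched = schedule_from_duty(50.0, on_block_s=300.0, total_on_s=600.0)
        exposure = AMFExposure(1.5 * mnph.CLINICAL_HF_LIMIT / 155e3, 155e3)
        res = simulate(body, exposure, sched,
                       loading=MIONLoading.for_tumor_radius(5.0, 0.02),
                       config=cfg)
        muscle = res.trace("muscle", "max")
        block = int(300.0 / 30.0)
        # rising within the first on-block, falling within the first off
        assert muscle[block] > muscle[1]
        assert muscle[2 * block] < muscle[block]
        # and rising again in the second on-block
        assert muscle[3 * block] > muscle[2 * block]

    def test_dt_must_divide_on_block(self):
        body = build_default_body(0.02)
        cfg = SolverConfig(time_step=70.0, spacing=0.008)
        sched = schedule_from_duty(50.0, on_block_s=300.0, total_on_s=600.0)
        with pytest.raises(ValueError, match="on-block"):
            simulate(body, AMFExposure(0.0, 155e3), sched, config=cfg)

    def test_baseline_wrapper_physiological(self):
        body = mnph.effective_body(build_default_body(0.02), 0.008)
        grid = mnph.voxelize(body, 0.008, merge_superficial=False)
        fld = steady_state_baseline(body, grid, SolverConfig(spacing=0.008))
        vals = fld.values[np.isfinite(fld.values)]
        assert np.all(vals > 25.0) and np.all(vals < 40.0)

    def test_mesh_and_timestep_independence(self):
        # halving both spacing and dt moves the tumor peak by < 0.2 C
        body = build_default_body(0.03)
        exposure = AMFExposure(mnph.CLINICAL_HF_LIMIT / 155e3, 155e3)
        loading = MIONLoading.for_tumor_radius(5.0, 0.03)
        peaks = []
        for spacing, dt in ((0.006, 60.0), (0.003, 30.0)):
            cfg = SolverConfig(time_step=dt, spacing=spacing)
            sched = schedule_from_duty(100.0, on_block_s=1200.0,
                                       total_on_s=1200.0)
            res = simulate(body, exposure, sched, loading=loading, config=cfg)
            peaks.append(res.trace("tumor+mion", "max").max())
        assert abs(peaks[1] - peaks[0]) < 0.2
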