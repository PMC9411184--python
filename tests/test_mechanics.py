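"""Gor'kov forces, drag, virtual mass and the time-domain integrator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import acoustopattern as ap
from acoustopattern.field_engine import FieldGrid, Grid, WATER
from acoustopattern.mechanics import (
    ForceGrid,
    POLYSTYRENE,
    integrate_ensemble,
    stability_bound,
    viscous_relaxation_time,
    _HAVE_NUMBA,
)

LAM = 0.644e-3
K = 2 * np.pi / LAM


def standing_wave_field(grid, amplitude=1000.0):
    X, _ = grid.mesh()
    return FieldGrid(grid=grid, pressure=(amplitude * np.cos(K * X)).astype(complex))


class TestMaterial:
    def test_contrast_factors_from_printed_constants(self):
        """f1, f2 recomputed independently from the printed c, rho values."""
        kappa_p = 1.0 / (1050.0 * 2047.0**2)
        kappa_0 = 1.0 / (997.0 * 1500.0**2)
        assert POLYSTYRENE.f1(WATER) == pytest.approx(1 - kappa_p / kappa_0, rel=1e-12)
        assert POLYSTYRENE.f1(WATER) == pytest.approx(0.49015, abs=1e-4)
        assert POLYSTYRENE.f2(WATER) == pytest.approx(2 * 53 / 3097, rel=1e-12)
        assert POLYSTYRENE.f2(WATER) == pytest.approx(0.0342, abs=1e-4)

    def test_virtual_mass_value_and_scalings(self):
        assert ap.virtual_mass(POLYSTYRENE, WATER) == pytest.approx(5.91e-10, rel=1e-3)
        vacuum_ish = ap.Medium(c0=1500.0, rho0=1e-12, mu0=1e-12)
        plain = 4 / 3 * np.pi * POLYSTYRENE.radius**3 * POLYSTYRENE.density
        assert ap.virtual_mass(POLYSTYRENE, vacuum_ish) == pytest.approx(plain, rel=1e-9)
        double = ap.ParticleMaterial(2 * POLYSTYRENE.radius, 1050.0, 2047.0)
        assert ap.virtual_mass(double, WATER) == pytest.approx(
            8 * ap.virtual_mass(POLYSTYRENE, WATER)
        )


class TestAcousticVelocity:
    def test_uniform_pressure_zero_velocity(self):
        grid = ap.make_grid(1e-3)
        fld = FieldGrid(grid=grid, pressure=np.full(grid.shape, 5.0 + 1j))
        assert np.allclose(ap.acoustic_velocity(fld), 0.0)

    def test_linearity(self, rng):
        grid = ap.make_grid(1e-3)
        p = rng.normal(size=grid.shape) + 1j * rng.normal(size=grid.shape)
        f1 = FieldGrid(grid=grid, pressure=p)
        f2 = FieldGrid(grid=grid, pressure=3.0 * p)
        assert np.allclose(3.0 * ap.acoustic_velocity(f1), ap.acoustic_velocity(f2))

    def test_far_field_plane_wave_impedance(self, ws_central, geometry):
        """|v| ~ |p| / (rho0 c0) away from a single small source."""
        amps = np.zeros(64)
        amps[0] = 1.0
        d = ap.DriveState(amplitudes=amps, phases=np.zeros(64))
        fld = ws_central.pressure(d)
        v = ap.acoustic_velocity(fld)
        speed = np.hypot(np.abs(v[..., 0]), np.abs(v[..., 1]))
        ratio = speed / (np.abs(fld.pressure) / (WATER.rho0 * WATER.c0))
        # interior nodes (avoid one-sided border stencils)
        assert np.median(ratio[5:-5, 5:-5]) == pytest.approx(1.0, rel=0.05)


class TestGorkov:
    def test_zero_field_zero_potential(self):
        grid = ap.make_grid(1e-3)
        fld = FieldGrid(grid=grid, pressure=np.zeros(grid.shape, complex))
        assert np.all(ap.gorkov_potential(fld) == 0.0)

    def test_standing_wave_closed_form(self):
        """U(x) for p = A cos(kx) against the analytic expression."""
        grid = ap.make_grid(1.5e-3)
        A = 1000.0
        fld = standing_wave_field(grid, A)
        U = ap.gorkov_potential(fld)
        X, _ = grid.mesh()
        f1, f2 = POLYSTYRENE.f1(WATER), POLYSTYRENE.f2(WATER)
        pref = 4 * POLYSTYRENE.radius**3 / 3
        U_th = (
            pref
            * (A**2 * WATER.kappa0 / 4)
            * (f1 * np.cos(K * X) ** 2 - 1.5 * f2 * np.sin(K * X) ** 2)
        )
        inner = np.s_[5:-5, 5:-5]
        assert np.abs(U[inner] - U_th[inner]).max() <= 0.02 * np.abs(U_th).max()

    def test_force_zeros_at_nodes_and_antinodes(self):
        grid = ap.make_grid(1.5e-3)
        fg = ap.radiation_force(ap.gorkov_potential(standing_wave_field(grid)), grid)
        lookup = ap.BilinearForce(grid, fg.force)
        fmax = np.abs(fg.force[..., 0]).max()
        at_node = lookup(np.array([LAM / 4, 0.0]))  # pressure node
        at_anti = lookup(np.array([LAM / 2, 0.0]))
        assert abs(at_node[0]) < 0.05 * fmax
        assert abs(at_anti[0]) < 0.05 * fmax

    def test_volume_prefactor_flag(self):
        grid = ap.make_grid(0.5e-3)
        fld = standing_wave_field(grid)
        assert np.allclose(
            ap.gorkov_potential(fld, prefactor="volume"),
            np.pi * ap.gorkov_potential(fld, prefactor="printed"),
        )


class TestRadiationForce:
    def test_uniform_potential_zero_force(self):
        grid = ap.make_grid(1e-3)
        fg = ap.radiation_force(np.full(grid.shape, 3.3), grid)
        assert np.allclose(fg.force, 0.0)

    def test_linear_ramp_constant_force(self):
        grid = ap.make_grid(1e-3)
        X, _ = grid.mesh()
        alpha = 2.0e-12
        fg = ap.radiation_force(alpha * X, grid)
        assert np.allclose(fg.force[..., 0], -alpha, rtol=1e-9)
        assert np.allclose(fg.force[..., 1], 0.0, atol=1e-25)

    def test_matches_brute_force_gradient_oracle(self, ws_central, geometry, rng):
        """Interior force equals an independently coded central difference."""
        d = ap.twin_trap_drive(geometry, (0.3e-3, 0.1e-3), 0.2)
        U = ap.gorkov_potential(ws_central.pressure(d))
        fg = ap.radiation_force(U, ws_central.grid)
        h = ws_central.grid.spacing
        nx, ny = ws_central.grid.shape
        for _ in range(200):
            i = rng.integers(1, nx - 1)
            j = rng.integers(1, ny - 1)
            fx = -(U[i + 1, j] - U[i - 1, j]) / (2 * h)
            fy = -(U[i, j + 1] - U[i, j - 1]) / (2 * h)
            assert fg.force[i, j, 0] == pytest.approx(fx, rel=1e-9, abs=1e-30)
            assert fg.force[i, j, 1] == pytest.approx(fy, rel=1e-9, abs=1e-30)


class TestNormalize:
    def _force_grid(self, ws, geometry):
        d = ap.twin_trap_drive(geometry, (0.0, 0.0), 0.0)
        U = ap.gorkov_potential(ws.pressure(d))
        return ap.radiation_force(U, ws.grid)

    def test_max_equals_target(self, ws_central, geometry):
        fg = ap.normalize_force(self._force_grid(ws_central, geometry), 10e-9)
        assert fg.magnitude.max() == pytest.approx(1e-8, rel=1e-12)

    def test_idempotent_and_scale_invariant(self, ws_central, geometry):
        fg = self._force_grid(ws_central, geometry)
        once = ap.normalize_force(fg, 10e-9)
        twice = ap.normalize_force(once, 10e-9)
        assert np.allclose(once.force, twice.force)
        scaled = ForceGrid(grid=fg.grid, potential=7 * fg.potential, force=7 * fg.force)
        assert np.allclose(
            ap.normalize_force(scaled, 10e-9).force, once.force, rtol=1e-12
        )

    def test_zero_field_rejected(self):
        grid = ap.make_grid(0.5e-3)
        z = ForceGrid(
            grid=grid,
            potential=np.zeros(grid.shape),
            force=np.zeros(grid.shape + (2,)),
        )
        with pytest.raises(ValueError):
            ap.normalize_force(z, 1e-8)


class TestDrag:
    def test_zero_velocity_zero_drag(self):
        assert np.allclose(ap.drag_force(np.zeros(2)), 0.0)

    def test_stokes_limit(self):
        v = np.array([1e-6, 0.0])  # 1 um/s, Re ~ 1e-4
        stokes = 6 * np.pi * WATER.mu0 * POLYSTYRENE.radius * 1e-6
        assert np.linalg.norm(ap.drag_force(v)) == pytest.approx(stokes, rel=1e-4)

    def test_always_opposes_motion(self, rng):
        for _ in range(20):
            v = rng.normal(size=2) * 10 ** rng.uniform(-8, -1)
            f = ap.drag_force(v)
            assert float(f @ v) >= 0.0  # F_d parallel to v; opposes via F_e = F_ac - F_d
            cross = f[0] * v[1] - f[1] * v[0]
            assert abs(cross) <= 1e-12 * np.linalg.norm(f) * np.linalg.norm(v)

    @given(st.floats(1e-9, 1e-1), st.floats(1.01, 10.0))
    @settings(derandomize=True, max_examples=40)
    def test_magnitude_monotone_in_speed(self, speed, factor):
        f1 = np.linalg.norm(ap.drag_force(np.array([speed, 0.0])))
        f2 = np.linalg.norm(ap.drag_force(np.array([speed * factor, 0.0])))
        assert f2 > f1

    def test_stokes_deviation_bounded_by_re_factor(self):
        for speed in (1e-6, 1e-4, 1e-2):
            re = 2 * POLYSTYRENE.radius * WATER.rho0 * speed / WATER.mu0
            stokes = 6 * np.pi * WATER.mu0 * POLYSTYRENE.radius * speed
            ratio = np.linalg.norm(ap.drag_force(np.array([speed, 0.0]))) / stokes
            assert abs(ratio - 1.0) <= np.sqrt(1 + 3 * re / 16) - 1 + 1e-12


class TestStep:
    def test_rest_with_no_force_stays_put(self):
        p = ap.Particle(position=np.zeros(2), velocity=np.zeros(2))
        dt = ap.default_timestep()
        out = ap.step(p, lambda x: np.zeros(2), dt)
        assert np.all(out.position == 0) and np.all(out.velocity == 0)

    def test_constant_force_single_step_displacement(self):
        """x(dt) = F dt^2 / m_v from rest, exactly as the update rule states."""
        F = np.array([3e-9, -1e-9])
        p = ap.Particle(position=np.zeros(2), velocity=np.zeros(2))
        dt = ap.default_timestep()
        out = ap.step(p, lambda x: F, dt)
        mv = ap.virtual_mass(POLYSTYRENE, WATER)
        assert np.allclose(out.position, F * dt**2 / mv, rtol=1e-12)

    def test_dt_above_stability_bound_raises(self):
        p = ap.Particle(position=np.zeros(2), velocity=np.zeros(2))
        with pytest.raises(ValueError, match="stability"):
            ap.step(p, lambda x: np.zeros(2), 2 * stability_bound())

    def test_damped_oscillator_closed_form(self):
        """Linear restoring force: trajectory matches the analytic damped
        solution within 1% over 100 viscous relaxation times."""
        kspring = 2e-6
        mv = ap.virtual_mass(POLYSTYRENE, WATER)
        gam = 6 * np.pi * WATER.mu0 * POLYSTYRENE.radius
        tau = viscous_relaxation_time(POLYSTYRENE, WATER)
        dt = tau / 50
        x0 = 20e-6
        p = ap.Particle(position=np.array([x0, 0.0]), velocity=np.zeros(2))
        n = int(100 * tau / dt)
        xs, ts = [x0], [0.0]
        for i in range(n):
            p = ap.step(p, lambda x: -kspring * x, dt)
            xs.append(p.position[0])
            ts.append((i + 1) * dt)
        ts = np.asarray(ts)
        disc = np.sqrt(gam**2 - 4 * mv * kspring)
        s1, s2 = (-gam + disc) / (2 * mv), (-gam - disc) / (2 * mv)
        x_th = x0 * (s2 * np.exp(s1 * ts) - s1 * np.exp(s2 * ts)) / (s2 - s1)
        assert np.abs(np.asarray(xs) - x_th).max() <= 0.01 * x0

    def test_boundary_clamp_zeroes_velocity(self):
        r_max = 5.49e-3 - POLYSTYRENE.radius
        p = ap.Particle(
            position=np.array([r_max - 1e-7, 0.0]), velocity=np.array([0.05, 0.0])
        )
        out = ap.step(p, lambda x: np.zeros(2), ap.default_timestep(), chamber_radius=5.49e-3)
        assert np.hypot(*out.position) == pytest.approx(r_max, rel=1e-12)
        assert np.all(out.velocity == 0)


class TestEnsembleIntegration:
    def _setup(self, rng):
        grid = ap.make_grid(1.5e-3)
        fg = ap.normalize_force(
            ap.radiation_force(ap.gorkov_potential(standing_wave_field(grid)), grid),
            10e-9,
        )
        pos = rng.uniform(-1e-3, 1e-3, (12, 2))
        vel = np.zeros((12, 2))
        stack = fg.force[None]
        seq = np.zeros(400, dtype=np.int64)
        return pos, vel, stack, seq, grid

    @pytest.mark.skipif(not _HAVE_NUMBA, reason="numba not installed")
    def test_numba_and_numpy_kernels_agree(self, rng):
        pos, vel, stack, seq, grid = self._setup(rng)
        dt = ap.default_timestep()
        p1, v1, _ = integrate_ensemble(pos, vel, stack, seq, grid, dt, use_numba=True)
        p2, v2, _ = integrate_ensemble(pos, vel, stack, seq, grid, dt, use_numba=False)
        assert np.allclose(p1, p2, rtol=1e-12, atol=1e-18)
        assert np.allclose(v1, v2, rtol=1e-12, atol=1e-18)

    def test_kernel_matches_scalar_step(self, rng):
        """The vector kernel reproduces the public scalar integrator."""
        pos, vel, stack, seq, grid = self._setup(rng)
        dt = ap.default_timestep()
        p1, _, _ = integrate_ensemble(pos[:3], vel[:3], stack, seq[:50], grid, dt)
        lookup = ap.BilinearForce(grid, stack[0])
        for i in range(3):
            part = ap.Particle(position=pos[i].copy(), velocity=np.zeros(2))
            for _ in range(50):
                part = ap.step(part, lookup, dt, chamber_radius=5.49e-3)
            assert np.allclose(part.position, p1[i], rtol=1e-10, atol=1e-15)

    def test_particle_converges_to_pressure_node(self, rng):
        """Positive-contrast particles settle at the standing-wave nodes."""
        pos, vel, stack, seq, grid = self._setup(rng)
        seq = np.zeros(30000, dtype=np.int64)
        p, v, _ = integrate_ensemble(pos, vel, stack, seq, grid, ap.default_timestep())
        nodes = (np.round((p[:, 0] - LAM / 4) / (LAM / 2)) * (LAM / 2)) + LAM / 4
        assert np.allclose(p[:, 0], nodes, atol=LAM / 100)

    def test_speed_decays_inside_trap_basin(self):
        grid = ap.make_grid(1.5e-3)
        fg = ap.normalize_force(
            ap.radiation_force(ap.gorkov_potential(standing_wave_field(grid)), grid),
            10e-9,
        )
        pos = np.array([[LAM / 4 + LAM / 16, 0.0]])  # inside the node basin
        vel = np.zeros((1, 2))
        dt = ap.default_timestep()
        _, _, rec = integrate_ensemble(
            pos, vel, fg.force[None], np.zeros(4000, np.int64), grid, dt, record_stride=40
        )
        speeds = np.linalg.norm(np.diff(rec[:, 0, :], axis=0), axis=1)
        peak = int(np.argmax(speeds))
        tail = speeds[peak:]
        assert np.all(np.diff(tail) <= 1e-12 + 1e-6 * tail[:-1])


class TestBilinearForce:
    def test_matches_scipy_interpolator(self, rng):
        from scipy.interpolate import RegularGridInterpolator

        grid = ap.make_grid(1e-3)
        F = rng.normal(size=grid.shape + (2,))
        mine = ap.BilinearForce(grid, F)
        ref = RegularGridInterpolator((grid.x, grid.y), F)
        pts = rng.uniform(-0.9e-3, 0.9e-3, (100, 2))
        assert np.allclose(mine(pts), ref(pts), rtol=1e-12)

    def test_outside_grid_clamps_to_edge(self):
        grid = ap.make_grid(1e-3)
        F = np.ones(grid.shape + (2,))
        F[-1, :, 0] = 7.0
        mine = ap.BilinearForce(grid, F)
        out = mine(np.array([[5e-3, 0.0]]))
        assert out[0, 0] == pytest.approx(7.0)
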