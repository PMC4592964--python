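import math

import numpy as np
import pytest

from rolltank import (
    Design2Field,
    FluidProps,
    ParticleProps,
    SolidBodyField,
    TankGeometry,
    orbit_fit,
    relaxation_time,
    ring_positions,
    settling_velocity,
    simulate_ensemble,
    simulate_trajectory,
)

G = 9.81
PERIOD18 = 60.0 / 1.8  # one rotation at 1.8 rpm, s


class TestSettlingVelocity:
    def test_stokes_closed_form(self, particle, fluid):
        # (rho_p - rho_f) g d^2 / (18 mu), recomputed independently
        expected = (1005.0 - 1000.0) * G * (1e-3) ** 2 / (18.0 * 1e-3)
        ws = settling_velocity(particle, fluid)
        assert ws == pytest.approx(expected, rel=1e-12)
        assert ws == pytest.approx(2.725e-3, rel=1e-3)

    def test_schiller_naumann_fixed_point(self, particle_sn, fluid):
        ws = settling_velocity(particle_sn, fluid)
        # independent oracle: damped iteration from a different start point
        w_st = 2.725e-3
        w = 1e-4
        for _ in range(500):
            re = w * 1e-3 / 1e-6
            w = 0.5 * w + 0.5 * w_st / (1.0 + 0.15 * re**0.687)
        assert ws == pytest.approx(w, rel=1e-6)
        assert ws == pytest.approx(2.17e-3, rel=5e-3)
        # the fixed point satisfies its own defining equation
        re = ws * 1e-3 / 1e-6
        assert ws * (1.0 + 0.15 * re**0.687) == pytest.approx(2.725e-3, rel=1e-8)

    def test_neutral_buoyancy_settles_at_zero(self, fluid):
        p = ParticleProps(density=1000.0)
        assert settling_velocity(p, fluid) == 0.0
        p_sn = ParticleProps(density=1000.0, drag_law="schiller_naumann")
        assert settling_velocity(p_sn, fluid) == 0.0

    def test_buoyant_particle_rises(self, fluid):
        assert settling_velocity(ParticleProps(density=900.0), fluid) < 0.0


class TestRelaxationTime:
    def test_default_value(self, particle, fluid):
        assert relaxation_time(particle, fluid) == pytest.approx(5.583e-2, rel=1e-3)

    def test_diameter_squared_scaling(self, fluid):
        t1 = relaxation_time(ParticleProps(diameter=1e-3), fluid)
        t2 = relaxation_time(ParticleProps(diameter=2e-3), fluid)
        assert t2 == pytest.approx(4.0 * t1, rel=1e-12)


class TestClosedTankOrbits:
    def test_overdamped_orbit_circles_the_analytic_fixed_point(
        self, field_closed, geom_closed, particle, fluid
    ):
        """The overdamped velocity (-wy, wx - w_s) vanishes at (w_s/w, 0);
        trajectories are circles about it with the rotation period."""
        ws = settling_velocity(particle, fluid)
        tr = simulate_trajectory(
            field_closed,
            geom_closed,
            particle,
            fluid,
            (0.02, 0.0, 0.135),
            model="overdamped",
            dt=0.05,
            t_max=3 * PERIOD18,
        )
        fit = orbit_fit(tr, PERIOD18)
        expected_cx = ws / geom_closed.rotation_rate
        assert fit.center[0] == pytest.approx(expected_cx, rel=0.01)
        assert abs(fit.center[1]) < 0.01 * expected_cx
        # parameter recovery: w_s back from the orbit centre
        assert fit.center[0] * geom_closed.rotation_rate == pytest.approx(ws, rel=0.01)
        # z is untouched by the planar flow + settling
        assert np.max(np.abs(tr.positions[:, 2] - 0.135)) < 1e-12

    def test_massless_tracer_conserves_radius_and_z(self, field_closed, geom_closed, fluid):
        tr = simulate_trajectory(
            field_closed,
            geom_closed,
            None,
            fluid,
            (0.02, 0.0, 0.135),
            model="massless",
            dt=0.05,
            t_max=10 * PERIOD18,
        )
        r = tr.cylindrical_radius()
        assert np.max(np.abs(r - 0.02)) < 1e-6 * geom_closed.inner_radius
        assert np.max(np.abs(tr.positions[:, 2] - 0.135)) < 1e-6 * geom_closed.inner_radius

    def test_inertial_matches_overdamped_at_small_stokes_number(
        self, field_closed, geom_closed, fluid
    ):
        """d -> 0 at fixed w_s (density adjusted): the inertial trajectory
        collapses onto the overdamped one."""
        d = 3e-4
        delta_rho = 5.0 * (1e-3 / d) ** 2  # keeps w_s = 2.725 mm/s
        p = ParticleProps(diameter=d, density=1000.0 + delta_rho)
        kw = dict(dt=2e-3, t_max=100.0, record_every=50)
        tr_in = simulate_trajectory(
            field_closed, geom_closed, p, fluid, (0.02, 0.0, 0.135), model="inertial", **kw
        )
        tr_ov = simulate_trajectory(
            field_closed, geom_closed, p, fluid, (0.02, 0.0, 0.135), model="overdamped", **kw
        )
        gap = np.linalg.norm(tr_in.positions[-1] - tr_ov.positions[-1])
        assert gap < 1e-3 * geom_closed.inner_radius

    def test_inertial_drifts_slowly_outward(self, field_closed, geom_closed, particle, fluid):
        tr = simulate_trajectory(
            field_closed,
            geom_closed,
            particle,
            fluid,
            (0.02, 0.0, 0.135),
            model="inertial",
            dt=0.02,
            t_max=6 * PERIOD18,
            record_every=5,
        )
        fit = orbit_fit(tr, PERIOD18)
        assert np.all(np.diff(fit.period_radii) > 0.0)
        assert 0.0 < fit.drift_rate < 1e-6


class TestDesign2Transport:
    def test_tracer_spirals_at_constant_radius_with_plug_advance(self, field_d2, geom_d2, fluid):
        tr = simulate_trajectory(
            field_d2,
            geom_d2,
            None,
            fluid,
            (0.02, 0.0, 0.135),
            model="massless",
            dt=0.1,
            t_max=1000.0,
            record_every=10,
        )
        r = tr.cylindrical_radius()
        assert np.max(np.abs(r - 0.02)) < 0.005 * 0.02
        dz = np.diff(tr.positions[:, 2])
        assert np.all(dz > 0.0)  # monotone axial advance
        plug = geom_d2.flow_rate / (math.pi * geom_d2.inner_radius**2)
        assert tr.positions[-1, 2] - 0.135 == pytest.approx(plug * 1000.0, rel=0.02)


class TestEventHandling:
    def test_sinking_particle_reaches_the_wall(self, fluid):
        g = TankGeometry("closed", rotation_rate=0.0)
        p = ParticleProps(density=1100.0)
        tr = simulate_trajectory(
            SolidBodyField(g), g, p, fluid, (0.0, -0.02, 0.135), model="overdamped", dt=0.05,
            t_max=500.0,
        )
        assert tr.status == "wall_contact"
        assert tr.times[-1] < 500.0
        r_final = math.hypot(*tr.positions[-1, :2])
        assert r_final >= g.inner_radius - p.diameter / 2.0 - 1e-6

    def test_axial_advection_exits_through_outlet(self, fluid):
        """Without rotation and at neutral buoyancy, a tracer seeded near the
        wall in line with an end-cap hole is flushed out through it."""
        g = TankGeometry.from_bench_units("design2", rpm=0.0, flow_ml_min=100.0)
        tr = simulate_trajectory(
            Design2Field(g), g, None, fluid, (0.0435, 0.0, 0.25), model="massless",
            dt=0.5, t_max=200.0,
        )
        assert tr.status == "exited_outlet"

    def test_stiff_dt_warns_and_is_reduced(self, field_closed, geom_closed, particle, fluid):
        tau = relaxation_time(particle, fluid)
        with pytest.warns(UserWarning, match="stiff"):
            tr = simulate_trajectory(
                field_closed, geom_closed, particle, fluid, (0.02, 0.0, 0.135),
                model="inertial", dt=0.5, t_max=2.0,
            )
        assert tr.metadata["dt"] < tau / 2.0

    def test_high_reynolds_stokes_drag_warns(self, field_closed, geom_closed, particle, fluid):
        with pytest.warns(UserWarning, match="Reynolds"):
            simulate_trajectory(
                field_closed, geom_closed, particle, fluid, (0.02, 0.0, 0.135),
                model="overdamped", dt=0.1, t_max=1.0,
            )

    def test_initial_position_outside_rejected(self, field_closed, geom_closed, particle, fluid):
        with pytest.raises(ValueError, match="outside"):
            simulate_trajectory(
                field_closed, geom_closed, particle, fluid, (0.05, 0.0, 0.135),
                model="massless", dt=0.1, t_max=1.0,
            )


class TestEnsembles:
    def test_ring_seeding_is_evenly_spaced(self):
        pos = ring_positions(4, 0.02, 0.1)
        assert pos.shape == (4, 3)
        assert np.allclose(np.hypot(pos[:, 0], pos[:, 1]), 0.02)
        assert np.allclose(pos[:, 2], 0.1)

    def test_empty_seeding_gives_empty_list(self, field_closed, geom_closed, particle, fluid):
        out = simulate_ensemble(
            field_closed, geom_closed, particle, fluid, np.empty((0, 3)),
            model="massless", dt=0.1, t_max=1.0,
        )
        assert out == []

    def test_random_seeding_is_reproducible(self, field_closed, geom_closed, particle, fluid):
        spec = {"mode": "random", "count": 4, "max_radius": 0.02, "z_range": (0.1, 0.2)}
        kw = dict(model="overdamped", dt=0.1, t_max=5.0, rng_seed=7)
        a = simulate_ensemble(field_closed, geom_closed, particle, fluid, spec, **kw)
        b = simulate_ensemble(field_closed, geom_closed, particle, fluid, spec, **kw)
        assert all(np.array_equal(x.positions, y.positions) for x, y in zip(a, b))

    def test_seed_outside_cylinder_rejected(self, field_closed, geom_closed, particle, fluid):
        with pytest.raises(ValueError, match="outside"):
            simulate_ensemble(
                field_closed, geom_closed, particle, fluid, [(0.0, 0.0, 0.5)],
                model="massless", dt=0.1, t_max=1.0,
            )

    def test_displacement_ensemble_stays_interior(self, ring_ensemble_30s):
        assert all(tr.status == "interior" for tr in ring_ensemble_30s)
        assert len(ring_ensemble_30s) == 15
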