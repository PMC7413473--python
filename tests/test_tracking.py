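"""Drag/lift laws and Lagrangian path-line integration."""

import math

import numpy as np
import pytest

from cathflow.fields import AnalyticFieldSpec, make_analytic_field
from cathflow.rheology import BLOOD_CARREAU, CarreauParameters
from cathflow.tracking import (
    IntegrationSettings,
    PlateletProperties,
    SeedSpec,
    advance_platelet,
    drag_acceleration,
    drag_coefficient,
    particle_reynolds,
    saffman_lift_acceleration,
    seed_positions,
    track_ensemble,
)

NEWTONIAN = CarreauParameters(mu_inf=0.001, mu_zero=0.00345, lambda_time=1.0, n_index=1.0)
# n = 1 collapses the law to a constant viscosity mu_zero


class TestParticleReynolds:
    def test_hand_value(self):
        props = PlateletProperties()
        re = particle_reynolds(0.1, props, 0.00345)
        assert re == pytest.approx(1060 * 0.1 * 2e-6 / 0.00345, rel=1e-12)

    def test_zero_slip(self):
        assert particle_reynolds(0.0, PlateletProperties(), 0.00345) == 0.0

    def test_linear_in_slip(self):
        props = PlateletProperties()
        assert particle_reynolds(0.2, props, 0.003) == pytest.approx(
            2 * particle_reynolds(0.1, props, 0.003)
        )


class TestDragCoefficient:
    def test_newton_regime_constant(self):
        assert drag_coefficient(2000.0) == 0.44

    def test_stokes_limit_cd_re_24(self):
        re = 1e-8
        assert drag_coefficient(re) * re == pytest.approx(24.0, rel=1e-5)

    def test_low_re_closed_form(self):
        re = 0.1
        assert drag_coefficient(re) == pytest.approx(
            24 * (1 + 0.15 * 0.1**0.687) / 0.1, rel=1e-12
        )

    def test_continuity_at_branch_point(self):
        below = drag_coefficient(1000.0 - 1e-9)
        above = drag_coefficient(1000.0 + 1e-9)
        assert abs(below - above) / below < 0.005

    def test_negative_re_rejected(self):
        with pytest.raises(ValueError):
            drag_coefficient(-1.0)


class TestDragAcceleration:
    def test_zero_at_equal_velocities(self):
        u = np.array([0.3, 0.1])
        a = drag_acceleration(u, u, PlateletProperties(), 0.00345)
        np.testing.assert_array_equal(a, 0.0)

    def test_stokes_response_time(self):
        # small slip: a = slip / tau_p with tau_p = rho_p d^2 / (18 mu)
        props = PlateletProperties()
        mu = 0.00345
        tau_p = 1060 * (2e-6) ** 2 / (18 * mu)
        slip = np.array([1e-6, 0.0])
        a = drag_acceleration(slip, np.zeros(2), props, mu)
        assert a[0] == pytest.approx(slip[0] / tau_p, rel=1e-3)
        assert tau_p == pytest.approx(props.response_time(mu))

    def test_direction_along_slip(self):
        u_f = np.array([0.4, -0.2])
        u_p = np.array([0.1, 0.1])
        a = drag_acceleration(u_f, u_p, PlateletProperties(), 0.003)
        slip = u_f - u_p
        cos = a @ slip / (np.linalg.norm(a) * np.linalg.norm(slip))
        assert cos == pytest.approx(1.0)


class TestSaffmanLift:
    def test_zero_slip_gives_zero(self):
        g = np.array([[0.0, 100.0], [0.0, 0.0]])
        u = np.array([0.3, 0.0])
        a = saffman_lift_acceleration(u, u, g, PlateletProperties(), 3e-6)
        np.testing.assert_array_equal(a, 0.0)

    def test_zero_strain_gives_zero(self):
        rot = np.array([[0.0, 5.0], [-5.0, 0.0]])  # rigid rotation
        a = saffman_lift_acceleration(
            np.array([0.1, 0.0]), np.zeros(2), rot, PlateletProperties(), 3e-6
        )
        np.testing.assert_allclose(a, 0.0, atol=1e-15)

    def test_simple_shear_matches_classical_saffman(self):
        # du/dy = G with axial slip s: the generalized tensor form with
        # K = 2.594 must reduce to F = 1.615 mu d_p^2 s (G/nu)^0.5 per mass
        props = PlateletProperties()
        G, s = 500.0, 0.01
        mu = 0.00345
        nu = mu / props.fluid_density
        grad = np.array([[0.0, G], [0.0, 0.0]])
        a = saffman_lift_acceleration(
            np.array([s, 0.0]), np.zeros(2), grad, props, nu
        )
        m_p = props.density * math.pi * props.diameter**3 / 6.0
        f_classical = 1.615 * mu * props.diameter**2 * s * math.sqrt(G / nu)
        assert abs(a[1]) == pytest.approx(f_classical / m_p, rel=2e-2)
        # lift acts transverse to the slip in simple shear
        assert abs(a[0]) < abs(a[1]) * 1e-10


class TestPathLines:
    def test_uniform_flow_residence_time(self):
        spec = AnalyticFieldSpec("uniform", 0.3, 0.01, (0.05, 0.02))
        f = make_analytic_field(spec, (26, 11))
        line = advance_platelet(
            (0.001, 0.01), f, NEWTONIAN,
            settings=IntegrationSettings(target_step=5e-5),
        )
        assert line.termination == "exited_vessel_outlet"
        expected = (0.05 - 0.001) / 0.3
        assert line.residence_time == pytest.approx(expected, rel=1e-3)
        # straight path
        assert np.abs(line.position[:, 1] - 0.01).max() < 1e-12

    def test_residence_time_equals_sum_of_steps(self):
        spec = AnalyticFieldSpec("poiseuille_planar", 0.2, 0.02, (0.05, 0.02))
        f = make_analytic_field(spec, (26, 21))
        line = advance_platelet(
            (0.002, 0.013), f, NEWTONIAN,
            settings=IntegrationSettings(target_step=1e-4),
        )
        assert line.dt.sum() == pytest.approx(line.t[-1] - line.t[0], abs=1e-15)
        assert np.all(np.diff(line.t) > 0)

    def test_slip_relaxes_exponentially(self):
        # particle released at rest in a uniform stream approaches the fluid
        # velocity as 1 - exp(-t/tau_p)
        spec = AnalyticFieldSpec("uniform", 0.1, 0.01, (0.01, 0.01))
        f = make_analytic_field(spec, (11, 11))
        props = PlateletProperties()
        mu = NEWTONIAN.mu_zero
        tau_p = props.response_time(mu)
        line = advance_platelet(
            (0.001, 0.005), f, NEWTONIAN, props,
            settings=IntegrationSettings(target_step=2e-9, max_time=5 * tau_p),
            initial_velocity=(0.0, 0.0),
        )
        # Schiller-Naumann correction at this Re is small; compare against
        # the Stokes relaxation with its finite-Re rate
        t = line.t[1:50]
        up = line.velocity[1:50, 0]
        slip0 = 0.1
        rates = -np.log((0.1 - up) / slip0) / t
        assert np.all(rates > 1.0 / tau_p * 0.95)
        assert rates[0] == pytest.approx(1.0 / tau_p, rel=0.1)

    def test_tracer_limit_follows_streamlines(self):
        # stagnation flow: streamlines are hyperbolae x*y = const
        spec = AnalyticFieldSpec("stagnation", 0.5, 0.01, (0.02, 0.02))
        f = make_analytic_field(spec, (41, 41))
        line = advance_platelet(
            (0.002, 0.015), f, NEWTONIAN,
            settings=IntegrationSettings(target_step=2e-5, max_time=0.2),
        )
        xy = line.position[:, 0] * line.position[:, 1]
        assert np.abs(xy - xy[0]).max() / xy[0] < 5e-3

    def test_poiseuille_tracer_negligible_drift(self):
        # neutrally buoyant 2 um particle: transverse drift under 1% of the
        # channel height while crossing many heights
        H = 0.001
        spec = AnalyticFieldSpec("poiseuille_planar", 0.2, H, (0.1, H))
        f = make_analytic_field(spec, (101, 21))
        y0 = 0.00035
        line = advance_platelet(
            (0.0005, y0), f, NEWTONIAN,
            settings=IntegrationSettings(target_step=2e-5, max_time=5.0),
        )
        assert line.termination == "exited_vessel_outlet"
        assert abs(line.position[-1, 0] - 0.1) < 1e-6
        drift = np.abs(line.position[:, 1] - y0).max()
        assert drift < 0.01 * H

    def test_seed_outside_or_in_solid_rejected(self):
        spec = AnalyticFieldSpec("uniform", 0.1, 0.01, (0.01, 0.01))
        f = make_analytic_field(spec, (5, 5))
        with pytest.raises(ValueError, match="outside"):
            advance_platelet((0.5, 0.5), f, NEWTONIAN)
        f.mask[:, :, :] = False
        f.velocity[:] = 0.0
        with pytest.raises(ValueError, match="solid"):
            advance_platelet((0.005, 0.005), f, NEWTONIAN)


class TestEnsembles:
    def test_deterministic_and_counted(self):
        from cathflow.geometry import SideHole, TipGeometry2D

        geom = TipGeometry2D(
            side_holes=(SideHole("straight_cut", 0.004, 0.0165),)
        )
        spec = AnalyticFieldSpec("uniform", 0.2, 0.01, (0.05, 0.02))
        f = make_analytic_field(spec, (26, 11))
        seeds = SeedSpec(count=3)
        kw = dict(settings=IntegrationSettings(target_step=1e-4))
        lines1 = track_ensemble(seeds, geom, f, NEWTONIAN, **kw)
        lines2 = track_ensemble(seeds, geom, f, NEWTONIAN, **kw)
        assert len(lines1) == 3
        for a, b in zip(lines1, lines2):
            np.testing.assert_array_equal(a.position, b.position)
            assert a.termination == b.termination

    def test_single_seed(self):
        spec = AnalyticFieldSpec("uniform", 0.2, 0.01, (0.05, 0.02))
        f = make_analytic_field(spec, (26, 11))
        lines = track_ensemble(
            SeedSpec(count=1), None, f, NEWTONIAN,
            settings=IntegrationSettings(target_step=1e-4),
            positions=[(0.01, 0.01)],
        )
        assert len(lines) == 1

    def test_empty_seed_set_rejected(self):
        spec = AnalyticFieldSpec("uniform", 0.2, 0.01, (0.05, 0.02))
        f = make_analytic_field(spec, (6, 6))
        with pytest.raises(ValueError, match="empty|no side-holes"):
            track_ensemble(SeedSpec(count=1), None, f, NEWTONIAN,
                           positions=np.empty((0, 2)))

    def test_seed_positions_layout(self):
        from cathflow.geometry import SideHole, TipGeometry2D

        geom = TipGeometry2D(side_holes=(SideHole("straight_cut", 0.004, 0.0165),))
        pts = seed_positions(SeedSpec(count=5, plane_offset=1e-3), geom)
        assert pts.shape == (5, 2)
        np.testing.assert_allclose(pts[:, 1], geom.wall_bottom - 1e-3)
        x_d, x_a = geom.hole_inner_span(geom.side_holes[0])
        assert np.all((pts[:, 0] > x_a) & (pts[:, 0] < x_d))
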