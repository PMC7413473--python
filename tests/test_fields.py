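"""Structured-field interpolation, gradients, analytic fixtures and VTK I/O."""

import numpy as np
import pytest

from cathflow.fields import (
    AnalyticFieldSpec,
    StructuredField,
    VTKParseError,
    analytic_gradient,
    make_analytic_field,
    read_field,
    write_field,
)


def random_field(seed=0, nx=6, ny=5):
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(0, 1, nx))
    x[0], x[-1] = 0.0, 1.0
    y = np.linspace(0, 0.5, ny)
    vel = rng.normal(size=(nx, ny, 1, 3))
    mask = np.ones((nx, ny, 1), dtype=bool)
    visc = rng.uniform(0.003, 0.025, size=(nx, ny, 1))
    return StructuredField(x=x, y=y, z=np.array([0.0]), velocity=vel, mask=mask,
                           viscosity=visc)


class TestSampling:
    def test_uniform_field_everywhere(self):
        spec = AnalyticFieldSpec("uniform", 0.3, 0.01, (0.05, 0.02))
        f = make_analytic_field(spec, (21, 11))
        for p in [(0.001, 0.001), (0.027, 0.013), (0.05, 0.02)]:
            np.testing.assert_allclose(f.sample_velocity(p), [0.3, 0.0, 0.0])

    def test_poiseuille_centerline_is_1_5_mean(self):
        spec = AnalyticFieldSpec("poiseuille_planar", 0.2, 0.02, (0.05, 0.02))
        f = make_analytic_field(spec, (11, 41))
        v = f.sample_velocity((0.025, 0.01))
        assert v[0] == pytest.approx(1.5 * 0.2)

    def test_exact_at_nodes(self):
        f = random_field(3)
        for i in (0, 2, 5):
            for j in (0, 4):
                np.testing.assert_allclose(
                    f.sample_velocity((f.x[i], f.y[j])), f.velocity[i, j, 0], atol=1e-14
                )

    def test_outside_domain_is_signal_not_error(self):
        f = random_field(1)
        assert f.sample_velocity((2.0, 0.1)) is None
        assert f.velocity_gradient_at((-0.1, 0.1)) is None

    def test_interpolated_speed_bounded_by_cell_max(self):
        f = random_field(7)
        rng = np.random.default_rng(42)
        speeds = np.linalg.norm(f.velocity[..., 0, :], axis=-1)
        for _ in range(50):
            p = (rng.uniform(0, 1), rng.uniform(0, 0.5))
            v = f.sample_velocity(p)
            assert np.linalg.norm(v) <= speeds.max() + 1e-12

    def test_solid_nodes_must_be_zero(self):
        vel = np.ones((3, 3, 1, 3))
        mask = np.ones((3, 3, 1), dtype=bool)
        mask[1, 1, 0] = False
        with pytest.raises(ValueError):
            StructuredField(x=np.arange(3.0), y=np.arange(3.0), z=np.array([0.0]),
                            velocity=vel, mask=mask)


class TestGradients:
    def test_uniform_gradient_is_zero(self):
        spec = AnalyticFieldSpec("uniform", 1.0, 0.01, (0.05, 0.02))
        f = make_analytic_field(spec, (11, 11))
        np.testing.assert_allclose(f.velocity_gradient_at((0.02, 0.01)), 0.0, atol=1e-12)

    def test_couette_gradient_matches_closed_form(self):
        spec = AnalyticFieldSpec("couette", 0.5, 0.02, (0.05, 0.02))
        f = make_analytic_field(spec, (11, 21))
        g = f.velocity_gradient_at((0.02, 0.011))
        assert g[0, 1] == pytest.approx(0.5 / 0.02, rel=1e-9)
        g_exact = analytic_gradient(spec, 0.02, 0.011)
        np.testing.assert_allclose(g, g_exact, atol=1e-9)

    def test_parabolic_profile_gradient_exact(self):
        # central differences are exact for quadratics, including the
        # one-sided second-order boundary stencils
        spec = AnalyticFieldSpec("poiseuille_tube", 0.3, 0.02, (0.05, 0.02))
        f = make_analytic_field(spec, (6, 21))
        for p in [(0.02, 0.01), (0.02, 0.003), (0.04, 0.02)]:
            g = f.velocity_gradient_at(p)
            g_exact = analytic_gradient(spec, *p)
            np.testing.assert_allclose(g[0, 1], g_exact[0, 1], atol=1e-8)

    def test_gradient_second_order_on_refinement(self):
        # sinusoidal transverse profile: node-gradient error shrinks ~4x per
        # halving of the spacing
        k = 2.0 * np.pi / 0.02
        errs = []
        for n in (21, 41):
            y = np.linspace(0, 0.02, n)
            x = np.linspace(0, 0.05, 4)
            vel = np.zeros((4, n, 1, 3))
            vel[..., 0, 0] = np.sin(k * y)[None, :]
            f = StructuredField(x=x, y=y, z=np.array([0.0]), velocity=vel,
                                mask=np.ones((4, n, 1), bool))
            g = f.velocity_gradient_at((0.02, 0.0052))
            exact = k * np.cos(k * 0.0052)
            errs.append(abs(g[0, 1] - exact))
        assert errs[1] < errs[0] / 2.5

    def test_stagnation_divergence_free(self):
        spec = AnalyticFieldSpec("stagnation", 1.0, 0.01, (0.02, 0.02))
        f = make_analytic_field(spec, (15, 15))
        for p in [(0.003, 0.007), (0.011, 0.015)]:
            g = f.velocity_gradient_at(p)
            assert g[0, 0] + g[1, 1] == pytest.approx(0.0, abs=1e-9)


class TestAnalyticFixtures:
    def test_tube_centerline_is_twice_mean(self):
        spec = AnalyticFieldSpec("poiseuille_tube", 0.3, 0.02, (0.05, 0.02))
        f = make_analytic_field(spec, (5, 41))
        j_center = 20
        assert f.velocity[2, j_center, 0, 0] == pytest.approx(0.6)

    def test_couette_constant_shear_everywhere(self):
        from cathflow.rheology import shear_rate_magnitude

        spec = AnalyticFieldSpec("couette", 0.4, 0.02, (0.05, 0.02))
        f = make_analytic_field(spec, (9, 17))
        rates = [
            shear_rate_magnitude(f.velocity_gradient_at(p))
            for p in [(0.01, 0.003), (0.03, 0.017), (0.049, 0.01)]
        ]
        np.testing.assert_allclose(rates, 0.4 / 0.02, rtol=1e-9)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            AnalyticFieldSpec("vortex", 1.0, 0.01, (0.05, 0.02))


class TestVTKRoundTrip:
    def test_round_trip_random_field(self, tmp_path):
        f = random_field(11)
        path = tmp_path / "field.vtk"
        write_field(path, f)
        g = read_field(path)
        scale = np.abs(f.velocity).max()
        assert np.abs(g.velocity - f.velocity).max() < 1e-10 * scale
        np.testing.assert_array_equal(g.mask, f.mask)
        np.testing.assert_allclose(g.viscosity, f.viscosity, rtol=1e-12)
        np.testing.assert_allclose(g.x, f.x, rtol=1e-15)

    def test_missing_velocity_rejected(self, tmp_path):
        f = random_field(2, nx=3, ny=3)
        path = tmp_path / "field.vtk"
        write_field(path, f)
        text = path.read_text().replace("VECTORS velocity", "VECTORS other")
        path.write_text(text)
        with pytest.raises(VTKParseError, match="velocity"):
            read_field(path)

    def test_malformed_line_named_in_error(self, tmp_path):
        path = tmp_path / "bad.vtk"
        path.write_text("# vtk DataFile Version 3.0\nt\nASCII\nDATASET POLYDATA\n")
        with pytest.raises(VTKParseError, match="line 4"):
            read_field(path)

    def test_reads_minimal_external_fixture(self):
        # a hand-written minimal rectilinear file, as another tool would emit
        from pathlib import Path

        path = Path(__file__).parent / "data" / "minimal_external.vtk"
        f = read_field(path)
        assert f.shape == (3, 2, 1)
        np.testing.assert_allclose(f.velocity[..., 0, 0], 1.0)
        assert f.mask.all()
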