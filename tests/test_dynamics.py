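"""Diffusion coefficients, landscapes, Brownian updates, boundaries."""

import math

import numpy as np
import pytest

from mesobd import dynamics as dyn


class TestDiffusionCoefficients:
    def test_stokes_einstein_value(self, ctx):
        D = dyn.diffusion_coefficient_3d(ctx, 1e-3, 5e-9)
        assert D == pytest.approx(4.3676e-11, rel=1e-3)

    def test_stokes_einstein_scaling(self, ctx):
        D1 = dyn.diffusion_coefficient_3d(ctx, 1e-3, 2e-9)
        D2 = dyn.diffusion_coefficient_3d(ctx, 1e-3, 4e-9)
        assert D1 == pytest.approx(2 * D2, rel=1e-12)
        assert D2 > 0

    def test_saffman_delbrueck_value(self, ctx):
        # mu=1 Pa s, h=5 nm, eta_w=1e-3 Pa s, r=2.5 nm: ln(2000)-gamma = 7.0237
        D = dyn.diffusion_coefficient_membrane(ctx, 1.0, 5e-9, 1e-3, 2.5e-9)
        assert D == pytest.approx(4.602e-13, rel=1e-3)

    def test_saffman_delbrueck_monotone_in_radius(self, ctx):
        radii = np.linspace(1e-9, 20e-9, 10)
        ds = [dyn.diffusion_coefficient_membrane(ctx, 1.0, 5e-9, 1e-3, r) for r in radii]
        assert all(a > b for a, b in zip(ds, ds[1:]))

    def test_saffman_delbrueck_regime_error(self, ctx):
        with pytest.raises(dyn.RegimeError):
            dyn.diffusion_coefficient_membrane(ctx, 1e-4, 5e-9, 1e-3, 50e-9)

    def test_invalid_radius(self, ctx):
        with pytest.raises(ValueError):
            dyn.diffusion_coefficient_3d(ctx, 1e-3, 0.0)


class TestEffectiveLandscape:
    @pytest.mark.parametrize(
        "tags,expected",
        [
            ({"unrestricted", "static"}, "static"),
            ({"unrestricted", "membrane"}, "membrane"),
            ({"membrane", "static"}, "static"),
            ({"above_membrane"}, "above_membrane"),
            ({"above_membrane", "unrestricted"}, "above_membrane"),
            ({"unrestricted"}, "unrestricted"),
            ({"above_membrane", "below_membrane", "membrane"}, "membrane"),
        ],
    )
    def test_precedence(self, tags, expected):
        assert dyn.effective_landscape(tags) == expected

    def test_contradictory_half_spaces(self):
        with pytest.raises(dyn.LandscapeError):
            dyn.effective_landscape({"above_membrane", "below_membrane"})

    def test_empty_set(self):
        with pytest.raises(dyn.LandscapeError):
            dyn.effective_landscape(set())


class TestSampling:
    def test_zero_d_no_displacement(self, rng):
        assert np.all(dyn.sample_displacement(0.0, 1e-4, "unrestricted", rng) == 0)

    def test_static_no_displacement(self, rng):
        assert np.all(dyn.sample_displacement(1e-12, 1e-4, "static", rng) == 0)

    def test_membrane_y_component_exactly_zero(self, rng):
        for _ in range(100):
            d = dyn.sample_displacement(1e-12, 1e-4, "membrane", rng)
            assert d[1] == 0.0

    def test_displacement_variance(self, rng):
        D, dt, n = 1e-12, 1e-4, 100_000
        draws = np.array(
            [dyn.sample_displacement(D, dt, "unrestricted", rng) for _ in range(n // 10)]
        )
        var = draws.var()
        expected = 2 * D * dt
        se = expected * math.sqrt(2.0 / (3 * n // 10))
        assert abs(var - expected) < 3 * se

    def test_static_orientation_identity(self, rng):
        np.testing.assert_array_equal(
            dyn.sample_orientation("static", rng), [1.0, 0, 0, 0]
        )

    def test_membrane_orientation_is_about_y(self, rng):
        for _ in range(50):
            q = dyn.sample_orientation("membrane", rng)
            assert q[1] == 0.0 and q[3] == 0.0

    def test_unrestricted_orientation_uniform(self, rng):
        from mesobd.geometry import qrotate

        n = 10_000
        vecs = np.array(
            [qrotate(dyn.sample_orientation("unrestricted", rng), [0, 0, 1.0]) for _ in range(n)]
        )
        assert np.all(np.abs(vecs.mean(axis=0)) < 3.0 / math.sqrt(n))


class TestBoundaries:
    def _faces(self, kind, L=1e-6):
        cond = dyn.BoundaryConditionSet([(kind, 1.0)])
        out = []
        for axis in range(3):
            for level, sign in ((-L / 2, -1), (L / 2, +1)):
                out.append(
                    dyn.PlaneBoundary(axis=axis, level=level, outward_sign=sign,
                                      conditions=cond, wrap=L)
                )
        return out

    def test_reflective_mirror(self, rng):
        res = dyn.resolve_boundary(
            np.array([0.4e-6, 0, 0]), np.array([0.6e-6, 0, 0]),
            self._faces("reflective"), rng,
        )
        assert res[0] == pytest.approx(0.4e-6)

    def test_periodic_wrap(self, rng):
        res = dyn.resolve_boundary(
            np.array([0.4e-6, 0, 0]), np.array([0.6e-6, 0, 0]),
            self._faces("periodic"), rng,
        )
        assert res[0] == pytest.approx(-0.4e-6)

    def test_absorbing_removes(self, rng):
        res = dyn.resolve_boundary(
            np.array([0.4e-6, 0, 0]), np.array([0.6e-6, 0, 0]),
            self._faces("absorbing"), rng,
        )
        assert res is dyn.ABSORBED

    def test_corner_double_reflection_stays_inside(self, rng):
        res = dyn.resolve_boundary(
            np.array([0.45e-6, 0.45e-6, 0]), np.array([0.55e-6, 0.62e-6, 0]),
            self._faces("reflective"), rng,
        )
        assert np.all(np.abs(res) <= 0.5e-6)

    def test_probabilities_must_normalise(self):
        with pytest.raises(ValueError):
            dyn.BoundaryConditionSet([("open", 0.5), ("reflective", 0.4)])


class TestMembraneDomains:
    def _domains(self):
        return [
            dyn.MembraneDomain(id="big", centre=(0, 0), radius=200e-9, viscosity=1.0),
            dyn.MembraneDomain(id="small", centre=(0, 0), radius=100e-9, viscosity=2.0),
        ]

    def test_innermost_wins(self):
        dom = dyn.membrane_domain_of((0, 0), self._domains())
        assert dom.id == "small"

    def test_point_on_circumference_is_inside(self):
        dom = dyn.membrane_domain_of((100e-9, 0), self._domains())
        assert dom.id == "small"

    def test_none_outside(self):
        assert dyn.membrane_domain_of((1e-6, 1e-6), self._domains()) is None

    def test_equal_radius_tie_break_by_id(self):
        doms = [
            dyn.MembraneDomain(id="b", centre=(0, 0), radius=100e-9, viscosity=1.0),
            dyn.MembraneDomain(id="a", centre=(0, 0), radius=100e-9, viscosity=2.0),
        ]
        assert dyn.membrane_domain_of((0, 0), doms).id == "a"

    def test_reflective_circle_crossing(self, rng):
        dom = dyn.MembraneDomain(
            id="d", centre=(0.0, 0.0), radius=100e-9, viscosity=1.0,
            boundary_out=dyn.BoundaryConditionSet([("reflective", 1.0)]),
        )
        x, z = dyn.resolve_domain_crossing((90e-9, 0.0), (110e-9, 0.0), [dom], rng)
        assert math.hypot(x, z) == pytest.approx(90e-9, rel=1e-9)
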