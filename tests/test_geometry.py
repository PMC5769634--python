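import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blastosim.geometry import (
    Eggshell,
    axes_from_ar,
    contains,
    min_shell_distance,
    nearest_surface_point,
    shell_inward_normal,
)

from .helpers import brute_force_shell_distance

SPHERE_VOLUME_R10 = (4.0 / 3.0) * math.pi * 1000.0


class TestEggshell:
    def test_invariants(self):
        with pytest.raises(ValueError):
            Eggshell(5.0, 10.0)  # lx < ly
        with pytest.raises(ValueError):
            Eggshell(10.0, -1.0)

    def test_properties(self):
        sh = Eggshell(20.0, 10.0)
        assert sh.lz == sh.ly
        assert sh.aspect_ratio == 2.0
        assert sh.volume == pytest.approx((4 / 3) * math.pi * 2000.0)


class TestAxesFromAr:
    def test_sphere_case(self):
        sh = axes_from_ar(1.0, SPHERE_VOLUME_R10)
        assert sh.lx == pytest.approx(10.0, rel=1e-12)
        assert sh.ly == pytest.approx(10.0, rel=1e-12)

    def test_ar2_closed_form(self):
        # ly = (3V / (4 pi ar))^(1/3) = (1000/2)^(1/3)
        sh = axes_from_ar(2.0, SPHERE_VOLUME_R10)
        assert sh.ly == pytest.approx(500.0 ** (1 / 3), rel=1e-12)
        assert sh.lx == pytest.approx(2 * 500.0 ** (1 / 3), rel=1e-12)

    @pytest.mark.parametrize("ar,volume", [(0.5, 1.0), (1.0, 0.0), (1.0, -3.0)])
    def test_invalid_parameters(self, ar, volume):
        with pytest.raises(ValueError):
            axes_from_ar(ar, volume)

    def test_volume_preserved_across_sweep_grid(self):
        for k in range(31):
            ar = 1.0 + 0.1 * k
            sh = axes_from_ar(ar, SPHERE_VOLUME_R10)
            assert abs(sh.volume - SPHERE_VOLUME_R10) / SPHERE_VOLUME_R10 < 1e-12
            assert sh.aspect_ratio == pytest.approx(ar, rel=1e-12)


class TestContains:
    @pytest.mark.parametrize(
        "shell,point,expected",
        [
            (Eggshell(10, 10), (0, 0, 0), True),
            (Eggshell(10, 10), (10, 0, 0), False),  # boundary is outside
            (Eggshell(20, 10), (19, 0, 0), True),
            (Eggshell(20, 10), (0, 10, 0), False),
            (Eggshell(20, 10), (0, 0, -9.99), True),
        ],
    )
    def test_cases(self, shell, point, expected):
        assert contains(shell, np.array(point, dtype=float)) is expected


class TestMinShellDistance:
    def test_sphere_centre(self):
        assert min_shell_distance(Eggshell(10, 10), np.zeros(3)) == pytest.approx(10.0)

    def test_sphere_radial(self):
        d = min_shell_distance(Eggshell(10, 10), np.array([5.0, 0, 0]))
        assert d == pytest.approx(5.0, abs=1e-9)

    def test_ellipsoid_centre_short_axis(self):
        d = min_shell_distance(Eggshell(20, 10), np.zeros(3))
        assert d == pytest.approx(10.0, abs=1e-9)

    def test_derived_interior_point(self):
        # frozen from the dense-surface brute-force oracle
        d = min_shell_distance(Eggshell(20, 10), np.array([15.0, 3.0, 0.0]))
        assert d == pytest.approx(3.0199125196689445, abs=1e-6)

    def test_outside_point_rejected(self):
        with pytest.raises(ValueError):
            min_shell_distance(Eggshell(10, 10), np.array([10.0, 0, 0]))
        with pytest.raises(ValueError):
            min_shell_distance(Eggshell(10, 10), np.array([0.0, 12.0, 0]))

    def test_sphere_limit_closed_form(self):
        rng = np.random.default_rng(7)
        shell = Eggshell(10.0, 10.0)
        for _ in range(1000):
            p = rng.uniform(-1, 1, 3)
            p *= rng.uniform(0, 0.999) * 10.0 / np.linalg.norm(p)
            expected = 10.0 - float(np.linalg.norm(p))
            assert min_shell_distance(shell, p) == pytest.approx(expected, abs=1e-9)

    def test_on_axis_points_prolate(self):
        # includes points below/above the evolute threshold on the x-axis
        shell = Eggshell(20.0, 10.0)
        for x in [0.0, 3.0, 7.5, 14.9, 15.1, 19.5, -19.5, -3.0]:
            p = np.array([x, 0.0, 0.0])
            expected = brute_force_shell_distance(20.0, 10.0, p)
            assert min_shell_distance(shell, p) == pytest.approx(expected, abs=1e-6)

    def test_brute_force_oracle_agreement(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            ar = rng.uniform(1.0, 4.0)
            shell = axes_from_ar(ar, SPHERE_VOLUME_R10)
            p = rng.uniform(-1, 1, 3)
            p /= np.linalg.norm(p)
            # scale to a random fraction of the boundary along this ray
            bound = 1.0 / math.sqrt(
                p[0] ** 2 / shell.lx**2 + (p[1] ** 2 + p[2] ** 2) / shell.ly**2
            )
            p = p * bound * rng.uniform(0.0, 0.999)
            expected = brute_force_shell_distance(shell.lx, shell.ly, p)
            assert min_shell_distance(shell, p) == pytest.approx(expected, abs=1e-6)


class TestInwardNormal:
    def test_sphere_examples(self):
        sh = Eggshell(10, 10)
        np.testing.assert_allclose(
            shell_inward_normal(sh, np.array([5.0, 0, 0])), [-1, 0, 0], atol=1e-12
        )
        np.testing.assert_allclose(
            shell_inward_normal(sh, np.array([0.0, -4.0, 0])), [0, 1, 0], atol=1e-12
        )

    def test_sphere_centre_sentinel(self):
        e = shell_inward_normal(Eggshell(10, 10), np.zeros(3))
        np.testing.assert_allclose(e, [1.0, 0.0, 0.0])

    def test_unit_norm_random(self):
        rng = np.random.default_rng(3)
        shell = Eggshell(25.0, 12.0)
        for _ in range(200):
            p = rng.uniform(-1, 1, 3)
            p /= np.linalg.norm(p)
            bound = 1.0 / math.sqrt(
                p[0] ** 2 / shell.lx**2 + (p[1] ** 2 + p[2] ** 2) / shell.ly**2
            )
            p = p * bound * rng.uniform(0.01, 0.99)
            e = shell_inward_normal(shell, p)
            assert abs(np.linalg.norm(e) - 1.0) < 1e-12

    def test_perpendicular_to_tangent_plane(self):
        rng = np.random.default_rng(11)
        shell = Eggshell(30.0, 12.0)
        for _ in range(100):
            p = rng.uniform(-1, 1, 3)
            p /= np.linalg.norm(p)
            bound = 1.0 / math.sqrt(
                p[0] ** 2 / shell.lx**2 + (p[1] ** 2 + p[2] ** 2) / shell.ly**2
            )
            p = p * bound * rng.uniform(0.05, 0.98)
            s = nearest_surface_point(shell, p)
            e = shell_inward_normal(shell, p)
            grad = np.array(
                [
                    2 * s[0] / shell.lx**2,
                    2 * s[1] / shell.ly**2,
                    2 * s[2] / shell.ly**2,
                ]
            )
            grad /= np.linalg.norm(grad)
            # two independent tangent vectors at the foot point
            t1 = np.cross(grad, [0.0, 0.0, 1.0])
            if np.linalg.norm(t1) < 1e-8:
                t1 = np.cross(grad, [0.0, 1.0, 0.0])
            t1 /= np.linalg.norm(t1)
            t2 = np.cross(grad, t1)
            assert abs(np.dot(e, t1)) < 1e-8
            assert abs(np.dot(e, t2)) < 1e-8

    def test_ellipsoid_derived_direction(self):
        from .helpers import brute_force_shell_foot

        shell = Eggshell(20.0, 10.0)
        p = np.array([15.0, 3.0, 0.0])
        foot = brute_force_shell_foot(20.0, 10.0, p)
        expected = (p - foot) / np.linalg.norm(p - foot)
        np.testing.assert_allclose(shell_inward_normal(shell, p), expected, atol=1e-6)


@settings(max_examples=60, deadline=None)
@given(
    ar=st.floats(1.0, 4.0),
    frac=st.floats(0.0, 0.99),
    direction=st.tuples(
        st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)
    ).filter(lambda v: 1e-3 < math.hypot(*v) <= 2.0),
)
def test_distance_positive_and_bounded(ar, frac, direction):
    shell = axes_from_ar(ar, SPHERE_VOLUME_R10)
    d = np.array(direction) / np.linalg.norm(direction)
    bound = 1.0 / math.sqrt(
        d[0] ** 2 / shell.lx**2 + (d[1] ** 2 + d[2] ** 2) / shell.ly**2
    )
    p = d * bound * frac
    a = min_shell_distance(shell, p)
    assert 0.0 < a <= shell.lx + 1e-9
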