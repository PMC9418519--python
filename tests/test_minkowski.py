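"""Minkowski functionals: analytic oracles, topology, shape finder."""

import numpy as np
import pytest
from scipy.integrate import quad
from skimage.measure import euler_number as sk_euler

import frustule3d as f3
from frustule3d.minkowski import MinkowskiSet, euler_characteristic_2d
from frustule3d.synthetic import generate_primitive


def _single_label(volume):
    return f3.label_components(volume, 26)


class TestEulerCharacteristic:
    def test_ball_torus_shell_topologies_exact(self):
        grid = f3.GridSpec((64, 64, 64), 1.0)
        ball, _ = generate_primitive("ball", grid, center=(32, 32, 32), radius=20)
        shell, _ = generate_primitive(
            "hollow_shell", grid, center=(32, 32, 32), outer_radius=20, inner_radius=12
        )
        torus, _ = generate_primitive(
            "torus", grid, center=(32, 32, 32), ring_radius=18, tube_radius=7
        )
        assert f3.euler_characteristic(ball.data) == 1
        assert f3.euler_characteristic(shell.data) == 2
        assert f3.euler_characteristic(torus.data) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_estimator_on_random_volumes(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((12, 12, 12)) < 0.35
        assert f3.euler_characteristic(mask) == sk_euler(mask, connectivity=3)

    def test_2d_euler_of_ring_is_zero(self):
        ring = np.ones((7, 7), dtype=bool)
        ring[2:5, 2:5] = False
        ring[3, 3] = False
        assert euler_characteristic_2d(ring) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_2d_matches_independent_estimator(self, seed):
        rng = np.random.default_rng(100 + seed)
        mask = rng.random((16, 16)) < 0.4
        assert euler_characteristic_2d(mask) == sk_euler(mask, connectivity=2)


class TestSurfaceAndCurvature:
    @pytest.mark.parametrize("radius", [15, 20, 25])
    def test_ball_surface_within_3pct(self, radius):
        n = 2 * radius + 24
        grid = f3.GridSpec((n, n, n), 1.0)
        c = n // 2
        ball, _ = generate_primitive("ball", grid, center=(c, c, c), radius=radius)
        s = f3.surface_area(ball.data, 1.0)
        assert s == pytest.approx(4 * np.pi * radius**2, rel=0.03)

    def test_ball_mean_curvature_integral(self):
        grid = f3.GridSpec((64, 64, 64), 1.0)
        ball, _ = generate_primitive("ball", grid, center=(32, 32, 32), radius=20)
        h = f3.integral_mean_curvature(ball.data, 1.0)
        assert h == pytest.approx(4 * np.pi * 20, rel=0.05)

    def test_functionals_invariant_under_translation_and_rotation(self):
        grid = f3.GridSpec((48, 48, 48), 1.0)
        vol, _ = generate_primitive(
            "ellipsoid", grid, center=(24, 24, 24), semi_axes=(7, 10, 14)
        )
        base = (
            f3.surface_area(vol.data),
            f3.integral_mean_curvature(vol.data),
            f3.euler_characteristic(vol.data),
        )
        shifted = np.roll(vol.data, (3, -2, 5), axis=(0, 1, 2))
        rotated = np.rot90(vol.data, k=1, axes=(1, 2))
        for other in (shifted, rotated):
            assert f3.surface_area(other) == pytest.approx(base[0], rel=1e-12)
            assert f3.integral_mean_curvature(other) == pytest.approx(base[1], rel=1e-12)
            assert f3.euler_characteristic(other) == base[2]

    def test_prolate_spheroid_against_closed_forms(self):
        a, c = 6.0, 30.0  # semi-axes (a, a, c), elongated along x
        grid = f3.GridSpec((20, 20, 72), 1.0)
        vol, _ = generate_primitive(
            "ellipsoid", grid, center=(10, 10, 36), semi_axes=(a, a, c)
        )
        e = np.sqrt(1 - (a / c) ** 2)
        s_true = 2 * np.pi * a**2 * (1 + (c / (a * e)) * np.arcsin(e))

        def h_integrand(theta):
            # principal curvatures of a spheroid parameterized by theta
            g = np.sqrt(a**2 * np.cos(theta) ** 2 + c**2 * np.sin(theta) ** 2)
            k_mer = a * c / g**3
            k_par = c / (a * g)
            dA = 2 * np.pi * a * np.sin(theta) * g
            return 0.5 * (k_mer + k_par) * dA

        h_true, _ = quad(h_integrand, 0.0, np.pi)
        assert f3.surface_area(vol.data) == pytest.approx(s_true, rel=0.04)
        assert f3.integral_mean_curvature(vol.data) == pytest.approx(h_true, rel=0.15)


class TestMinkowskiFunctionals:
    def test_ball_v0_exact_s_within_3pct_chi_one(self, ball_r20):
        volume, _ = ball_r20
        labels = _single_label(volume)
        m = f3.minkowski_functionals(labels, 1)
        assert m.v0 == volume.pore_voxels * 1.0
        assert m.v0 == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.01)
        assert m.surface == pytest.approx(4 * np.pi * 20**2, rel=0.03)
        assert m.v3 == 1
        assert m.v1 == pytest.approx(m.surface / 6)
        assert m.v2 == pytest.approx(m.curvature / (3 * np.pi))

    def test_physical_units_scale_with_voxel_size(self, ball_r20):
        volume, _ = ball_r20
        scaled = f3.BinaryVolume(volume.data, f3.GridSpec(volume.shape, 2.0))
        m1 = f3.minkowski_functionals(_single_label(volume), 1)
        m2 = f3.minkowski_functionals(_single_label(scaled), 1)
        assert m2.v0 == pytest.approx(8 * m1.v0)
        assert m2.surface == pytest.approx(4 * m1.surface)
        assert m2.curvature == pytest.approx(2 * m1.curvature)
        assert m2.v3 == m1.v3

    def test_missing_label_rejected(self, ball_r20):
        volume, _ = ball_r20
        labels = _single_label(volume)
        with pytest.raises(ValueError, match="label"):
            f3.minkowski_functionals(labels, 5)


class TestShapeFinder:
    def test_ideal_sphere_has_zero_planarity_and_filamentarity(self):
        r = 7.0
        m = MinkowskiSet(
            label=1, voxel_count=0,
            v0=4 / 3 * np.pi * r**3, v1=4 * np.pi * r**2 / 6, v2=4 * r / 3, v3=1,
            surface=4 * np.pi * r**2, curvature=4 * np.pi * r, touches_boundary=False,
        )
        sf = f3.shape_finder(m)
        assert sf.x == pytest.approx(1.0)
        assert sf.y == pytest.approx(1.0)
        assert sf.planarity == pytest.approx(0.0, abs=1e-12)
        assert sf.filamentarity == pytest.approx(0.0, abs=1e-12)

    def test_unit_functionals_hand_evaluated(self):
        m = MinkowskiSet(1, 0, 1.0, 1.0, 1.0, 1, 6.0, 3 * np.pi, False)
        sf = f3.shape_finder(m)
        assert sf.x == pytest.approx(np.pi / 4)
        assert sf.planarity == pytest.approx((1 - np.pi / 4) / (1 + np.pi / 4))
        assert sf.planarity == pytest.approx(0.1202, abs=2e-4)
        assert sf.y == pytest.approx(8 / (3 * np.pi))
        assert sf.filamentarity == pytest.approx(0.0818, abs=2e-4)

    def test_prolate_spheroid_more_filamentary_than_planar(self):
        grid = f3.GridSpec((18, 18, 110), 1.0)
        vol, _ = generate_primitive(
            "ellipsoid", grid, center=(9, 9, 55), semi_axes=(5, 5, 50)
        )
        m = f3.minkowski_functionals(_single_label(vol), 1)
        sf = f3.shape_finder(m)
        assert sf.filamentarity > sf.planarity
        assert sf.filamentarity > 0.1

    def test_non_positive_v1_or_v2_rejected(self):
        bad = MinkowskiSet(1, 0, 1.0, 0.0, 1.0, 1, 0.0, 3 * np.pi, False)
        with pytest.raises(ValueError, match="V1"):
            f3.shape_finder(bad)
        bad2 = MinkowskiSet(1, 0, 1.0, 1.0, -0.5, 1, 6.0, -1.0, False)
        with pytest.raises(ValueError, match="V2"):
            f3.shape_finder(bad2)

    def test_forced_euler_keeps_measured_chi_available(self):
        grid = f3.GridSpec((64, 64, 64), 1.0)
        shell, _ = generate_primitive(
            "hollow_shell", grid, center=(32, 32, 32), outer_radius=20, inner_radius=12
        )
        m = f3.minkowski_functionals(_single_label(shell), 1)
        assert m.v3 == 2
        forced = f3.shape_finder(m, force_euler_one=True)
        free = f3.shape_finder(m, force_euler_one=False)
        assert free.y == pytest.approx(2 * forced.y)


class TestFPDiagram:
    def test_ball_field_cloud_centred_near_origin(self, ball_field):
        labels = f3.label_components(ball_field, 26)
        table, summary = f3.fp_diagram(labels)
        assert summary["n_in_diagram"] >= 10
        assert abs(summary["F_centroid"]) < 0.05
        assert abs(summary["P_centroid"]) < 0.05

    def test_elongated_field_filamentarity_dominates(self, nanopore_field):
        volume, _ = nanopore_field
        labels = f3.label_components(volume, 26)
        table, summary = f3.fp_diagram(labels)
        assert summary["F_centroid"] > summary["P_centroid"]
        assert summary["n_undefined"] + summary["n_in_diagram"] >= 1
        # every label appears in the table, defined or not
        assert len(table) == labels.n_labels

    def test_single_label_one_row(self, ball_r20):
        volume, _ = ball_r20
        table, summary = f3.fp_diagram(_single_label(volume))
        assert len(table) == 1
        assert summary["n_labels"] == 1

    def test_v0_agrees_with_voxel_count_conservation(self, ball_field):
        labels = f3.label_components(ball_field, 26)
        table, _ = f3.fp_diagram(labels)
        total_v0 = table.V0.sum()
        assert total_v0 == pytest.approx(ball_field.pore_voxels * 1.0)
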