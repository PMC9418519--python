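"""Porosity fractions, Prob(v), layer metrology, chambers and connectivity."""

import numpy as np
import pytest

import frustule3d as f3
from frustule3d.synthetic import generate_primitive


class TestPorosityFraction:
    def test_all_void_is_one(self):
        binary = f3.BinaryVolume(np.ones((6, 6, 6), bool), f3.GridSpec((6, 6, 6), 1.0))
        assert f3.porosity_fraction(binary) == 1.0

    def test_checkerboard_is_half(self):
        idx = np.indices((8, 8, 8)).sum(axis=0)
        binary = f3.BinaryVolume(idx % 2 == 0, f3.GridSpec((8, 8, 8), 1.0))
        assert f3.porosity_fraction(binary) == 0.5

    def test_nanopore_fixture_recovers_target(self, nanopore_field):
        volume, truth = nanopore_field
        assert f3.porosity_fraction(volume) == pytest.approx(1.9e-3, rel=0.10)
        assert f3.porosity_fraction(volume) == pytest.approx(
            truth.total_pore_voxels / volume.grid.n_voxels
        )

    def test_empty_mask_rejected(self):
        binary = f3.BinaryVolume(np.ones((4, 4, 4), bool), f3.GridSpec((4, 4, 4), 1.0))
        with pytest.raises(ValueError, match="mask"):
            f3.porosity_fraction(binary, mask=np.zeros((4, 4, 4), bool))


class TestPoreVolumeDistribution:
    def _labels_of_cubes(self, sides, voxel_size=1.0):
        n = 4 * sum(sides)
        data = np.zeros((n, 12, 12), dtype=np.int32)
        z0 = 1
        for k, s in enumerate(sides, start=1):
            data[z0 : z0 + s, 1 : 1 + s, 1 : 1 + s] = k
            z0 += s + 2
        return f3.LabeledVolume(
            data, f3.GridSpec(data.shape, voxel_size), n_labels=len(sides)
        )

    def test_three_cube_support_and_equal_mass(self):
        labels = self._labels_of_cubes([2, 3, 4])  # volumes 8, 27, 64
        dist = f3.pore_volume_distribution(labels)
        assert dist.count == 3
        assert sorted(dist.volumes_nm3) == [8.0, 27.0, 64.0]
        # density integrates to one over the log-spaced support
        widths = np.diff(dist.bin_edges_nm3)
        assert (dist.density * widths).sum() == pytest.approx(1.0)
        # each pore carries mass 1/3
        occupied = dist.density[dist.density > 0] * widths[dist.density > 0]
        assert np.allclose(occupied, 1 / 3)

    def test_duplication_leaves_density_invariant(self):
        a = self._labels_of_cubes([2, 3, 4])
        b = self._labels_of_cubes([2, 3, 4, 2, 3, 4])
        da = f3.pore_volume_distribution(a)
        db = f3.pore_volume_distribution(b)
        assert db.count == 2 * da.count
        assert np.allclose(da.density, db.density)

    def test_volumes_scale_with_voxel_size(self):
        dist = f3.pore_volume_distribution(self._labels_of_cubes([2], voxel_size=3.0))
        assert dist.volumes_nm3[0] == pytest.approx(8 * 27.0)

    def test_empty_labelling_flagged(self):
        labels = f3.LabeledVolume(
            np.zeros((4, 4, 4), np.int32), f3.GridSpec((4, 4, 4), 1.0), n_labels=0
        )
        with pytest.raises(ValueError, match="empty"):
            f3.pore_volume_distribution(labels)

    def test_nanopore_volumes_within_generator_envelope(self, nanopore_field):
        volume, _ = nanopore_field
        labels = f3.label_components(volume, 26)
        dist = f3.pore_volume_distribution(labels)
        # voxelization scatters individual volumes around the analytic ones;
        # the envelope check allows one voxel-quantization step of slack
        assert dist.volumes_nm3.min() >= 10.0 * 0.5
        assert dist.volumes_nm3.max() <= 1000.0 * 1.2


class TestEquivalentSize:
    @pytest.mark.parametrize("v,expected", [(1000.0, 10.0), (1.0, 1.0), (27.0, 3.0)])
    def test_cube_root(self, v, expected):
        assert f3.equivalent_size(v) == pytest.approx(expected)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            f3.equivalent_size(0.0)


class TestLayerDetection:
    def test_uniform_slab_profile_constant(self):
        grid = f3.GridSpec((20, 10, 10), 1.0)
        volume, _ = generate_primitive("slab", grid, axis=0, start=5, thickness=10)
        profile = f3.solid_fraction_profile(volume, axis=0)
        assert np.all(profile[5:15] == 0.0)
        assert np.all(profile[:5] == 1.0)

    def test_all_void_profile_is_zero(self):
        binary = f3.BinaryVolume(np.ones((6, 4, 4), bool), f3.GridSpec((6, 4, 4), 1.0))
        assert np.all(f3.solid_fraction_profile(binary, 0) == 0.0)

    def test_two_porosity_stack_single_boundary(self):
        m = np.zeros((40, 32, 32), bool)
        m[:20][:, ::2, :] = True       # porosity 0.5
        m[20:][:, ::4, ::2] = True     # porosity 0.125
        binary = f3.BinaryVolume(m, f3.GridSpec((40, 32, 32), 1.0))
        layers = f3.detect_layer_boundaries(binary, smoothing_nm=3)
        assert len(layers.boundaries) == 1
        assert abs(layers.boundaries[0] - 20) <= 1

    def test_uniform_block_reports_no_layering(self):
        binary = f3.BinaryVolume(np.zeros((20, 8, 8), bool), f3.GridSpec((20, 8, 8), 1.0))
        with pytest.raises(ValueError, match="no layering"):
            f3.detect_layer_boundaries(binary)

    def test_frustule_boundaries_within_two_slices(self, frustule_fib):
        _, volume, truth = frustule_fib
        layers = f3.detect_layer_boundaries(volume, axis=0)
        expected = list(truth.layer_boundaries.values())
        assert len(layers.boundaries) == 2
        for found, true in zip(layers.boundaries, expected):
            assert abs(found - true) <= 2
        assert layers.names == ["foramen", "areola", "cribrum"]

    def test_frustule_layer_porosities_match_truth(self, frustule_fib):
        _, volume, truth = frustule_fib
        layers = f3.detect_layer_boundaries(volume, axis=0)
        for name, true_p in truth.layer_porosity.items():
            got = layers.porosities[layers.layer_index(name)]
            assert got == pytest.approx(true_p, abs=0.03)


class TestCombineTotalPorosity:
    def test_equal_thickness_extremes_average_to_half(self):
        layers = f3.LayerModel(0, [5], ["a", "b"], [10.0, 10.0], [0.0, 1.0], 1.0)
        assert f3.combine_total_porosity(layers) == pytest.approx(0.5)

    def test_single_layer_returns_own_porosity(self):
        layers = f3.LayerModel(0, [], ["only"], [7.0], [0.42], 1.0)
        assert f3.combine_total_porosity(layers) == pytest.approx(0.42)

    def test_measured_layer_triple_under_thickness_weighting(self):
        # 180 nm at 33%, 200 nm at 27%, 2500 nm at 78%: the weighted mean is
        # 71.6% — notably above the ~64% sometimes quoted for the same
        # triple, whose combination rule is not thickness weighting
        layers = f3.LayerModel(
            0, [1, 2], ["foramen", "cribrum", "areola"],
            [180.0, 200.0, 2500.0], [0.33, 0.27, 0.78], 1.0,
        )
        assert f3.combine_total_porosity(layers) == pytest.approx(0.7165, abs=5e-4)

    def test_conservation_when_layers_tile_axis(self, frustule_fib):
        _, volume, _ = frustule_fib
        layers = f3.detect_layer_boundaries(volume, axis=0)
        assert f3.combine_total_porosity(layers) == pytest.approx(
            f3.porosity_fraction(volume), abs=1e-12
        )

    def test_zero_thickness_rejected(self):
        layers = f3.LayerModel(0, [], ["x"], [0.0], [0.5], 1.0)
        with pytest.raises(ValueError):
            f3.combine_total_porosity(layers)


class TestChamberMetrics:
    def test_synthetic_cylinder_dimensions_recovered(self):
        grid = f3.GridSpec((40, 48, 48), 1.0)
        volume, _ = generate_primitive(
            "cylinder", grid, center=(20, 24, 24), radius=20, length=30, axis=0
        )
        labels = f3.label_components(volume, 26)
        table = f3.chamber_metrics(labels, mid_slice=20)
        row = table.iloc[0]
        assert row.mid_diameter_nm == pytest.approx(40.0, abs=1.0)
        assert row.height_nm == pytest.approx(30.0, abs=1.0)

    def test_chamber_table_matches_frustule_truth(self, frustule_chambers):
        _, labels, truth = frustule_chambers
        nz = labels.data.shape[0]
        table = f3.chamber_metrics(labels, mid_slice=nz // 2)
        assert len(table) == 7
        got = np.sort(table.mid_diameter_nm.values)
        want = np.sort(truth.objects.mid_diameter_nm.values)
        assert np.allclose(got, want, rtol=0.02)
        assert np.allclose(table.height_nm, truth.objects.height_nm.iloc[0], rtol=0.02)

    def test_chamber_missing_midplane_flagged(self):
        data = np.zeros((10, 8, 8), np.int32)
        data[1:3, 2:5, 2:5] = 1   # low chamber, absent at mid-plane
        data[4:9, 2:5, 2:5] = 2   # spans the mid-plane
        labels = f3.LabeledVolume(data, f3.GridSpec((10, 8, 8), 1.0), n_labels=2)
        table = f3.chamber_metrics(labels, mid_slice=5)
        assert not table[table.label == 1].at_mid_plane.iloc[0]
        assert table[table.label == 2].at_mid_plane.iloc[0]


class TestConnectivityGraph:
    def test_two_chambers_with_cylindrical_throat(self):
        m = np.zeros((50, 24, 24), dtype=bool)
        z, y, x = np.ogrid[:50, :24, :24]
        m |= (z >= 2) & (z < 20) & ((y - 12) ** 2 + (x - 12) ** 2 <= 81)
        m |= (z >= 30) & (z < 48) & ((y - 12) ** 2 + (x - 12) ** 2 <= 81)
        m |= (
            (z >= 20) & (z < 30) & ((y - 12) ** 2 + (x - 12) ** 2 <= 25)
        )  # throat D=10
        binary = f3.BinaryVolume(m, f3.GridSpec((50, 24, 24), 1.0))
        labels = f3.watershed_separate(binary, h_min_nm=2.0)
        assert labels.n_labels == 2
        graph = f3.connectivity_graph(labels, binary)
        assert graph.n_edges == 1
        assert graph.edges.throat_diameter_nm.iloc[0] == pytest.approx(10.0, abs=1.0)

    def test_isolated_chambers_have_no_edges(self, nanopore_field):
        volume, _ = nanopore_field
        labels = f3.label_components(volume, 26)
        graph = f3.connectivity_graph(labels, volume)
        assert graph.n_edges == 0

    def test_frustule_throats_near_140nm(self, frustule_chambers):
        _, labels, truth = frustule_chambers
        graph = f3.connectivity_graph(labels)
        assert graph.n_edges == len(truth.adjacency)
        mean_throat = graph.edges.throat_diameter_nm.mean()
        assert mean_throat == pytest.approx(140.0, rel=0.15)
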