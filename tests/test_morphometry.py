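"""Volume, surface-area, soma, skeleton and Sholl measurement tests."""

import numpy as np
import pytest

from astromorph import (
    instance_surface_area,
    instance_volume,
    measure_all,
    sholl_profile,
    skeletonize_cell,
    soma_volume,
)
from astromorph.errors import AstromorphError, ConfigurationError, DisconnectedMaskError
from astromorph.grid import LabelVolume
from astromorph.morphometry import skeleton_census
from astromorph.synthgen import SkeletonTree

from helpers import digital_ball, tube_mask


def as_labels(mask, spacing):
    return LabelVolume(mask.astype(np.int32), spacing)


class TestVolume:
    def test_single_voxel_unit_spacing(self):
        arr = np.zeros((3, 3, 3), dtype=np.int32)
        arr[1, 1, 1] = 1
        assert instance_volume(LabelVolume(arr, (1, 1, 1)), 1) == 1.0

    def test_anisotropic_voxel_volume(self):
        arr = np.zeros((3, 5, 5), dtype=np.int32)
        arr[1, 1, :5] = 1
        arr[1, 2, :5] = 1
        vol = instance_volume(LabelVolume(arr, (1.0, 0.28, 0.28)), 1)
        assert vol == pytest.approx(10 * 1.0 * 0.28 * 0.28)

    def test_digital_sphere_volume_within_3pct(self):
        mask, vol, _ = digital_ball(10.0, 0.5)
        measured = instance_volume(as_labels(mask, (0.5, 0.5, 0.5)), 1)
        assert abs(measured - vol) / vol < 0.03

    def test_absent_id_raises(self):
        arr = np.zeros((3, 3, 3), dtype=np.int32)
        arr[1, 1, 1] = 1
        with pytest.raises(KeyError):
            instance_volume(LabelVolume(arr, (1, 1, 1)), 2)


class TestSurfaceArea:
    def test_digital_sphere_area_within_10pct(self):
        mask, _, area = digital_ball(10.0, 0.5)
        measured = instance_surface_area(as_labels(mask, (0.5, 0.5, 0.5)), 1)
        assert abs(measured - area) / area < 0.10

    def test_cube_area_within_5pct(self):
        mask = np.zeros((30, 30, 30), dtype=bool)
        mask[5:25, 5:25, 5:25] = True  # 10 um side at 0.5 um voxels
        measured = instance_surface_area(as_labels(mask, (0.5, 0.5, 0.5)), 1)
        assert abs(measured - 600.0) / 600.0 < 0.05

    def test_axis_permutation_invariance(self):
        mask = np.zeros((20, 26, 32), dtype=bool)
        mask[4:16, 5:22, 6:28] = True
        spacing = (1.0, 0.6, 0.4)
        a = instance_surface_area(as_labels(mask, spacing), 1)
        perm = (2, 0, 1)
        b = instance_surface_area(
            as_labels(np.transpose(mask, perm), tuple(spacing[i] for i in perm)), 1)
        assert abs(a - b) / a < 0.001

    def test_scale_equivariance(self):
        mask, _, _ = digital_ball(6.0, 0.5)
        a1 = instance_surface_area(as_labels(mask, (0.5, 0.5, 0.5)), 1)
        a2 = instance_surface_area(as_labels(mask, (1.0, 1.0, 1.0)), 1)
        v1 = instance_volume(as_labels(mask, (0.5, 0.5, 0.5)), 1)
        v2 = instance_volume(as_labels(mask, (1.0, 1.0, 1.0)), 1)
        assert a2 / a1 == pytest.approx(4.0, rel=0.01)
        assert v2 / v1 == pytest.approx(8.0, rel=1e-12)

    def test_mesh_refinement_reduces_sphere_error(self):
        coarse, _, area = digital_ball(10.0, 1.0)
        fine, _, _ = digital_ball(10.0, 0.5)
        e_coarse = abs(instance_surface_area(as_labels(coarse, (1, 1, 1)), 1) - area) / area
        e_fine = abs(instance_surface_area(as_labels(fine, (0.5, 0.5, 0.5)), 1) - area) / area
        assert e_fine < e_coarse

    def test_planar_instance_rejected(self):
        arr = np.zeros((6, 6, 6), dtype=np.int32)
        arr[3, 1:5, 1:5] = 1
        with pytest.raises(AstromorphError, match="axis 0"):
            instance_surface_area(LabelVolume(arr, (1, 1, 1)), 1)


class TestSomaVolume:
    def test_sphere_only_equals_instance_volume(self):
        mask, _, _ = digital_ball(5.0, 0.5)
        lab = as_labels(mask, (0.5, 0.5, 0.5))
        center = np.array(mask.shape) * 0.5 / 2
        # identity up to the sub-voxel boundary shell of discrete opening
        assert soma_volume(lab, 1, center, 2.0) == pytest.approx(
            instance_volume(lab, 1), rel=0.05)

    def test_opening_removes_thin_process(self):
        shape = (40, 80, 40)
        spacing = (0.5, 0.5, 0.5)
        coords = np.stack(np.indices(shape), axis=-1) * 0.5
        sph = np.linalg.norm(coords - np.array([10.0, 10.0, 10.0]), axis=-1) <= 5.0
        proc = tube_mask(shape, spacing, (10, 10, 10), (10, 35, 10), 0.8)
        lab = as_labels(sph | proc, spacing)
        sv = soma_volume(lab, 1, (10.0, 10.0, 10.0), 2.0)
        sphere_vol = float(sph.sum()) * 0.125
        assert abs(sv - sphere_vol) / sphere_vol < 0.10

    def test_opening_radius_zero_is_identity(self):
        mask, _, _ = digital_ball(4.0, 0.5)
        lab = as_labels(mask, (0.5, 0.5, 0.5))
        center = np.array(mask.shape) * 0.5 / 2
        assert soma_volume(lab, 1, center, 0.0) == instance_volume(lab, 1)

    def test_center_outside_instance_rejected(self):
        mask, _, _ = digital_ball(4.0, 0.5)
        lab = as_labels(mask, (0.5, 0.5, 0.5))
        with pytest.raises(ConfigurationError):
            soma_volume(lab, 1, (0.0, 0.0, 0.0), 2.0)


class TestSkeleton:
    def test_cylinder_is_single_path(self):
        shape = (20, 70, 20)
        cyl = tube_mask(shape, (0.5, 0.5, 0.5), (5, 2, 5), (5, 32, 5), 2.0)
        g = skeletonize_cell(cyl, (0.5, 0.5, 0.5))
        endpoints, junctions = skeleton_census(g)
        assert endpoints == 2
        assert junctions == 0

    def test_y_tube_has_one_junction_three_tips(self):
        shape = (20, 60, 60)
        sp = (0.5, 0.5, 0.5)
        y = (tube_mask(shape, sp, (5, 2, 15), (5, 14, 15), 1.5)
             | tube_mask(shape, sp, (5, 14, 15), (5, 26, 7), 1.5)
             | tube_mask(shape, sp, (5, 14, 15), (5, 26, 23), 1.5))
        endpoints, junctions = skeleton_census(skeletonize_cell(y, sp))
        assert endpoints == 3
        assert junctions == 1

    def test_single_voxel_skeleton(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        g = skeletonize_cell(mask, (1, 1, 1))
        assert g.number_of_nodes() == 1
        assert skeleton_census(g) == (1, 0)

    def test_disconnected_mask_rejected(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1, 1, 1] = True
        mask[4, 4, 4] = True
        with pytest.raises(DisconnectedMaskError) as exc:
            skeletonize_cell(mask, (1, 1, 1))
        assert exc.value.n_components == 2


class TestSholl:
    def make_star(self, k, length):
        dirs = [np.array(d, dtype=float) for d in
                [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]][:k]
        nodes = [np.zeros(3)] + [d * length for d in dirs]
        parents = [-1] + [0] * k
        radii = [1.0] * (k + 1)
        return SkeletonTree(np.array(nodes), np.array(parents), np.array(radii),
                            np.zeros(3), 3.0)

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_radial_star_counts_equal_arm_count(self, k):
        profile = sholl_profile(self.make_star(k, 20.0), (0, 0, 0), 2.0, 30.0)
        for r, c in zip(profile.radii_um, profile.counts):
            assert c == (k if r <= 20.0 else 0)

    def test_bifurcation_steps_from_one_to_two(self):
        nodes = np.array([[0, 0, 0], [0, 10, 0], [0, 16, 12], [0, 16, -12]], dtype=float)
        tree = SkeletonTree(nodes, np.array([-1, 0, 1, 1]),
                            np.array([1.0, 1.0, 0.5, 0.5]), np.zeros(3), 3.0)
        profile = sholl_profile(tree, (0, 0, 0), 2.0, 20.0)
        expected = {r: (1 if r <= 10 else 2) for r in range(2, 21, 2)}
        assert dict(zip(profile.radii_um, profile.counts)) == expected

    def test_empty_skeleton_gives_zero_counts(self):
        import networkx as nx

        profile = sholl_profile(nx.Graph(), (0, 0, 0), 2.0, 10.0)
        assert profile.counts.sum() == 0
        assert len(profile.radii_um) == 5

    def test_counts_match_edge_straddle_enumeration(self, rng):
        """Crossing counts equal an exhaustive per-edge straddle count."""
        from astromorph.synthgen import SimulationConfig, sample_tree

        tree = sample_tree(SimulationConfig(), np.array([40.0, 40.0, 40.0]), rng)
        profile = sholl_profile(tree, tree.soma_center, 2.0, 30.0)
        segs = tree.edge_segments_um()
        for r, c in zip(profile.radii_um, profile.counts):
            manual = 0
            for s in segs:
                d0 = np.linalg.norm(s[0] - tree.soma_center)
                d1 = np.linalg.norm(s[1] - tree.soma_center)
                if min(d0, d1) < r <= max(d0, d1):
                    manual += 1
            assert c == manual

    def test_rmax_below_step_rejected(self):
        with pytest.raises(ConfigurationError):
            sholl_profile(self.make_star(2, 10.0), (0, 0, 0), 2.0, 1.0)


class TestMeasureAll:
    def test_interior_measured_edge_excluded(self):
        from astromorph import rasterize, render, SimulationConfig
        from test_synthgen import soma_only_tree

        trees = [
            soma_only_tree((10.0, 15.0, 15.0), 5.0),
            soma_only_tree((10.0, 15.0, 50.0), 5.0),
            soma_only_tree((10.0, 45.0, 15.0), 5.0),
            soma_only_tree((10.0, 45.0, 57.0), 5.0),  # touches the lateral face
        ]
        labels, cells = rasterize(trees, (20, 60, 62), (1.0, 1.0, 1.0))
        assert [c.touches_edge for c in cells] == [False, False, False, True]
        cfg = SimulationConfig(psf_sigma_um=(0, 0, 0), noise_sd=0.0)
        grid = render(labels, cfg, 0)
        records, sholl = measure_all(labels, grid, edge_margin=(0, 1, 1))
        assert int(records.excluded.sum()) == 1
        measured = records[~records.excluded]
        assert len(measured) == 3
        assert (measured.volume_um3 > 0).all()
        assert (measured.soma_um3 <= measured.volume_um3).all()
        # volume additivity over retained instances
        from astromorph.instance import exclude_edge_instances

        kept, _ = exclude_edge_instances(labels, (0, 1, 1))
        total_fg = np.count_nonzero(kept.labels) * kept.voxel_volume_um3
        assert measured.volume_um3.sum() == pytest.approx(total_fg, rel=1e-9)

    def test_empty_labels_give_empty_tables(self):
        from astromorph.grid import VoxelGrid

        lab = LabelVolume(np.zeros((6, 6, 6), dtype=np.int32), (1, 1, 1))
        grid = VoxelGrid(np.ones((6, 6, 6)), (1, 1, 1))
        records, sholl = measure_all(lab, grid)
        assert list(records.columns)[:5] == [
            "cell_id", "sample_id", "volume_um3", "area_um2", "soma_um3"]
        assert len(records) == 0 and len(sholl) == 0

    def test_spacing_mismatch_rejected(self):
        from astromorph.grid import VoxelGrid

        lab = LabelVolume(np.zeros((6, 6, 6), dtype=np.int32), (1, 1, 1))
        grid = VoxelGrid(np.ones((6, 6, 6)), (2, 1, 1))
        with pytest.raises(ConfigurationError):
            measure_all(lab, grid)
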