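"""Voxel envelopes: volume/area oracles, axes, per-domain decomposition."""

import numpy as np
import pytest

from trimerbody import (
    BeadModel,
    DomainLabel,
    OccupancyGrid,
    envelope_axes,
    envelope_volume,
    surface_area,
    symmetry_stats,
    union_grids,
    voxelize,
)
from trimerbody.envelope_metrics import LatticeMismatchError
from trimerbody.structure_io import EmptySelectionError


def ball_grid(radius, spacing):
    model = BeadModel.from_arrays(
        np.zeros((1, 3)), radius, "A", DomainLabel.PAYLOAD_N
    )
    return voxelize(model, spacing=spacing, padding=radius / 4 + 3, probe_radius=0.0)


def single_voxel_grid(spacing=1.0):
    cells = np.zeros((5, 5, 5), dtype=bool)
    cells[2, 2, 2] = True
    return OccupancyGrid(origin=np.zeros(3), spacing=spacing, cells=cells)


class TestVoxelize:
    def test_ball_volume_analytic(self):
        grid = ball_grid(10.0, 1.0)
        expected = 4.0 / 3.0 * np.pi * 10.0**3
        assert abs(envelope_volume(grid) - expected) / expected < 0.03

    def test_volume_converges_under_refinement(self):
        coarse = envelope_volume(ball_grid(20.0, 2.0))
        fine = envelope_volume(ball_grid(20.0, 1.0))
        assert abs(fine - coarse) / fine < 0.01

    def test_bounds_enclose_beads(self, sphere_payload):
        grid = voxelize(sphere_payload.model, spacing=2.0, padding=10.0)
        lo = grid.origin - grid.spacing / 2
        hi = grid.origin + (np.array(grid.dims) - 0.5) * grid.spacing
        assert np.all(sphere_payload.model.positions > lo)
        assert np.all(sphere_payload.model.positions < hi)

    def test_missing_label_rejected(self, sphere_payload):
        with pytest.raises(EmptySelectionError):
            voxelize(sphere_payload.model, label_filter={DomainLabel.CORE})

    def test_invalid_spacing_rejected(self, sphere_payload):
        with pytest.raises(ValueError):
            voxelize(sphere_payload.model, spacing=0.0)


class TestSurfaceArea:
    def test_empty_grid_has_zero_area(self):
        grid = OccupancyGrid(
            origin=np.zeros(3), spacing=1.0, cells=np.zeros((4, 4, 4), dtype=bool)
        )
        assert surface_area(grid) == 0.0

    def test_ball_area_analytic(self):
        grid = ball_grid(20.0, 1.0)
        expected = 4.0 * np.pi * 20.0**2
        assert abs(surface_area(grid) - expected) / expected < 0.05

    def test_box_area_analytic(self):
        # solid 40 x 40 x 20 box: area 2(40*40 + 40*20 + 40*20) = 6400
        ax = np.arange(-23, 23) + 0.5
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        cells = (np.abs(gx) <= 20) & (np.abs(gy) <= 20) & (np.abs(gz) <= 10)
        grid = OccupancyGrid(origin=np.full(3, ax[0]), spacing=1.0, cells=cells)
        assert abs(surface_area(grid) - 6400.0) / 6400.0 < 0.05

    def test_deterministic(self):
        grid = ball_grid(8.0, 1.0)
        assert surface_area(grid) == surface_area(grid)


class TestEnvelopeVolume:
    def test_single_voxel_spacing_two(self):
        assert envelope_volume(single_voxel_grid(spacing=2.0)) == 8.0

    def test_union_volume_at_least_max_member(self):
        a = single_voxel_grid()
        b = single_voxel_grid()
        b.cells[...] = False
        b.cells[0, 0, 0] = True
        union = union_grids([a, b])
        assert envelope_volume(union) >= max(envelope_volume(a), envelope_volume(b))


class TestUnionGrids:
    def test_idempotent(self):
        g = single_voxel_grid()
        u = union_grids([g, g])
        assert np.array_equal(u.cells, g.cells)

    def test_disjoint_voxels_count(self):
        a = single_voxel_grid()
        b = single_voxel_grid()
        b.cells[...] = False
        b.cells[4, 4, 4] = True
        assert union_grids([a, b]).n_occupied == 2

    def test_lattice_mismatch_rejected(self):
        a = single_voxel_grid(spacing=1.0)
        b = single_voxel_grid(spacing=2.0)
        with pytest.raises(LatticeMismatchError):
            union_grids([a, b])


class TestEnvelopeAxes:
    def test_single_voxel_degenerate_extents(self):
        grid = single_voxel_grid(spacing=2.0)
        assert np.allclose(envelope_axes(grid), [2.0, 2.0, 2.0])

    def test_axis_aligned_ellipsoid_extents(self):
        # solid ellipsoid, semi-axes (60, 55, 40) -> extents ~ (120, 110, 80)
        s = 2.0
        ax = [np.arange(-33, 34) * s, np.arange(-30, 31) * s, np.arange(-22, 23) * s]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        cells = (gx / 60) ** 2 + (gy / 55) ** 2 + (gz / 40) ** 2 <= 1.0
        grid = OccupancyGrid(
            origin=np.array([a[0] for a in ax]), spacing=s, cells=cells
        )
        extents = envelope_axes(grid)
        assert np.allclose(extents, [120.0, 110.0, 80.0], rtol=0.03)

    def test_extents_invariant_under_rotation(self, rng):
        # rotate an anisotropic bead cloud; principal extents must not move
        # by more than about a voxel
        from scipy.spatial.transform import Rotation

        pts = rng.normal(size=(400, 3)) * np.array([20.0, 12.0, 5.0])
        model = BeadModel.from_arrays(pts, 2.0, "A", DomainLabel.PAYLOAD_N)
        grid = voxelize(model, spacing=1.0, padding=6.0)
        rot = Rotation.from_euler("xyz", [30, -45, 60], degrees=True).as_matrix()
        rotated = model.transformed(rot, np.zeros(3))
        grid_rot = voxelize(rotated, spacing=1.0, padding=6.0)
        assert np.allclose(
            envelope_axes(grid), envelope_axes(grid_rot), atol=1.5 * grid.spacing
        )

    def test_empty_grid_rejected(self):
        grid = OccupancyGrid(
            origin=np.zeros(3), spacing=1.0, cells=np.zeros((3, 3, 3), dtype=bool)
        )
        with pytest.raises(ValueError):
            envelope_axes(grid)


class TestSymmetryStats:
    def test_identical_areas_zero_se(self):
        stats = symmetry_stats(
            {DomainLabel.PAYLOAD_N: 5.0, DomainLabel.PAYLOAD_I: 5.0,
             DomainLabel.PAYLOAD_C: 5.0},
            [{DomainLabel.PAYLOAD_N, DomainLabel.PAYLOAD_I, DomainLabel.PAYLOAD_C}],
        )
        assert stats[0] == (5.0, 0.0)

    def test_hand_computed_sample_statistics(self):
        # areas (10, 20, 30): mean 20, sample SD 10, SE 10/sqrt(3)
        stats = symmetry_stats(
            {DomainLabel.PAYLOAD_N: 10.0, DomainLabel.PAYLOAD_I: 20.0,
             DomainLabel.PAYLOAD_C: 30.0},
            [{DomainLabel.PAYLOAD_N, DomainLabel.PAYLOAD_I, DomainLabel.PAYLOAD_C}],
        )
        mean, se = stats[0]
        assert mean == pytest.approx(20.0)
        assert se == pytest.approx(10.0 / np.sqrt(3.0))

    def test_singleton_set(self):
        stats = symmetry_stats({DomainLabel.PAYLOAD_N: 7.0}, [{DomainLabel.PAYLOAD_N}])
        assert stats[0] == (7.0, 0.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            symmetry_stats({}, [set()])


class TestPerDomainAreas:
    def test_disjoint_clouds_merged_equals_sum(self, rng):
        # three payload clouds pushed into distant octants: no overlap, so the
        # merged area equals the sum of the individual areas
        from trimerbody.envelope_metrics import per_domain_areas

        class FakeEnsemble:
            pass

        labels = [DomainLabel.PAYLOAD_N, DomainLabel.PAYLOAD_I, DomainLabel.PAYLOAD_C]
        offsets = np.array([[80.0, 80, 80], [-80, -80, 80], [80, -80, -80]])
        configurations = []
        for i in range(4):
            blocks = []
            for label, off in zip(labels, offsets):
                pts = rng.normal(scale=6.0, size=(30, 3)) + off
                blocks.append(
                    BeadModel.from_arrays(pts, 2.5, f"{label.name[-1]}", label,
                                          start_residue=1 + 100 * i)
                )
            conf = type("Conf", (), {})()
            conf.model = BeadModel.concatenate(blocks)
            configurations.append(conf)
        ens = FakeEnsemble()
        ens.configurations = configurations
        areas, diag = per_domain_areas(ens, spacing=2.0)
        assert diag["merged_area"] == pytest.approx(sum(areas.values()), rel=0.02)

    def test_overlapping_clouds_merged_below_sum(self, rng):
        from trimerbody.envelope_metrics import per_domain_areas

        labels = [DomainLabel.PAYLOAD_N, DomainLabel.PAYLOAD_I, DomainLabel.PAYLOAD_C]
        configurations = []
        for i in range(4):
            blocks = [
                BeadModel.from_arrays(
                    rng.normal(scale=8.0, size=(40, 3)), 2.5, label.name[-1], label,
                    start_residue=1 + 100 * i,
                )
                for label in labels
            ]
            conf = type("Conf", (), {})()
            conf.model = BeadModel.concatenate(blocks)
            configurations.append(conf)
        ens = type("Ens", (), {})()
        ens.configurations = configurations
        areas, diag = per_domain_areas(ens, spacing=2.0)
        assert diag["merged_area"] < sum(areas.values())
        assert diag["merged_over_sum"] < 1.0
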