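import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mosaicspect.geometry as geo
from mosaicspect.physics import MaterialID


class TestMosaicPattern:
    def test_default_pattern_has_768_bars_inside_the_block_circle(self):
        pat = geo.generate_mosaic_pattern(seed=1)
        assert pat.n_occupied == 768
        centers = pat.cell_centers()
        assert (np.hypot(centers[:, 0], centers[:, 1])
                <= pat.block_diameter / 2.0).all()

    def test_same_seed_reproduces_mask_different_seed_changes_it(self):
        a = geo.generate_mosaic_pattern(seed=1)
        b = geo.generate_mosaic_pattern(seed=1)
        c = geo.generate_mosaic_pattern(seed=2)
        assert (a.occupancy == b.occupancy).all()
        assert not (a.occupancy == c.occupancy).all()
        assert c.n_occupied == 768

    def test_no_fully_occupied_2x2_square(self):
        occ = geo.generate_mosaic_pattern(seed=3).occupancy.astype(int)
        quads = occ[:-1, :-1] + occ[1:, :-1] + occ[:-1, 1:] + occ[1:, 1:]
        assert quads.max() <= 3

    def test_zero_bars_gives_empty_mask(self):
        assert geo.generate_mosaic_pattern(seed=1, n_bars=0).n_occupied == 0

    def test_requesting_more_bars_than_cells_is_infeasible(self):
        with pytest.raises(ValueError, match="infeasible"):
            geo.generate_mosaic_pattern(seed=1, n_bars=10_000)

    def test_fill_fraction_matches_analytic_value(self):
        pat = geo.generate_mosaic_pattern(seed=1)
        expected = 768 * 1.68**2 / (math.pi * 74.76**2)
        measured = pat.n_occupied * pat.pitch**2 / (
            math.pi * (pat.block_diameter / 2.0) ** 2)
        assert abs(measured - expected) < 1e-6
        assert abs(pat.occupied_area_fraction() - expected) < 1e-6

    def test_pair_serialisation_round_trip(self):
        pat = geo.generate_mosaic_pattern(seed=4)
        clone = geo.MosaicPattern.from_pairs(pat.to_pairs())
        assert (clone.occupancy == pat.occupancy).all()


class TestBinIndexing:
    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 6), st.integers(0, 767), st.integers(0, 49))
    def test_flat_index_bijection(self, k, c, s):
        assert geo.unflat_bin_index(geo.flat_bin_index(k, c, s)) == (k, c, s)

    def test_flat_ordering_is_module_major(self):
        assert geo.flat_bin_index(0, 0, 0) == 0
        assert geo.flat_bin_index(0, 0, 49) == 49
        assert geo.flat_bin_index(0, 1, 0) == 50
        assert geo.flat_bin_index(1, 0, 0) == 38_400
        assert geo.BinIndex(6, 767, 49).flat == 268_799


class TestSystemBuild:
    def test_default_system_bin_bookkeeping(self, full_geometry):
        assert full_geometry.n_bins == 268_800
        assert full_geometry.modules[0].n_gagg_segments == 38_400
        assert len(full_geometry.modules) == 7

    def test_single_module_system_scales_bin_count(self):
        geom = geo.build_system(geo.SystemConfig(n_modules=1))
        assert geom.n_bins == 38_400

    def test_rotational_placement_of_modules(self, full_geometry):
        m0 = full_geometry.modules[0]
        step = math.radians(30.0)
        for j, m in enumerate(full_geometry.modules):
            rot = np.array([
                [math.cos(j * step), -math.sin(j * step), 0],
                [math.sin(j * step), math.cos(j * step), 0],
                [0, 0, 1]])
            np.testing.assert_allclose(m.center, rot @ m0.center, atol=1e-9)

    def test_module_axial_extent_and_span(self, full_geometry):
        assert full_geometry.modules[0].axial_extent == 200.0
        assert full_geometry.angular_span == (-60.0, 120.0)

    def test_overlapping_modules_raise(self):
        with pytest.raises(ValueError, match="conflict"):
            geo.build_system(geo.SystemConfig(ring_diameter=200.0))


class TestMaterialQueries:
    def test_fov_center_is_air_or_water_with_attenuator(self):
        empty = geo.build_system()
        assert geo.material_at((0.0, 0.0, 0.0), empty) == MaterialID.AIR
        filled = geo.build_system(geo.SystemConfig(attenuator=True))
        assert geo.material_at((0.0, 0.0, 0.0), filled) == MaterialID.WATER

    def test_occupied_cell_alternates_gagg_and_glass_axially(self, full_geometry):
        m0 = full_geometry.modules[0]
        pat = m0.pattern
        row, col = np.argwhere(pat.occupancy)[0]
        half = pat.grid_dims[0] * pat.pitch / 2.0
        u = (row + 0.5) * pat.pitch - half
        v = (col + 0.5) * pat.pitch - half
        # module 0 sits at -60 deg; rotate the local offset into the world
        a = math.radians(m0.angle_deg)
        x = m0.center[0] + u * math.cos(a) - v * math.sin(a)
        y = m0.center[1] + u * math.sin(a) + v * math.cos(a)
        phase = m0.axial.bar_phase(row, col)
        zmin = m0.z_range[0]
        z_gagg = zmin + (2 * 3 + phase) * 2.0 + 1.0   # slot matching the phase
        z_glass = z_gagg + 2.0
        assert geo.material_at((x, y, z_gagg), full_geometry) == MaterialID.GAGG
        assert geo.material_at((x, y, z_glass), full_geometry) == MaterialID.GLASS

    def test_axial_layout_sequence_has_five_of_each(self):
        layout = geo.AxialLayout()
        seq = layout.sequence(phase=0)
        assert seq.count(MaterialID.GAGG) == 5
        assert seq.count(MaterialID.GLASS) == 5
        assert seq[0] == MaterialID.GAGG
        assert layout.sequence(phase=1)[0] == MaterialID.GLASS


class TestTracePath:
    def test_zero_direction_raises(self, full_geometry):
        with pytest.raises(ValueError):
            geo.trace_path((0, 0, 0), (0, 0, 0), full_geometry)

    def test_ray_missing_all_modules_is_single_air_segment(self, full_geometry):
        segs = geo.trace_path((0, 0, 0), (0, 0, 1), full_geometry)
        assert len(segs) == 1
        assert segs[0][0] == MaterialID.AIR
        assert segs[0][1] == pytest.approx(full_geometry.world_radius)

    def test_axial_ray_along_occupied_bar_alternates_2mm_segments(
            self, full_geometry):
        m0 = full_geometry.modules[0]
        pat = m0.pattern
        row, col = np.argwhere(pat.occupancy)[0]
        half = pat.grid_dims[0] * pat.pitch / 2.0
        u = (row + 0.5) * pat.pitch - half
        v = (col + 0.5) * pat.pitch - half
        a = math.radians(m0.angle_deg)
        x = m0.center[0] + u * math.cos(a) - v * math.sin(a)
        y = m0.center[1] + u * math.sin(a) + v * math.cos(a)
        segs = geo.trace_path((x, y, -150.0), (0, 0, 1), full_geometry)
        inner = [s for s in segs if s[0] != MaterialID.AIR]
        assert len(inner) == 100
        for (mat_a, len_a), (mat_b, _) in zip(inner, inner[1:]):
            assert mat_a != mat_b
            assert len_a == pytest.approx(2.0, abs=1e-9)

    def test_lengths_sum_to_world_traversal_and_match_dense_sampling(
            self, full_geometry):
        rng = np.random.default_rng(5)
        step = 0.05
        for _ in range(12):
            origin = rng.uniform(-40, 40, size=3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            segs = geo.trace_path(origin, direction, full_geometry)
            total = sum(L for _, L in segs)
            # distance from origin to the world sphere along the ray
            b = 2 * origin @ direction
            c = origin @ origin - full_geometry.world_radius**2
            t_end = (-b + math.sqrt(b * b - 4 * c)) / 2
            assert total == pytest.approx(t_end, abs=1e-6)
            # dense material_at sampling as an independent oracle
            ts = np.arange(step / 2, t_end, step)
            mats = geo.material_at(origin + ts[:, None] * direction,
                                   full_geometry)
            gagg_dense = (mats == int(MaterialID.GAGG)).sum() * step
            gagg_trace = sum(L for m, L in segs if m == MaterialID.GAGG)
            assert abs(gagg_dense - gagg_trace) < 0.2


class TestVoxelGrid:
    def test_default_grids_match_fov_presets(self):
        g2 = geo.default_grid_2mm()
        assert g2.dims == (90, 90, 50)
        assert g2.voxel_size == (2.0, 2.0, 2.0)
        g3 = geo.default_grid_3mm()
        assert g3.dims == (60, 60, 34)

    def test_flat_index_is_x_fastest(self):
        g = geo.VoxelGrid.centered((1, 1, 1), (4, 3, 2))
        assert g.flat_index(1, 0, 0) == 1
        assert g.flat_index(0, 1, 0) == 4
        assert g.flat_index(0, 0, 1) == 12
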