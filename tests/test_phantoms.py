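import math

import numpy as np
import pytest

import mosaicspect.geometry as geo
import mosaicspect.phantoms as ph
from mosaicspect.physics import MaterialID, MaterialTable


def total_activity(img):
    return img.total() / ph.MCI_TO_PHOTONS_PER_S


class TestHotRodLayout:
    def test_six_sectors_with_expected_diameters(self):
        rods = ph.hot_rod_layout()
        assert {d for _, _, d in rods} == set(ph.ROD_DIAMETERS_MM)

    def test_lattice_spacing_is_twice_the_diameter(self):
        rods = ph.hot_rod_layout()
        for d in ph.ROD_DIAMETERS_MM:
            centers = np.array([(x, y) for x, y, dd in rods if dd == d])
            dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
            np.fill_diagonal(dists, np.inf)
            assert dists.min() == pytest.approx(2 * d, rel=1e-9)
            # nearest neighbours realise the hexagonal packing distance
            assert np.allclose(dists.min(axis=1), 2 * d, rtol=1e-9)

    def test_margins_from_rim_and_sector_boundaries(self):
        for i, d in enumerate(ph.ROD_DIAMETERS_MM):
            rods = [(x, y) for x, y, dd in ph.hot_rod_layout() if dd == d]
            t0, t1 = math.radians(60 * i), math.radians(60 * (i + 1))
            n0 = np.array([-math.sin(t0), math.cos(t0)])
            n1 = np.array([math.sin(t1), -math.cos(t1)])
            for p in np.asarray(rods):
                assert np.hypot(*p) + d / 2 <= 90.0 - 5.0 + 1e-9
                assert p @ n0 >= 5.0 + d / 2 - 1e-9
                assert p @ n1 >= 5.0 + d / 2 - 1e-9

    def test_counts_match_bruteforce_hexagonal_packing(self):
        # independent enumeration with complex-number lattice arithmetic
        rods = ph.hot_rod_layout()
        for i, d in enumerate(ph.ROD_DIAMETERS_MM):
            got = sum(1 for _, _, dd in rods if dd == d)
            bis = math.radians(60 * i + 30)
            a1 = 2 * d * np.exp(1j * bis)
            a2 = a1 * np.exp(1j * math.pi / 3)
            count = 0
            for m in range(-30, 31):
                for n in range(-30, 31):
                    p = m * a1 + n * a2
                    ang = math.atan2(p.imag, p.real) % (2 * math.pi)
                    r = abs(p)
                    if r + d / 2 > 85.0 or r == 0 and i > 0:
                        continue
                    clear = 5.0 + d / 2
                    lo, hi = math.radians(60 * i), math.radians(60 * (i + 1))
                    d0 = r * math.sin(ang - lo)
                    d1 = r * math.sin(hi - ang)
                    # handle wrap-around of the angle into the sector
                    if d0 >= clear and d1 >= clear and lo <= ang <= hi:
                        count += 1
            assert got == count


class TestHotRodPhantom:
    def test_normalised_to_total_activity(self, grid2mm):
        img = ph.make_hot_rod(grid2mm)
        assert total_activity(img) == pytest.approx(0.45, rel=1e-9)

    def test_zero_background_between_sectors(self, grid2mm):
        img = ph.make_hot_rod(grid2mm)
        # the central 10-mm margin region holds no rods
        c = grid2mm.dims[0] // 2
        assert img.values[c - 2:c + 2, c - 2:c + 2, :].sum() == 0.0
        assert (img.values == 0).mean() > 0.5

    def test_coarse_grid_warns(self):
        coarse = geo.VoxelGrid.centered((4.0, 4.0, 4.0), (45, 45, 25))
        with pytest.warns(UserWarning):
            ph.make_hot_rod(coarse)


class TestDiskPhantoms:
    def test_disk_diameter_and_gap(self, grid2mm):
        img = ph.make_disks(5.0, grid2mm)
        nz = img.values.sum(axis=2)
        xs, ys = np.nonzero(nz)
        centers = grid2mm.voxel_centers().reshape(
            (90, 90, 50, 3), order="F")[..., 0]
        r = np.hypot(*(np.array(np.nonzero(nz)) * 2.0 - 89.0))
        assert r.max() <= 60.0 + 2.0
        assert (ph.disk_centers_mm(5.0)[1:] -
                ph.disk_centers_mm(5.0)[:-1] == pytest.approx(15.0))

    def test_axial_profile_is_five_pulse_square_wave(self):
        # 4-mm disks align exactly with 2-mm voxels: duty cycle 1/3
        grid = geo.default_grid_2mm()
        img = ph.make_disks(4.0, grid)
        prof = img.values[45, 45, :]
        on = prof > 0
        blocks = np.diff(np.flatnonzero(np.diff(np.r_[0, on, 0])))
        assert on.sum() == 5 * 2              # five disks, two voxels each
        assert list(blocks[::2]) == [2] * 5   # disk widths in voxels
        assert list(blocks[1::2]) == [4] * 4  # gaps twice the thickness

    def test_8mm_stack_extends_beyond_the_fov(self, grid2mm):
        img = ph.make_disks(8.0, grid2mm)
        prof = img.values.sum(axis=(0, 1))
        assert prof[0] > 0 and prof[-1] > 0   # outermost 2-mm slices occupied

    def test_invalid_thickness_rejected(self, grid2mm):
        with pytest.raises(ValueError):
            ph.make_disks(3.0, grid2mm)

    def test_normalisation(self, grid2mm):
        for t in (4.0, 8.0):
            assert total_activity(ph.make_disks(t, grid2mm)) == pytest.approx(
                0.45, rel=1e-9)


class TestCardiacPhantom:
    def test_uptake_ratio_75_to_2(self):
        grid = geo.default_grid_3mm()
        act, _ = ph.make_cardiac(grid)
        vals = np.unique(act.values[act.values > 0])
        assert vals.max() / vals.min() == pytest.approx(75.0 / 2.0, rel=1e-9)
        assert total_activity(act) == pytest.approx(0.45, rel=1e-9)

    def test_attenuation_map_is_water_cylinder(self):
        grid = geo.default_grid_3mm()
        _, att = ph.make_cardiac(grid)
        mu_water = MaterialTable().mu(MaterialID.WATER, 140.0)
        assert att.values[30, 30, 17] == pytest.approx(mu_water)
        assert att.values[0, 0, 0] == 0.0

    def test_zero_wall_leaves_only_blood_and_vessels(self):
        grid = geo.default_grid_3mm()
        act, _ = ph.make_cardiac(grid, wall_value=0.0)
        full, _ = ph.make_cardiac(grid)
        assert (act.values > 0).sum() < (full.values > 0).sum()
        # every remaining voxel held blood or vessel uptake before scaling
        assert len(np.unique(act.values[act.values > 0])) == 1


class TestUniformCylinder:
    def test_inside_positive_outside_zero(self, grid2mm):
        img = ph.make_uniform_cylinder(grid2mm)
        assert img.values[45, 45, 25] > 0
        assert img.values[0, 0, 0] == 0.0

    def test_voxel_count_matches_analytic_volume(self, grid2mm):
        img = ph.make_uniform_cylinder(grid2mm)
        n_occupied = (img.values > 0).sum()
        expected = math.pi * 90.0**2 * 100.0 / 8.0
        # within one voxel shell of the rim
        shell = 2 * math.pi * 90.0 * 100.0 * 2.0 / 8.0
        assert abs(n_occupied - expected) < shell

    def test_quarter_turn_symmetry(self, grid2mm):
        img = ph.make_uniform_cylinder(grid2mm)
        np.testing.assert_array_equal(img.values,
                                      np.rot90(img.values, axes=(0, 1)))

    def test_refining_voxels_changes_volume_below_2_percent(self):
        # smooth-boundary phantoms; slab phantoms quantize in whole voxel
        # layers and only refine cleanly when thickness divides the voxel
        for make in (ph.make_uniform_cylinder, ph.make_hot_rod):
            coarse = geo.VoxelGrid.centered((2, 2, 2), (100, 100, 56))
            fine = geo.VoxelGrid.centered((1, 1, 1), (200, 200, 112))
            v_coarse = (make(coarse).values > 0).sum() * 8.0
            v_fine = (make(fine).values > 0).sum() * 1.0
            assert abs(v_fine - v_coarse) / v_fine < 0.02


class TestVoxelImage:
    def test_negative_values_rejected(self, grid2mm):
        bad = np.zeros(grid2mm.dims)
        bad[0, 0, 0] = -1.0
        with pytest.raises(ValueError):
            ph.VoxelImage(grid2mm, bad)

    def test_flatten_is_x_fastest(self):
        grid = geo.VoxelGrid.centered((1, 1, 1), (3, 2, 2))
        vals = np.arange(12.0).reshape((3, 2, 2))
        img = ph.VoxelImage(grid, vals)
        flat = img.flatten()
        assert flat[grid.flat_index(1, 0, 0)] == vals[1, 0, 0]
        assert flat[grid.flat_index(0, 1, 1)] == vals[0, 1, 1]
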