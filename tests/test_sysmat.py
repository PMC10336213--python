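import numpy as np
import pytest

import mosaicspect.geometry as geo
import mosaicspect.sysmat as sm
from mosaicspect.phantoms import make_uniform_cylinder
from mosaicspect.transport import (ListModeSet, build_slice_system,
                                   simulate_slice2d)


def _toy_listmode(bins, voxels, emitted, n_histories=None):
    bins = np.asarray(bins, dtype=np.int32)
    n = bins.size
    ones = np.ones(n, dtype=np.uint8)
    return ListModeSet(
        bin=bins, e_measured=np.full(n, 140.0, dtype=np.float32),
        emission_voxel=np.asarray(voxels, dtype=np.int32),
        n_compton_detector=np.zeros(n, dtype=np.uint8),
        n_compton_gagg=np.zeros(n, dtype=np.uint8),
        n_gagg_elements_hit=ones, flags=ones,
        emitted_per_voxel=np.asarray(emitted, dtype=np.int64),
        n_histories=n_histories or int(np.sum(emitted)), seed=0)


class TestEstimation:
    def test_hand_enumerated_six_history_trace(self):
        # 6 histories: voxel 0 emits 4 (hits bins 0,0,1), voxel 1 emits 2 (bin 1)
        grid = geo.VoxelGrid.centered((1, 1, 1), (2, 1, 1))
        lm = _toy_listmode(bins=[0, 0, 1, 1], voxels=[0, 0, 0, 1],
                           emitted=[4, 2])
        A = sm.estimate_sysmat(lm, grid, n_bins=3)
        dense = A.matrix.toarray()
        np.testing.assert_allclose(dense, [[2 / 4, 0.0],
                                           [1 / 4, 1 / 2],
                                           [0.0, 0.0]])

    def test_single_voxel_source_leaves_other_columns_zero(self):
        grid = geo.VoxelGrid.centered((1, 1, 1), (3, 1, 1))
        lm = _toy_listmode(bins=[2, 2], voxels=[1, 1], emitted=[5, 5, 5])
        A = sm.estimate_sysmat(lm, grid, n_bins=4)
        dense = A.matrix.toarray()
        assert dense[:, 0].sum() == 0 and dense[:, 2].sum() == 0
        assert dense[2, 1] == pytest.approx(0.4)

    def test_full_scale_row_bookkeeping(self, uniform_run_200k, grid2mm):
        A = sm.estimate_sysmat(uniform_run_200k, grid2mm)
        assert A.shape == (268_800, 405_000)
        s = A.sensitivity()
        assert ((0.0 <= s) & (s <= 1.0)).all()
        # probabilities bounded: every column sums below 1
        assert s.max() <= 1.0

    def test_grid_mismatch_raises(self, uniform_run_200k):
        small = geo.VoxelGrid.centered((2, 2, 2), (10, 10, 10))
        with pytest.raises(ValueError):
            sm.estimate_sysmat(uniform_run_200k, small)

    def test_uncovered_fov_voxel_raises(self):
        grid = geo.VoxelGrid.centered((1, 1, 1), (2, 1, 1))
        lm = _toy_listmode(bins=[0], voxels=[0], emitted=[3, 0])
        with pytest.raises(ValueError, match="zero emissions"):
            sm.estimate_sysmat(lm, grid, n_bins=1,
                               fov_mask=np.array([True, True]))


class TestSensitivity:
    def test_single_entry_matrix(self):
        import scipy.sparse as sp

        A = sm.SystemMatrix(sp.csr_matrix(np.array([[0.0, 0.5, 0.0]])))
        stats = sm.sensitivity_stats(A, np.ones(3, dtype=bool))
        np.testing.assert_allclose(stats.values, [0.0, 0.5, 0.0])

    def test_empty_mask_rejected(self):
        import scipy.sparse as sp

        A = sm.SystemMatrix(sp.csr_matrix((2, 2)))
        with pytest.raises(ValueError):
            sm.sensitivity_stats(A, np.zeros(2, dtype=bool))

    def test_emission_weighted_mean_equals_detected_over_emitted(
            self, uniform_run_200k, grid2mm):
        A = sm.estimate_sysmat(uniform_run_200k, grid2mm)
        s = A.sensitivity()
        emitted = uniform_run_200k.emitted_per_voxel
        weighted = float(s @ emitted) / emitted.sum()
        direct = len(uniform_run_200k) / uniform_run_200k.n_histories
        assert weighted == pytest.approx(direct, abs=1e-12)

    def test_fov_mean_tracks_direct_ratio(self, full_geometry):
        # coarse voxels so every FOV voxel collects plenty of emissions
        grid = geo.VoxelGrid.centered((18.0, 18.0, 17.0), (10, 10, 6))
        activity = make_uniform_cylinder(grid)
        from mosaicspect.transport import simulate

        run = simulate(activity, full_geometry, 100_000, seed=31)
        A = sm.estimate_sysmat(run, grid,
                               fov_mask=activity.flatten() > 0)
        stats = sm.sensitivity_stats(A, activity.flatten() > 0)
        direct = 100.0 * len(run) / run.n_histories
        assert stats.mean_pct == pytest.approx(direct, rel=0.05)
        assert stats.std_pct > 0.0

    def test_axial_slice_extraction(self, uniform_run_200k, grid2mm):
        A = sm.estimate_sysmat(uniform_run_200k, grid2mm)
        mask = make_uniform_cylinder(grid2mm).flatten() > 0
        stats = sm.sensitivity_stats(A, mask)
        maps = sm.axial_slices(stats, grid2mm, [5, 25, 44])
        assert len(maps) == 3
        assert all(m.shape == (90, 90) for m in maps)
        with pytest.raises(IndexError):
            sm.axial_slices(stats, grid2mm, [50])

    def test_constant_matrix_gives_constant_slices(self, grid2mm):
        import scipy.sparse as sp

        n_vox = grid2mm.n_voxels
        A = sm.SystemMatrix(sp.csr_matrix(np.full((1, n_vox), 0.25)))
        stats = sm.sensitivity_stats(A, np.ones(n_vox, dtype=bool))
        maps = sm.axial_slices(stats, grid2mm, [0, 49])
        for m in maps:
            np.testing.assert_allclose(m, 0.25)

    def test_mirror_symmetric_slices_agree(self, uniform_run_200k, grid2mm):
        A = sm.estimate_sysmat(uniform_run_200k, grid2mm)
        mask3 = (make_uniform_cylinder(grid2mm).values > 0)
        s3 = A.sensitivity().reshape((90, 90, 50), order="F")
        top = s3[:, :, 5][mask3[:, :, 5]].mean()
        bottom = s3[:, :, 44][mask3[:, :, 44]].mean()
        assert top == pytest.approx(bottom, rel=0.10)


class TestSliceUnbiasedness:
    def test_estimate_matches_dense_path_integral_oracle(self):
        """Point-source detection probability vs numerical ray integration.

        A tiny single-module slice system with forced photoelectric
        absorption: the Monte Carlo detection probability must converge to
        the angular integral of per-ray first-interaction probabilities
        computed by dense material sampling.
        """
        cfg = geo.SystemConfig(n_modules=1, angle_start_deg=0.0, n_bars=200,
                               pattern_seed=5)
        system = build_slice_system(cfg, n_pix=15, pixel_mm=2.0)
        activity = np.zeros((15, 15))
        activity[7, 7] = 1.0          # point-ish source at the FOV centre
        n = 300_000
        ev_bin, _, _ = simulate_slice2d(activity, system, n, seed=6,
                                        pe_force=1.0, window_on=False)
        p_mc = ev_bin.size / n

        # dense-sampling oracle over emission angles
        mu_mm = 0.4746
        n_ang = 2880
        step = 0.05
        ts = np.arange(step / 2, 400.0, step)
        p_sum = 0.0
        cell_id = system.cell_id
        half, pitch, gn = system.half, system.pitch, system.grid_n
        cx, cy = system.cx[0], system.cy[0]
        for ang in 2 * np.pi * (np.arange(n_ang) + 0.5) / n_ang:
            x = ts * np.cos(ang)         # pixel (7,7) is centred on the axis
            y = ts * np.sin(ang)
            u = x - cx
            v = y - cy
            iu = np.floor((u + half) / pitch).astype(int)
            iv = np.floor((v + half) / pitch).astype(int)
            ok = (iu >= 0) & (iu < gn) & (iv >= 0) & (iv < gn)
            gagg = np.zeros(ts.size, dtype=bool)
            gagg[ok] = cell_id[iu[ok], iv[ok]] >= 0
            g = gagg.astype(np.float64)
            tau = np.cumsum(g) * step * mu_mm
            # probability the first interaction happens in any GAGG sample
            surv = np.exp(-(tau - g * step * mu_mm))
            p_ray = float(np.sum(surv * (1.0 - np.exp(-g * step * mu_mm))))
            p_sum += p_ray
        p_oracle = p_sum / n_ang
        sigma = np.sqrt(p_oracle * (1 - p_oracle) / n)
        assert abs(p_mc - p_oracle) < max(3 * sigma, 0.01 * p_oracle + 0.002)

    def test_doubling_histories_shrinks_the_spread(self):
        cfg = geo.SystemConfig(n_modules=1, angle_start_deg=0.0, n_bars=100,
                               pattern_seed=5)
        system = build_slice_system(cfg, n_pix=9, pixel_mm=2.0)
        activity = np.ones((9, 9))

        def estimates(n, seeds):
            out = []
            for s in seeds:
                ev_bin, _, _ = simulate_slice2d(activity, system, n, seed=s)
                out.append(ev_bin.size / n)
            return np.std(out)

        std_small = estimates(4_000, range(100, 112))
        std_large = estimates(16_000, range(200, 212))
        assert std_large < std_small


class TestMatrixIO:
    def test_hdf5_and_mtx_round_trips_preserve_triplets(self, tmp_path):
        import scipy.sparse as sp

        rng = np.random.default_rng(3)
        dense = rng.random((6, 8)) * (rng.random((6, 8)) > 0.5)
        A = sm.SystemMatrix(sp.csr_matrix(dense), dict(n_histories=10, seed=1))
        h5 = tmp_path / "A.h5"
        mtx = tmp_path / "A.mtx"
        A.to_hdf5(h5)
        A.to_mtx(mtx)
        back_h5 = sm.SystemMatrix.from_hdf5(h5)
        back_mtx = sm.SystemMatrix.from_mtx(mtx)
        np.testing.assert_allclose(back_h5.matrix.toarray(), dense)
        np.testing.assert_allclose(back_mtx.matrix.toarray(), dense)
        assert back_h5.provenance["n_histories"] == 10
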