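"""Monte-Carlo transport engine: decay sampling, photon/electron physics,
dose scoring and the kernel-convolution alternative."""

import numpy as np
import pytest

from marrowdose import (CoefficientTables, DecayData, TIAMap, VoxelGrid,
                        hu_to_material, kernel_dose, simulate_dose,
                        transport_photons, sample_decay)
from marrowdose.engine import KEV_TO_MGY_G, deposit_electrons
from marrowdose.kinetics import TIAMap
from marrowdose.materials import MaterialMap
from marrowdose.skeleton import assign_skeletal_regions


def _uniform_block(shape=(32, 32, 32), spacing=4.0, hu=0.0):
    g = VoxelGrid(shape, (spacing,) * 3)
    mat = hu_to_material(np.full(shape, hu), g)
    skel = assign_skeletal_regions(np.zeros(shape, bool),
                                   np.zeros(shape, int), grid=g)
    return g, mat, skel


def _uniform_tia(grid, total=1e12):
    return TIAMap(grid, np.full(grid.shape, total / grid.n_voxels),
                  {"rob": total})


class TestSampleDecay:
    def test_single_line_every_history(self, rng):
        dd = DecayData.monoenergetic(100.0, "photon")
        groups = sample_decay(dd, rng, n_histories=1000)
        particle, energies, hist = groups[0]
        assert particle == "photon"
        assert len(hist) == 1000
        np.testing.assert_allclose(energies, 100.0)

    def test_line_yield_binomial(self, rng):
        dd = DecayData(np.array([[208.37, 0.1036]]), np.zeros((0, 3)))
        n = 1_000_000
        (_, energies, hist), = sample_decay(dd, rng, n_histories=n)
        sigma = np.sqrt(n * 0.1036 * (1 - 0.1036))
        assert abs(len(hist) - n * 0.1036) < 4 * sigma

    def test_beta_mean_matches_table(self, lu177, rng):
        e = lu177.sample_beta_energies(1_000_000, rng)
        assert e.mean() == pytest.approx(lu177.mean_beta_energy_kev,
                                         rel=0.01)


class TestPhotonTransport:
    def test_vacuum_escapes_without_deposit(self, tables, rng):
        g = VoxelGrid((8, 8, 8))
        mat = MaterialMap(g, np.zeros(g.shape), np.zeros(g.shape, np.int8))
        pos = np.tile([4.0, 4.0, 4.0], (100, 1))
        d = np.tile([0.0, 0.0, 1.0], (100, 1))
        res = transport_photons(pos, d, np.full(100, 208.0), mat, tables, rng)
        assert len(res["voxel"]) == 0
        np.testing.assert_allclose(res["escaped"], 208.0)

    def test_beer_lambert_transmission(self, tables):
        # 208 keV pencil beam through 10 cm of water-equivalent tissue
        g = VoxelGrid((20, 20, 50), (2, 2, 2))
        mat = hu_to_material(np.zeros(g.shape), g)
        n = 100_000
        rng = np.random.default_rng(7)
        res = transport_photons(np.tile([10.0, 10.0, 0.0], (n, 1)),
                                np.tile([0.0, 0.0, 1.0], (n, 1)),
                                np.full(n, 208.366), mat, tables, rng,
                                primary_only=True)
        survived = float((res["escaped"] > 0).sum()) / n
        mu = tables.coefficient("soft_tissue", 208.366, "photon") * 1.0
        p = float(np.exp(-mu * 10.0))
        z = (survived - p) / np.sqrt(p * (1 - p) / n)
        assert abs(z) < 3.0

    def test_energy_conservation_per_history(self, tables, rng):
        g = VoxelGrid((16, 16, 16), (4, 4, 4))
        mat = hu_to_material(np.zeros(g.shape), g)
        n = 2000
        pos = np.tile([8.0, 8.0, 8.0], (n, 1))
        from marrowdose.engine import _isotropic_directions
        d = _isotropic_directions(n, rng)
        e0 = 208.366
        res = transport_photons(pos, d, np.full(n, e0), mat, tables, rng)
        deposited = np.bincount(res["photon"], weights=res["energy"],
                                minlength=n)
        np.testing.assert_allclose(deposited + res["escaped"], e0,
                                   rtol=1e-9)

    def test_missed_grid_is_not_an_error(self, tables, rng):
        g = VoxelGrid((8, 8, 8))
        mat = hu_to_material(np.zeros(g.shape), g)
        pos = np.tile([-10.0, -10.0, -10.0], (10, 1))
        d = np.tile([0.0, 0.0, -1.0], (10, 1))
        res = transport_photons(pos, d, np.full(10, 100.0), mat, tables, rng)
        assert len(res["voxel"]) == 0


class TestElectronDeposition:
    def test_local_mode_identity(self, material):
        vox = np.array([0, 5, 10])
        e = np.array([100.0, 50.0, 10.0])
        v, en, esc = deposit_electrons(vox, e, material, mode="local")
        np.testing.assert_array_equal(v, vox)
        np.testing.assert_array_equal(en, e)
        assert esc == 0.0

    def test_csda_short_range_equals_local(self, tables, rng):
        # 100 keV electron CSDA range in water ~0.14 mm << 2 mm half-voxel
        g, mat, _ = _uniform_block((8, 8, 8), spacing=4.0)
        vox = np.full(50, 8 * 8 * 4 + 8 * 4 + 4)  # central voxel
        e = np.full(50, 100.0)
        v, en, esc = deposit_electrons(vox, e, mat, mode="csda", rng=rng,
                                       tables=tables)
        # all energy stays in the emission voxel
        agg = np.bincount(v, weights=en, minlength=g.n_voxels)
        assert agg[vox[0]] == pytest.approx(e.sum(), rel=1e-12)
        assert esc == 0.0

    def test_csda_conserves_energy(self, tables, rng):
        g, mat, _ = _uniform_block((8, 8, 8), spacing=1.0)
        vox = np.arange(50)
        e = np.full(50, 400.0)
        v, en, esc = deposit_electrons(vox, e, mat, mode="csda", rng=rng,
                                       tables=tables)
        assert en.sum() + esc == pytest.approx(e.sum(), rel=1e-12)


class TestSimulateDose:
    def test_zero_tia_warns_and_returns_zero(self, tables, lu177):
        g, mat, skel = _uniform_block((8, 8, 8))
        tia = TIAMap(g, np.zeros(g.shape), {"rob": 0.0})
        with pytest.warns(UserWarning):
            dm = simulate_dose(tia, mat, skel, lu177, tables,
                               n_histories=10, seed=0)
        assert not dm.dose_bone.any() and not dm.dose_bm.any()

    def test_grid_mismatch_rejected(self, tables, lu177):
        g, mat, skel = _uniform_block((8, 8, 8))
        g2 = VoxelGrid((8, 8, 8), (2, 2, 2))
        tia = _uniform_tia(g2)
        with pytest.raises(ValueError, match="grid"):
            simulate_dose(tia, mat, skel, lu177, tables, n_histories=10)

    def test_electron_equilibrium_closed_form(self, tables):
        g, mat, skel = _uniform_block((32, 32, 32))
        total = 1e12
        tia = _uniform_tia(g, total)
        dd = DecayData.monoenergetic(100.0, "electron")
        dm = simulate_dose(tia, mat, skel, dd, tables, n_histories=100_000,
                           seed=11, include_photons=False)
        mass = mat.voxel_mass_g.sum()
        mean_dose = float((dm.dose_bone * mat.voxel_mass_g).sum() / mass)
        expected = total * 100.0 * KEV_TO_MGY_G / mass
        assert mean_dose == pytest.approx(expected, rel=5e-3)

    def test_linearity_in_tia(self, tables):
        g, mat, skel = _uniform_block((16, 16, 16))
        dd = DecayData.monoenergetic(100.0, "electron")
        d1 = simulate_dose(_uniform_tia(g, 1e10), mat, skel, dd, tables,
                           n_histories=20_000, seed=4, include_photons=False)
        d2 = simulate_dose(_uniform_tia(g, 2e10), mat, skel, dd, tables,
                           n_histories=20_000, seed=4, include_photons=False)
        np.testing.assert_allclose(d2.dose_bone, 2.0 * d1.dose_bone,
                                   rtol=1e-12)

    def test_stderr_shrinks_with_sqrt_histories(self, tables):
        g, mat, skel = _uniform_block((16, 16, 16))
        tia = _uniform_tia(g)
        dd = DecayData.monoenergetic(100.0, "electron")
        d1 = simulate_dose(tia, mat, skel, dd, tables, n_histories=50_000,
                           seed=8, include_photons=False)
        d2 = simulate_dose(tia, mat, skel, dd, tables, n_histories=200_000,
                           seed=9, include_photons=False)
        r1 = np.nanmean(d1.rel_stderr)
        r2 = np.nanmean(d2.rel_stderr)
        assert r1 / r2 == pytest.approx(2.0, rel=0.10)

    def test_marrow_dose_within_weighting_bounds(self, phantom, material,
                                                 skeletal, tables):
        from marrowdose import weighting_factor
        tia = TIAMap(phantom.grid, phantom.truth_tia,
                     phantom.compartment_tias)
        dd = DecayData.lu177()
        dm = simulate_dose(tia, material, skeletal, dd, tables,
                           n_histories=30_000, seed=2,
                           include_photons=False)
        e_grid = np.linspace(10.0, 500.0, 50)
        w_all = []
        import pandas as pd
        from marrowdose import load_skeletal_composition
        for _, row in load_skeletal_composition().iterrows():
            w_all.append(weighting_factor(
                e_grid, "electron", (row["f_bm"], row["f_iabm"],
                                     row["f_hb"]), tables))
        w_min, w_max = np.min(w_all), np.max(w_all)
        skel = skeletal.skeleton_mask & (skeletal.f_bm > 0) & \
            (dm.dose_bone > 0)
        ratio = dm.dose_bm[skel] / dm.dose_bone[skel]
        assert np.all(ratio >= w_min - 1e-9)
        assert np.all(ratio <= w_max + 1e-9)

    def test_w_degeneracy_equal_curves(self, phantom, material, skeletal):
        flat = CoefficientTables.from_constants(
            {"marrow_red": 0.2, "marrow_yellow": 0.2, "bone_cortical": 0.2,
             "water": 0.2, "air": 0.2, "lung": 0.2, "soft_tissue": 0.2})
        flat.z_over_a = {}
        tia = TIAMap(phantom.grid, phantom.truth_tia,
                     phantom.compartment_tias)
        dd = DecayData.monoenergetic(150.0, "electron")
        dm = simulate_dose(tia, material, skeletal, dd, flat,
                           n_histories=20_000, seed=3,
                           include_photons=False)
        active = skeletal.f_bm > 0
        np.testing.assert_allclose(dm.dose_bm[active],
                                   dm.dose_bone[active], rtol=1e-12)
        assert not dm.dose_bm[~active].any()


class TestKernelDose:
    def test_delta_kernel_matches_local_expectation(self, tables):
        g, mat, _ = _uniform_block((16, 16, 16))
        tia = _uniform_tia(g, 1e10)
        kernel = np.zeros((3, 3, 3))
        kernel[1, 1, 1] = 100.0  # keV per decay, all in the source voxel
        dm = kernel_dose(tia, kernel, mat)
        expected = tia.tia * 100.0 * KEV_TO_MGY_G / mat.voxel_mass_g
        np.testing.assert_allclose(dm.dose_bone, expected, rtol=1e-9)
        assert dm.meta["approximate"] is True

    def test_shift_equivariance(self, rng):
        g, mat, _ = _uniform_block((16, 16, 16))
        tia_arr = np.zeros(g.shape)
        tia_arr[4:8, 4:8, 4:8] = rng.random((4, 4, 4)) * 1e8
        kernel = rng.random((3, 3, 3)) * 10.0
        d1 = kernel_dose(TIAMap(g, tia_arr, {"rob": tia_arr.sum()}),
                         kernel, mat)
        shifted = np.roll(tia_arr, (3, 2, 1), axis=(0, 1, 2))
        d2 = kernel_dose(TIAMap(g, shifted, {"rob": shifted.sum()}),
                         kernel, mat)
        np.testing.assert_allclose(
            d2.dose_bone, np.roll(d1.dose_bone, (3, 2, 1), axis=(0, 1, 2)),
            atol=1e-12 * d1.dose_bone.max())

    def test_rejects_incompatible_kernel(self, tables):
        g, mat, _ = _uniform_block((8, 8, 8))
        tia = _uniform_tia(g)
        with pytest.raises(ValueError):
            kernel_dose(tia, np.ones((2, 2, 2)), mat)
        with pytest.raises(ValueError):
            kernel_dose(tia, np.ones((3, 3, 3)), mat,
                        kernel_spacing_mm=(1.0, 1.0, 1.0))
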