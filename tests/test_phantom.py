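"""Voxel phantom stage: materials, skeleton, segmentation, generator."""

import numpy as np
import pandas as pd
import pytest

from marrowdose import (PhantomConfig, VoxelGrid, generate_phantom,
                        hu_to_material, kmeans_segment,
                        load_skeletal_composition, assign_skeletal_regions,
                        segment_skeleton)
from marrowdose.materials import TISSUE_CLASSES


class TestVoxelGrid:
    def test_rejects_degenerate_geometry(self):
        with pytest.raises(ValueError):
            VoxelGrid((0, 4, 4))
        with pytest.raises(ValueError):
            VoxelGrid((4, 4, 4), spacing=(0.0, 1, 1))

    def test_voxel_volume(self):
        g = VoxelGrid((2, 2, 2), spacing=(4.0, 4.0, 2.0))
        assert g.voxel_volume_mm3 == 32.0
        assert g.voxel_volume_ml == pytest.approx(0.032)

    def test_nifti_round_trip(self, tmp_path):
        from marrowdose import load_volume, save_volume
        g = VoxelGrid((3, 4, 5), spacing=(2, 2, 3), origin=(1, 2, 3))
        data = np.arange(60, dtype=float).reshape(g.shape)
        save_volume(tmp_path / "v.nii.gz", data, g)
        back, g2 = load_volume(tmp_path / "v.nii.gz")
        np.testing.assert_allclose(back, data)
        assert g2.shape == g.shape
        np.testing.assert_allclose(g2.spacing, g.spacing)


class TestHuToMaterial:
    def test_water_anchor(self):
        g = VoxelGrid((2, 2, 2))
        m = hu_to_material(np.zeros(g.shape), g)
        np.testing.assert_allclose(m.density, 1.0)
        assert np.all(m.tissue_class == TISSUE_CLASSES["soft_tissue"])

    def test_air_anchor(self):
        g = VoxelGrid((2, 2, 2))
        m = hu_to_material(np.full(g.shape, -1000.0), g)
        assert np.all(m.tissue_class == TISSUE_CLASSES["air"])
        np.testing.assert_allclose(m.density, 0.0012)

    def test_hand_interpolated_densities(self):
        # bundled anchors: (200, 1.10) - (1000, 1.90): HU 600 -> 1.50;
        # (0, 1.00) - (200, 1.10): HU 100 -> 1.05
        g = VoxelGrid((2, 1, 1))
        m = hu_to_material(np.array([[[600.0]], [[100.0]]]).reshape(2, 1, 1), g)
        np.testing.assert_allclose(m.density.ravel(), [1.50, 1.05])
        assert m.tissue_class.ravel().tolist() == [TISSUE_CLASSES["bone"],
                                                   TISSUE_CLASSES["soft_tissue"]]

    @pytest.mark.parametrize("bad", [np.nan, np.inf, -2000.0, 5000.0])
    def test_rejects_uncalibrated_hu(self, bad):
        g = VoxelGrid((1, 1, 1))
        with pytest.raises(ValueError):
            hu_to_material(np.full(g.shape, bad), g)


class TestSegmentSkeleton:
    def test_empty_volume_warns(self):
        with pytest.warns(UserWarning):
            mask = segment_skeleton(np.zeros((4, 4, 4)), 200.0)
        assert not mask.any()

    def test_hollow_ring_is_filled(self):
        # HU-500 ring around an HU-50 core in one slice: hole filling must
        # close the marrow cavity
        hu = np.zeros((9, 9, 1))
        hu[2:7, 2:7, 0] = 500.0
        hu[3:6, 3:6, 0] = 50.0
        mask = segment_skeleton(hu, 200.0)
        expected = np.zeros((9, 9, 1), dtype=bool)
        expected[2:7, 2:7, 0] = True
        np.testing.assert_array_equal(mask, expected)

    def test_recovers_phantom_truth_skeleton(self, phantom):
        mask = segment_skeleton(phantom.ct_hu, 200.0)
        np.testing.assert_array_equal(mask, phantom.skeleton_mask)

    def test_rejects_nonfinite_threshold(self):
        with pytest.raises(ValueError):
            segment_skeleton(np.zeros((2, 2, 2)), np.nan)


class TestAssignSkeletalRegions:
    def _one_region_table(self, f):
        rows = [{"region_id": i, "region": f"r{i}",
                 "f_bm": f[0], "f_iabm": f[1], "f_hb": f[2]}
                for i in range(1, 14)]
        return pd.DataFrame(rows)

    def test_single_region_fractions_copied(self):
        mask = np.ones((3, 3, 3), dtype=bool)
        labels = np.ones((3, 3, 3), dtype=int)
        comp = self._one_region_table((0.1, 0.3, 0.6))
        out = assign_skeletal_regions(mask, labels, comp, default_region=1)
        np.testing.assert_allclose(out.f_bm[mask], 0.1)
        np.testing.assert_allclose(out.f_hb[mask], 0.6)

    def test_rejects_row_not_summing_to_one(self):
        comp = self._one_region_table((0.5, 0.6, 0.0))
        with pytest.raises(ValueError, match="sum"):
            assign_skeletal_regions(np.ones((2, 2, 2), bool),
                                    np.ones((2, 2, 2), int), comp,
                                    default_region=1)

    def test_rejects_out_of_range_label(self):
        labels = np.full((2, 2, 2), 14)
        with pytest.raises(ValueError):
            assign_skeletal_regions(np.ones((2, 2, 2), bool), labels)

    def test_phantom_region_means_match_table(self, phantom, skeletal):
        comp = load_skeletal_composition().set_index("region_id")
        for rid in range(1, 14):
            sel = skeletal.region_label == rid
            assert sel.any(), f"region {rid} missing from phantom"
            # per-voxel lookup is exact, so the region values are uniform
            assert np.all(skeletal.f_bm[sel] == comp.loc[rid, "f_bm"])
            assert np.all(skeletal.f_hb[sel] == comp.loc[rid, "f_hb"])

    def test_fraction_sum_is_exactly_one(self, skeletal):
        skel = skeletal.skeleton_mask
        total = skeletal.f_bm + skeletal.f_iabm + skeletal.f_hb
        assert np.all(np.abs(total[skel] - 1.0) <= 1e-9)
        assert np.all(total[~skel] == 0.0)

    def test_default_region_fills_unlabeled_voxels(self):
        mask = np.ones((2, 2, 2), bool)
        labels = np.zeros((2, 2, 2), int)
        out = assign_skeletal_regions(mask, labels,
                                      default_region="lumbar_spine")
        comp = load_skeletal_composition().set_index("region")
        np.testing.assert_allclose(out.f_bm[mask],
                                   comp.loc["lumbar_spine", "f_bm"])


class TestKmeansSegment:
    def test_matches_threshold_oracle(self, rng):
        vol = np.concatenate([0.1 + 0.01 * rng.standard_normal(500),
                              10.0 + 0.01 * rng.standard_normal(500)])
        vol = vol.reshape(10, 10, 10)
        labels = kmeans_segment(vol, 2, np.ones(vol.shape, bool), seed=0)
        oracle = np.where(vol > 5.05, 2, 1)
        np.testing.assert_array_equal(labels, oracle)

    def test_rejects_constant_input(self):
        with pytest.raises(ValueError):
            kmeans_segment(np.ones((3, 3, 3)), 2, np.ones((3, 3, 3), bool))

    def test_recovers_phantom_lesions(self, phantom):
        body = phantom.truth_voi >= 1
        kidneys = np.isin(phantom.truth_voi, (2, 3))
        labels = kmeans_segment(phantom.activity_24h, 2, body & ~kidneys,
                                seed=0)
        np.testing.assert_array_equal(labels == 2, phantom.lesion_mask)

    def test_deterministic_and_order_invariant(self, rng):
        vol = rng.random((6, 6, 6))
        mask = np.ones(vol.shape, bool)
        a = kmeans_segment(vol, 3, mask, seed=42)
        b = kmeans_segment(vol, 3, mask, seed=42)
        np.testing.assert_array_equal(a, b)
        perm = rng.permutation(vol.size)
        shuffled = vol.ravel()[perm].reshape(vol.shape)
        c = kmeans_segment(shuffled, 3, mask, seed=42)
        np.testing.assert_array_equal(c.ravel(), a.ravel()[perm])


class TestGeneratePhantom:
    def test_no_lesion_config(self):
        cfg = PhantomConfig(n_bone_lesions=0, n_soft_lesions=0,
                            lesion_fraction=0.0)
        pat = generate_phantom(cfg, seed=2)
        assert not pat.lesion_mask.any()
        assert set(np.unique(pat.truth_voi)) == {0, 1, 2, 3}

    def test_lesion_tia_fraction_bookkeeping(self):
        cfg = PhantomConfig(lesion_tia_fraction=0.5)
        pat = generate_phantom(cfg, seed=3)
        frac = pat.truth_tia[pat.lesion_mask].sum() / pat.truth_tia.sum()
        assert frac == pytest.approx(0.5, abs=1e-9)

    def test_same_seed_is_bit_identical(self):
        a = generate_phantom(PhantomConfig(), seed=7)
        b = generate_phantom(PhantomConfig(), seed=7)
        assert np.array_equal(a.ct_hu, b.ct_hu)
        assert np.array_equal(a.truth_tia, b.truth_tia)
        assert a.measured.equals(b.measured)

    def test_truth_tia_matches_analytic_integral(self, phantom):
        from marrowdose import tia_analytic
        for name in ("kidney_L", "kidney_R", "lesions", "rob"):
            expected = tia_analytic(phantom.truth_kinetics[name])
            assert phantom.compartment_tias[name] == pytest.approx(
                expected, rel=1e-12)
        assert phantom.truth_tia.sum() == pytest.approx(
            sum(phantom.compartment_tias.values()), rel=1e-9)

    def test_t0_activity_within_administered(self, phantom):
        a0 = sum(float(phantom.truth_kinetics[k].amplitudes.sum())
                 for k in ("kidney_L", "kidney_R", "lesions", "rob"))
        assert a0 <= phantom.administered_gbq * 1000.0 + 1e-9

    def test_rejects_nonpositive_activity(self):
        with pytest.raises(ValueError):
            generate_phantom(PhantomConfig(administered_gbq=0.0), seed=0)

    def test_rejects_overfull_compartments(self):
        with pytest.raises(ValueError, match="exceed"):
            PhantomConfig(rob_fraction=0.99).validate()
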