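import numpy as np
import pytest

import voxel2id as v
from voxel2id.io import MaskedVolume, VolumeError


def _masked(arr):
    return MaskedVolume(np.asarray(arr, float), "T1")


class TestPhaseFeatureMatrix:
    def test_twelve_by_L(self, rng):
        arr = rng.uniform(0, 10, (16, 16, 155))
        pm = v.phase_feature_matrix(_masked(arr), v.TransformConfig(gray_levels=16))
        assert pm.values.shape == (12, 155)
        assert pm.row_names == v.ROW_NAMES
        assert np.all(np.isfinite(pm.values))

    def test_generalizes_in_L(self, rng):
        arr = rng.uniform(0, 10, (16, 16, 32))
        pm = v.phase_feature_matrix(_masked(arr), v.TransformConfig(gray_levels=16))
        assert pm.values.shape == (12, 32)

    def test_fos_only_degenerate_is_6_rows(self, rng):
        arr = rng.uniform(0, 10, (16, 16, 8))
        cfg = v.TransformConfig(gray_levels=16, include_glrlm=False)
        assert v.phase_feature_matrix(_masked(arr), cfg).values.shape == (6, 8)

    def test_cleaned_slice_column_matches_zero_signature(self, rng):
        arr = rng.uniform(1, 10, (16, 16, 6))
        arr[:, :, 3] = 0.0  # as left by cleaning
        cfg = v.TransformConfig(gray_levels=16)
        pm = v.phase_feature_matrix(_masked(arr), cfg)
        # signature computed once from a pure all-zero slice
        zero_only = np.zeros((16, 16, 1))
        zero_only_vol = MaskedVolume(
            np.concatenate([arr[:, :, :1], zero_only], axis=2), "T1")
        sig = v.phase_feature_matrix(zero_only_vol, cfg).values[:, 1]
        np.testing.assert_allclose(pm.values[:, 3], sig)

    def test_zero_slice_volume_rejected(self):
        with pytest.raises(VolumeError, match="zero slices"):
            v.phase_feature_matrix(_masked(np.zeros((4, 4, 0))))


class TestNormalizeRows:
    def _pm(self, values):
        return v.PhaseFeatureMatrix(np.asarray(values, float), "T1",
                                    row_names=("r",) * len(values))

    def test_minmax_example(self):
        out = v.normalize_rows(self._pm([[2, 4, 6]]), "minmax")
        np.testing.assert_allclose(out.values, [[0, 0.5, 1]])

    def test_zscore_example_population_sigma(self):
        out = v.normalize_rows(self._pm([[1, 2, 3]]), "zscore")
        np.testing.assert_allclose(out.values, [[-1.22474, 0, 1.22474]],
                                   atol=1e-5)

    @pytest.mark.parametrize("mode", ["minmax", "zscore"])
    def test_constant_row_maps_to_zeros(self, mode):
        out = v.normalize_rows(self._pm([[5, 5, 5], [1, 2, 3]]), mode)
        assert np.all(out.values[0] == 0)
        assert np.any(out.values[1] != 0)

    def test_none_is_identity(self, rng):
        pm = self._pm(rng.uniform(0, 1, (3, 5)))
        np.testing.assert_array_equal(
            v.normalize_rows(pm, "none").values, pm.values)

    @pytest.mark.parametrize("mode", ["minmax", "zscore"])
    def test_positive_affine_invariance(self, mode, rng):
        row = rng.uniform(0, 1, (1, 10))
        a, b = 3.7, 12.0
        out1 = v.normalize_rows(self._pm(row), mode).values
        out2 = v.normalize_rows(self._pm(a * row + b), mode).values
        np.testing.assert_allclose(out1, out2, atol=1e-9)

    def test_minmax_range_and_zscore_moments(self, rng):
        pm = self._pm(rng.uniform(-5, 5, (6, 20)))
        mm = v.normalize_rows(pm, "minmax").values
        assert mm.min() >= 0 and mm.max() <= 1
        zs = v.normalize_rows(pm, "zscore").values
        np.testing.assert_allclose(zs.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(zs.std(axis=1), 1, atol=1e-9)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            v.normalize_rows(self._pm([[1, 2]]), "robust")


class TestAssemble:
    def _pm(self, label, L=5, seed=0):
        rng = np.random.default_rng(seed)
        return v.PhaseFeatureMatrix(rng.uniform(0, 1, (12, L)), label)

    def test_stacks_to_48_rows(self):
        mats = [self._pm(p, seed=i) for i, p in enumerate(v.PHASE_LABELS)]
        img = v.assemble_identity_image(mats, "c")
        assert img.values.shape == (48, 5)
        np.testing.assert_array_equal(img.values[:12], mats[0].values)

    def test_dispatch_by_label_not_position(self):
        mats = [self._pm(p, seed=i) for i, p in enumerate(v.PHASE_LABELS)]
        shuffled = [mats[2], mats[0], mats[3], mats[1]]
        a = v.assemble_identity_image(mats, "c").values
        b = v.assemble_identity_image(shuffled, "c").values
        np.testing.assert_array_equal(a, b)

    def test_missing_phase_rejected(self):
        with pytest.raises(VolumeError, match="missing phase"):
            v.assemble_identity_image([self._pm("T1")], "c")

    def test_mixed_L_rejected(self):
        mats = [self._pm(p, L=5) for p in v.PHASE_LABELS[:3]]
        mats.append(self._pm("FLAIR", L=6))
        with pytest.raises(VolumeError, match="mixed slice counts"):
            v.assemble_identity_image(mats, "c")

    def test_mixed_normalization_rejected(self):
        mats = [self._pm(p) for p in v.PHASE_LABELS]
        mats[0] = v.normalize_rows(mats[0], "zscore")
        with pytest.raises(VolumeError, match="mixed normalization"):
            v.assemble_identity_image(mats, "c")


class TestTransformCase:
    def test_deterministic_bit_identical(self, small_case):
        phases, labels = small_case
        cfg = v.TransformConfig()
        a = v.transform_case(phases, labels, cfg)
        b = v.transform_case(phases, labels, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_zscore_rows_standardized(self, small_identity):
        vals = small_identity.values
        nonconst = vals.std(axis=1) > 0
        np.testing.assert_allclose(vals[nonconst].mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(vals[nonconst].std(axis=1), 1, atol=1e-9)

    def test_matches_normalize_then_stack_oracle(self, small_case):
        """Per-phase normalization happens before stacking; row-normalizing
        the stacked unnormalized image is generally different."""
        phases, labels = small_case
        cfg_none = v.TransformConfig(normalization="none")
        cfg_z = v.TransformConfig(normalization="zscore")
        pipeline = v.transform_case(phases, labels, cfg_z)

        mask = v.binarize_mask(labels)
        mats = []
        for ph in phases:
            masked = v.apply_tumor_mask(ph, mask)
            masked = v.clean_null_slices(masked, v.default_tau(masked))
            pm = v.phase_feature_matrix(masked, cfg_none)
            mats.append(v.normalize_rows(pm, "zscore"))
        oracle = v.assemble_identity_image(mats, "oracle")
        np.testing.assert_array_equal(pipeline.values, oracle.values)

    def test_output_shape_contract(self, small_case):
        phases, labels = small_case
        img = v.transform_case(phases, labels, v.TransformConfig())
        assert img.values.shape == (48, phases[0].n_slices)
        assert img.phase_order == v.PHASE_LABELS

    def test_stage_error_carries_phase_name(self, small_case):
        phases, labels = small_case
        bad = v.PhaseVolume(phases[0].intensities[:, :, :1], "T1")
        with pytest.raises(VolumeError, match="phase T1"):
            v.transform_case([bad] + list(phases[1:]), labels)


class TestExport:
    def test_lossless_round_trip(self, small_identity, tmp_path):
        p = tmp_path / "img.npz"
        v.export_identity(small_identity, p)
        back = v.load_identity(p)
        np.testing.assert_array_equal(back.values, small_identity.values)
        assert back.phase_order == small_identity.phase_order
        assert back.normalization == "zscore"
        assert back.config_hash == small_identity.config_hash

    def test_8bit_rescale_contract(self, small_identity, tmp_path):
        from PIL import Image

        p = tmp_path / "img.png"
        v.export_identity(small_identity, p, "image-8bit")
        arr = np.asarray(Image.open(p))
        assert small_identity.values.min() < 0  # zscore has negatives
        assert arr.min() == 0 and arr.max() == 255
        assert arr.shape == small_identity.values.shape

    def test_8bit_constant_image_all_zero(self, tmp_path):
        from PIL import Image

        img = v.IdentityImage(np.full((4, 3), 2.5), v.PHASE_LABELS,
                              "none", "c")
        p = tmp_path / "c.png"
        v.export_identity(img, p, "image-8bit")
        assert not np.asarray(Image.open(p)).any()

    def test_unknown_format_rejected(self, small_identity, tmp_path):
        with pytest.raises(ValueError, match="format"):
            v.export_identity(small_identity, tmp_path / "x", "tiff-16")
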