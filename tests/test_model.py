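"""Backbone contracts: shapes, determinism, equivariance, checkpointing."""

import numpy as np
import pytest

from lesionseg.geometry import (
    MulticontrastVolume,
    Slab25D,
    TransformDescriptor,
    list_augmentations,
)
from lesionseg.model import (
    BackboneConfig,
    SegmentationModel,
    TINY_CONFIG,
    build_backbone,
    contrast_dropout,
    predict_slice,
    segment_volume,
    standardize_volume,
)
from lesionseg.normalization import all_combinations


@pytest.fixture(scope="module")
def tiny_model():
    return build_backbone(TINY_CONFIG, seed=1)


class TestConfig:
    def test_default_is_five_levels_to_1024(self):
        cfg = BackboneConfig()
        assert cfg.levels == 5
        assert cfg.channels == (64, 128, 256, 512, 1024)
        assert cfg.in_channels == 12

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            BackboneConfig(levels=1, channels=(8,))
        with pytest.raises(ValueError):
            BackboneConfig(levels=2, channels=(16, 8))

    def test_default_backbone_has_1024_bottleneck(self):
        model = build_backbone(BackboneConfig(), seed=0)
        # last conv of the bottleneck block outputs 1024 channels
        convs = [l for l in model.bottleneck if hasattr(l, "W")]
        assert convs[-1].W.shape[0] == 1024


class TestForward:
    def test_tiny_output_shape_and_range(self, tiny_model):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 12, 32, 32))
        y = tiny_model.forward(x, np.array([15, 15]))
        assert y.shape == (2, 32, 32)
        assert (y >= 0).all() and (y <= 1).all()

    def test_eval_forward_is_deterministic(self, tiny_model):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 12, 16, 16))
        y1 = tiny_model.forward(x, np.array([15]))
        y2 = tiny_model.forward(x, np.array([15]))
        np.testing.assert_array_equal(y1, y2)

    def test_all_zero_slab_gives_valid_map(self, tiny_model):
        slab = Slab25D(np.zeros((12, 16, 16)), "axial", 0)
        y = predict_slice(tiny_model, slab, combo=15)
        assert y.shape == (16, 16)
        assert np.isfinite(y).all()
        assert (y >= 0).all() and (y <= 1).all()

    def test_range_on_100_random_slabs(self, tiny_model):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 5, size=(100, 12, 16, 16))
        combos = rng.integers(1, 16, size=100)
        y = tiny_model.forward(x, combos, use_ttin=True)
        assert np.isfinite(y).all()
        assert (y >= 0).all() and (y <= 1).all()

    def test_in_mode_ttin_equals_eval_at_batch_one(self):
        model = build_backbone(BackboneConfig(levels=2, channels=(8, 16), norm_mode="IN"), seed=3)
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 12, 16, 16))
        np.testing.assert_allclose(
            model.forward(x, np.array([15]), use_ttin=True),
            model.forward(x, np.array([15]), use_ttin=False),
        )

    def test_channel_mismatch_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(np.zeros((1, 8, 16, 16)), np.array([15]))

    def test_odd_extent_padded_and_cropped(self, tiny_model):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(1, 12, 15, 17))
        y = tiny_model.forward(x, np.array([15]))
        assert y.shape == (1, 15, 17)


class TestSegmentVolume:
    @staticmethod
    def _vol(seed=0, shape=(8, 8, 8)):
        rng = np.random.default_rng(seed)
        return MulticontrastVolume(rng.normal(1.0, 0.3, size=(4,) + shape), np.ones(4, bool))

    class _ConstantModel:
        """Test double obeying the forward contract with a fixed output."""

        def __init__(self, value):
            self.value = value
            self.config = TINY_CONFIG

        def forward(self, x, combos, train=False, use_ttin=False):
            return np.full((x.shape[0],) + x.shape[2:], self.value)

    class _ChannelThresholdModel:
        """Equivariant-by-construction double: thresholds the central FLAIR."""

        def __init__(self):
            self.config = TINY_CONFIG

        def forward(self, x, combos, train=False, use_ttin=False):
            return (x[:, 7] > 1.0).astype(float)  # central-slice FLAIR channel

    def test_constant_zero_model_gives_empty_mask(self):
        vol = self._vol()
        for d in list_augmentations()[:4]:
            assert segment_volume(self._ConstantModel(0.0), vol, d, combo=15).sum() == 0

    def test_constant_one_model_gives_full_mask_any_transform(self):
        vol = self._vol()
        for d in list_augmentations():
            mask = segment_volume(self._ConstantModel(1.0), vol, d, combo=15)
            assert mask.shape == vol.shape
            assert mask.all()

    def test_equivariant_model_agrees_across_all_24_transforms(self):
        """A voxel-wise model must give the same mask under every transform."""
        vol = self._vol(seed=5)
        model = self._ChannelThresholdModel()
        ref = segment_volume(model, vol, list_augmentations()[0], combo=15)
        assert 0 < ref.sum() < ref.size
        for d in list_augmentations()[1:]:
            np.testing.assert_array_equal(segment_volume(model, vol, d, combo=15), ref)

    def test_real_tiny_model_mask_is_binary_original_grid(self, tiny_model):
        vol = self._vol(seed=6, shape=(6, 8, 10))
        d = TransformDescriptor("sagittal", 1, True)
        mask = segment_volume(tiny_model, vol, d, combo=15)
        assert mask.shape == vol.shape
        assert set(np.unique(mask)) <= {0, 1}


class TestContrastDropout:
    @staticmethod
    def _vol(present=(True, True, True, True)):
        arr = np.ones((4, 4, 4, 4))
        return MulticontrastVolume(arr, np.array(present))

    def test_single_contrast_survives_unchanged(self):
        vol = self._vol((False, False, False, True))
        (out,) = contrast_dropout([vol], np.random.default_rng(0))
        np.testing.assert_array_equal(out.present, vol.present)

    def test_at_least_one_contrast_always_survives(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            (out,) = contrast_dropout([self._vol()], rng)
            assert out.present.any()

    def test_dropped_channels_zeroed_and_flagged(self):
        rng = np.random.default_rng(2)
        (out,) = contrast_dropout([self._vol()], rng)
        for i in range(4):
            if not out.present[i]:
                assert (out.intensities[i] == 0).all()

    def test_seeded_reproducibility(self):
        outs1 = contrast_dropout([self._vol()] * 5, np.random.default_rng(7))
        outs2 = contrast_dropout([self._vol()] * 5, np.random.default_rng(7))
        for a, b in zip(outs1, outs2):
            np.testing.assert_array_equal(a.present, b.present)

    def test_all_15_combinations_occur(self):
        from lesionseg.normalization import combo_from_present

        rng = np.random.default_rng(3)
        seen = set()
        for _ in range(2000):
            (out,) = contrast_dropout([self._vol()], rng)
            seen.add(combo_from_present(out.present))
        assert seen == set(all_combinations())


class TestStandardize:
    def test_nonzero_voxels_zero_mean_unit_sd(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(50, 7, size=(4, 8, 8, 8))
        arr[:, :2] = 0.0  # air
        vol = MulticontrastVolume(arr, np.ones(4, bool))
        out = standardize_volume(vol)
        for c in range(4):
            nz = out.intensities[c] != 0
            assert abs(out.intensities[c][nz].mean()) < 1e-8
            assert abs(out.intensities[c][nz].std() - 1) < 1e-8

    def test_absent_contrast_stays_zero(self):
        arr = np.ones((4, 4, 4, 4))
        vol = MulticontrastVolume(arr, np.array([True, True, True, False]))
        out = standardize_volume(vol)
        assert (out.intensities[3] == 0).all()


class TestCheckpoint:
    def test_save_load_predict_bit_identical(self, tmp_path):
        for mode in ("BN", "IN", "CondIN"):
            model = build_backbone(
                BackboneConfig(levels=2, channels=(8, 16), norm_mode=mode), seed=9
            )
            # make BN moving stats non-trivial before saving
            rng = np.random.default_rng(9)
            x = rng.normal(size=(2, 12, 16, 16))
            model.forward(x, np.array([15, 15]), train=True)
            model.backward(np.zeros((2, 16, 16)))
            path = tmp_path / f"ckpt_{mode}.npz"
            model.save(path)
            loaded = SegmentationModel.load(path)
            xt = rng.normal(size=(1, 12, 16, 16))
            for ttin in (False, True):
                np.testing.assert_array_equal(
                    model.forward(xt, np.array([15]), use_ttin=ttin),
                    loaded.forward(xt, np.array([15]), use_ttin=ttin),
                )
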