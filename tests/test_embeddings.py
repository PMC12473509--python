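"""Branch embeddings: temporal shift, shape contracts, alignment."""

import numpy as np
import pytest

from facephys.embeddings import (
    BRANCH_ORDER,
    LandmarkEmbedding,
    STMapEmbedding,
    SubregionEmbedding,
    concat_features,
    wtsm,
    wtsm_tensor,
)
from facephys.nn import Tensor
from facephys.preprocessing import SubregionClip

RNG = np.random.default_rng(0)


def clip_tensor(B=1, L=10, C=3, h=25, w=25):
    return Tensor(RNG.normal(0, 1, (B, L, C, h, w)).astype(np.float32))


class TestWTSM:
    def test_shape_preserved(self):
        x = clip_tensor()
        assert wtsm_tensor(x, 3).shape == x.shape

    def test_constant_clip_zero_filled_ends(self):
        x = Tensor(np.ones((1, 6, 3, 4, 4), dtype=np.float32))
        y = wtsm_tensor(x, 3).data
        # group 1 (shifted forward): first frame vacated
        np.testing.assert_array_equal(y[0, 0, 0], 0.0)
        np.testing.assert_array_equal(y[0, 1:, 0], 1.0)
        # group 2 (shifted backward): last frame vacated
        np.testing.assert_array_equal(y[0, -1, 1], 0.0)
        np.testing.assert_array_equal(y[0, :-1, 1], 1.0)
        # group 3 untouched
        np.testing.assert_array_equal(y[0, :, 2], 1.0)

    def test_impulse_moves_forward_one_frame(self):
        x = np.zeros((1, 8, 3, 2, 2), dtype=np.float32)
        x[0, 4, 0] = 1.0  # impulse in a forward-shifted channel at t0=4
        y = wtsm_tensor(Tensor(x), 3).data
        assert y[0, 5, 0].max() == 1.0
        assert y[0, 4, 0].max() == 0.0

    def test_linearity(self):
        a, b = clip_tensor(), clip_tensor()
        lhs = wtsm_tensor(Tensor(2.0 * a.data + 3.0 * b.data), 3).data
        rhs = 2.0 * wtsm_tensor(a, 3).data + 3.0 * wtsm_tensor(b, 3).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-6)

    def test_incompatible_fold_div_rejected(self):
        with pytest.raises(ValueError):
            wtsm_tensor(clip_tensor(), 4)  # 3 // 4 == 0 channels per group

    def test_numpy_clip_wrapper(self):
        clip = SubregionClip("left_eye", RNG.uniform(0, 1, (6, 3, 25, 25)).astype(np.float32))
        out = wtsm(clip, 3)
        assert out.pixels.shape == clip.pixels.shape
        assert out.region == "left_eye"


class TestSubregionEmbedding:
    def test_eye_shape(self):
        emb = SubregionEmbedding("left_eye", 16, np.random.default_rng(0))
        out = emb(clip_tensor(B=2, L=12))
        assert out.shape == (2, 12, 16)

    def test_mouth_shape(self):
        emb = SubregionEmbedding("mouth", 16, np.random.default_rng(0))
        out = emb(clip_tensor(B=1, L=12, h=15, w=35))
        assert out.shape == (1, 12, 16)

    def test_zero_input_zero_biases_zero_output(self):
        emb = SubregionEmbedding("left_eye", 8, np.random.default_rng(0))
        for t in (emb.conv1.bias, emb.conv2.bias, emb.fc.bias):
            t.data[:] = 0.0
        out = emb(Tensor(np.zeros((1, 4, 3, 25, 25), dtype=np.float32)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-8)

    def test_per_frame_determinism_without_wtsm(self):
        """With the temporal shift disabled, identical frames at different
        timesteps embed identically (the encoder is purely per-frame)."""
        emb = SubregionEmbedding("left_eye", 8, np.random.default_rng(0), use_wtsm=False)
        frame = RNG.normal(0, 1, (3, 25, 25)).astype(np.float32)
        x = np.stack([frame] * 5)[None]
        out = emb(Tensor(x)).data
        np.testing.assert_allclose(out[0, 0], out[0, 3], atol=1e-6)

    def test_bad_shape_rejected(self):
        emb = SubregionEmbedding("left_eye", 8, np.random.default_rng(0))
        with pytest.raises(ValueError):
            emb(clip_tensor(h=15, w=35))

    def test_nonpositive_d_rejected(self):
        with pytest.raises(ValueError):
            SubregionEmbedding("left_eye", 0, np.random.default_rng(0))


class TestLandmarkEmbedding:
    def test_shape(self):
        emb = LandmarkEmbedding(16, np.random.default_rng(0))
        out = emb(Tensor(RNG.uniform(0, 1, (2, 12, 106, 2)).astype(np.float32)))
        assert out.shape == (2, 12, 16)

    def test_translation_is_not_invariant(self):
        """Documented non-invariance: shifting all landmarks changes the
        embedding (the encoder sees absolute positions)."""
        emb = LandmarkEmbedding(8, np.random.default_rng(0))
        emb.eval()
        x = RNG.uniform(0.2, 0.6, (1, 4, 106, 2)).astype(np.float32)
        a = emb(Tensor(x)).data
        b = emb(Tensor(x + 0.1)).data
        assert np.abs(a - b).max() > 1e-4

    def test_wrong_point_count_rejected(self):
        emb = LandmarkEmbedding(8, np.random.default_rng(0))
        with pytest.raises(ValueError):
            emb(Tensor(np.zeros((1, 4, 68, 2), dtype=np.float32)))


class TestSTMapEmbedding:
    def test_shape_and_time_resampling(self):
        emb = STMapEmbedding(16, np.random.default_rng(0))
        out = emb(Tensor(RNG.uniform(0, 1, (2, 3, 25, 300)).astype(np.float32)), 300)
        assert out.shape == (2, 300, 16)

    def test_output_length_forced_to_L(self):
        """Valid convolutions shorten the time axis internally; adaptive
        pooling restores exactly L steps."""
        emb = STMapEmbedding(8, np.random.default_rng(0))
        out = emb(Tensor(RNG.uniform(0, 1, (1, 3, 25, 123)).astype(np.float32)), 123)
        assert out.shape == (1, 123, 8)

    def test_time_constant_map_gives_constant_features(self):
        emb = STMapEmbedding(8, np.random.default_rng(0))
        emb.eval()
        vals = np.tile(RNG.uniform(0, 1, (1, 3, 25, 1)), (1, 1, 1, 60)).astype(np.float32)
        out = emb(Tensor(vals), 60).data
        np.testing.assert_allclose(out - out[:, :1, :], 0.0, atol=1e-5)

    def test_small_spatial_axis_rejected(self):
        emb = STMapEmbedding(8, np.random.default_rng(0))
        with pytest.raises(ValueError):
            emb(Tensor(np.zeros((1, 3, 4, 60), dtype=np.float32)), 60)


class TestConcatFeatures:
    def branches(self, L=20, d=16):
        return {k: Tensor(RNG.normal(0, 1, (1, L, d)).astype(np.float32))
                for k in BRANCH_ORDER}

    @pytest.mark.parametrize("d,expected", [(16, 80), (64, 320)])
    def test_width_is_five_d(self, d, expected):
        out = concat_features(self.branches(d=d))
        assert out.shape == (1, 20, expected)

    def test_column_blocks_follow_branch_order(self):
        br = self.branches(d=4)
        out = concat_features(br).data
        for i, k in enumerate(BRANCH_ORDER):
            np.testing.assert_array_equal(out[:, :, 4 * i : 4 * (i + 1)], br[k].data)

    def test_mismatched_lengths_rejected(self):
        br = self.branches()
        br["stmap"] = Tensor(RNG.normal(0, 1, (1, 19, 16)).astype(np.float32))
        with pytest.raises(ValueError):
            concat_features(br)

    def test_missing_branch_rejected(self):
        br = self.branches()
        del br["mouth"]
        with pytest.raises(KeyError):
            concat_features(br)
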