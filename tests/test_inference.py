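"""Sliding windows, end-to-end prediction, TTA and the uncertainty score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemseg.inference import (PredictConfig, SpatialTransform, TTAConfig,
                              calibrate_threshold, plan_sliding_windows,
                              predict_case, sliding_window_infer, tta_predict,
                              uncertainty_score, volume_of)
from hemseg.metrics import dice_coefficient


class _ConstantModel:
    """Returns the same probability triple everywhere, whatever the input."""

    def __init__(self, probs=(0.2, 0.5, 0.3), patch=(8, 16, 16)):
        self.probs = probs

        class cfg:
            patch_size = patch
        self.cfg = cfg

    def predict_probs(self, patch):
        out = np.empty((3, *patch.shape), np.float32)
        for c, p in enumerate(self.probs):
            out[c] = p
        return out


class _WindowOracleModel:
    """Thresholds the brain-windowed intensities: the phantom's HU structure
    makes hemorrhage bright (~0.81) and edema dark (~0.23) so near-perfect
    probabilities can be read off the input directly."""

    def __init__(self, patch=(16, 64, 64)):
        class cfg:
            patch_size = patch
        self.cfg = cfg

    def predict_probs(self, patch):
        out = np.zeros((3, *patch.shape), np.float32)
        ich = patch > 0.62
        phe = (patch > 0.15) & (patch < 0.34)
        out[1][ich] = 1.0
        out[2][phe] = 1.0
        out[0] = 1.0 - out[1] - out[2]
        return out


class TestPlan:
    def test_single_window_when_image_smaller(self):
        plan = plan_sliding_windows((16, 64, 64), (32, 256, 256), 0.5)
        assert plan.origins == [(0, 0, 0)]
        assert plan.padded_shape == (32, 256, 256)

    def test_clamped_final_origin(self):
        """Axis 300 / window 256 / overlap 0.5: stride 128 gives 0, then the
        next window would overrun, so the last origin clamps to 44."""
        plan = plan_sliding_windows((300, 256, 256), (256, 256, 256), 0.5)
        first_axis = sorted({o[0] for o in plan.origins})
        assert first_axis == [0, 44]

    def test_every_voxel_covered(self):
        plan = plan_sliding_windows((37, 50, 41), (16, 24, 20), 0.3)
        covered = np.zeros(plan.padded_shape, bool)
        for o in plan.origins:
            covered[o[0]:o[0] + 16, o[1]:o[1] + 24, o[2]:o[2] + 20] = True
        assert covered.all()

    def test_stride_bounded(self):
        plan = plan_sliding_windows((100, 100, 100), (32, 32, 32), 0.5)
        for axis in range(3):
            origins = sorted({o[axis] for o in plan.origins})
            stride_cap = int(np.ceil(32 * 0.5))
            assert all(b - a <= stride_cap for a, b in zip(origins, origins[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            plan_sliding_windows((8, 8, 8), (0, 8, 8), 0.5)
        with pytest.raises(ValueError):
            plan_sliding_windows((8, 8, 8), (8, 8, 8), 1.0)


class TestSlidingWindowInfer:
    def test_constant_model_blends_to_constant(self):
        model = _ConstantModel()
        vol = np.random.default_rng(0).random((20, 40, 40)).astype(np.float32)
        plan = plan_sliding_windows(vol.shape, (8, 16, 16), 0.5)
        probs = sliding_window_infer(model, vol, plan)
        for c, p in enumerate(model.probs):
            np.testing.assert_allclose(probs[c], p, atol=1e-5)

    def test_output_on_simplex(self):
        model = _ConstantModel((0.6, 0.3, 0.1))
        vol = np.zeros((10, 20, 20), np.float32)
        plan = plan_sliding_windows(vol.shape, (8, 16, 16), 0.25, blend="uniform")
        probs = sliding_window_infer(model, vol, plan)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    def test_single_covering_window_equals_padded_forward(self):
        """With one window the blended result is exactly the padded forward
        pass cropped back."""
        from hemseg.network import DualModel, DualModelConfig
        model = DualModel(DualModelConfig(patch_size=(8, 32, 32), base_width=4,
                                          levels=2, seed=3))
        vol = np.random.default_rng(4).random((6, 20, 24)).astype(np.float32)
        plan = plan_sliding_windows(vol.shape, (8, 32, 32), 0.5)
        assert len(plan.origins) == 1
        blended = sliding_window_infer(model, vol, plan)
        padded = np.pad(vol, plan.pad)
        direct = model.predict_probs(padded)
        crop = tuple(slice(lo, lo + s) for (lo, _), s in zip(plan.pad, vol.shape))
        np.testing.assert_allclose(blended, direct[(slice(None),) + crop],
                                   atol=1e-5)


class TestVolume:
    def test_examples(self):
        assert volume_of(np.zeros((4, 4, 4)), 1, (1, 1, 1)) == 0.0
        mask = np.zeros((10, 10, 10)); mask[:10, :10, :10] = 1
        assert volume_of(mask, 1, (1, 1, 1)) == pytest.approx(1.0)

    def test_linear_in_spacing(self):
        mask = np.ones((5, 5, 5))
        v1 = volume_of(mask, 1, (1, 1, 1))
        v2 = volume_of(mask, 1, (2, 1, 1))
        assert v2 == pytest.approx(2 * v1)


class TestUncertaintyScore:
    def test_identical_volumes_score_zero(self):
        assert uncertainty_score(7.0, [7.0, 7.0, 7.0]) == 0.0

    def test_vanished_baseline_scores_one(self):
        assert uncertainty_score(0.0, [5.0, 2.0]) == 1.0

    def test_hand_evaluated_example(self):
        assert uncertainty_score(10.0, [10.0, 30.0]) == pytest.approx(0.25)

    def test_agreement_on_absence_contributes_zero(self):
        assert uncertainty_score(0.0, [0.0, 0.0]) == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            uncertainty_score(1.0, [])

    @given(st.lists(st.floats(0.0, 1e6), min_size=1, max_size=10),
           st.floats(0.0, 1e6), st.floats(0.01, 100.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_range_permutation_and_scale_invariance(self, vi, v0, c):
        s = uncertainty_score(v0, vi)
        assert 0.0 <= s <= 1.0
        assert uncertainty_score(v0, vi[::-1]) == pytest.approx(s, abs=1e-12)
        assert uncertainty_score(c * v0, [c * v for v in vi]) == \
            pytest.approx(s, abs=1e-9)


class TestSpatialTransform:
    def test_identity_round_trip_exact(self):
        tf = SpatialTransform()
        lab = np.random.default_rng(0).integers(0, 3, (6, 12, 12)).astype(np.uint8)
        np.testing.assert_array_equal(tf.invert_labels(tf.apply(lab, order=0),
                                                       lab.shape), lab)

    def test_flip_round_trip_exact(self):
        tf = SpatialTransform(flip_lr=True)
        lab = np.random.default_rng(1).integers(0, 3, (4, 8, 8)).astype(np.uint8)
        np.testing.assert_array_equal(tf.invert_labels(tf.apply(lab, order=0),
                                                       lab.shape), lab)

    def test_rotation_zoom_round_trip_near_lossless(self):
        """Rotation + zoom inverted on labels loses only boundary voxels."""
        tf = SpatialTransform(flip_lr=True, angle_deg=8.0, zoom=1.07)
        lab = np.zeros((8, 32, 32), np.uint8)
        lab[2:6, 8:24, 8:24] = 1
        back = tf.invert_labels(tf.apply(lab.astype(np.float32), order=0)
                                .astype(np.uint8), lab.shape)
        assert dice_coefficient(back == 1, lab == 1) >= 0.85


class TestEndToEnd:
    def test_oracle_model_recovers_phantom_truth(self, clean_phantom):
        """With a stub that reads class probabilities off the windowed HU
        structure, the end-to-end path recovers the ground truth almost
        perfectly — remaining loss comes only from the grid round trip."""
        pred = predict_case(_WindowOracleModel(), clean_phantom.ct,
                            PredictConfig(target_spacing=clean_phantom.ct.spacing))
        assert pred.shape == clean_phantom.ct.voxels.shape
        assert set(np.unique(pred)) <= {0, 1, 2}
        for c in (1, 2):
            assert dice_coefficient(pred == c, clean_phantom.gt == c) >= 0.95

    def test_identity_tta_scores_zero(self, clean_phantom):
        tta = TTAConfig(n=2, identity_only=True, seed=1, threshold=0.1)
        _, unc = tta_predict(_WindowOracleModel(), clean_phantom.ct, tta,
                             PredictConfig(target_spacing=clean_phantom.ct.spacing))
        assert unc.per_class["ich"]["score"] == 0.0
        assert unc.per_class["phe"]["score"] == 0.0
        assert unc.subject_score == 0.0
        assert not unc.flagged

    def test_tta_deterministic_in_seed(self, small_phantom):
        cfg = PredictConfig(target_spacing=small_phantom.ct.spacing)
        tta = TTAConfig(n=3, seed=42)
        _, a = tta_predict(_WindowOracleModel(patch=(16, 64, 64)),
                           small_phantom.ct, tta, cfg)
        _, b = tta_predict(_WindowOracleModel(patch=(16, 64, 64)),
                           small_phantom.ct, tta, cfg)
        assert a.per_class["ich"]["vi"] == b.per_class["ich"]["vi"]
        assert a.subject_score == b.subject_score

    def test_subject_score_is_mean_of_class_scores(self, small_phantom):
        cfg = PredictConfig(target_spacing=small_phantom.ct.spacing)
        _, unc = tta_predict(_WindowOracleModel(patch=(16, 64, 64)),
                             small_phantom.ct, TTAConfig(n=3, seed=0), cfg)
        expected = 0.5 * (unc.per_class["ich"]["score"]
                          + unc.per_class["phe"]["score"])
        assert unc.subject_score == pytest.approx(expected)


def test_calibrate_threshold_hits_target_rate():
    scores = np.linspace(0, 1, 101)
    thr = calibrate_threshold(scores, target_flag_rate=0.1)
    assert (scores > thr).mean() <= 0.1
    assert thr == pytest.approx(0.9, abs=0.02)
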