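"""Training: label coarsening, combined loss, schedulers, grouped folds."""

import math

import numpy as np
import pandas as pd
import pytest

from hemseg.network import DualModel, DualModelConfig, MultiResOutputs
from hemseg.training import (TrainConfig, default_supervision_weights,
                             downsample_labels, lr_schedule, multires_loss,
                             split_folds, train_model)

_EPS = 1e-5


class TestDownsampleLabels:
    def test_k0_is_identity(self):
        gt = np.random.default_rng(0).integers(0, 3, (4, 4, 4)).astype(np.uint8)
        np.testing.assert_array_equal(downsample_labels(gt, 0), gt)

    def test_uniform_block_stays_uniform(self):
        gt = np.ones((4, 4, 4), np.uint8)
        assert (downsample_labels(gt, 2) == 1).all()

    def test_tie_prefers_lesion_over_background(self):
        gt = np.zeros((2, 2, 2), np.uint8)
        gt[0] = 1                                   # four 1s, four 0s
        assert downsample_labels(gt, 1).item() == 1

    def test_tie_prefers_edema_over_hemorrhage(self):
        gt = np.zeros((2, 2, 2), np.uint8)
        gt[0] = 1
        gt[1] = 2                                   # four 1s, four 2s
        assert downsample_labels(gt, 1).item() == 2

    def test_majority_wins_when_no_tie(self):
        gt = np.zeros((2, 2, 2), np.uint8)
        gt.flat[:3] = 2                             # five 0s beat three 2s
        assert downsample_labels(gt, 1).item() == 0

    def test_no_new_labels(self):
        rng = np.random.default_rng(1)
        gt = (rng.random((8, 8, 8)) > 0.7).astype(np.uint8) * 2
        out = downsample_labels(gt, 2)
        assert set(np.unique(out)) <= {0, 2}

    def test_indivisible_shape_rejected(self):
        with pytest.raises(ValueError, match="not divisible"):
            downsample_labels(np.zeros((3, 4, 4), np.uint8), 1)


def _outputs_from_probs(prob_a, prob_b):
    return MultiResOutputs(per_branch=[[np.asarray(prob_a, np.float32)],
                                       [np.asarray(prob_b, np.float32)]])


def _one_voxel_probs(p_true, num_classes=2, true_class=1):
    prob = np.zeros((1, num_classes, 1, 1, 1), np.float32)
    prob[0, true_class] = p_true
    prob[0, 1 - true_class] = 1.0 - p_true
    return prob


class TestMultiresLoss:
    def test_perfect_one_hot_prediction_is_near_zero(self):
        gt = np.zeros((4, 4, 4), np.uint8)
        gt[1:3, 1:3, 1:3] = 1
        onehot = np.stack([(gt == c).astype(np.float32) for c in range(3)])[None]
        outs = MultiResOutputs(per_branch=[[onehot], [onehot]])
        report = multires_loss(outs, gt, weights=[1.0])
        assert report.total <= 1e-3

    def test_branch_swap_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.dirichlet([1] * 3, size=(1, 2, 2, 2)).astype(np.float32)
        b = rng.dirichlet([1] * 3, size=(1, 2, 2, 2)).astype(np.float32)
        a, b = (np.moveaxis(p, -1, 1) for p in (a, b))
        gt = rng.integers(0, 3, (2, 2, 2)).astype(np.uint8)
        t_ab = multires_loss(_outputs_from_probs(a, b), gt, weights=[1.0]).total
        t_ba = multires_loss(_outputs_from_probs(b, a), gt, weights=[1.0]).total
        assert t_ab == pytest.approx(t_ba, abs=1e-6)

    def test_sharper_correct_prediction_scores_lower(self):
        """Single-voxel two-class toy: loss at p=0.9 < loss at p=0.6."""
        gt = np.ones((1, 1, 1, 1), np.uint8)
        losses = {}
        for p in (0.9, 0.6):
            outs = _outputs_from_probs(_one_voxel_probs(p), _one_voxel_probs(p))
            losses[p] = multires_loss(outs, gt[0], weights=[1.0]).total
        assert losses[0.9] < losses[0.6]

    def test_matches_hand_evaluated_formula(self):
        """CE + (1 - soft Dice) on a single voxel, evaluated by hand."""
        p = 0.9
        gt = np.ones((1, 1, 1), np.uint8)
        outs = _outputs_from_probs(_one_voxel_probs(p), _one_voxel_probs(p))
        report = multires_loss(outs, gt, weights=[1.0])
        ce = -math.log(p + 1e-8)
        dice = (2 * p + _EPS) / (p + 1 + _EPS)
        expected = ce + (1.0 - dice)       # both branches, weights halved
        assert report.total == pytest.approx(expected, rel=1e-4)
        for branch in report.per_branch:
            assert branch[0][0] == pytest.approx(ce, rel=1e-4)
            assert branch[0][1] == pytest.approx(1.0 - dice, rel=1e-4)

    def test_loss_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = np.moveaxis(rng.dirichlet([1] * 3, size=(1, 4, 4, 4)), -1, 1)
            gt = rng.integers(0, 3, (4, 4, 4)).astype(np.uint8)
            outs = _outputs_from_probs(p, p)
            assert multires_loss(outs, gt, weights=[1.0]).total >= 0.0

    def test_misaligned_shapes_rejected(self):
        p = np.full((1, 3, 2, 2, 2), 1 / 3, np.float32)
        outs = _outputs_from_probs(p, p)
        with pytest.raises(ValueError, match="misaligned"):
            multires_loss(outs, np.zeros((4, 4, 4), np.uint8), weights=[1.0])

    def test_default_weights_geometric_and_normalized(self):
        w = default_supervision_weights(3)
        np.testing.assert_allclose(w, np.array([4, 2, 1]) / 7.0)


class TestTrainConfig:
    def test_presets_match_published_protocols(self):
        d = TrainConfig.default_protocol()
        assert (d.optimizer, d.scheduler) == ("sgd", "polynomial")
        assert d.initial_lr == pytest.approx(1e-2)
        assert d.weight_decay == pytest.approx(3e-5)
        assert d.num_epochs == 100
        c = TrainConfig.comparator_protocol()
        assert (c.optimizer, c.scheduler, c.loss) == ("adam", "cosine", "dice_focal")
        assert c.initial_lr == pytest.approx(1e-4)
        assert c.patch_size == (64, 64, 64)

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError, match="num_epochs"):
            TrainConfig(num_epochs=0)

    def test_bad_supervision_weights_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(deep_supervision_weights=(0.5, 0.6))
        with pytest.raises(ValueError):
            TrainConfig(deep_supervision_weights=(-0.5, 1.5))


class TestSchedulers:
    def test_polynomial_starts_at_initial_and_decreases(self):
        cfg = TrainConfig(num_epochs=10, initial_lr=1e-2)
        lrs = [lr_schedule(cfg, e) for e in range(10)]
        assert lrs[0] == pytest.approx(1e-2)
        assert all(a > b for a, b in zip(lrs, lrs[1:]))

    def test_cosine_decreases(self):
        cfg = TrainConfig(num_epochs=10, scheduler="cosine", initial_lr=1e-4)
        lrs = [lr_schedule(cfg, e) for e in range(10)]
        assert lrs[0] == pytest.approx(1e-4)
        assert all(a > b for a, b in zip(lrs, lrs[1:]))


def _manifest(n_patients, scans_per_patient=1):
    rows = []
    for p in range(n_patients):
        for t in range(scans_per_patient):
            rows.append({"case_id": f"c{p}_{t}", "patient_id": f"p{p}"})
    return pd.DataFrame(rows)


class TestSplitFolds:
    def test_even_patient_distribution(self):
        split = split_folds(_manifest(10), k=5, seed=1)
        sizes = [len(split.cases_in_fold(f)) for f in range(5)]
        assert sizes == [2] * 5

    def test_paired_scans_stay_together(self):
        split = split_folds(_manifest(8, scans_per_patient=2), k=4, seed=2)
        for p in range(8):
            folds = {split.assignments[f"c{p}_{t}"] for t in range(2)}
            assert len(folds) == 1

    def test_seeded_determinism(self):
        a = split_folds(_manifest(12), k=3, seed=9)
        b = split_folds(_manifest(12), k=3, seed=9)
        assert a.assignments == b.assignments

    def test_fewer_patients_than_folds_rejected(self):
        with pytest.raises(ValueError, match="fewer patients"):
            split_folds(_manifest(3), k=5, seed=0)


class TestTrainLoop:
    def test_empty_training_set_rejected(self):
        model = DualModel(DualModelConfig(patch_size=(8, 16, 16), base_width=4,
                                          levels=2))
        cfg = TrainConfig(num_epochs=1, patch_size=(8, 16, 16))
        with pytest.raises(ValueError, match="empty training set"):
            train_model(model, [], [], cfg)

    def test_two_runs_same_seed_identical(self):
        """Seeded training is bit-reproducible within a process."""
        rng = np.random.default_rng(0)
        cases = []
        for _ in range(3):
            vol = rng.random((8, 16, 16)).astype(np.float32)
            gt = (vol > 0.8).astype(np.uint8)
            cases.append((vol, gt))
        histories = []
        for _ in range(2):
            model = DualModel(DualModelConfig(patch_size=(8, 16, 16),
                                              base_width=4, levels=2, seed=5))
            cfg = TrainConfig(num_epochs=2, patch_size=(8, 16, 16),
                              batch_size=2, seed=5)
            res = train_model(model, cases, cases[:1], cfg)
            histories.append(res.history)
        pd.testing.assert_frame_equal(histories[0], histories[1])

    def test_history_contains_epoch_zero_baseline(self):
        rng = np.random.default_rng(1)
        vol = rng.random((8, 16, 16)).astype(np.float32)
        gt = (vol > 0.8).astype(np.uint8)
        model = DualModel(DualModelConfig(patch_size=(8, 16, 16), base_width=4,
                                          levels=2, seed=1))
        res = train_model(model, [(vol, gt)], [(vol, gt)],
                          TrainConfig(num_epochs=1, patch_size=(8, 16, 16), seed=1))
        assert list(res.history["epoch"]) == [0, 1]
        assert np.isnan(res.history["train_loss"].iloc[0])
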