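"""Patch prep, splitting, Dice, stopping rule, decoding, thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ptsscore import (
    TileSpec, TissueClass, UnetConfig, dice_coefficient, early_stop_epoch,
    make_labeled_tiles, predict_labelmap, reflect_pad, split_dataset,
    tissue_threshold,
)
from ptsscore.segmentation import summarize_dice, _majority_class
from ptsscore.synthetic import DEFAULT_PALETTE

from .oracles import exhaustive_multiotsu_thresholds, reference_stop_epoch


class _ColorLookupModel:
    """Stand-in segmenter: maps each pixel's exact RGB to its class.

    Lets decoding/shape contracts be tested independently of training.
    """

    depth = 0

    def predict_proba(self, x):
        n, _, h, w = x.shape
        rgb = np.rint(x.transpose(0, 2, 3, 1) * 255.0).astype(int)
        prob = np.full((n, 7, h, w), 1e-6, dtype=np.float64)
        for cls, color in DEFAULT_PALETTE.items():
            hit = (rgb == np.array(color)).all(axis=-1)
            prob[:, int(cls) - 1][hit] = 1.0
        return prob / prob.sum(axis=1, keepdims=True)


class TestReflectPad:
    def test_224_to_512_mirrors_without_edge_repeat(self):
        tile = np.arange(224 * 224 * 3, dtype=np.uint8).reshape(224, 224, 3)
        out = reflect_pad(tile, 512)
        assert out.shape == (512, 512, 3)
        # 144 px on each side; mirrored band equals the flipped interior band
        assert np.array_equal(out[144:368, 144:368], tile)
        assert np.array_equal(out[143], out[145])  # mirror plane at the edge
        assert np.array_equal(out[:, 143], out[:, 145])

    def test_already_at_target_is_unchanged(self):
        tile = np.random.default_rng(0).integers(0, 255, (512, 512)).astype(np.uint8)
        assert np.array_equal(reflect_pad(tile, 512), tile)

    def test_one_dimensional_reflect_semantics(self):
        # [a,b,c] padded by 2 on each side -> [c,b,a,b,c,b,a]
        full = reflect_pad(np.array([[1, 2, 3]]), 7)[3]
        assert full.tolist() == [3, 2, 1, 2, 3, 2, 1]

    def test_larger_than_target_rejected(self):
        with pytest.raises(ValueError, match="larger than target"):
            reflect_pad(np.zeros((600, 600)), 512)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(2, 30), st.integers(2, 30))
    def test_pad_then_center_crop_is_identity(self, h, w):
        rng = np.random.default_rng(h * 31 + w)
        tile = rng.integers(0, 255, (h, w)).astype(np.uint8)
        target = 64
        out = reflect_pad(tile, target)
        py, px = (target - h) // 2, (target - w) // 2
        assert np.array_equal(out[py : py + h, px : px + w], tile)


class TestSplitDataset:
    def _pairs(self, n, seed=0):
        spec = TileSpec(tile_size=8)
        return make_labeled_tiles(spec, n, seed=seed)

    def test_eighty_ten_ten_counts(self):
        train, val, test = split_dataset(self._pairs(100), seed=1)
        assert (len(train), len(val), len(test)) == (80, 10, 10)

    def test_disjoint_and_exhaustive(self):
        pairs = self._pairs(63)
        train, val, test = split_dataset(pairs, seed=2)
        ids = [id(p) for split in (train, val, test) for p in split]
        assert len(ids) == len(set(ids)) == 63

    def test_same_seed_identical_membership(self):
        pairs = self._pairs(50)
        a = split_dataset(pairs, seed=3)
        b = split_dataset(pairs, seed=3)
        for sa, sb in zip(a, b):
            assert [id(p) for p in sa] == [id(p) for p in sb]

    def test_stratified_within_two_tiles_on_balanced_set(self):
        pairs = self._pairs(700)  # 100 per class
        train, val, test = split_dataset(pairs, seed=4)
        for split, target in ((train, 80), (val, 10), (test, 10)):
            per_class = {}
            for _, labels in split:
                cls = _majority_class(labels)
                per_class[cls] = per_class.get(cls, 0) + 1
            assert all(abs(c - target) <= 2 for c in per_class.values())

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset(self._pairs(20), fractions=(0.8, 0.1, 0.2), seed=0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            split_dataset(self._pairs(9), seed=0)


class TestDice:
    def test_identical_masks_score_one(self):
        labels = np.full((5, 5), int(TissueClass.STROMA))
        assert dice_coefficient(labels, labels, TissueClass.STROMA) == 1.0

    def test_disjoint_single_pixels_score_zero(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.zeros((4, 4), dtype=int)
        a[0, 0] = b[3, 3] = int(TissueClass.TUMOR)
        assert dice_coefficient(a, b, TissueClass.TUMOR) == 0.0

    def test_half_overlap_scores_half(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.zeros((4, 4), dtype=int)
        a[0, 0] = a[0, 1] = int(TissueClass.MUCUS)
        b[0, 1] = b[0, 2] = int(TissueClass.MUCUS)
        assert dice_coefficient(a, b, TissueClass.MUCUS) == 0.5

    def test_absent_from_both_is_defined_one(self):
        z = np.zeros((3, 3), dtype=int)
        assert dice_coefficient(z, z, TissueClass.ADIPOSE) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            dice_coefficient(np.zeros((3, 3), int), np.zeros((4, 4), int), 1)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 8, (6, 6))
        b = rng.integers(0, 8, (6, 6))
        cls = int(rng.integers(1, 8))
        d_ab = dice_coefficient(a, b, cls)
        assert d_ab == dice_coefficient(b, a, cls)
        assert 0.0 <= d_ab <= 1.0


class TestEarlyStopping:
    @pytest.mark.parametrize("values,expected_stop,expected_best", [
        # peak at epoch 5 then flat: stop after 10 more epochs
        ([0.2, 0.4, 0.6, 0.8, 0.9] + [0.9] * 20, 15, 5),
        # monotone increase with >=0.1% gains: never triggers
        ([0.5 * 1.002 ** k for k in range(30)], 30, 30),
        # sub-threshold creep: improvements below 0.1% do not reset patience
        ([0.9] + [0.9 + 1e-6 * k for k in range(1, 25)], 11, 11),
    ])
    def test_matches_reference_on_scripted_sequences(self, values, expected_stop, expected_best):
        stop, best = early_stop_epoch(values, patience=10, min_rel_gain=0.001)
        assert stop == expected_stop
        assert stop == reference_stop_epoch(values, 10, 0.001)
        assert best == expected_best

    def test_random_sequences_agree_with_reference(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            vals = np.clip(rng.normal(0.8, 0.1, size=rng.integers(5, 40)), 0.01, 1).tolist()
            stop, _ = early_stop_epoch(vals, patience=5, min_rel_gain=0.001)
            assert stop == reference_stop_epoch(vals, 5, 0.001)


class TestPredictDecode:
    def test_probability_rows_sum_to_one_and_argmax_decodes(self):
        spec = TileSpec(tile_size=16, noise_sd=0.0, layout="quadrant")
        tile, labels = make_labeled_tiles(spec, 1, seed=0)[0]
        prob, pred = predict_labelmap(_ColorLookupModel(), tile, input_size=16)
        assert prob.shape == (16, 16, 7)
        np.testing.assert_allclose(prob.sum(axis=-1), 1.0, atol=1e-5)
        assert np.array_equal(pred, labels)

    def test_pad_predict_crop_restores_original_extent(self):
        spec = TileSpec(tile_size=24, noise_sd=0.0)
        tile, _ = make_labeled_tiles(spec, 1, seed=1)[0]
        prob, pred = predict_labelmap(_ColorLookupModel(), tile, input_size=32)
        assert prob.shape == (24, 24, 7) and pred.shape == (24, 24)


class TestDscAggregation:
    def test_perfect_predictions_give_mean_one_sd_zero(self):
        report = summarize_dice({int(c): [1.0, 1.0, 1.0] for c in TissueClass})
        for row in report.rows.values():
            assert row["mean"] == 1.0 and row["sd"] == 0.0

    def test_two_patch_closed_form(self):
        report = summarize_dice({int(TissueClass.TUMOR): [1.0, 0.5]})
        row = report.rows["tumor"]
        assert row["mean"] == pytest.approx(0.75)
        assert row["sd"] == pytest.approx(np.sqrt(0.125), abs=1e-9)  # 0.35355
        assert row["n"] == 2

    def test_ci_brackets_mean_everywhere(self):
        rng = np.random.default_rng(3)
        values = {int(c): rng.uniform(0, 1, 12).tolist() for c in TissueClass}
        report = summarize_dice(values)
        for row in report.rows.values():
            assert row["ci_lower"] <= row["mean"] <= row["ci_upper"]


class TestTissueThreshold:
    def test_all_white_tile_has_empty_mask(self):
        tile = np.full((16, 16, 3), 255, dtype=np.uint8)
        assert not tissue_threshold(tile).any()

    def test_half_dark_half_white(self):
        tile = np.full((16, 16, 3), 250, dtype=np.uint8)
        tile[:8] = 60
        mask = tissue_threshold(tile)
        assert mask[:8].all() and not mask[8:].any()

    def test_matches_exhaustive_between_class_variance_search(self):
        rng = np.random.default_rng(6)
        gray = np.concatenate([
            rng.normal(40, 6, 400), rng.normal(128, 6, 400), rng.normal(220, 6, 400),
        ]).clip(0, 255)
        from skimage.filters import threshold_multiotsu

        gray = np.rint(gray)
        hist = np.histogram(gray, bins=256, range=(-0.5, 255.5))[0]
        ours = threshold_multiotsu(classes=3, hist=(hist, np.arange(256.0)))
        cuts = exhaustive_multiotsu_thresholds(gray, classes=3)
        # same discretization; thresholds may sit on either side of a cut bin
        assert abs(ours[0] - cuts[0]) <= 1.5
        assert abs(ours[1] - cuts[1]) <= 1.5

    def test_levels_validated(self):
        with pytest.raises(ValueError, match="levels"):
            tissue_threshold(np.zeros((4, 4, 3), dtype=np.uint8), levels=1)


class TestTraining:
    def test_separable_tiles_reach_high_validation_dsc(self, separable_training):
        model, history, test, config = separable_training
        assert max(history["val_dsc"]) >= 0.95
        assert len(history["val_dsc"]) <= 20
        assert history["best_epoch"] == int(np.argmax(history["val_dsc"])) + 1

    def test_best_weights_are_restored_not_last(self, separable_training):
        from ptsscore import evaluate_dsc

        model, history, test, config = separable_training
        report = evaluate_dsc(model, test, input_size=config.input_size)
        # restored best model performs at least near the best validation DSC
        assert report.overall_mean >= 0.9
        assert all(
            row["ci_lower"] <= row["mean"] <= row["ci_upper"]
            for row in report.rows.values() if row["n"] > 0
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            UnetConfig(input_size=30, depth=3)
        with pytest.raises(ValueError, match="patience"):
            UnetConfig(input_size=32, depth=3, patience=0)
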