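import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsseg.augment import named_set, tta_set
from nsseg.datamodel import load_sample
from nsseg.metrics import (
    ConfusionCounts,
    ValidationPurityError,
    bootstrap_ci,
    confusion_counts,
    dice,
    evaluate_model,
    fraction_above,
    iou,
    precision,
    recall,
    soft_dice_grad,
    soft_dice_loss,
    tta_evaluate,
)
from nsseg.seeding import derive_seed


class TestSoftDiceLoss:
    def test_perfect_overlap_is_zero(self):
        ones = np.ones((2, 2))
        assert soft_dice_loss(ones, ones.astype(np.uint8)) == 0.0

    def test_both_empty_is_zero_through_smoothing(self):
        zeros = np.zeros((2, 2))
        assert soft_dice_loss(zeros, zeros.astype(np.uint8)) == 0.0

    def test_total_miss_on_four_pixels(self):
        # Σp=4, Σy=0, λ=1: 1 − 1/5
        pred = np.ones((2, 2))
        target = np.zeros((2, 2), np.uint8)
        assert soft_dice_loss(pred, target, smooth=1.0) == pytest.approx(0.8, abs=1e-15)

    def test_batch_is_mean_of_per_image_losses(self):
        rng = np.random.default_rng(0)
        probs = rng.random((3, 4, 4))
        targets = (rng.random((3, 4, 4)) > 0.5).astype(np.uint8)
        per_image = [soft_dice_loss(probs[i], targets[i]) for i in range(3)]
        assert soft_dice_loss(probs, targets) == pytest.approx(np.mean(per_image))

    def test_binary_prediction_matches_confusion_form(self):
        # on binary maps the soft loss equals 1 − (2TP+λ)/(2TP+FP+FN+λ)
        rng = np.random.default_rng(1)
        for _ in range(20):
            pred = (rng.random((8, 8)) > 0.5).astype(np.uint8)
            truth = (rng.random((8, 8)) > 0.5).astype(np.uint8)
            c = confusion_counts(pred, truth)
            expected = 1.0 - (2 * c.tp + 1.0) / (2 * c.tp + c.fp + c.fn + 1.0)
            assert soft_dice_loss(pred.astype(float), truth) == pytest.approx(expected)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((2, 2)), np.zeros((3, 3), np.uint8))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        prob = rng.uniform(0.1, 0.9, (5, 5))
        target = (rng.random((5, 5)) > 0.5).astype(np.float64)
        grad = soft_dice_grad(prob, target)[0]
        eps = 1e-6
        for r, c in [(0, 0), (2, 3), (4, 4)]:
            p = prob.copy()
            p[r, c] += eps
            lp = soft_dice_loss(p, target.astype(np.uint8))
            p[r, c] -= 2 * eps
            lm = soft_dice_loss(p, target.astype(np.uint8))
            assert grad[r, c] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)


class TestConfusionAndMetrics:
    def test_identical_masks(self):
        m = np.eye(4, dtype=np.uint8)
        c = confusion_counts(m, m)
        assert (c.fp, c.fn) == (0, 0)
        assert iou(c) == dice(c) == precision(c) == recall(c) == 1.0

    def test_complement_masks(self):
        m = np.eye(4, dtype=np.uint8)
        c = confusion_counts(m, 1 - m)
        assert (c.tp, c.tn) == (0, 0)

    def test_rows_versus_columns_hand_count(self):
        pred = np.zeros((4, 4), np.uint8)
        pred[:2] = 1
        truth = np.zeros((4, 4), np.uint8)
        truth[:, :2] = 1
        c = confusion_counts(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (4, 4, 4, 4)
        assert iou(c) == pytest.approx(1 / 3)
        assert dice(c) == precision(c) == recall(c) == 0.5

    def test_both_empty_convention(self):
        c = ConfusionCounts(tp=0, fp=0, fn=0, tn=16)
        assert iou(c) == dice(c) == precision(c) == recall(c) == 1.0

    def test_counts_sum_to_pixel_count(self):
        rng = np.random.default_rng(3)
        pred = (rng.random((6, 6)) > 0.3).astype(np.uint8)
        truth = (rng.random((6, 6)) > 0.7).astype(np.uint8)
        assert confusion_counts(pred, truth).total == 36

    @given(
        tp=st.integers(0, 1000), fp=st.integers(0, 1000), fn=st.integers(0, 1000)
    )
    @settings(deadline=None)
    def test_dice_iou_identity(self, tp, fp, fn):
        c = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=0)
        assert dice(c) == pytest.approx(2 * iou(c) / (1 + iou(c)))

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(1, 500))
    @settings(deadline=None)
    def test_extra_true_positive_never_decreases_iou(self, tp, fp, fn):
        before = iou(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=0))
        after = iou(ConfusionCounts(tp=tp + 1, fp=fp, fn=max(fn - 1, 0), tn=0))
        assert after >= before

    def test_bruteforce_pixel_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            pred = (rng.random((16, 16)) > 0.5).astype(np.uint8)
            truth = (rng.random((16, 16)) > 0.5).astype(np.uint8)
            tp = fp = fn = tn = 0
            for r in range(16):
                for c in range(16):
                    if pred[r, c] and truth[r, c]:
                        tp += 1
                    elif pred[r, c]:
                        fp += 1
                    elif truth[r, c]:
                        fn += 1
                    else:
                        tn += 1
            got = confusion_counts(pred, truth)
            assert (got.tp, got.fp, got.fn, got.tn) == (tp, fp, fn, tn)


class TestEvaluateModel:
    def test_oracle_model_scores_perfectly(self, tiny_dataset, oracle_model_factory):
        report = evaluate_model(oracle_model_factory(tiny_dataset), tiny_dataset)
        assert report.miou == 1.0 and report.mdice == 1.0

    def test_constant_zero_model(self, tiny_dataset):
        report = evaluate_model(lambda img: np.zeros(img.shape[:2]), tiny_dataset)
        assert report.mrecall == 0.0 and report.miou == 0.0

    def test_constant_one_model_precision_is_mean_fg_fraction(self, tiny_dataset):
        report = evaluate_model(lambda img: np.ones(img.shape[:2]), tiny_dataset)
        assert report.mrecall == 1.0
        fracs = []
        for rec in tiny_dataset:
            _, mask = load_sample(rec, tiny_dataset.target_size)
            fracs.append(mask.values.mean())
        assert report.mprecision == pytest.approx(np.mean(fracs))

    def test_pseudo_record_rejected(self, tiny_dataset):
        from dataclasses import replace

        bad = tiny_dataset.with_records(
            [replace(tiny_dataset.records[0], provenance="pseudo")]
        )
        with pytest.raises(ValidationPurityError):
            evaluate_model(lambda img: np.zeros(img.shape[:2]), bad)


class TestFractionAbove:
    def test_strict_inequality(self, tiny_dataset, oracle_model_factory):
        from nsseg.metrics import MetricsReport, PerImageMetrics

        per = [
            PerImageMetrics(id=str(i), iou=v, dice=v, precision=v, recall=v)
            for i, v in enumerate([0.7, 0.8, 0.9])
        ]
        report = MetricsReport(
            per_image=per, miou=0.8, mdice=0.8, mprecision=0.8, mrecall=0.8
        )
        assert fraction_above(report, 0.8) == pytest.approx(1 / 3)
        assert fraction_above(report, 0.786) == pytest.approx(2 / 3)

    def test_all_above(self, tiny_dataset, oracle_model_factory):
        report = evaluate_model(oracle_model_factory(tiny_dataset), tiny_dataset)
        assert fraction_above(report, 0.8) == 1.0


class TestBootstrapCI:
    def test_degenerate_distribution_zero_width(self):
        lo, hi = bootstrap_ci([0.9] * 20, level=0.95, reps=500, seed=1)
        assert lo == hi
        assert lo == pytest.approx(0.9, abs=1e-12)

    def test_seeded_determinism(self):
        values = np.random.default_rng(5).random(50)
        assert bootstrap_ci(values, seed=3) == bootstrap_ci(values, seed=3)

    def test_low_reps_warns(self):
        with pytest.warns(UserWarning):
            bootstrap_ci([0.1, 0.2, 0.3], reps=50, seed=0)

    def test_interval_brackets_the_sample_mean(self):
        values = np.random.default_rng(6).normal(0.8, 0.05, 200)
        lo, hi = bootstrap_ci(values, level=0.95, reps=2000, seed=2)
        assert lo < values.mean() < hi


class TestTTA:
    def test_empty_set_equals_plain_evaluation(self, tiny_dataset, oracle_model_factory):
        model = oracle_model_factory(tiny_dataset)
        plain = evaluate_model(model, tiny_dataset)
        tta = tta_evaluate(model, tiny_dataset, named_set("none"), R=2, seed=9)
        assert tta.miou == plain.miou
        assert tta.mdice == plain.mdice
        assert [m.iou for m in tta.per_image] == [m.iou for m in plain.per_image]

    def test_r3_equals_explicit_loop_mean(self, tiny_dataset):
        from nsseg.augment import apply
        from nsseg.metrics import _aggregate, _per_image

        model = lambda img: (img.mean(axis=2) < 0.45).astype(float)
        aset = tta_set()
        seed = 13
        got = tta_evaluate(model, tiny_dataset, aset, R=3, seed=seed)
        run_mious = []
        for r in range(3):
            run_seed = derive_seed(seed, "tta_run", r)
            per = []
            for rec in tiny_dataset:
                image, mask = load_sample(rec, tiny_dataset.target_size)
                aug_img, aug_mask = apply(
                    aset, image, mask.values, seed=derive_seed(run_seed, rec.id)
                )
                pred = (model(aug_img) >= 0.5).astype(np.uint8)
                per.append(_per_image(rec.id, pred, aug_mask))
            run_mious.append(_aggregate(per).miou)
        assert got.miou == pytest.approx(np.mean(run_mious), abs=1e-15)

    def test_r1_is_single_seeded_run(self, tiny_dataset):
        model = lambda img: (img.mean(axis=2) < 0.45).astype(float)
        a = tta_evaluate(model, tiny_dataset, tta_set(), R=1, seed=4)
        b = tta_evaluate(model, tiny_dataset, tta_set(), R=1, seed=4)
        assert a.miou == b.miou
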