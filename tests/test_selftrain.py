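import numpy as np
import pytest
from sklearn.base import clone

from nsseg.datamodel import read_manifest
from nsseg.estimators import ConvSegmenter, NoisyStudentSegmenter
from nsseg.metrics import ValidationPurityError
from nsseg.nnet import CompactSegNet
from nsseg.segmodel import ModelSpec, load_checkpoint
from nsseg.selftrain import cosine_lr, run_selftrain, train
from nsseg.config import RunConfig, RunPaths, TrainConfig
from nsseg.synthetic import strip_labels

TINY = dict(depth=2, base_channels=4, epochs=2, batch_size=4, random_state=5)


class TestCosineSchedule:
    def test_endpoints_and_midpoint(self):
        assert cosine_lr(0, 60, 0.002) == 0.002
        assert cosine_lr(60, 60, 0.002) == pytest.approx(0.0, abs=1e-18)
        assert cosine_lr(30, 60, 0.002) == pytest.approx(0.001, abs=1e-18)

    def test_out_of_range_epoch_rejected(self):
        with pytest.raises(ValueError):
            cosine_lr(61, 60, 0.002)
        with pytest.raises(ValueError):
            cosine_lr(-1, 60, 0.002)

    def test_monotone_decrease(self):
        lrs = [cosine_lr(e, 20, 0.1) for e in range(21)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))


class TestConvSegmenter:
    def test_zero_epochs_returns_initial_weights(self, sample_arrays32):
        X, y = sample_arrays32
        est = ConvSegmenter(**{**TINY, "epochs": 0}).fit(X[:4], y[:4])
        fresh = CompactSegNet(
            depth=2, base_channels=4, use_aspp=False, skip_connections=True,
            dropout_p=0.5, seed=est.net_.seed,
        )
        for got, want in zip(est.net_.get_weights(), fresh.get_weights()):
            assert np.array_equal(got, want)

    def test_fixed_seed_reproduces_history_and_predictions(self, sample_arrays32):
        X, y = sample_arrays32
        a = ConvSegmenter(**TINY).fit(X[:6], y[:6], X[6:9], y[6:9])
        b = ConvSegmenter(**TINY).fit(X[:6], y[:6], X[6:9], y[6:9])
        assert a.history_.train_loss == b.history_.train_loss
        assert a.history_.val_miou == b.history_.val_miou
        assert np.array_equal(a.predict_proba(X[9:]), b.predict_proba(X[9:]))

    def test_lr_trace_matches_closed_form(self, sample_arrays32):
        X, y = sample_arrays32
        est = ConvSegmenter(**{**TINY, "epochs": 4}).fit(X[:4], y[:4])
        for epoch, lr in enumerate(est.history_.lr):
            assert lr == pytest.approx(cosine_lr(epoch, 4, est.lr0), abs=1e-12)

    def test_best_epoch_tracks_max_val_miou(self, sample_arrays32):
        X, y = sample_arrays32
        est = ConvSegmenter(**{**TINY, "epochs": 4}).fit(X[:6], y[:6], X[6:9], y[6:9])
        history = est.history_
        assert history.val_miou[history.best_epoch] == max(history.val_miou)
        assert est.best_val_miou_ == max(history.val_miou)

    def test_sklearn_params_round_trip(self):
        est = ConvSegmenter(depth=4, lr0=0.3)
        cloned = clone(est)
        assert cloned.get_params()["depth"] == 4
        assert cloned.get_params()["lr0"] == 0.3

    def test_rejects_bad_inputs(self, sample_arrays32):
        X, y = sample_arrays32
        est = ConvSegmenter(**TINY)
        with pytest.raises(ValueError):
            est.fit(X[:2] * 300.0, y[:2])
        with pytest.raises(ValueError):
            est.fit(X[:2], y[:2] + 5)
        with pytest.raises(RuntimeError):
            ConvSegmenter(**TINY).predict(X[:1])


class TestTrainOnManifests:
    def test_validation_purity_enforced(self, tiny_dataset):
        from dataclasses import replace

        train_m = tiny_dataset.with_records(
            [r for r in tiny_dataset if r.split == "train"]
        )
        bad_val = tiny_dataset.with_records(
            [replace(r, provenance="pseudo") for r in tiny_dataset if r.split == "val"]
        )
        spec = ModelSpec(depth=2, base_channels=4)
        cfg = TrainConfig(epochs=1, batch_size=4)
        with pytest.raises(ValidationPurityError):
            train(spec, train_m, bad_val, cfg)

    def test_empty_training_set_rejected(self, tiny_dataset):
        empty = tiny_dataset.with_records([])
        val = tiny_dataset.with_records([r for r in tiny_dataset if r.split == "val"])
        with pytest.raises(ValueError):
            train(ModelSpec(depth=2, base_channels=4), empty, val, TrainConfig(epochs=1))


@pytest.fixture(scope="module")
def small_run(tmp_path_factory, tiny_dataset):
    """One tiny end-to-end self-training run shared by the assertions below."""
    out = tmp_path_factory.mktemp("run")
    labeled, pool = strip_labels(tiny_dataset, 0.7, seed=2)
    train_m = labeled.with_records([r for r in labeled if r.split == "train"])
    val_m = labeled.with_records([r for r in labeled if r.split == "val"])
    test_m = labeled.with_records([r for r in labeled if r.split == "test"])
    cfg = RunConfig(
        seed=3,
        target_size=32,
        paths=RunPaths(out_dir=out),
        model=ModelSpec(depth=2, base_channels=4),
        train=TrainConfig(lr0=0.1, epochs=2, batch_size=4),
        augset_name="simple",
        ratio_m=1,
        min_mask_pixels=100,
    )
    result = run_selftrain(train_m, val_m, test_m, pool, cfg)
    return result, cfg


class TestRunSelftrain:
    def test_produces_three_stage_checkpoints(self, small_run):
        result, _ = small_run
        assert set(result.checkpoints) == {"teacher", "student", "student_star"}
        for stage, path in result.checkpoints.items():
            model, tag = load_checkpoint(path)
            assert tag == stage

    def test_second_iteration_labels_come_from_student(self, small_run):
        result, _ = small_run
        assert result.pseudo_sets["iter1"].source_model_tag == "teacher"
        assert result.pseudo_sets["iter2"].source_model_tag == "student"

    def test_every_stage_reports_val_and_test(self, small_run):
        result, _ = small_run
        for stage in ("teacher", "student", "student_star"):
            assert 0.0 <= result.reports[stage]["val"].miou <= 1.0
            assert 0.0 <= result.reports[stage]["test"].miou <= 1.0

    def test_outputs_written(self, small_run):
        _, cfg = small_run
        out = cfg.paths.out_dir
        assert (out / "metrics.json").is_file()
        assert (out / "config_resolved.yaml").is_file()
        assert any((out / "pseudo_iter1").glob("*.png"))


class TestNoisyStudentSegmenter:
    def test_three_stages_and_composition_counts(self, sample_arrays32, params32):
        from nsseg.synthetic import generate_sample

        images, masks = [], []
        for i in range(40):
            img, m = generate_sample(params32, 3000 + i)
            images.append(img)
            masks.append(m.values)
        X, y = np.stack(images), np.stack(masks)
        ns = NoisyStudentSegmenter(
            segmenter=ConvSegmenter(**TINY),
            ratio_m=2,
            min_mask_pixels=100,
            random_state=8,
        )
        ns.fit(X[:6], y[:6], X_unlabeled=X[6:36], X_val=X[36:], y_val=y[36:])
        assert hasattr(ns, "teacher_") and hasattr(ns, "student_star_")
        assert len(ns.pseudo_selected_["student"]) == 6 * 2
        pred = ns.predict(X[36:])
        assert pred.shape == y[36:].shape

    def test_shortfall_raises(self, sample_arrays32):
        X, y = sample_arrays32
        ns = NoisyStudentSegmenter(
            segmenter=ConvSegmenter(**TINY), ratio_m=8, random_state=1
        )
        from nsseg.pseudolabel import InsufficientPseudoPoolError

        with pytest.raises(InsufficientPseudoPoolError):
            ns.fit(X[:6], y[:6], X_unlabeled=X[6:10])
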