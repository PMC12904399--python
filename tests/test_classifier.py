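"""CNN building, training determinism, fine-tuning, and inference."""

import copy

import numpy as np
import pytest

from sirenet import classifier as clf
from sirenet import nn
from sirenet import soundscape_sim as sim
from sirenet.features import SLICE_SAMPLES, TARGET_RATE_HZ, AudioSegment
from sirenet.raven_io import DatasetManifest, LabeledSegment


def _toy_dataset(n_pos=20, n_neg=20, snr_gain=0.5, seed=0):
    """A separable recording: tonal-call slices vs pure-noise slices."""
    rng = np.random.default_rng(seed)
    params = sim.CallParams(duration_s=(0.2, 0.2))
    slices, rows = [], []
    flags = [True] * n_pos + [False] * n_neg
    rng.shuffle(flags)
    for i, is_pos in enumerate(flags):
        noise = rng.standard_normal(SLICE_SAMPLES) * 0.05
        x = noise + snr_gain * sim.synth_call(params, TARGET_RATE_HZ, rng) \
            if is_pos else noise
        slices.append(x)
        rows.append(
            LabeledSegment(
                "toy", i * 0.2, 0.2,
                "positive" if is_pos else "negative",
                overlap_fraction=1.0 if is_pos else 0.0,
            )
        )
    audio = {"toy": np.concatenate(slices)}
    return rows, audio


def _manifest(rows, n_val=8, seed=0):
    split = ["val" if i < n_val else "train" for i in range(len(rows))]
    return DatasetManifest(rows=rows, split=split, seed=seed)


@pytest.fixture(scope="module")
def toy():
    rows, audio = _toy_dataset()
    return _manifest(rows), audio


class TestBuild:
    @pytest.mark.parametrize("backbone", ["small_cnn", "resnet18_2d"])
    def test_softmax_outputs_normalize(self, backbone, rng):
        model = clf.build_classifier(
            clf.ClassifierConfig(backbone=backbone, epochs=1, seed=0)
        )
        x = rng.standard_normal((2, 1, 513, 75)).astype(np.float32)
        probs = nn.softmax(model.net.forward(x))
        assert probs.shape == (2, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_shape_contract(self, rng):
        model = clf.build_classifier(clf.ClassifierConfig(epochs=1, seed=0))
        x = rng.standard_normal((8, 1, 513, 75)).astype(np.float32)
        assert model.net.forward(x).shape == (8, 2)

    def test_identical_seeds_identical_first_loss(self, toy):
        manifest, audio = toy
        losses = []
        for _ in range(2):
            model = clf.build_classifier(clf.ClassifierConfig(epochs=1, seed=7))
            clf.train(model, manifest, audio, epochs=1, eval_val=False)
            losses.append(model.training_history[0]["train_loss"])
        assert losses[0] == losses[1]

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="backbone"):
            clf.ClassifierConfig(backbone="vgg")

    def test_imagenet_init_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="ImageNet"):
            clf.build_classifier(
                clf.ClassifierConfig(init="imagenet-if-available", seed=0)
            )


class TestTrain:
    def test_overfits_separable_toy_data(self, toy):
        manifest, audio = toy
        model = clf.build_classifier(clf.ClassifierConfig(epochs=30, seed=0))
        clf.train(model, manifest, audio, eval_val=False)
        train_rows = manifest.subset("train")
        scores = clf.predict(
            model, [clf.segment_waveform(audio, r) for r in train_rows]
        )
        preds = [s.score >= 0.5 for s in scores]
        truth = [r.label == "positive" for r in train_rows]
        accuracy = np.mean([p == t for p, t in zip(preds, truth)])
        assert accuracy >= 0.95

    def test_history_is_bitwise_reproducible(self, toy):
        manifest, audio = toy
        histories = []
        for _ in range(2):
            model = clf.build_classifier(clf.ClassifierConfig(epochs=2, seed=3))
            clf.train(model, manifest, audio, eval_val=True)
            histories.append(model.training_history)
        assert histories[0] == histories[1]

    def test_lr_decays_by_gamma_each_epoch(self, toy):
        manifest, audio = toy
        model = clf.build_classifier(
            clf.ClassifierConfig(epochs=4, seed=0, lr_decay_gamma=0.995)
        )
        clf.train(model, manifest, audio, eval_val=False)
        for rec in model.training_history:
            assert rec["lr"] == pytest.approx(1e-3 * 0.995 ** rec["epoch"])

    def test_single_class_split_rejected(self, toy):
        _, audio = toy
        rows = [
            LabeledSegment("toy", i * 0.2, 0.2, "negative") for i in range(10)
        ]
        model = clf.build_classifier(clf.ClassifierConfig(epochs=1, seed=0))
        with pytest.raises(ValueError, match="both classes"):
            clf.train(model, _manifest(rows, n_val=2), audio)

    def test_test_split_rows_never_read(self, toy):
        """Audio for test rows may be entirely absent: training must not touch it."""
        manifest, audio = toy
        rows = manifest.rows + [
            LabeledSegment("missing-recording", 0.0, 0.2, "negative")
        ]
        split = manifest.split + ["test"]
        model = clf.build_classifier(clf.ClassifierConfig(epochs=1, seed=0))
        clf.train(model, DatasetManifest(rows, split, 0), audio, eval_val=True)
        assert model.provenance == ["dataset"]


class TestFinetune:
    def test_requires_trained_checkpoint(self, toy):
        manifest, audio = toy
        model = clf.build_classifier(clf.ClassifierConfig(epochs=1, seed=0))
        with pytest.raises(ValueError, match="trained"):
            clf.finetune(model, manifest, audio, 0.5)

    def test_fraction_subsamples_exact_row_count(self, toy):
        manifest, audio = toy
        rows, audio_big = _toy_dataset(n_pos=100, n_neg=100, seed=1)
        big = _manifest(rows, n_val=0)
        model = clf.build_classifier(clf.ClassifierConfig(epochs=1, seed=0))
        clf.train(model, manifest, audio, epochs=1, eval_val=False)
        clf.finetune(model, big, audio_big, 0.10, epochs=1, eval_val=False)
        assert model.training_history[-1]["n_rows"] == 20  # 10 % of 200

    def test_full_fraction_equals_continued_training(self, toy):
        manifest, audio = toy
        model = clf.build_classifier(clf.ClassifierConfig(epochs=1, seed=0))
        clf.train(model, manifest, audio, epochs=1, eval_val=False)
        tuned = copy.deepcopy(model)
        clf.finetune(tuned, manifest, audio, 1.0, epochs=3, eval_val=False)
        assert len(tuned.training_history) == 4
        assert tuned.training_history[-1]["n_rows"] == len(manifest.subset("train"))
        assert tuned.provenance == ["dataset", "finetune-dataset"]

    def test_single_class_subsample_reports_counts(self, toy):
        manifest, audio = toy
        neg_rows = [
            LabeledSegment("toy", i * 0.2, 0.2, "negative") for i in range(40)
        ]
        neg_manifest = _manifest(neg_rows, n_val=0)
        model = clf.build_classifier(clf.ClassifierConfig(epochs=1, seed=0))
        clf.train(model, manifest, audio, epochs=1, eval_val=False)
        with pytest.raises(ValueError, match="positives"):
            clf.finetune(model, neg_manifest, audio, 0.2, eval_val=False)


@pytest.fixture(scope="module")
def trained():
    rows, audio = _toy_dataset()
    model = clf.build_classifier(clf.ClassifierConfig(epochs=5, seed=0))
    clf.train(model, _manifest(rows), audio, eval_val=False)
    return model, rows, audio


class TestPredict:
    def test_duplicate_inputs_get_identical_scores(self, trained, rng):
        model, _, _ = trained
        seg = AudioSegment(rng.standard_normal(SLICE_SAMPLES), TARGET_RATE_HZ)
        a, b = clf.predict(model, [seg, seg])
        assert a.score == b.score

    def test_batch_size_does_not_change_scores(self, trained, rng):
        model, _, _ = trained
        segs = [
            AudioSegment(rng.standard_normal(SLICE_SAMPLES), TARGET_RATE_HZ)
            for _ in range(7)
        ]
        s1 = [s.score for s in clf.predict(model, segs, batch_size=7)]
        s2 = [s.score for s in clf.predict(model, segs, batch_size=2)]
        np.testing.assert_allclose(s1, s2, atol=1e-6)

    def test_scores_are_probabilities(self, trained, rng):
        model, rows, audio = trained
        scores = clf.predict(
            model, [clf.segment_waveform(audio, r) for r in rows[:10]]
        )
        assert all(0.0 <= s.score <= 1.0 for s in scores)

    def test_separable_data_auc_near_one(self, trained):
        from sirenet.evaluation import auc_pr

        model, rows, audio = trained
        scores = clf.predict(model, [clf.segment_waveform(audio, r) for r in rows])
        labels = [r.label == "positive" for r in rows]
        assert auc_pr(labels, [s.score for s in scores]) >= 0.95


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, toy, tmp_path, rng):
        manifest, audio = toy
        model = clf.build_classifier(clf.ClassifierConfig(epochs=2, seed=0))
        clf.train(model, manifest, audio, eval_val=False)
        path = clf.save_checkpoint(model, tmp_path / "m.ckpt.npz")
        back = clf.load_checkpoint(path)
        seg = AudioSegment(rng.standard_normal(SLICE_SAMPLES), TARGET_RATE_HZ)
        assert clf.predict(model, [seg])[0].score == clf.predict(back, [seg])[0].score
        assert back.provenance == model.provenance
        assert back.training_history == model.training_history
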