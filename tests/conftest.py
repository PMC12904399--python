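"""Shared fixtures, including the session-scoped reference study.

The reference study — generate a clean and a noise-shifted synthetic
site, train the small CNN on the clean site, evaluate it on both, then
fine-tune on 10 % of the shifted site's rows for five seeds — is the
expensive backbone of the end-to-end tests, so it runs once per session
and its results are shared.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pytest

from sirenet import classifier as clf
from sirenet import evaluation as ev
from sirenet import raven_io
from sirenet import soundscape_sim as sim
from sirenet.augment import AugmentConfig

# reference study problem sizes (desk scale: minutes, not hours)
TRAIN_DURATION_S = 600.0
TEST_DURATION_S = 600.0
SHIFTED_TRAIN_DURATION_S = 1200.0
SHIFTED_TRAIN_FRACTION = 0.9
TRAIN_EPOCHS = 40
FINETUNE_FRACTION = 0.10
FINETUNE_SEEDS = (0, 1, 2, 3, 4)


def evaluate_on_test(model, corpus, threshold=0.5):
    """Full-tiling segment evaluation of a model on a corpus' test recording."""
    segs = raven_io.segment_and_label(corpus.test_table)
    manifest = raven_io.DatasetManifest(segs, ["test"] * len(segs), 0)
    scores = clf.score_manifest(model, manifest, corpus.audio, split="test")
    labels = [s.label == "positive" for s in segs]
    vals = [x.score for x in scores]
    report = ev.metrics(ev.confusion(labels, vals, threshold), threshold)
    return report, scores


@dataclass
class StudyResult:
    clean_corpus: sim.DomainCorpus
    shifted_corpus: sim.DomainCorpus
    base_model: clf.TrainedModel
    clean_report: ev.EvalReport
    zero_shot_report: ev.EvalReport
    finetuned_reports: dict[int, ev.EvalReport] = field(default_factory=dict)
    correlations: dict[int, ev.CorrelationResult] = field(default_factory=dict)


def run_reference_study(seed: int = 0) -> StudyResult:
    clean_cfg, shifted_cfg = sim.reference_study_configs(seed)
    clean, shifted = sim.make_domain_pair(
        clean_cfg,
        shifted_cfg,
        train_duration_s=TRAIN_DURATION_S,
        test_duration_s=TEST_DURATION_S,
        shifted_train_duration_s=SHIFTED_TRAIN_DURATION_S,
        shifted_train_fraction=SHIFTED_TRAIN_FRACTION,
    )
    model = clf.build_classifier(
        clf.ClassifierConfig(backbone="small_cnn", epochs=TRAIN_EPOCHS, seed=seed)
    )
    clf.train(
        model,
        clean.train_manifest,
        clean.audio,
        augment_config=AugmentConfig(seed=seed),
        dataset_id="clean-site",
        eval_val=False,
    )
    clean_report, _ = evaluate_on_test(model, clean)
    zero_shot, _ = evaluate_on_test(model, shifted)

    result = StudyResult(clean, shifted, model, clean_report, zero_shot)
    duration = shifted.test_table.recording_duration_s
    truth_density = ev.call_density(
        [a.begin_s for a in shifted.test_table.annotations],
        "minute",
        (0.0, duration),
    )
    for ft_seed in FINETUNE_SEEDS:
        tuned = copy.deepcopy(model)
        clf.finetune(
            tuned,
            shifted.train_manifest,
            shifted.audio,
            FINETUNE_FRACTION,
            augment_config=AugmentConfig(seed=ft_seed),
            seed=ft_seed,
            dataset_id="shifted-site",
            eval_val=False,
        )
        report, scores = evaluate_on_test(tuned, shifted)
        events = ev.assemble_events(scores, 0.5)
        predicted = ev.call_density(
            [e.start_s for e in events], "minute", (0.0, duration)
        )
        result.finetuned_reports[ft_seed] = report
        result.correlations[ft_seed] = ev.density_correlation(
            predicted, truth_density
        )
    return result


@pytest.fixture(scope="session")
def study() -> StudyResult:
    return run_reference_study(seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_table() -> raven_io.SelectionTable:
    """Two calls on a 5 s recording (the gap-tiling worked example)."""
    return raven_io.SelectionTable(
        "rec-a",
        5.0,
        (
            raven_io.CallAnnotation("rec-a", 1.0, 1.5, 2000.0, 6000.0),
            raven_io.CallAnnotation("rec-a", 3.0, 3.4),
        ),
    )
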