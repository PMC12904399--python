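"""The binary call/no-call CNN: building, training, fine-tuning, inference.

The reference architecture ("resnet18_2d") is an 18-layer residual
network with four stages of [64, 128, 256, 512] filters whose original
fully connected head is replaced by a 256-unit ReLU layer with 0.5
dropout and a 2-unit softmax classifier. A "small_cnn" backbone (four
conv/BN/ReLU blocks) shares the identical head and training loop and
trains on a CPU in minutes; it is the default for desk-scale work.

Training follows the detector's fixed recipe: Adam (lr 1e-3, betas
0.9/0.999), cross-entropy, per-epoch exponential learning-rate decay
(gamma 0.995), batch size 32, no early stopping. Partial positives —
segments holding only part of a call — train as positives. Fine-tuning
continues back-propagation on the entire checkpoint (no layer freezing)
on a seeded subsample of a new site's training rows, typically for 3
epochs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from sirenet import nn
from sirenet.augment import AugmentConfig, augment_waveform
from sirenet.features import (
    N_FREQ,
    N_TIME,
    SLICE_SAMPLES,
    TARGET_RATE_HZ,
    AudioSegment,
    spectrogram,
)
from sirenet.raven_io import DatasetManifest, LabeledSegment

__all__ = [
    "ClassifierConfig",
    "TrainedModel",
    "SegmentScore",
    "build_classifier",
    "train",
    "finetune",
    "predict",
    "score_manifest",
    "segment_waveform",
    "save_checkpoint",
    "load_checkpoint",
]

_BACKBONES = ("small_cnn", "resnet18_2d")


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture and optimization settings for the detector."""

    backbone: str = "small_cnn"
    head_hidden_units: int = 256
    head_dropout: float = 0.5
    n_classes: int = 2
    init: str = "random"
    epochs: int = 100
    learning_rate: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    lr_decay_gamma: float = 0.995
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in _BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; choose from {_BACKBONES}"
            )
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 < self.lr_decay_gamma <= 1.0:
            raise ValueError("lr_decay_gamma must lie in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.init not in ("random", "imagenet-if-available"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class TrainedModel:
    """A network plus its config, per-epoch history, and data provenance."""

    net: nn.Layer
    config: ClassifierConfig
    training_history: list[dict] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    @property
    def trained(self) -> bool:
        return bool(self.training_history)


@dataclass(frozen=True)
class SegmentScore:
    """Positive-class probability for one segment (softmax entry 1)."""

    segment: LabeledSegment | None
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


def _conv_block(c_in, c_out, stride, rng):
    return nn.Sequential(
        nn.Conv2d(c_in, c_out, 3, stride=stride, pad=1, bias=False, rng=rng),
        nn.BatchNorm2d(c_out),
        nn.ReLU(),
    )


def _head(c_in: int, cfg: ClassifierConfig, rng) -> list[nn.Layer]:
    return [
        nn.GlobalAvgPool(),
        nn.Linear(c_in, cfg.head_hidden_units, rng=rng),
        nn.ReLU(),
        nn.Dropout(cfg.head_dropout),
        nn.Linear(cfg.head_hidden_units, cfg.n_classes, rng=rng),
    ]


def _small_cnn(cfg: ClassifierConfig, rng) -> nn.Layer:
    # aggressive early downsampling keeps activation maps small on CPU;
    # the head pools over time only (frequency position carries the
    # call/no-call signal, so it must survive into the classifier)
    return nn.Sequential(
        nn.Sequential(
            nn.Conv2d(1, 8, 5, stride=4, pad=2, bias=False, rng=rng),
            nn.BatchNorm2d(8),
            nn.ReLU(),
        ),
        _conv_block(8, 16, 2, rng),
        _conv_block(16, 32, 2, rng),
        _conv_block(32, 32, 2, rng),
        nn.TimeAvgFlatten(),
        nn.Linear(32 * 17, cfg.head_hidden_units, rng=rng),
        nn.ReLU(),
        nn.Dropout(cfg.head_dropout),
        nn.Linear(cfg.head_hidden_units, cfg.n_classes, rng=rng),
    )


def _basic_block(c_in, c_out, stride, rng) -> nn.Residual:
    body = nn.Sequential(
        nn.Conv2d(c_in, c_out, 3, stride=stride, pad=1, bias=False, rng=rng),
        nn.BatchNorm2d(c_out),
        nn.ReLU(),
        nn.Conv2d(c_out, c_out, 3, stride=1, pad=1, bias=False, rng=rng),
        nn.BatchNorm2d(c_out),
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = nn.Sequential(
            nn.Conv2d(c_in, c_out, 1, stride=stride, bias=False, rng=rng),
            nn.BatchNorm2d(c_out),
        )
    return nn.Residual(body, shortcut)


def _resnet18(cfg: ClassifierConfig, rng) -> nn.Layer:
    layers: list[nn.Layer] = [
        nn.Conv2d(1, 64, 7, stride=2, pad=3, bias=False, rng=rng),
        nn.BatchNorm2d(64),
        nn.ReLU(),
        nn.MaxPool2d(),
    ]
    widths = (64, 128, 256, 512)
    c_in = 64
    for i, c in enumerate(widths):
        layers.append(_basic_block(c_in, c, 1 if i == 0 else 2, rng))
        layers.append(_basic_block(c, c, 1, rng))
        c_in = c
    layers.extend(_head(512, cfg, rng))
    return nn.Sequential(*layers)


def build_classifier(config: ClassifierConfig) -> TrainedModel:
    """Build an untrained detector for 1 x 513 x 75 spectrogram input."""
    if config.init == "imagenet-if-available":
        warnings.warn(
            "pretrained ImageNet weights are not bundled; "
            "falling back to seeded random initialization",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    if config.backbone == "small_cnn":
        net = _small_cnn(config, rng)
    else:
        net = _resnet18(config, rng)
    return TrainedModel(net=net, config=config)


def segment_waveform(
    audio: Mapping[str, np.ndarray], seg: LabeledSegment
) -> AudioSegment:
    """Cut one labeled segment out of its recording (zero-padded at edges)."""
    rec = np.asarray(audio[seg.recording_id])
    start = int(round(seg.start_s * TARGET_RATE_HZ))
    n = int(round(seg.duration_s * TARGET_RATE_HZ))
    x = rec[start : start + n]
    if len(x) < n:
        x = np.pad(x, (0, n - len(x)))
    return AudioSegment(x, TARGET_RATE_HZ, origin=(seg.recording_id, seg.start_s))


def _to_batch(segments: Sequence[AudioSegment]) -> np.ndarray:
    batch = np.stack([spectrogram(s).values for s in segments])[:, None, :, :]
    return batch.astype(nn.DTYPE)


def predict(
    model: TrainedModel,
    segments: Sequence[AudioSegment],
    *,
    refs: Sequence[LabeledSegment | None] | None = None,
    batch_size: int = 64,
) -> list[SegmentScore]:
    """Score audio slices with the positive-class softmax probability.

    Inference is deterministic (no dropout, no augmentation) and
    order-preserving; batching does not change the scores.
    """
    if refs is None:
        refs = [None] * len(segments)
    if len(refs) != len(segments):
        raise ValueError("refs and segments must have equal length")
    out: list[SegmentScore] = []
    for i in range(0, len(segments), batch_size):
        chunk = segments[i : i + batch_size]
        x = _to_batch(chunk)
        probs = nn.softmax(model.net.forward(x, train=False))
        out.extend(
            SegmentScore(ref, float(p[1]))
            for ref, p in zip(refs[i : i + batch_size], probs)
        )
    return out


def score_manifest(
    model: TrainedModel,
    manifest: DatasetManifest,
    audio: Mapping[str, np.ndarray],
    split: str | None = None,
) -> list[SegmentScore]:
    """Score every manifest row (optionally one split) against its audio."""
    rows = manifest.rows if split is None else manifest.subset(split)
    segs = [segment_waveform(audio, r) for r in rows]
    return predict(model, segs, refs=rows)


def _epoch_val_metrics(model, val_rows, audio):
    from sirenet import evaluation  # local import avoids a cycle at import time

    scores = predict(
        model, [segment_waveform(audio, r) for r in val_rows], refs=val_rows
    )
    y = [r.label == "positive" for r in val_rows]
    s = [sc.score for sc in scores]
    cm = evaluation.confusion(y, s, threshold=0.5)
    rep = evaluation.metrics(cm)
    out = {"val_precision": rep.precision, "val_recall": rep.recall,
           "val_f1": rep.f1}
    out["val_auc_pr"] = evaluation.auc_pr(y, s) if any(y) else float("nan")
    return out


def _run_epochs(
    model: TrainedModel,
    train_rows: list[LabeledSegment],
    val_rows: list[LabeledSegment],
    audio: Mapping[str, np.ndarray],
    *,
    epochs: int,
    augment_config: AugmentConfig | None,
    seed: int,
    eval_val: bool,
) -> None:
    cfg = model.config
    opt = nn.Adam(
        model.net,
        lr=cfg.learning_rate,
        betas=cfg.betas,
        gamma=cfg.lr_decay_gamma,
    )
    rng = np.random.default_rng(seed)
    labels = np.array([r.label == "positive" for r in train_rows], dtype=np.int64)
    for epoch in range(epochs):
        lr = opt.set_epoch(epoch)
        order = rng.permutation(len(train_rows))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            segs = []
            for j in idx:
                seg = segment_waveform(audio, train_rows[j])
                if augment_config is not None:
                    seg = augment_waveform(seg, augment_config, rng)
                segs.append(seg)
            x = _to_batch(segs)
            logits = model.net.forward(x, train=True, rng=rng)
            loss, dlogits = nn.cross_entropy_with_grad(logits, labels[idx])
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
        record = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": float(np.mean(losses)),
            "n_rows": len(train_rows),
        }
        if eval_val and val_rows:
            record.update(_epoch_val_metrics(model, val_rows, audio))
        model.training_history.append(record)


def train(
    model: TrainedModel,
    manifest: DatasetManifest,
    audio: Mapping[str, np.ndarray],
    *,
    augment_config: AugmentConfig | None = None,
    epochs: int | None = None,
    dataset_id: str = "dataset",
    eval_val: bool = True,
) -> TrainedModel:
    """Train the detector on a manifest's train split (in place).

    Augmentation, when configured, touches only training batches; the
    validation metrics recorded per epoch are computed on clean audio.
    Test rows are never read. Fully seeded via ``model.config.seed``.
    """
    train_rows = manifest.subset("train")
    val_rows = manifest.subset("val")
    if not train_rows or (eval_val and not val_rows):
        raise ValueError("manifest needs non-empty train and val splits")
    n_pos = sum(r.label == "positive" for r in train_rows)
    if n_pos == 0 or n_pos == len(train_rows):
        raise ValueError(
            f"training split must contain both classes "
            f"(got {n_pos} positives of {len(train_rows)} rows)"
        )
    _run_epochs(
        model,
        train_rows,
        val_rows,
        audio,
        epochs=epochs if epochs is not None else model.config.epochs,
        augment_config=augment_config,
        seed=model.config.seed,
        eval_val=eval_val,
    )
    model.provenance.append(dataset_id)
    return model


def finetune(
    model: TrainedModel,
    manifest: DatasetManifest,
    audio: Mapping[str, np.ndarray],
    fraction: float,
    *,
    epochs: int = 3,
    augment_config: AugmentConfig | None = None,
    dataset_id: str = "finetune-dataset",
    seed: int | None = None,
    eval_val: bool = True,
) -> TrainedModel:
    """Continue back-propagation on a seeded fraction of new train rows.

    All weights update (no freezing). ``fraction`` subsamples the target
    manifest's train split uniformly without replacement; with
    ``fraction = 1`` this is exactly 3 (or ``epochs``) more epochs of
    ordinary training on the new site.
    """
    if not model.trained:
        raise ValueError("finetune requires an already-trained checkpoint")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    train_rows = manifest.subset("train")
    if not train_rows:
        raise ValueError("manifest has no train rows")
    seed = model.config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n_use = int(round(fraction * len(train_rows)))
    idx = rng.choice(len(train_rows), size=max(n_use, 1), replace=False)
    subset = [train_rows[i] for i in sorted(idx)]
    n_pos = sum(r.label == "positive" for r in subset)
    n_neg = len(subset) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"fine-tuning subsample is single-class: {n_pos} positives, "
            f"{n_neg} negatives of {len(subset)} rows; increase fraction"
        )
    _run_epochs(
        model,
        subset,
        manifest.subset("val"),
        audio,
        epochs=epochs,
        augment_config=augment_config,
        seed=seed,
        eval_val=eval_val,
    )
    model.provenance.append(dataset_id)
    return model


def _iter_layers(layer: nn.Layer):
    yield layer
    if isinstance(layer, nn.Sequential):
        for sub in layer.layers:
            yield from _iter_layers(sub)
    elif isinstance(layer, nn.Residual):
        yield from _iter_layers(layer.body)
        if layer.shortcut is not None:
            yield from _iter_layers(layer.shortcut)


def save_checkpoint(model: TrainedModel, path: str | Path) -> Path:
    """Persist weights, BN statistics, config, history, and provenance."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for i, (layer, name) in enumerate(model.net.walk()):
        arrays[f"p{i}"] = layer.params[name]
    for j, layer in enumerate(_iter_layers(model.net)):
        if isinstance(layer, nn.BatchNorm2d):
            arrays[f"bn{j}_mean"] = layer.running_mean
            arrays[f"bn{j}_var"] = layer.running_var
    meta = {
        "config": asdict(model.config),
        "training_history": model.training_history,
        "provenance": model.provenance,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> TrainedModel:
    """Rebuild a model from :func:`save_checkpoint` output."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_d = meta["config"]
        cfg_d["betas"] = tuple(cfg_d["betas"])
        config = ClassifierConfig(**cfg_d)
        model = build_classifier(config)
        for i, (layer, name) in enumerate(model.net.walk()):
            layer.params[name] = data[f"p{i}"].copy()
        for j, layer in enumerate(_iter_layers(model.net)):
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean = data[f"bn{j}_mean"].copy()
                layer.running_var = data[f"bn{j}_var"].copy()
    model.training_history = meta["training_history"]
    model.provenance = meta["provenance"]
    return model
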