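"""End-to-end training, prediction and evaluation orchestration.

Pipeline per run: load the label table -> completeness filter (>= 14 ROI
classes) -> pose alignment -> ROI cropping -> patch embedding + sex-token
fusion -> windowed-attention backbone -> hybrid mean-variance-cross-entropy
loss, optimised with Adam at an initial learning rate of 0.001 decayed by
1/3 every 10 epochs. All randomness (weight init, train/validation split,
batch order) derives from the run seed; per-epoch loss components and
validation MAE are logged.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import align_sample
from .autograd import Adam
from .detection_io import (
    MIN_ROI_CLASSES,
    SampleRecord,
    dedupe_detections,
    filter_complete_samples,
    load_label_table,
    parse_yolo_labels,
)
from .loss import LossWeights, hybrid_loss, hybrid_loss_grad
from .metrics import EvalReport, evaluate
from .model import BoneAgeModel, ModelConfig
from .patches import batch_stacks, crop_rois

logger = logging.getLogger("boneage")


@dataclass(frozen=True)
class TrainConfig:
    """Run configuration (model, loss, optimiser schedule, data handling)."""

    model: ModelConfig = field(default_factory=ModelConfig.tiny)
    loss: LossWeights = field(default_factory=LossWeights)
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 0.001
    lr_decay_every: int = 10  # epochs per decay step
    lr_decay_divisor: float = 3.0  # lr divided by this each step
    val_fraction: float = 0.2
    min_classes: int = MIN_ROI_CLASSES
    freeze_sex_gate: bool = False
    seed: int = 0
    #: separate seed for the train/validation split; None -> derive from seed.
    #: Fixing it across runs gives paired comparisons on identical splits.
    split_seed: int | None = None


def learning_rate_at(epoch: int, config: TrainConfig) -> float:
    """The scheduled learning rate: lr0 / divisor**(epoch // every)."""
    return config.learning_rate / config.lr_decay_divisor ** (
        epoch // config.lr_decay_every
    )


@dataclass
class Dataset:
    """Aligned, cropped samples ready for the model."""

    stacks: np.ndarray  # (N, 18, 58, 58)
    sexes: list[str]
    ages_months: np.ndarray  # (N,)
    ids: list[str]

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            stacks=self.stacks[idx],
            sexes=[self.sexes[i] for i in idx],
            ages_months=self.ages_months[idx],
            ids=[self.ids[i] for i in idx],
        )


def prepare_dataset(records: list[SampleRecord]) -> Dataset:
    """Align and crop every record into the model-input stack."""
    import imageio.v3 as iio

    stacks, sexes, ages, ids = [], [], [], []
    for rec in records:
        image = iio.imread(rec.image_path)
        det = dedupe_detections(parse_yolo_labels(rec.label_path))
        aligned_img, aligned_det, _, _ = align_sample(image, det)
        stacks.append(crop_rois(aligned_img, aligned_det))
        sexes.append(rec.sex)
        ages.append(rec.boneage_months)
        ids.append(rec.image_id)
    return Dataset(
        stacks=batch_stacks(stacks),
        sexes=sexes,
        ages_months=np.asarray(ages, dtype=float),
        ids=ids,
    )


def load_corpus(corpus_dir: str | Path, min_classes: int = MIN_ROI_CLASSES):
    """Read a corpus directory and apply the completeness filter."""
    corpus_dir = Path(corpus_dir)
    records = load_label_table(
        corpus_dir / "labels.csv",
        images_dir=corpus_dir / "images",
        labels_dir=corpus_dir / "labels",
    )
    return filter_complete_samples(records, min_classes=min_classes)


def ages_to_classes(ages_months: np.ndarray, num_classes: int) -> np.ndarray:
    """Map month labels to the nearest class index in [1, K]."""
    return np.clip(np.rint(ages_months).astype(int), 1, num_classes)


@dataclass
class TrainResult:
    model: BoneAgeModel
    log: list[dict]  # per-epoch: epoch, lr, loss components, val MAE
    train_ids: list[str]
    val_ids: list[str]
    train_mean_age: float


def train_on_dataset(data: Dataset, config: TrainConfig) -> TrainResult:
    """Train a model on an in-memory dataset; returns the model and log."""
    if len(data) == 0:
        raise ValueError("empty dataset after filtering")
    rng = np.random.default_rng(config.seed)
    n = len(data)
    n_val = int(round(config.val_fraction * n))
    split_rng = (
        rng if config.split_seed is None else np.random.default_rng(config.split_seed)
    )
    perm = split_rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("no training samples left after the validation split")
    train, val = data.subset(train_idx), data.subset(val_idx)

    model = BoneAgeModel(replace(config.model, seed=config.seed))
    model.sex_gate_frozen = config.freeze_sex_gate
    k = config.model.num_classes
    y_train = ages_to_classes(train.ages_months, k)
    opt = Adam(model.params(), lr=config.learning_rate)
    log: list[dict] = []

    for epoch in range(config.epochs):
        opt.lr = learning_rate_at(epoch, config)
        order = rng.permutation(len(train))
        sums = {"cross_entropy": 0.0, "mean": 0.0, "variance": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, len(train), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward_logits(
                train.stacks[idx], [train.sexes[i] for i in idx]
            )
            z = logits.data
            total, comps = hybrid_loss(z, y_train[idx], config.loss)
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"loss diverged (non-finite) at epoch {epoch}: {comps}"
                )
            grad = hybrid_loss_grad(z, y_train[idx], config.loss)
            opt.zero_grad()
            logits.backward(grad)
            opt.step()
            for key in sums:
                sums[key] += comps[key]
            n_batches += 1
        row = {
            "epoch": epoch,
            "lr": opt.lr,
            **{f"loss_{k_}": v / n_batches for k_, v in sums.items()},
        }
        if len(val):
            preds = predict_ages(model, val)
            row["val_mae"] = float(np.mean(np.abs(preds - val.ages_months)))
        log.append(row)
        logger.info("epoch %d: %s", epoch, row)

    return TrainResult(
        model=model,
        log=log,
        train_ids=train.ids,
        val_ids=val.ids,
        train_mean_age=float(np.mean(train.ages_months)),
    )


def predict_ages(model: BoneAgeModel, data: Dataset, batch_size: int = 64) -> np.ndarray:
    """Predicted ages (distribution means, months) for every sample."""
    out = []
    for start in range(0, len(data), batch_size):
        dists = model.forward_batch(
            data.stacks[start : start + batch_size],
            data.sexes[start : start + batch_size],
        )
        out.extend(d.mean_months for d in dists)
    return np.asarray(out)


def train(
    corpus_dir: str | Path,
    config: TrainConfig = TrainConfig(),
    out_dir: str | Path | None = None,
) -> TrainResult:
    """Train from a corpus directory; optionally write checkpoint + CSV log."""
    kept, dropped = load_corpus(corpus_dir, config.min_classes)
    logger.info("corpus: %d kept, %d dropped by the completeness filter",
                len(kept), len(dropped))
    if not kept:
        raise ValueError("no samples passed the completeness filter")
    result = train_on_dataset(prepare_dataset(kept), config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.model.save(out_dir / "checkpoint.npz")
        write_training_log(result.log, out_dir / "training_log.csv")
    return result


def write_training_log(log: list[dict], path: str | Path) -> None:
    fieldnames = sorted({k for row in log for k in row}, key=lambda s: (s != "epoch", s))
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(log)


def predict_batch(model: BoneAgeModel, data: Dataset) -> pd.DataFrame:
    """One row per sample: id, true and predicted months, distribution variance."""
    rows = []
    for start in range(0, len(data), 64):
        dists = model.forward_batch(
            data.stacks[start : start + 64], data.sexes[start : start + 64]
        )
        for offset, dist in enumerate(dists):
            i = start + offset
            rows.append(
                {
                    "id": data.ids[i],
                    "true_months": data.ages_months[i],
                    "predicted_months": dist.mean_months,
                    "variance_months2": dist.var_months2,
                }
            )
    return pd.DataFrame(rows)


def evaluate_run(predictions: pd.DataFrame, truth: dict[str, float]) -> EvalReport:
    """Join predictions with a truth map (id -> months) and evaluate."""
    missing = [i for i in predictions["id"] if i not in truth]
    if missing:
        raise ValueError(f"ids missing from truth: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    y_true = np.array([truth[i] for i in predictions["id"]])
    return evaluate(y_true, predictions["predicted_months"].to_numpy())


def mean_baseline_mae(train_ages: np.ndarray, test_ages: np.ndarray) -> float:
    """MAE of the null predictor that always outputs the training-mean age."""
    return float(np.mean(np.abs(np.asarray(test_ages) - np.mean(train_ages))))


__all__ = [
    "TrainConfig",
    "TrainResult",
    "Dataset",
    "learning_rate_at",
    "prepare_dataset",
    "load_corpus",
    "ages_to_classes",
    "train_on_dataset",
    "train",
    "predict_ages",
    "predict_batch",
    "evaluate_run",
    "mean_baseline_mae",
    "write_training_log",
]
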