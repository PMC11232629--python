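"""Training loop, evaluation, dilation-rate sweep and ablation grid.

Training follows the benchmark protocol: Adam, soft-Dice loss on the
logistic output, mini-batches, a fixed epoch budget, and the checkpoint
retained from the epoch with the best validation Dice.  Everything is
seeded: the shuffle order, the weight initialisation and the synthetic
data are pure functions of the configured seeds, so two runs with the
same configuration produce identical trajectories.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .metrics import (ConfusionCounts, MetricsReport, compute_metrics,
                      confusion_counts, dice_loss_grad, macro_average,
                      micro_average)
from .model import (ModelConfig, SegmentationModel, ablation_variants,
                    build_model, count_parameters, load_checkpoint,
                    save_checkpoint)
from .phantoms import DatasetSplit, PhantomSample
from .layers import Adam

logger = logging.getLogger("sonoseg")


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol (benchmark defaults: Adam, lr 1e-4, batch 8,
    50 epochs, Dice-based loss, best-validation-Dice checkpointing)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 50
    loss: str = "dice"
    checkpoint_metric: str = "val_dice"
    threshold: float = 0.5
    dice_eps: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be >= 1")


@dataclass
class RunRecord:
    """Per-epoch history plus the final (best-epoch) evaluation."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dice: float = -1.0
    test_report: MetricsReport | None = None
    cost: int = 0
    wall_time: float = 0.0
    train_config: dict = field(default_factory=dict)
    model_config: dict = field(default_factory=dict)
    first_batch_loss: float = float("nan")


def _stack(samples: list[PhantomSample], indices) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([samples[i].image for i in indices])[..., None]
    masks = np.stack([samples[i].mask for i in indices])[..., None]
    return images.astype(np.float32), masks.astype(np.float32)


def _predict_batched(model: SegmentationModel, images: np.ndarray,
                     batch_size: int = 8) -> np.ndarray:
    outs = [model.forward(images[i:i + batch_size], training=False)
            for i in range(0, len(images), batch_size)]
    return np.concatenate(outs, axis=0)


@dataclass
class EvalResult:
    metrics: MetricsReport
    counts: ConfusionCounts
    cost: int


def evaluate(model: SegmentationModel, samples: list[PhantomSample],
             indices, threshold: float = 0.5, average: str = "micro",
             batch_size: int = 8) -> EvalResult:
    """Binarise predictions and score them against the ground truth.

    ``average='micro'`` pools confusion counts over every pixel of the
    split before applying the metric formulas; ``'macro'`` averages
    per-image metric values instead.
    """
    indices = list(indices)
    if not indices:
        raise ValueError("cannot evaluate an empty split")
    images, masks = _stack(samples, indices)
    probs = _predict_batched(model, images, batch_size)
    preds = (probs >= threshold).astype(np.uint8)
    per_image = [confusion_counts(preds[i, ..., 0], masks[i, ..., 0].astype(np.uint8))
                 for i in range(len(indices))]
    report = micro_average(per_image) if average == "micro" else macro_average(per_image)
    total = per_image[0]
    for c in per_image[1:]:
        total = total + c
    return EvalResult(metrics=report, counts=total, cost=count_parameters(model))


def train(model: SegmentationModel, samples: list[PhantomSample],
          split: DatasetSplit, tc: TrainConfig,
          checkpoint_path: str | Path | None = None,
          max_steps: int | None = None, restore_best: bool = True) -> RunRecord:
    """Mini-batch gradient descent on the soft-Dice loss.

    After each epoch the validation Dice (micro-averaged at the configured
    threshold) is computed; the parameters of the best epoch are restored
    into ``model`` on return (``restore_best=False`` keeps the final-step
    parameters instead, e.g. for capacity probes) and, if
    ``checkpoint_path`` is given, written to disk.  ``max_steps``
    optionally caps total optimisation steps.
    """
    if not split.train:
        raise ValueError("training split is empty")
    if not split.validation:
        raise ValueError("validation split is empty")

    record = RunRecord(train_config=asdict(tc),
                       model_config=asdict(model.config))
    opt = Adam(model.parameters(), lr=tc.learning_rate)
    rng = np.random.default_rng(tc.seed)
    train_idx = np.asarray(split.train)
    images, masks = _stack(samples, train_idx)

    start = time.time()
    best_params: tuple[list, list] | None = None
    steps = 0
    for epoch in range(tc.epochs):
        order = rng.permutation(len(train_idx))
        losses = []
        for lo in range(0, len(order), tc.batch_size):
            sel = order[lo: lo + tc.batch_size]
            probs = model.forward(images[sel], training=True)
            loss, grad = dice_loss_grad(probs, masks[sel], tc.dice_eps)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {steps}")
            if steps == 0:
                record.first_batch_loss = float(loss)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
            steps += 1
            if max_steps is not None and steps >= max_steps:
                break
        val = evaluate(model, samples, split.validation,
                       threshold=tc.threshold, batch_size=tc.batch_size)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "val_dice": val.metrics.dice, "steps": steps}
        record.epochs.append(entry)
        logger.info("epoch %03d  train_loss %.4f  val_dice %.4f",
                    epoch, entry["train_loss"], entry["val_dice"])
        if val.metrics.dice > record.best_val_dice:
            record.best_val_dice = val.metrics.dice
            record.best_epoch = epoch
            best_params = ([p.value.copy() for p in model.parameters()],
                           [getattr(o, a).copy() for o, a in model.buffers()])
        if max_steps is not None and steps >= max_steps:
            break

    if restore_best and best_params is not None:
        values, buffers = best_params
        for p, v in zip(model.parameters(), values):
            p.value = v.copy()
        for (owner, attr), v in zip(model.buffers(), buffers):
            setattr(owner, attr, v.copy())
    record.cost = count_parameters(model)
    record.wall_time = time.time() - start
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model,
                        extra={"best_epoch": record.best_epoch,
                               "best_val_dice": record.best_val_dice})
    return record


def _run_variant(config: ModelConfig, samples, split, tc: TrainConfig,
                 test_indices=None) -> RunRecord:
    model = build_model(config, np.random.default_rng(tc.seed))
    record = train(model, samples, split, tc)
    test_idx = test_indices if test_indices is not None else split.test
    if test_idx:
        record.test_report = evaluate(model, samples, test_idx,
                                      threshold=tc.threshold,
                                      batch_size=tc.batch_size).metrics
    return record


def sensitivity_sweep(rates: list[int], base_config: ModelConfig,
                      tc: TrainConfig, samples: list[PhantomSample],
                      split: DatasetSplit) -> list[tuple[int, RunRecord]]:
    """Train one model per encoder dilation rate, all else fixed."""
    if any(r < 1 for r in rates):
        raise ValueError("dilation rates must be >= 1")
    rows = []
    for r in rates:
        cfg = base_config.replace(r_enc=r)
        logger.info("sensitivity sweep: dilation rate %d", r)
        rows.append((r, _run_variant(cfg, samples, split, tc)))
    return rows


def ablation_run(base_config: ModelConfig, tc: TrainConfig,
                 samples: list[PhantomSample], split: DatasetSplit
                 ) -> list[tuple[bool, bool, RunRecord]]:
    """Train the 2x2 ablation grid with shared data and seeds."""
    rows = []
    for cfg in ablation_variants(base_config):
        logger.info("ablation: multiscale=%s self_attention=%s",
                    cfg.use_multiscale_cnn, cfg.use_self_attention)
        rows.append((cfg.use_multiscale_cnn, cfg.use_self_attention,
                     _run_variant(cfg, samples, split, tc)))
    return rows


# ---------------------------------------------------------------------------
# tabular output (layout mirrors the benchmark's metric tables)
# ---------------------------------------------------------------------------

_METRIC_COLS = ["Dice", "Acc", "Pre", "Sen", "Spec"]


def write_metrics_table(path: str | Path, rows: list[dict]) -> None:
    """Write one row per model/variant as tab-separated text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fields = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def sweep_table(rows: list[tuple[int, RunRecord]]) -> list[dict]:
    out = []
    for rate, rec in rows:
        entry = {"DilationRate": rate}
        rep = rec.test_report or MetricsReport(*(float("nan"),) * 5)
        entry.update({k: round(v, 4) for k, v in rep.as_dict().items()})
        entry["Cost"] = rec.cost
        out.append(entry)
    return out


def ablation_table(rows: list[tuple[bool, bool, RunRecord]]) -> list[dict]:
    out = []
    for ms, sa, rec in rows:
        entry = {"MultiScaleCNN": int(ms), "SelfAttention": int(sa)}
        rep = rec.test_report or MetricsReport(*(float("nan"),) * 5)
        entry.update({k: round(v, 4) for k, v in rep.as_dict().items()})
        entry["Cost"] = rec.cost
        out.append(entry)
    return out
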