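"""Training loop, learning-rate schedules and evaluation harness.

Training uses Adam against the binary cross-entropy loss. Two schedules are
provided: a constant learning rate of 1e-4 (the volumetric-dataset recipe)
and multi-cycle cosine annealing from 1e-3 down to 1e-6 with warm restarts
every 20 epochs for 10 cycles (the small-dataset recipe). Validation runs
every 5 epochs and checkpoints are written every 10 by default.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor
from .data import SliceSample, stack_batch
from .metrics import (SegMetrics, aggregate, bce_loss, compute_metrics,
                      confusion)
from .network import (LightAWNet, NetworkConfig, build, predict_mask,
                      save_checkpoint)


@dataclass
class TrainConfig:
    schedule: str = "constant"          # "constant" or "cosine"
    lr: float = 1e-4                    # constant-mode learning rate
    max_lr: float = 1e-3                # cosine-mode ceiling
    min_lr: float = 1e-6                # cosine-mode floor
    cycles: int = 10
    epochs_per_cycle: int = 20
    epochs: int = 100
    batch_size: int = 8
    validate_every: int = 5
    checkpoint_every: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be positive")
        if self.min_lr > self.max_lr:
            raise ValueError("min_lr must not exceed max_lr")


#: preset recipes for the two published training regimes
TRAIN_PRESETS = {
    "volumetric": TrainConfig(schedule="constant", lr=1e-4, epochs=100),
    "small_sample": TrainConfig(schedule="cosine", cycles=10,
                                epochs_per_cycle=20, epochs=200),
}


def lr_at(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate at an epoch index (0-based).

    Cosine mode restarts every ``epochs_per_cycle`` epochs:
    lr = min + (max - min) * (1 + cos(pi * t / T)) / 2 with t = epoch mod T.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if cfg.schedule == "constant":
        return cfg.lr
    T = cfg.epochs_per_cycle
    t = epoch % T
    return cfg.min_lr + (cfg.max_lr - cfg.min_lr) * (
        1.0 + math.cos(math.pi * t / T)) / 2.0


@dataclass
class RunLog:
    rows: list = field(default_factory=list)

    def append(self, **row) -> None:
        self.rows.append(row)

    def to_csv(self, path) -> None:
        if not self.rows:
            return
        keys = sorted({k for r in self.rows for k in r})
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(self.rows)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.rows:
                fh.write(json.dumps(row) + "\n")


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_dsc(net: LightAWNet, samples: list[SliceSample],
              threshold: float = 0.5) -> float:
    """Mean Dice of the current network over a sample list (eval mode)."""
    net.eval()
    scores = []
    for s in samples:
        probs = net(Tensor(s.chw()[None])).data[0, 0]
        m = compute_metrics(confusion(predict_mask(probs, threshold), s.mask))
        scores.append(m.dsc)
    net.train()
    return float(np.mean(scores))


def train(net_config: NetworkConfig, train_config: TrainConfig,
          samples: list[SliceSample], *, val_samples=None,
          out_dir=None, max_steps: int | None = None,
          stop_at_dsc: float | None = None,
          verbose: bool = False) -> tuple[LightAWNet, RunLog]:
    """Train a freshly built network on a list of slice samples.

    Fully deterministic given the seed (CPU arithmetic, seeded shuffling and
    initialization). ``max_steps`` bounds the number of optimizer steps and
    ``stop_at_dsc`` stops early once the training Dice reaches the target —
    both are conveniences for smoke tests; ordinary runs use epochs.
    """
    rng = np.random.default_rng(train_config.seed)
    net = build(net_config, seed=train_config.seed)
    opt = Adam(list(net.parameters()), lr=lr_at(train_config, 0))
    log = RunLog()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    step = 0
    for epoch in range(train_config.epochs):
        opt.lr = lr_at(train_config, epoch)
        losses = []
        for idx in _epoch_batches(len(samples), train_config.batch_size, rng):
            batch = [samples[i] for i in idx]
            imgs, masks = stack_batch(batch)
            probs = net(Tensor(imgs))
            loss = bce_loss(probs, masks)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {step}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            step += 1
            if stop_at_dsc is not None and step % 10 == 0:
                if train_dsc(net, samples, net_config.threshold) >= stop_at_dsc:
                    log.append(epoch=epoch, lr=opt.lr,
                               train_loss=float(np.mean(losses)), step=step)
                    return net, log
            if max_steps is not None and step >= max_steps:
                log.append(epoch=epoch, lr=opt.lr,
                           train_loss=float(np.mean(losses)), step=step)
                return net, log
        row = {"epoch": epoch, "lr": opt.lr,
               "train_loss": float(np.mean(losses)), "step": step}
        if (val_samples and train_config.validate_every
                and (epoch + 1) % train_config.validate_every == 0):
            row["val_dsc"] = train_dsc(net, val_samples, net_config.threshold)
        log.append(**row)
        if verbose:
            print(", ".join(f"{k}={v:.5g}" if isinstance(v, float) else
                            f"{k}={v}" for k, v in row.items()))
        if (out_dir is not None and train_config.checkpoint_every
                and (epoch + 1) % train_config.checkpoint_every == 0):
            save_checkpoint(out_dir / f"epoch{epoch + 1:04d}.npz", net,
                            epoch=epoch + 1)
    if out_dir is not None:
        save_checkpoint(out_dir / "last.npz", net,
                        epoch=train_config.epochs)
        log.to_csv(out_dir / "runlog.csv")
        log.to_jsonl(out_dir / "runlog.jsonl")
    return net, log


def evaluate(net: LightAWNet, samples: list[SliceSample],
             threshold: float | None = None) -> dict:
    """Per-case metrics (slices averaged within each case) plus aggregates."""
    if threshold is None:
        threshold = net.config.threshold
    net.eval()
    by_case: dict[str, list[SegMetrics]] = {}
    for s in samples:
        probs = net(Tensor(s.chw()[None])).data[0, 0]
        m = compute_metrics(confusion(predict_mask(probs, threshold), s.mask))
        by_case.setdefault(s.case_id, []).append(m)
    per_case = {}
    case_means = []
    for case, ms in sorted(by_case.items()):
        cm = SegMetrics(*(float(np.mean([getattr(m, k) for m in ms]))
                          for k in ("dsc", "iou", "ur", "fnr")))
        per_case[case] = cm.as_dict()
        case_means.append(cm)
    return {"per_case": per_case, "summary": aggregate(case_means)}


def write_evaluation(report: dict, out_dir) -> None:
    """Emit the per-case CSV and JSON summary of an evaluation report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "per_case.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "dsc", "iou", "ur", "fnr"])
        for case, m in report["per_case"].items():
            writer.writerow([case, m["dsc"], m["iou"], m["ur"], m["fnr"]])
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(report["summary"], fh, indent=1)
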