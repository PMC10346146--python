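"""Training and evaluation pipeline: config, seeded SGD loop, checkpoints, reports.

Defaults mirror the published training recipe — SGD with learning rate 0.01,
momentum 0.9, weight decay 1e-4, batch size 24, 224x224 inputs, 20 000
iterations, loss weights lambda1 = lambda2 = 0.5 — while ``desk_preset``
scales everything to a single CPU (64x64 phantoms, reduced widths, 500
iterations).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import yaml

from .losses import LossWeights, mixed_loss_graph
from .metrics import MetricsReport, evaluate_report, format_report_text, write_report_csv
from .model import RFEUNet
from .nn import SGD, Tensor
from .phantoms import SegSample

__all__ = [
    "TrainConfig",
    "TrainingDiverged",
    "TrainResult",
    "desk_preset",
    "build_model",
    "train",
    "evaluate",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger("rfeunet")

CHECKPOINT_VERSION = 1


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    resolution: int = 224
    n_classes: int = 8
    widths: tuple = (64, 128, 256, 512)
    rfe_layers: int = 2
    units_per_stage: int = 2
    batch_size: int = 24
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0001
    max_iterations: int = 20000
    lr_schedule: str = "constant"   # "constant" | "poly"
    lambda1: float = 0.5            # dice weight
    lambda2: float = 0.5            # cross-entropy weight
    seed: int = 0
    log_every: int = 50
    dtype: str = "float32"
    out_dir: str = "runs"

    def __post_init__(self):
        if self.resolution % 16:
            raise ValueError("resolution must be divisible by 16")
        if self.rfe_layers > 0 and self.resolution % 32:
            raise ValueError("resolution must be divisible by 32 with RFE layers")
        if min(self.learning_rate, self.momentum + 1e-12, self.weight_decay + 1e-12,
               self.batch_size, self.max_iterations) <= 0:
            raise ValueError("rates, batch size and iteration count must be positive")
        if self.lr_schedule not in ("constant", "poly"):
            raise ValueError("lr_schedule must be 'constant' or 'poly'")

    # ------------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        d = asdict(self)
        d["widths"] = list(self.widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "widths" in d:
            d["widths"] = tuple(int(w) for w in d["widths"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def with_overrides(self, overrides: Sequence[str]) -> "TrainConfig":
        """Apply ``key=value`` strings, coercing to the field's current type."""
        updates = {}
        current = self.to_dict()
        for item in overrides:
            if "=" not in item:
                raise ValueError(f"override {item!r} is not of the form key=value")
            key, value = item.split("=", 1)
            if key not in current:
                raise ValueError(f"unknown config key {key!r}")
            ref = getattr(self, key)
            if key == "widths":
                updates[key] = tuple(int(v) for v in value.split(","))
            elif isinstance(ref, bool):
                updates[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(ref, int):
                updates[key] = int(value)
            elif isinstance(ref, float):
                updates[key] = float(value)
            else:
                updates[key] = value
        return replace(self, **updates)


def desk_preset(seed: int = 0, **overrides) -> TrainConfig:
    """Single-CPU preset: 64x64 inputs, widths 8/16/32/64, 500 iterations."""
    cfg = TrainConfig(
        resolution=64, widths=(8, 16, 32, 64), rfe_layers=1, units_per_stage=1,
        batch_size=4, max_iterations=500, learning_rate=0.05, seed=seed, log_every=100,
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class TrainResult:
    model: RFEUNet
    losses: List[float]
    log_lines: List[str]
    checkpoint_path: Optional[str] = None
    best_checkpoint_path: Optional[str] = None


def build_model(config: TrainConfig, rng=None) -> RFEUNet:
    return RFEUNet(
        resolution=config.resolution, n_classes=config.n_classes,
        widths=config.widths, rfe_layers=config.rfe_layers,
        units_per_stage=config.units_per_stage, rng=rng, seed=config.seed,
        dtype=np.dtype(config.dtype).type,
    )


def _lr_at(config: TrainConfig, iteration: int) -> float:
    if config.lr_schedule == "poly":
        return config.learning_rate * (1.0 - iteration / config.max_iterations) ** 0.9
    return config.learning_rate


def train(config: TrainConfig, samples: Sequence[SegSample],
          write_checkpoints: bool = True) -> TrainResult:
    """Seeded, shuffled mini-batch SGD on the mixed dice/cross-entropy loss.

    All randomness (weight init, shuffling) flows from ``config.seed``;
    repeated runs on one device produce identical loss curves.
    """
    if not samples:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(config.seed)
    model = build_model(config, rng=rng)
    opt = SGD(model.parameters(), lr=config.learning_rate,
              momentum=config.momentum, weight_decay=config.weight_decay)
    weights = LossWeights(config.lambda1, config.lambda2)
    dtype = np.dtype(config.dtype).type

    images = np.stack([s.image for s in samples]).astype(dtype)
    masks = np.stack([s.mask for s in samples])
    n = len(samples)

    log_lines = [
        "effective config: " + json.dumps(config.to_dict(), sort_keys=True),
        f"model parameters: {model.num_parameters()}",
    ]
    for line in log_lines:
        logger.info(line)

    losses: List[float] = []
    best = (math.inf, None)
    order = rng.permutation(n)
    cursor = 0
    model.train()
    for it in range(config.max_iterations):
        if cursor + config.batch_size > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor : cursor + config.batch_size]
        if len(idx) == 0:  # batch larger than dataset: sample with wraparound
            idx = rng.integers(0, n, config.batch_size)
        cursor += config.batch_size

        logits = model(Tensor(images[idx]))
        loss = mixed_loss_graph(logits, masks[idx], weights)
        value = loss.item()
        if not math.isfinite(value):
            raise TrainingDiverged(f"non-finite loss {value} at iteration {it}")
        losses.append(value)
        opt.zero_grad()
        loss.backward()
        opt.lr = _lr_at(config, it)
        opt.step()

        if value < best[0]:
            best = (value, model.state_dict())
        if config.log_every and (it % config.log_every == 0 or it == config.max_iterations - 1):
            line = f"iter {it:6d}  loss {value:.4f}  lr {opt.lr:.4g}"
            log_lines.append(line)
            logger.info(line)

    result = TrainResult(model=model, losses=losses, log_lines=log_lines)
    if write_checkpoints:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        final_path = out / "checkpoint_final.npz"
        save_checkpoint(final_path, model, config)
        best_path = out / "checkpoint_best.npz"
        _save_state(best_path, best[1], config)
        (out / "train_log.txt").write_text("\n".join(log_lines) + "\n")
        result.checkpoint_path = str(final_path)
        result.best_checkpoint_path = str(best_path)
    return result


def _save_state(path, state: dict, config: TrainConfig) -> None:
    meta = json.dumps({"version": CHECKPOINT_VERSION, "config": config.to_dict()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def save_checkpoint(path, model: RFEUNet, config: TrainConfig) -> None:
    _save_state(path, model.state_dict(), config)


def load_checkpoint(path) -> tuple:
    """Returns (model, config); the architecture is rebuilt from the embedded config."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        config = TrainConfig.from_dict(meta["config"])
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = build_model(config)
    model.load_state_dict(state)
    model.eval()
    return model, config


def predict(model: RFEUNet, image: np.ndarray, batch: bool = False) -> np.ndarray:
    """Argmax label map for one (3, H, W) image (or a batch)."""
    model.eval()
    arr = np.asarray(image)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    logits = model(Tensor(arr)).numpy()
    masks = logits.argmax(axis=1).astype(np.uint8)
    return masks[0] if squeeze and not batch else masks


def evaluate(model: RFEUNet, samples: Sequence[SegSample], batch_size: int = 4,
             out_dir: Optional[str] = None) -> MetricsReport:
    """Per-sample argmax prediction and per-class DSC / HD95 report."""
    if not samples:
        raise ValueError("evaluation set is empty")
    max_label = max(int(s.mask.max()) for s in samples)
    if max_label > model.config["n_classes"]:
        raise ValueError(
            f"labels contain class {max_label} but the model predicts only "
            f"{model.config['n_classes']} foreground classes"
        )
    model.eval()
    preds = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start : start + batch_size]
        arr = np.stack([s.image for s in chunk]).astype(np.float32)
        logits = model(Tensor(arr)).numpy()
        preds.extend(list(logits.argmax(axis=1).astype(np.uint8)))
    report = evaluate_report(
        preds, [s.mask for s in samples], spacing=samples[0].spacing_mm,
        n_classes=model.config["n_classes"],
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(format_report_text(report) + "\n")
        write_report_csv(report, out / "report.csv")
    return report
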