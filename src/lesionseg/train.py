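"""Patient-disjoint splitting, BCE optimization, checkpointing, prediction.

Hyperparameter defaults: binary cross-entropy loss, batch size 4, Adam with
learning rate 0.001, dropout 0.2, 100 epochs, patient-level 90:10 split.
The encoder is kept frozen for ``freeze_epochs`` epochs (default: the whole
run) when transfer-learned weights are in use; with random initialization a
caller normally sets ``freeze_epochs=0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .core import Prediction, SlicePair
from .evalx import confusion, metric_panel
from .model import DualAttentionASPPUNet, ModelConfig

__all__ = ["TrainConfig", "SplitPlan", "split_patients", "bce_loss",
           "train_model", "predict_batch", "Checkpoint", "LeakageError"]


@dataclass
class TrainConfig:
    batch_size: int = 4
    learning_rate: float = 0.001
    dropout: float = 0.2
    epochs: int = 100
    test_fraction: float = 0.10
    seed: int = 0
    freeze_epochs: int | None = None   # None -> frozen for the whole run
    threshold: float = 0.5
    max_steps: int | None = None       # optional cap on optimizer steps
    stop_at_train_dice: float | None = None
    loss: str = "bce"
    optimizer: str = "adam"

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class SplitPlan:
    train_patients: set[str]
    test_patients: set[str]

    def __post_init__(self):
        if self.train_patients & self.test_patients:
            raise ValueError("train and test patient sets overlap")


class LeakageError(RuntimeError):
    """A test patient appeared in the training set."""


def split_patients(patient_ids, test_fraction: float, seed: int) -> SplitPlan:
    """Patient-level split: shuffle with a seeded RNG and send
    ceil(n * test_fraction) patients to the test set."""
    ids = list(dict.fromkeys(patient_ids))   # unique, order-preserving
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    n_test = int(np.ceil(len(ids) * test_fraction))
    if n_test == 0 or n_test >= len(ids):
        raise ValueError(
            f"test_fraction {test_fraction} yields an empty or full test set "
            f"for {len(ids)} patients"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    test = {ids[i] for i in order[:n_test]}
    return SplitPlan(train_patients=set(ids) - test, test_patients=test)


def bce_loss(y: np.ndarray, o: np.ndarray, reduction: str = "sum",
             eps: float = 1e-7) -> float:
    """Binary cross-entropy  -sum_i [y_i log o_i + (1-y_i) log(1-o_i)].

    ``reduction='sum'`` is the raw per-pixel sum; ``'mean'`` divides by the
    pixel count (the variant used for optimization).  Probabilities are
    clamped to [eps, 1-eps] before the logs.
    """
    y = np.asarray(y, dtype=np.float64)
    o = np.asarray(o, dtype=np.float64)
    if y.shape != o.shape:
        raise ValueError(f"shape mismatch: ground truth {y.shape} vs prediction {o.shape}")
    p = np.clip(o, eps, 1.0 - eps)
    total = float(-(y * np.log(p) + (1.0 - y) * np.log1p(-p)).sum())
    if reduction == "sum":
        return total
    if reduction == "mean":
        return total / y.size
    raise ValueError(f"unknown reduction {reduction!r}")


@dataclass
class Checkpoint:
    state: dict[str, np.ndarray]
    model_config: ModelConfig
    train_config: TrainConfig
    seed: int
    epochs_trained: int
    steps_trained: int
    history: pd.DataFrame = field(repr=False)

    def save(self, path):
        path = Path(path)
        meta = {
            "model_config": self.model_config.to_dict(),
            "train_config": asdict(self.train_config),
            "seed": self.seed,
            "epochs_trained": self.epochs_trained,
            "steps_trained": self.steps_trained,
            "history": self.history.to_dict(orient="list"),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **{f"param/{k}": v for k, v in self.state.items()})

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k[len("param/"):]: data[k] for k in data.files
                     if k.startswith("param/")}
        return cls(state=state,
                   model_config=ModelConfig.from_dict(meta["model_config"]),
                   train_config=TrainConfig(**meta["train_config"]),
                   seed=meta["seed"], epochs_trained=meta["epochs_trained"],
                   steps_trained=meta["steps_trained"],
                   history=pd.DataFrame(meta["history"]))

    def build_model(self) -> DualAttentionASPPUNet:
        model = DualAttentionASPPUNet(self.model_config)
        model.load_state_dict(self.state)
        return model


def _epoch_dice(conf_sum) -> float:
    return metric_panel(conf_sum).dice


def train_model(train_slices: list[SlicePair], cfg: TrainConfig | None = None,
                model_cfg: ModelConfig | None = None,
                test_patients: set[str] | None = None,
                log=None) -> Checkpoint:
    """Train the network with Adam on mean-reduced BCE.

    Batches are drawn with a seeded shuffle each epoch.  The encoder stays
    frozen for the first ``freeze_epochs`` epochs (``None``: the whole run;
    0: never frozen).  If ``test_patients`` is given, training aborts with
    :class:`LeakageError` when any of them occurs in the training slices.
    """
    if not train_slices:
        raise ValueError("empty training set")
    shapes = {s.image.shape for s in train_slices}
    if len(shapes) != 1:
        raise ValueError(f"all training slices must share one shape, got {shapes}")
    if test_patients:
        leaked = {s.patient_id for s in train_slices} & set(test_patients)
        if leaked:
            raise LeakageError(
                f"test patients present in training manifest: {sorted(leaked)}"
            )
    cfg = cfg or TrainConfig()
    model_cfg = model_cfg or ModelConfig.reference(seed=cfg.seed)
    model = DualAttentionASPPUNet(model_cfg)
    freeze_epochs = cfg.epochs if cfg.freeze_epochs is None else cfg.freeze_epochs
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    model.cfg.decoder.dropout_rate = cfg.dropout

    images = np.stack([s.image for s in train_slices])[..., None]
    masks = np.stack([s.mask for s in train_slices]).astype(np.float64)[..., None]
    n = len(train_slices)

    history = []
    steps = 0
    stop = False
    for epoch in range(cfg.epochs):
        model.encoder.set_requires_grad(epoch >= freeze_epochs)
        order = rng.permutation(n)
        losses = []
        conf_sum = None
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            prob = model.forward(images[idx], training=True)
            loss = nn.bce_mean(prob, masks[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            pred = (prob.data >= cfg.threshold).astype(np.uint8)
            c = confusion(pred, masks[idx].astype(np.uint8))
            conf_sum = c if conf_sum is None else conf_sum + c
            steps += 1
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                stop = True
                break
        dice = _epoch_dice(conf_sum)
        history.append({"epoch": epoch, "mean_loss": float(np.mean(losses)),
                        "train_dice": dice, "steps": steps,
                        "encoder_frozen": epoch < freeze_epochs})
        if log is not None:
            log(f"epoch {epoch:3d}  loss {np.mean(losses):.5f}  train dice {dice:.4f}")
        if cfg.stop_at_train_dice is not None and dice >= cfg.stop_at_train_dice:
            stop = True
        if stop:
            break

    return Checkpoint(state=model.state_dict(), model_config=model_cfg,
                      train_config=cfg, seed=cfg.seed,
                      epochs_trained=len(history), steps_trained=steps,
                      history=pd.DataFrame(history))


def predict_batch(checkpoint: Checkpoint | DualAttentionASPPUNet,
                  slices: list[SlicePair], threshold: float = 0.5
                  ) -> list[Prediction]:
    """Deterministic inference (dropout off) on a list of slices."""
    model = checkpoint.build_model() if isinstance(checkpoint, Checkpoint) else checkpoint
    out = []
    for s in slices:
        out.append(model.predict(s.image, threshold=threshold))
    return out
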