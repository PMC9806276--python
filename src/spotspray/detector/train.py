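"""Toy-scale detector training: Adam + cosine-annealed learning rate.

A dataset is a list of ``(image_chw, targets)`` pairs — image as CHW float
in [0, 1] at the network input size, targets as an (N, 5) array of
``class, cx, cy, w, h`` in input pixels.  The loop keeps a loss history
(and optionally a validation-AP history) and returns the weights with the
lowest training loss among the final cycles of the schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Tensor
from .loss import DEFAULT_LAMBDAS, total_loss
from .model import DetectorConfig, WeedDetector
from .nn import Adam, cosine_annealing


@dataclass
class TrainResult:
    history: list[float] = field(default_factory=list)
    lr_history: list[float] = field(default_factory=list)
    val_ap_history: list[tuple[int, float]] = field(default_factory=list)
    best_epoch: int = -1
    best_loss: float = float("inf")
    best_state: dict[str, np.ndarray] = field(default_factory=dict)


def train(model: WeedDetector, dataset: list[tuple[np.ndarray, np.ndarray]],
          epochs: int = 50, lr_max: float = 1e-2, lr_min: float = 5e-5,
          batch_size: int = 10, seed: int = 0,
          lambdas: tuple[float, float, float] = DEFAULT_LAMBDAS,
          val_dataset: list[tuple[np.ndarray, np.ndarray]] | None = None,
          val_every: int = 0, final_cycles_frac: float = 0.25,
          verbose: bool = False) -> TrainResult:
    """Fit the detector; deterministic given the seed.

    The returned best checkpoint is selected as the lowest-loss epoch among
    the last ``final_cycles_frac`` of the schedule (after the learning rate
    has annealed), and the model is left loaded with those weights.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(seed)
    opt = Adam(list(model.parameters()), lr=lr_max)
    result = TrainResult()
    tail_start = int(np.floor(epochs * (1.0 - final_cycles_frac)))
    model.train()
    for epoch in range(epochs):
        lr = cosine_annealing(epoch, epochs, lr_max, lr_min)
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(dataset), batch_size):
            idx = order[start:start + batch_size]
            images = np.stack([dataset[i][0] for i in idx])
            targets = [dataset[i][1] for i in idx]
            loss, _ = total_loss(model.forward(Tensor(images)), targets,
                                 model.config.anchors,
                                 n_classes=model.config.n_classes,
                                 lambdas=lambdas)
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            epoch_loss += loss.item()
            n_batches += 1
        epoch_loss /= n_batches
        result.history.append(epoch_loss)
        result.lr_history.append(lr)
        if val_dataset and val_every and (epoch + 1) % val_every == 0:
            from .evaluate import evaluate_dataset
            model.eval()
            ap = evaluate_dataset(model, val_dataset).AP
            model.train()
            result.val_ap_history.append((epoch, ap))
        if epoch >= tail_start and epoch_loss < result.best_loss:
            result.best_loss = epoch_loss
            result.best_epoch = epoch
            result.best_state = model.state_dict()
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}  lr {lr:.2e}  loss {epoch_loss:.4f}")
    if result.best_state:
        model.load_state_dict(result.best_state)
    model.eval()
    return result


def save_checkpoint(path: str | Path, model: WeedDetector, seed: int,
                    extra: dict | None = None) -> None:
    """Persist weights (npz) with config + seed metadata (sidecar json)."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    cfg = model.config
    meta = {
        "input_size": cfg.input_size, "n_classes": cfg.n_classes,
        "backbone": cfg.backbone, "se_reduction": cfg.se_reduction,
        "neck_width": cfg.neck_width, "conf_threshold": cfg.conf_threshold,
        "nms_threshold": cfg.nms_threshold,
        "anchors": cfg.anchors.tolist(), "seed": seed,
    }
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> WeedDetector:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = DetectorConfig(
        input_size=meta["input_size"], n_classes=meta["n_classes"],
        backbone=meta["backbone"], se_reduction=meta["se_reduction"],
        neck_width=meta["neck_width"], conf_threshold=meta["conf_threshold"],
        nms_threshold=meta["nms_threshold"], anchors=np.array(meta["anchors"]))
    model = WeedDetector(config, seed=meta.get("seed", 0))
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    model.eval()
    return model
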