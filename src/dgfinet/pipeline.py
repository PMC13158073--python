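"""Dataset I/O, the training protocol, and the ablation / loss harnesses.

The training protocol follows the reference regime: Adam at learning rate
1e-3, batch size 16, 200 epochs, inputs resized to 256 x 256 — all of which
scale down through :class:`TrainConfig` for CPU-sized experiments.  Training
is fully deterministic given the config seed (seeded shuffling, seeded
weight init, single-threaded numpy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import losses as losses_mod
from . import metrics as metrics_mod
from . import nn
from .network import (ModelConfig, DGFINet, ablation_variant, build_model,
                      count_mult_adds, count_parameters, get_state, set_state,
                      save_checkpoint)
from .synthetic import SegmentationSample

ABLATION_ORDER = ["baseline", "ecrb", "agfrb", "ecrb_agfrb_dgfi", "full"]

ABLATION_LABELS = {
    "baseline": "Baseline (U-Net)",
    "ecrb": "Baseline+ECRB",
    "agfrb": "Baseline+AGFRB",
    "ecrb_agfrb_dgfi": "Baseline+ECRB+AGFRB+DGFI",
    "full": "Baseline+ECRB+AGFRB+DGFI+LRM (DGFI-Net)",
}


@dataclass
class TrainConfig:
    """Optimization protocol; defaults mirror the reference training regime."""

    epochs: int = 200
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 16
    image_size: int = 256
    loss: str = "dice"
    loss_params: dict = field(default_factory=dict)
    seed: int = 0
    device: str = "cpu"
    checkpoint_dir: str | None = None
    log_dir: str | None = None
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    weight_decay: float = 0.0
    max_steps: int | None = None
    early_stop_train_dice: float | None = None
    threshold: float = 0.5

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.optimizer != "adam":
            raise ValueError(f"only the adam optimizer is supported, "
                             f"got {self.optimizer!r}")
        if self.loss not in losses_mod.LOSS_KINDS:
            raise ValueError(f"loss must be one of {losses_mod.LOSS_KINDS}, "
                             f"got {self.loss!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "adam_betas" in d:
            d["adam_betas"] = tuple(d["adam_betas"])
        return cls(**d)


@dataclass
class TrainHistory:
    """Per-epoch train/val loss and metric records."""

    records: list = field(default_factory=list)

    def append(self, **kw):
        self.records.append(dict(kw))

    def __len__(self):
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def _load_png(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64) / 255.0


def load_dataset(data_dir, split: str | None = None,
                 image_size: int | None = None) -> list[SegmentationSample]:
    """Load image/mask PNG pairs listed in ``manifest.tsv``.

    Images are rescaled to [0, 1] floats and resized bilinearly; masks are
    resized nearest-neighbor and re-binarized.  Pairing is by filename stem
    with the ``_mask`` suffix.
    """
    data_dir = Path(data_dir)
    manifest = data_dir / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.tsv under {data_dir}")
    entries = []
    with open(manifest) as fh:
        for line in fh:
            if line.strip():
                sid, ssplit = line.rstrip("\n").split("\t")
                entries.append((sid, ssplit))
    samples = []
    for sid, ssplit in entries:
        if split is not None and ssplit != split:
            continue
        img_path = data_dir / f"{sid}.png"
        mask_path = data_dir / f"{sid}_mask.png"
        if not img_path.exists():
            raise FileNotFoundError(f"missing image for stem {sid!r}")
        if not mask_path.exists():
            raise FileNotFoundError(f"missing mask for stem {sid!r}")
        if image_size is not None:
            with Image.open(img_path) as im:
                img = np.asarray(
                    im.convert("L").resize((image_size, image_size),
                                           Image.BILINEAR),
                    dtype=np.float64) / 255.0
            with Image.open(mask_path) as im:
                mask_raw = np.asarray(
                    im.convert("L").resize((image_size, image_size),
                                           Image.NEAREST),
                    dtype=np.float64) / 255.0
        else:
            img = _load_png(img_path)
            mask_raw = _load_png(mask_path)
        uniq = np.unique(mask_raw)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError(
                f"mask for stem {sid!r} is not binary after load "
                f"(values {uniq[:5]})"
            )
        mask = (mask_raw >= 0.5).astype(np.uint8)
        samples.append(SegmentationSample(image=img, mask=mask, id=sid))
    return samples


def load_splits(data_dir, image_size: int | None = None):
    """(train, val, test) sample lists from one dataset directory."""
    return tuple(load_dataset(data_dir, s, image_size)
                 for s in ("train", "val", "test"))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _stack(samples) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([s.image[None] for s in samples]).astype(nn.DTYPE)
    masks = np.stack([s.mask[None] for s in samples]).astype(nn.DTYPE)
    return images, masks


def _split_metrics(model: DGFINet, samples, cfg: TrainConfig):
    report = metrics_mod.evaluate(model, samples, threshold=cfg.threshold,
                                  aggregation="per_image_mean",
                                  batch_size=cfg.batch_size)
    return report


def train(model: DGFINet, train_samples, val_samples,
          cfg: TrainConfig):
    """Optimize ``model``; returns (history, best_state).

    ``best_state`` is the parameter/buffer snapshot with the highest
    validation Dice (restorable via :func:`dgfinet.network.set_state`); it is
    also written to ``cfg.checkpoint_dir/best.npz`` when a directory is set.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and val splits must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(dict(model.named_parameters()), lr=cfg.learning_rate,
                  betas=cfg.adam_betas, eps=cfg.adam_eps,
                  weight_decay=cfg.weight_decay)
    images, masks = _stack(train_samples)
    n = images.shape[0]
    history = TrainHistory()
    best_dice = -1.0
    best_state = get_state(model)
    steps = 0
    log_fh = None
    if cfg.log_dir:
        Path(cfg.log_dir).mkdir(parents=True, exist_ok=True)
        log_fh = open(Path(cfg.log_dir) / "train_log.jsonl", "w")
    try:
        for epoch in range(cfg.epochs):
            model.train()
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = images[idx], masks[idx]
                pred = model(xb)
                loss = losses_mod.alt_loss(cfg.loss, pred, yb,
                                           cfg.loss_params)
                lval = float(loss.data)
                if not np.isfinite(lval):
                    raise FloatingPointError(
                        f"non-finite {cfg.loss} loss at epoch {epoch}, "
                        f"step {steps}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(lval)
                steps += 1
                if cfg.max_steps is not None and steps >= cfg.max_steps:
                    break
            train_rep = _split_metrics(model, train_samples, cfg)
            val_rep = _split_metrics(model, val_samples, cfg)
            record = dict(
                epoch=epoch,
                steps=steps,
                train_loss=float(np.mean(epoch_losses)),
                train_dice=train_rep.dice,
                train_mcc=train_rep.mcc,
                train_jaccard=train_rep.jaccard,
                val_dice=val_rep.dice,
                val_mcc=val_rep.mcc,
                val_jaccard=val_rep.jaccard,
            )
            history.append(**record)
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
            if val_rep.dice > best_dice:
                best_dice = val_rep.dice
                best_state = get_state(model)
            if (cfg.early_stop_train_dice is not None
                    and train_rep.dice >= cfg.early_stop_train_dice):
                break
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                break
    finally:
        if log_fh:
            log_fh.close()
    if cfg.checkpoint_dir:
        ckdir = Path(cfg.checkpoint_dir)
        ckdir.mkdir(parents=True, exist_ok=True)
        current = get_state(model)
        set_state(model, best_state)
        save_checkpoint(model, ckdir / "best.npz")
        set_state(model, current)
    return history, best_state


# ---------------------------------------------------------------------------
# harnesses
# ---------------------------------------------------------------------------

def run_ablation(data_dir, variants, train_cfg: TrainConfig,
                 model_cfg: ModelConfig | None = None,
                 out_tsv=None) -> pd.DataFrame:
    """Train and evaluate each ablation variant under identical seeds/data.

    Returns a table with columns Method / Dice / Mcc / Jaccard (test split,
    per-image mean, best-validation checkpoint), in the canonical variant
    order; optionally written as TSV.
    """
    for v in variants:
        if v not in ABLATION_ORDER:
            raise ValueError(f"unknown variant {v!r}; valid: {ABLATION_ORDER}")
    train_s, val_s, test_s = load_splits(data_dir, train_cfg.image_size)
    rows = []
    for name in [v for v in ABLATION_ORDER if v in set(variants)]:
        cfg = ablation_variant(name, model_cfg)
        model = build_model(cfg, train_cfg.seed)
        _, best_state = train(model, train_s, val_s, train_cfg)
        set_state(model, best_state)
        report = metrics_mod.evaluate(model, test_s,
                                      threshold=train_cfg.threshold,
                                      batch_size=train_cfg.batch_size)
        rows.append({"Method": ABLATION_LABELS[name], "Dice": report.dice,
                     "Mcc": report.mcc, "Jaccard": report.jaccard})
    table = pd.DataFrame(rows, columns=["Method", "Dice", "Mcc", "Jaccard"])
    if out_tsv is not None:
        table.to_csv(out_tsv, sep="\t", index=False, float_format="%.4f")
    return table


def run_loss_selection(data_dir, kinds, train_cfg: TrainConfig,
                       model_cfg: ModelConfig | None = None,
                       out_tsv=None) -> pd.DataFrame:
    """Train the same model under each loss; one comparable metric row each."""
    train_s, val_s, test_s = load_splits(data_dir, train_cfg.image_size)
    rows = []
    for kind in kinds:
        cfg_d = train_cfg.to_dict()
        cfg_d["loss"] = kind
        cfg = TrainConfig(**cfg_d)
        model = build_model(model_cfg or ModelConfig(), cfg.seed)
        history, best_state = train(model, train_s, val_s, cfg)
        set_state(model, best_state)
        report = metrics_mod.evaluate(model, test_s, threshold=cfg.threshold,
                                      batch_size=cfg.batch_size)
        rows.append({"Loss": kind,
                     "FinalTrainLoss": history.records[-1]["train_loss"],
                     "Dice": report.dice, "Mcc": report.mcc,
                     "Jaccard": report.jaccard})
    table = pd.DataFrame(rows,
                         columns=["Loss", "FinalTrainLoss", "Dice", "Mcc",
                                  "Jaccard"])
    if out_tsv is not None:
        table.to_csv(out_tsv, sep="\t", index=False, float_format="%.4f")
    return table


def report_complexity(model_cfg: ModelConfig, input_size: int = 256) -> dict:
    """Exact parameter count and analytic conv mult-adds at ``input_size``."""
    model = build_model(model_cfg, seed=0)
    params = count_parameters(model)
    macs = count_mult_adds(model, input_size)
    return {
        "params": params,
        "mult_adds": macs,
        "params_m": params / 1e6,
        "mult_adds_g": macs / 1e9,
        "input_size": int(input_size),
    }
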