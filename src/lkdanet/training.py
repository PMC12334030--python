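"""Seeded training loop with resumable checkpoints.

One iteration = {sample a volume, crop a patch (foreground-biased),
augment, forward, deep-supervised Dice+CE loss, AdamW step}.  All
randomness flows from a single master generator whose state is stored in
the checkpoint, so resuming reproduces the exact loss trajectory the
uninterrupted run would have produced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .network import LKDANet, LKDANetConfig, sliding_window_predict
from .objectives import deep_supervised_loss, dice_ce_loss, dice_score
from .synthetic_data import AugmentConfig, LabeledSample, augment, crop_patch


@dataclass
class TrainConfig:
    """Everything the training loop needs besides the data.

    Defaults follow the reference schedule (AdamW, initial learning rate
    1e-4, 40000 iterations, 96³ patches); tests and the smoke profile
    scale these down.
    """

    model: LKDANetConfig
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    max_iterations: int = 40000
    patch_size: tuple[int, int, int] = (96, 96, 96)
    batch_size: int = 2
    seed: int = 0
    fg_bias: float = 0.5
    augment: bool = True
    augment_config: AugmentConfig = field(default_factory=AugmentConfig)
    poly_lr_decay: bool = False
    poly_power: float = 0.9
    val_interval: int = 100
    log_interval: int = 10

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        self.patch_size = tuple(
            int(p) for p in (self.patch_size
                             if hasattr(self.patch_size, "__len__")
                             else (self.patch_size,) * 3))
        if any(p % 32 for p in self.patch_size):
            raise ValueError(f"patch dims must be divisible by 32 "
                             f"(the encoder's scale ladder), got "
                             f"{self.patch_size}")


def _rng_state_to_json(rng: np.random.Generator) -> str:
    return json.dumps(rng.bit_generator.state)

def _rng_from_json(text: str) -> np.random.Generator:
    rng = np.random.default_rng()
    rng.bit_generator.state = json.loads(text)
    return rng


def save_checkpoint(path, model: LKDANet, optimizer: nn.AdamW,
                    iteration: int, rng: np.random.Generator,
                    config: TrainConfig) -> None:
    payload = {f"model/{k}": v for k, v in model.state_dict().items()}
    opt_state = optimizer.state_dict()
    for i, (m, v) in enumerate(zip(opt_state["m"], opt_state["v"])):
        payload[f"opt/m/{i}"] = m
        payload[f"opt/v/{i}"] = v
    payload["opt/t"] = np.array(opt_state["t"])
    payload["iteration"] = np.array(iteration)
    payload["rng_state"] = np.array(_rng_state_to_json(rng))
    payload["model_config"] = np.array(json.dumps(model.cfg.to_dict()))
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path):
    """Return (model, raw archive) with weights restored."""
    archive = np.load(str(path), allow_pickle=False)
    cfg = LKDANetConfig.from_dict(json.loads(str(archive["model_config"])))
    model = LKDANet(cfg, seed=0)
    state = {k[len("model/"):]: archive[k]
             for k in archive.files if k.startswith("model/")}
    model.load_state_dict(state)
    return model, archive


@dataclass
class TrainResult:
    model: LKDANet
    history: list[dict]

    @property
    def losses(self) -> list[float]:
        return [h["loss"] for h in self.history]


def _make_batch(samples: list[LabeledSample], cfg: TrainConfig,
                rng: np.random.Generator):
    images, labels = [], []
    for _ in range(cfg.batch_size):
        idx = int(rng.integers(len(samples)))
        crop_seed = int(rng.integers(2 ** 31))
        patch = crop_patch(samples[idx], cfg.patch_size, seed=crop_seed,
                           fg_bias=cfg.fg_bias)
        if cfg.augment:
            patch = augment(patch, seed=int(rng.integers(2 ** 31)),
                            config=cfg.augment_config)
        images.append(patch.image)
        labels.append(patch.labels)
    x = nn.Tensor(np.stack(images)[:, None])
    y = np.stack(labels).astype(np.int64)
    return x, y


def _validate(model: LKDANet, samples: list[LabeledSample],
              cfg: TrainConfig) -> float:
    """Mean foreground DSC over the training volumes (smoke-scale check)."""
    scores = []
    for s in samples:
        pred = sliding_window_predict(model, s.image,
                                      window=cfg.patch_size, overlap=0.5)
        for k in range(1, model.cfg.num_classes):
            scores.append(dice_score(pred, s.labels, k))
    return float(np.mean(scores)) if scores else float("nan")


def train(config: TrainConfig, samples: list[LabeledSample], *,
          checkpoint_path=None, resume_from=None,
          log_path=None, validate: bool = False) -> TrainResult:
    """Run the seeded optimisation loop.

    ``samples`` is the training set (phantoms or loaded NIfTI pairs).
    When ``resume_from`` is given, weights, optimiser moments, iteration
    counter and RNG state are restored and the loop continues bit-exactly.
    """
    if not samples:
        raise ValueError("no training samples")
    model = LKDANet(config.model, seed=config.seed)
    optimizer = nn.AdamW(model.parameters(), lr=config.learning_rate,
                         weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    start = 0
    if resume_from is not None:
        model, archive = load_checkpoint(resume_from)
        opt_state = {
            "t": int(archive["opt/t"]),
            "m": [archive[f"opt/m/{i}"]
                  for i in range(len(model.parameters()))],
            "v": [archive[f"opt/v/{i}"]
                  for i in range(len(model.parameters()))],
        }
        optimizer = nn.AdamW(model.parameters(), lr=config.learning_rate,
                             weight_decay=config.weight_decay)
        optimizer.load_state_dict(opt_state)
        rng = _rng_from_json(str(archive["rng_state"]))
        start = int(archive["iteration"])

    history: list[dict] = []
    log_file = open(log_path, "a") if log_path else None
    try:
        model.train()
        for it in range(start, config.max_iterations):
            if config.poly_lr_decay:
                frac = 1.0 - it / config.max_iterations
                optimizer.lr = config.learning_rate * frac ** config.poly_power
            x, y = _make_batch(samples, config, rng)
            if model.cfg.deep_supervision:
                logits, aux = model(x, return_aux=True)
                loss = deep_supervised_loss(logits, aux, y)
            else:
                logits = model(x)
                loss = dice_ce_loss(logits, y)
            loss_val = loss.item()
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss {loss_val} at iteration {it}; "
                    f"lower the learning rate or check the input intensities")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            record = {"iteration": it, "loss": loss_val, "lr": optimizer.lr}
            if validate and (it + 1) % config.val_interval == 0:
                record["mean_dsc"] = _validate(model, samples, config)
                model.train()
            history.append(record)
            if log_file and ((it + 1) % config.log_interval == 0
                             or "mean_dsc" in record):
                log_file.write(json.dumps(record) + "\n")
                log_file.flush()
        if checkpoint_path is not None:
            save_checkpoint(checkpoint_path, model, optimizer,
                            config.max_iterations, rng, config)
    finally:
        if log_file:
            log_file.close()
    return TrainResult(model=model, history=history)
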