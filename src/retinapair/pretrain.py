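"""Training loops for multi-modal (CLIP/CLOOB) and uni-modal (SimCLR/BYOL/
VICReg) pre-training.

Multi-modal training shows the model one randomly selected (fundus, OCT)
pair per patient per epoch; the per-epoch random seed is derived from the
master seed so runs are exactly reproducible.  The temperature is a
learnable log-inverse-temperature initialized at ``log(1/0.07)`` and clamped
to inverse temperature <= 100.  The optimizer is AdamW with weight decay 0.1
(biases and the temperature are excluded from decay) under a cosine
learning-rate schedule with warmup.  Per-epoch history records train loss,
validation loss and validation top-1 retrieval in both directions; the
final-epoch weights are the checkpoint.

Everything runs single-process on CPU in float64.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._autodiff import Tensor, l2_normalize, no_grad
from . import objectives as obj
from .encoders import (
    EncoderConfig,
    ProjectionHead,
    embed,
    encoder_config_from_dict,
    encoder_config_to_dict,
    load_modules,
    load_weights,
    make_encoder,
    save_modules,
)
from .nn import Linear, Module
from .optim import AdamW, cosine_warmup_lr
from .preprocess import AugmentationPolicy, PreprocessConfig, augment, normalize, preprocess_fundus, preprocess_volume
from .splits import SplitAssignment, epoch_pair_indices

__all__ = [
    "PretrainConfig",
    "PretrainResult",
    "build_training_arrays",
    "pretrain",
    "pretrain_multimodal",
    "pretrain_unimodal",
    "save_checkpoint",
    "load_checkpoint",
    "search_learning_rate",
]

CONTRASTIVE_OBJECTIVES = ("clip", "cloob", "simclr")
MIN_BATCH_TWO = ("clip", "cloob", "simclr", "vicreg")  # pairwise losses need >= 2 rows


@dataclass
class PretrainConfig:
    objective: str = "clip"  # clip | cloob | simclr | byol | vicreg
    epochs: int = 300
    batch_size: int = 32
    lr: float = 1e-4
    weight_decay: float = 0.1
    warmup_epochs: int = 1
    embed_dim: int = 512
    backbone: str = "tiny"
    init_tau: float = 0.07
    learnable_tau: bool = True
    hopfield_beta: float = 8.0
    # CLOOB only: epochs trained with InfoNCE before ramping in the
    # Hopfield-InfoLOOB objective (linear blend over loob_ramp_epochs).  At
    # small batch sizes InfoLOOB has an attractive collapse fixed point and a
    # hard objective switch can throw the encoders into it; the warm-up plus
    # gradual ramp keeps training out of that basin.
    loob_warmup_epochs: int = 5
    loob_ramp_epochs: int = 5
    ema_momentum: float = 0.996  # BYOL target network
    projection_dim: int = 128    # uni-modal projection head
    modality: str = "fundus2d"   # uni-modal runs only
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    input_noise_sd: float = 0.3  # multi-modal runs: per-step Gaussian input jitter
    multimodal_crop: bool = False  # multi-modal runs: random center-crop jitter
    seed: int = 0

    def validate(self) -> None:
        if self.objective not in ("clip", "cloob", "simclr", "byol", "vicreg"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.objective in CONTRASTIVE_OBJECTIVES and self.batch_size < 2:
            raise ValueError(f"{self.objective} needs batch_size >= 2 (contrastive negatives)")


@dataclass
class PretrainResult:
    encoders: dict  # name -> Module
    temperature: obj.TemperatureParam | None
    history: pd.DataFrame
    config: PretrainConfig
    extras: dict = field(default_factory=dict)


def build_training_arrays(
    scans,
    fundus_size: tuple[int, int] = (32, 32),
    oct_size: tuple[int, int, int] = (8, 96, 32),
) -> dict:
    """Preprocess a cohort into dense arrays for the training loops.

    Applies the canonical pipeline (grayscale, bilinear resize, ordered slice
    subsampling, per-image/volume normalization) at the requested encoder
    input sizes.
    """
    f_cfg = PreprocessConfig(target_size=fundus_size)
    o_cfg = PreprocessConfig(target_size=oct_size[1:], n_keep_slices=oct_size[0])
    fundus = np.stack([preprocess_fundus(s.fundus, f_cfg) for s in scans])
    oct_v = np.stack([preprocess_volume(s.oct, o_cfg) for s in scans])
    return {
        "fundus": fundus,
        "oct": oct_v,
        "patient_id": np.array([s.patient_id for s in scans]),
        "visit": np.array([s.visit_index for s in scans]),
        "scans": list(scans),
    }


def _split_indices(data: dict, split: SplitAssignment, name: str) -> np.ndarray:
    wanted = set(split.patients(name))
    return np.array([i for i, p in enumerate(data["patient_id"]) if p in wanted], dtype=int)


def _epoch_seed(master_seed: int, epoch: int, salt: int = 0) -> int:
    return int((master_seed * 1_000_003 + 7919 * epoch + salt) % (2**31 - 1))


def _decay_mask(params, named) -> list[bool]:
    # decay weights only; biases and the temperature are excluded
    no_decay_ids = {id(p) for name, p in named.items() if "bias" in name or "log_inv_tau" in name}
    return [id(p) not in no_decay_ids for p in params]


class _Bundle(Module):
    """Container module so named_parameters covers all trainable parts."""

    def __init__(self, **modules):
        for k, v in modules.items():
            setattr(self, k, v)


def pretrain(data: dict, split: SplitAssignment, config: PretrainConfig) -> PretrainResult:
    """Dispatch to the multi-modal or uni-modal training loop."""
    config.validate()
    if config.objective in ("clip", "cloob"):
        return pretrain_multimodal(data, split, config)
    return pretrain_unimodal(data, split, config)


# --------------------------------------------------------------- multi-modal
def pretrain_multimodal(
    data: dict,
    split: SplitAssignment,
    config: PretrainConfig,
    enc_x: Module | None = None,
    enc_y: Module | None = None,
) -> PretrainResult:
    config.validate()
    from .retrieval import topk_accuracy  # deferred: avoid import-order churn

    fundus, oct_v = data["fundus"], data["oct"]
    if enc_x is None:
        enc_x = make_encoder(
            EncoderConfig("fundus2d", config.backbone, config.embed_dim,
                          fundus.shape[1:], seed=config.seed)
        )
    if enc_y is None:
        enc_y = make_encoder(
            EncoderConfig("oct3d", config.backbone, config.embed_dim,
                          oct_v.shape[1:], seed=config.seed + 1)
        )
    temp = obj.TemperatureParam(config.init_tau, learnable=config.learnable_tau)
    bundle = _Bundle(enc_x=enc_x, enc_y=enc_y, temp=temp)
    params = bundle.parameters()
    optimizer = AdamW(
        params,
        lr=config.lr,
        weight_decay=config.weight_decay,
        decay_mask=_decay_mask(params, bundle.named_parameters()),
    )

    train_idx = _split_indices(data, split, "train")
    val_idx = _split_indices(data, split, "val")
    if train_idx.size == 0:
        raise ValueError("train split is empty")

    n_patients = len(set(data["patient_id"][train_idx]))
    steps_per_epoch = max(1, math.ceil(n_patients / config.batch_size))
    total_steps = config.epochs * steps_per_epoch
    warmup = config.warmup_epochs * steps_per_epoch

    history = []
    step = 0
    for epoch in range(config.epochs):
        pair_local = epoch_pair_indices(
            data["patient_id"][train_idx], _epoch_seed(config.seed, epoch)
        )
        epoch_idx = train_idx[pair_local]
        rng = np.random.default_rng(_epoch_seed(config.seed, epoch, salt=17))
        order = rng.permutation(len(epoch_idx))
        losses = []
        for start in range(0, len(order), config.batch_size):
            sel = epoch_idx[order[start : start + config.batch_size]]
            if len(sel) < 2:
                continue
            optimizer.lr = cosine_warmup_lr(step, total_steps, config.lr, warmup)
            xb, yb = fundus[sel], oct_v[sel]
            if config.multimodal_crop:
                policy = AugmentationPolicy(p_crop=0.5, p_hflip=0.0, p_blur=0.0,
                                            p_contrast=0.0, crop_scale=(0.85, 1.0))
                xb = np.stack([augment(x, policy, rng) for x in xb])
                yb = np.stack([augment(v, policy, rng) for v in yb])
            if config.input_noise_sd > 0:
                # light per-step input jitter regularizes the small-cohort
                # regime where contrastive training otherwise memorizes pairs
                xb = xb + rng.normal(0.0, config.input_noise_sd, size=xb.shape)
                yb = yb + rng.normal(0.0, config.input_noise_sd, size=yb.shape)
            U = l2_normalize(enc_x(Tensor(xb)), axis=-1)
            V = l2_normalize(enc_y(Tensor(yb)), axis=-1)
            tau_t = temp.inv_tau() ** -1.0
            if config.objective == "clip":
                loss = obj.info_nce(U @ V.T, tau_t)
            else:
                ramp = max(1, config.loob_ramp_epochs)
                w = min(1.0, max(0.0, (epoch - config.loob_warmup_epochs + 1) / ramp))
                loss = w * obj.cloob_loss(U, V, tau_t, config.hopfield_beta)
                if w < 1.0:
                    loss = loss + (1.0 - w) * obj.info_nce(U @ V.T, tau_t)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
            step += 1
        record = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)) if losses else np.nan,
            "lr": optimizer.lr,
            "tau": temp.tau,
        }
        if val_idx.size >= 2:
            record.update(_validate_multimodal(data, val_idx, enc_x, enc_y, temp, config, topk_accuracy))
        history.append(record)
    return PretrainResult(
        encoders={"fundus2d": enc_x, "oct3d": enc_y},
        temperature=temp,
        history=pd.DataFrame(history),
        config=config,
    )


def _validate_multimodal(data, val_idx, enc_x, enc_y, temp, config, topk_accuracy) -> dict:
    with no_grad():
        U = embed(data["fundus"][val_idx], enc_x).values
        V = embed(data["oct"][val_idx], enc_y).values
        S = U @ V.T
        tau = temp.tau
        if config.objective == "clip":
            val_loss = float(obj.info_nce(S, tau).data)
        else:
            val_loss = float(obj.cloob_loss(U, V, tau, config.hopfield_beta).data)
        return {
            "val_loss": val_loss,
            "val_top1_f2o": topk_accuracy(S, (1,), "fundus_to_oct")[1],
            "val_top1_o2f": topk_accuracy(S, (1,), "oct_to_fundus")[1],
        }


# ---------------------------------------------------------------- uni-modal
def _two_views(batch: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator):
    v1, v2 = [], []
    for x in batch:
        v1.append(normalize(augment(x, policy, rng)))
        v2.append(normalize(augment(x, policy, rng)))
    return np.stack(v1), np.stack(v2)


def pretrain_unimodal(
    data: dict,
    split: SplitAssignment,
    config: PretrainConfig,
    encoder: Module | None = None,
) -> PretrainResult:
    """SimCLR / BYOL / VICReg on one modality with a 128-d projection head.

    The projection head (and, for BYOL, the predictor and EMA target
    network) is discarded for downstream use; only the encoder is kept.
    """
    config.validate()
    key = "fundus" if config.modality == "fundus2d" else "oct"
    arrays = data[key]
    if encoder is None:
        encoder = make_encoder(
            EncoderConfig(config.modality, config.backbone, config.embed_dim,
                          arrays.shape[1:], seed=config.seed)
        )
    projector = ProjectionHead(config.embed_dim, config.projection_dim, seed=config.seed + 11)
    modules = {"encoder": encoder, "projector": projector}
    extras: dict = {}
    if config.objective == "byol":
        predictor = Linear(
            config.projection_dim,
            config.projection_dim,
            np.random.default_rng(np.random.SeedSequence([config.seed, 21])),
        )
        target_enc = make_encoder(
            EncoderConfig(config.modality, config.backbone, config.embed_dim,
                          arrays.shape[1:], seed=config.seed)
        )
        target_proj = ProjectionHead(config.embed_dim, config.projection_dim, seed=config.seed + 11)
        target_enc.load_state_dict(encoder.state_dict())
        target_proj.load_state_dict(projector.state_dict())
        modules["predictor"] = predictor
        extras["target_encoder"] = target_enc
        extras["target_projector"] = target_proj

    bundle = _Bundle(**modules)
    params = bundle.parameters()
    optimizer = AdamW(
        params,
        lr=config.lr,
        weight_decay=config.weight_decay,
        decay_mask=_decay_mask(params, bundle.named_parameters()),
    )
    temp = obj.TemperatureParam(config.init_tau, learnable=False)

    train_idx = _split_indices(data, split, "train")
    val_idx = _split_indices(data, split, "val")
    if train_idx.size == 0:
        raise ValueError("train split is empty")

    n_patients = len(set(data["patient_id"][train_idx]))
    steps_per_epoch = max(1, math.ceil(n_patients / config.batch_size))
    total_steps = config.epochs * steps_per_epoch
    warmup = config.warmup_epochs * steps_per_epoch

    def batch_loss(xb: np.ndarray, rng: np.random.Generator) -> Tensor:
        v1, v2 = _two_views(xb, config.augmentation, rng)
        if config.objective == "simclr":
            z1 = projector(encoder(Tensor(v1)))
            z2 = projector(encoder(Tensor(v2)))
            return obj.nt_xent(z1, z2, temp.tau)
        if config.objective == "vicreg":
            z1 = projector(encoder(Tensor(v1)))
            z2 = projector(encoder(Tensor(v2)))
            return obj.vicreg_loss(z1, z2)
        # BYOL, symmetrized
        p1 = modules["predictor"](projector(encoder(Tensor(v1))))
        p2 = modules["predictor"](projector(encoder(Tensor(v2))))
        with no_grad():
            t1 = extras["target_projector"](extras["target_encoder"](Tensor(v1)))
            t2 = extras["target_projector"](extras["target_encoder"](Tensor(v2)))
        return 0.5 * (obj.byol_loss(p1, Tensor(t2.data)) + obj.byol_loss(p2, Tensor(t1.data)))

    history = []
    step = 0
    for epoch in range(config.epochs):
        pair_local = epoch_pair_indices(
            data["patient_id"][train_idx], _epoch_seed(config.seed, epoch)
        )
        epoch_idx = train_idx[pair_local]
        rng = np.random.default_rng(_epoch_seed(config.seed, epoch, salt=23))
        order = rng.permutation(len(epoch_idx))
        losses = []
        for start in range(0, len(order), config.batch_size):
            sel = epoch_idx[order[start : start + config.batch_size]]
            if config.objective in MIN_BATCH_TWO and len(sel) < 2:
                continue
            optimizer.lr = cosine_warmup_lr(step, total_steps, config.lr, warmup)
            loss = batch_loss(arrays[sel], rng)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            if config.objective == "byol":
                _ema_update(extras["target_encoder"], encoder, config.ema_momentum)
                _ema_update(extras["target_projector"], projector, config.ema_momentum)
            losses.append(float(loss.data))
            step += 1
        record = {"epoch": epoch, "train_loss": float(np.mean(losses)) if losses else np.nan,
                  "lr": optimizer.lr}
        if val_idx.size >= 2:
            rng_val = np.random.default_rng(_epoch_seed(config.seed, 10_000, salt=29))
            with no_grad():
                record["val_loss"] = float(batch_loss(arrays[val_idx], rng_val).data)
        history.append(record)
    return PretrainResult(
        encoders={config.modality: encoder},
        temperature=None,
        history=pd.DataFrame(history),
        config=config,
        extras={"projector": projector, **extras},
    )


def _ema_update(target: Module, online: Module, momentum: float) -> None:
    t_named = target.named_parameters()
    o_named = online.named_parameters()
    for k, p in t_named.items():
        p.data = momentum * p.data + (1.0 - momentum) * o_named[k].data


# ------------------------------------------------------------- checkpointing
def save_checkpoint(directory: str, result: PretrainResult) -> None:
    """Persist final-epoch weights, encoder configs and training history."""
    modules = dict(result.encoders)
    if result.temperature is not None:
        modules["temperature"] = result.temperature
    config = {
        "pretrain": asdict(result.config),
        "encoders": {
            name: encoder_config_to_dict(mod.config) for name, mod in result.encoders.items()
        },
        "has_temperature": result.temperature is not None,
    }
    save_modules(directory, modules, config)
    result.history.to_csv(f"{directory}/history.csv", index=False)


def load_checkpoint(directory: str) -> dict:
    """Rebuild encoders (and temperature) from a checkpoint directory."""
    config = load_modules(directory)
    encoders = {
        name: make_encoder(encoder_config_from_dict(cfg))
        for name, cfg in config["encoders"].items()
    }
    modules = dict(encoders)
    if config.get("has_temperature"):
        pc = config["pretrain"]
        modules["temperature"] = obj.TemperatureParam(
            pc.get("init_tau", 0.07), learnable=pc.get("learnable_tau", True)
        )
    load_weights(directory, modules)
    return {"encoders": encoders, "temperature": modules.get("temperature"), "config": config}


def search_learning_rate(
    data: dict,
    split: SplitAssignment,
    config: PretrainConfig,
    grid=(1e-5, 1e-4, 1e-3),
    search_epochs: int = 5,
) -> float:
    """Small grid search within [1e-6, 1e-3], selected on validation loss."""
    from dataclasses import replace

    best_lr, best_val = grid[0], np.inf
    for lr in grid:
        trial = replace(config, lr=lr, epochs=search_epochs)
        res = pretrain(data, split, trial)
        val = res.history["val_loss"].iloc[-1] if "val_loss" in res.history else res.history["train_loss"].iloc[-1]
        if val < best_val:
            best_val, best_lr = val, lr
    return best_lr
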