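"""Modality encoders h_x (2D fundus) and h_y (3D OCT) and the uni-modal
projection head.

The encoders are stacks of non-overlapping strided convolutions (patch
embeddings, stride equal to kernel size) with ReLU nonlinearities, followed
by a linear map into the shared d-dimensional embedding space.  Two desk-
scale variants ship:

* ``tiny`` — for 32x32 fundus images and 8x96x32 volumes; a forward pass on
  a batch of 32 runs in well under a second on one CPU, which is what makes
  end-to-end contrastive training testable.
* ``small`` — for the full 224x224 / 20x224x224 preprocessing output, still
  CPU-trainable at modest batch sizes.

The shipping embedding dimension default is ``d = 512``; tests use smaller
``d``.  Embeddings are l2-normalized before contrastive losses and retrieval
(cosine-similarity convention); downstream probing uses unnormalized encoder
outputs by default.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from ._autodiff import Tensor, l2_normalize, leaky_relu, no_grad
from .nn import Linear, Module

__all__ = [
    "EncoderConfig",
    "EmbeddingMatrix",
    "Fundus2DEncoder",
    "OCT3DEncoder",
    "ProjectionHead",
    "make_encoder",
    "embed",
    "project",
    "save_modules",
    "load_modules",
]

TINY_FUNDUS_SIZE = (32, 32)
TINY_OCT_SIZE = (8, 96, 32)
SMALL_FUNDUS_SIZE = (224, 224)
SMALL_OCT_SIZE = (20, 224, 224)


@dataclass
class EncoderConfig:
    modality: str = "fundus2d"  # fundus2d | oct3d
    backbone: str = "tiny"      # tiny | small
    embed_dim: int = 512
    input_size: tuple | None = None  # defaults per backbone/modality
    seed: int = 0

    def __post_init__(self):
        if self.modality not in ("fundus2d", "oct3d"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.backbone not in ("tiny", "small"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if self.input_size is None:
            defaults = {
                ("fundus2d", "tiny"): TINY_FUNDUS_SIZE,
                ("fundus2d", "small"): SMALL_FUNDUS_SIZE,
                ("oct3d", "tiny"): TINY_OCT_SIZE,
                ("oct3d", "small"): SMALL_OCT_SIZE,
            }
            self.input_size = defaults[(self.modality, self.backbone)]
        self.input_size = tuple(self.input_size)


@dataclass
class EmbeddingMatrix:
    """n x d embeddings for one modality, rows aligned to manifest rows."""

    values: np.ndarray
    modality: str
    l2_normalized: bool
    ids: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("embedding matrix must be 2-D")
        if self.l2_normalized:
            norms = np.linalg.norm(self.values, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-5):
                raise ValueError("rows declared l2-normalized but norms deviate from 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


class _PatchEmbed2D(Module):
    """Non-overlapping strided convolution: patchify then linear."""

    def __init__(self, in_ch: int, out_ch: int, patch: int, rng: np.random.Generator):
        self.patch = patch
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.lin = Linear(patch * patch * in_ch, out_ch, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        p = self.patch
        gh, gw = h // p, w // p
        x = x.reshape(b, gh, p, gw, p, c)
        x = x.transpose((0, 1, 3, 2, 4, 5))
        x = x.reshape(b, gh, gw, p * p * c)
        return self.lin(x)


class _PatchEmbed3D(Module):
    """3D patch embedding with optional soft divisive patch normalization.

    OCT intensity gain varies per acquisition (scanner gain, per-layer
    reflectivity); dividing each patch by its norm plus a constant makes the
    first stage approximately gain-invariant, a standard contrast-
    normalization move for OCT analysis.
    """

    def __init__(self, in_ch: int, out_ch: int, patch: tuple[int, int, int], rng,
                 patch_norm: bool = False, norm_eps: float = 1.0):
        self.patch = patch
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.patch_norm = patch_norm
        self.norm_eps = norm_eps
        ps, ph, pw = patch
        self.lin = Linear(ps * ph * pw * in_ch, out_ch, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, s, h, w, c = x.shape
        ps, ph, pw = self.patch
        gs, gh, gw = s // ps, h // ph, w // pw
        x = x.reshape(b, gs, ps, gh, ph, gw, pw, c)
        x = x.transpose((0, 1, 3, 5, 2, 4, 6, 7))
        x = x.reshape(b, gs, gh, gw, ps * ph * pw * c)
        if self.patch_norm:
            sq = (x * x).sum(axis=-1, keepdims=True)
            x = x * ((sq.sqrt() + self.norm_eps) ** -1.0)
        return self.lin(x)


def _check_divisible(size, factors, what):
    for dim, f in zip(size, factors):
        if dim % f:
            raise ValueError(f"{what}: input dim {dim} not divisible by patch factor {f}")


class Fundus2DEncoder(Module):
    """2D patch-embedding stack -> d-dimensional embedding."""

    def __init__(self, config: EncoderConfig):
        if config.modality != "fundus2d":
            raise ValueError("config modality must be fundus2d")
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        h, w = config.input_size
        if config.backbone == "tiny":
            p1, c1, p2, c2 = 4, 16, 2, 32
        else:
            p1, c1, p2, c2 = 8, 32, 4, 64
        _check_divisible((h, w), (p1 * p2, p1 * p2), "fundus encoder")
        self.pe1 = _PatchEmbed2D(1, c1, p1, rng)
        self.pe2 = _PatchEmbed2D(c1, c2, p2, rng)
        gh, gw = h // (p1 * p2), w // (p1 * p2)
        self.head = Linear(gh * gw * c2, config.embed_dim, rng)
        self._flat = gh * gw * c2

    def forward(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        expected = self.config.input_size
        if x.ndim != 3 or x.shape[1:] != expected:
            raise ValueError(f"expected batch of shape (n, {expected[0]}, {expected[1]}), got {x.shape}")
        b = x.shape[0]
        x = x.reshape(b, *expected, 1)
        x = leaky_relu(self.pe1(x))
        x = leaky_relu(self.pe2(x))
        return self.head(x.reshape(b, self._flat))


class OCT3DEncoder(Module):
    """3D patch-embedding stack -> d-dimensional embedding."""

    def __init__(self, config: EncoderConfig):
        if config.modality != "oct3d":
            raise ValueError("config modality must be oct3d")
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
        s, h, w = config.input_size
        if config.backbone == "tiny":
            pa, c1, pb, c2 = (2, 4, 4), 32, (2, 2, 2), 64
        else:
            pa, c1, pb, c2 = (4, 8, 8), 32, (5, 4, 4), 64
        factors = tuple(a * b for a, b in zip(pa, pb))
        _check_divisible((s, h, w), factors, "oct encoder")
        self.pe1 = _PatchEmbed3D(1, c1, pa, rng)
        self.pe2 = _PatchEmbed3D(c1, c2, pb, rng)
        gs, gh, gw = (d // f for d, f in zip((s, h, w), factors))
        self.head = Linear(gs * gh * gw * c2, config.embed_dim, rng)
        self._flat = gs * gh * gw * c2

    def forward(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        expected = self.config.input_size
        if x.ndim != 4 or x.shape[1:] != expected:
            raise ValueError(f"expected batch of shape (n, {expected}), got {x.shape}")
        b = x.shape[0]
        x = x.reshape(b, *expected, 1)
        x = leaky_relu(self.pe1(x))
        x = leaky_relu(self.pe2(x))
        return self.head(x.reshape(b, self._flat))


class ProjectionHead(Module):
    """Single 128-d linear layer used only during uni-modal pre-training."""

    def __init__(self, in_dim: int, out_dim: int = 128, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
        self.lin = Linear(in_dim, out_dim, rng)

    def forward(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.shape[-1] != self.lin.in_dim:
            raise ValueError(f"projection head expects dim {self.lin.in_dim}, got {x.shape[-1]}")
        return self.lin(x)


def make_encoder(config: EncoderConfig) -> Module:
    return Fundus2DEncoder(config) if config.modality == "fundus2d" else OCT3DEncoder(config)


def embed(batch: np.ndarray, encoder: Module, l2norm: bool = True, ids=None) -> EmbeddingMatrix:
    """Evaluation-mode embedding of a preprocessed batch (deterministic)."""
    with no_grad():
        out = encoder(np.asarray(batch, dtype=float))
        if l2norm:
            out = l2_normalize(out, axis=-1)
    return EmbeddingMatrix(
        values=out.data,
        modality=encoder.config.modality,
        l2_normalized=l2norm,
        ids=None if ids is None else np.asarray(ids),
    )


def project(embeddings, head: ProjectionHead) -> np.ndarray:
    values = embeddings.values if isinstance(embeddings, EmbeddingMatrix) else np.asarray(embeddings)
    with no_grad():
        return head(values).data


def parameter_count(module: Module) -> int:
    return sum(p.data.size for p in module.parameters())


# ----------------------------------------------------------- checkpoint I/O
def save_modules(directory: str, modules: dict[str, Module], config: dict) -> None:
    """Write module weights (single npz) plus a JSON config sidecar."""
    os.makedirs(directory, exist_ok=True)
    arrays = {}
    for name, mod in modules.items():
        for k, v in mod.state_dict().items():
            arrays[f"{name}/{k}"] = v
    np.savez(os.path.join(directory, "weights.npz"), **arrays)
    with open(os.path.join(directory, "config.json"), "w") as fh:
        json.dump(config, fh, indent=2, default=_json_default)


def load_weights(directory: str, modules: dict[str, Module]) -> None:
    with np.load(os.path.join(directory, "weights.npz")) as data:
        for name, mod in modules.items():
            prefix = f"{name}/"
            state = {k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)}
            mod.load_state_dict(state)


def load_modules(directory: str) -> dict:
    """Load the checkpoint config; callers rebuild modules then load weights."""
    with open(os.path.join(directory, "config.json")) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def encoder_config_to_dict(config: EncoderConfig) -> dict:
    d = asdict(config)
    d["input_size"] = list(config.input_size)
    return d


def encoder_config_from_dict(d: dict) -> EncoderConfig:
    d = dict(d)
    if d.get("input_size") is not None:
        d["input_size"] = tuple(d["input_size"])
    return EncoderConfig(**d)
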