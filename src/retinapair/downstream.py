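"""Downstream adaptation: linear probing, fine-tuning, metrics, bootstrap
variance and the modality-interchange evaluation.

The prediction head is a single fully connected layer on top of the encoder
embedding.  Training uses the task loss (MSE for regression, binary
cross-entropy for binary targets, cross-entropy for multi-class), AdamW with
weight decay 0.1, a reduce-on-plateau learning-rate schedule, at most 100
epochs and early stopping after 5 non-improving validation epochs; the
weights from the best validation epoch are kept.  The head learning rate is
selected from a small grid inside [1e-6, 1e-3] on validation loss.

Regression is scored by R^2 (negative values allowed: worse than predicting
the mean) and RMSE; classification by support-weighted one-vs-rest AUROC and
average precision.  Test-set variability is estimated by bootstrapping.

The interchange evaluation feeds fundus embeddings into a head trained on
OCT embeddings from the same multi-modal checkpoint and reports the relative
performance decay ``(source - swapped) / source``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from ._autodiff import Tensor, logsumexp, no_grad
from .nn import Linear, Module
from .optim import AdamW, EarlyStopper, ReduceLROnPlateau

__all__ = [
    "ProbeTask",
    "ProbeConfig",
    "ProbeReport",
    "InterchangeReport",
    "ProbeHead",
    "linear_probe",
    "fine_tune",
    "compute_metrics",
    "weighted_one_vs_rest",
    "bootstrap_eval",
    "interchange_eval",
]

TASK_TYPES = ("regression", "binary", "multiclass")


@dataclass
class ProbeTask:
    name: str
    task_type: str
    label: str  # manifest column

    def __post_init__(self):
        if self.task_type not in TASK_TYPES:
            raise ValueError(f"task_type must be one of {TASK_TYPES}")

    @property
    def loss_name(self) -> str:
        return {"regression": "mse", "binary": "bce", "multiclass": "ce"}[self.task_type]


@dataclass
class ProbeConfig:
    lr_grid: tuple[float, ...] = (1e-5, 1e-4, 1e-3)
    max_epochs: int = 100
    batch_size: int = 16
    patience: int = 5
    weight_decay: float = 0.1
    plateau_factor: float = 0.5
    plateau_patience: int = 2
    bootstrap_B: int = 1000
    standardize: bool = True  # z-score features (and regression targets) on train stats
    seed: int = 0


@dataclass
class ProbeReport:
    task: str
    mode: str  # linear_probe | fine_tune
    metrics: dict[str, float]
    bootstrap: dict[str, tuple[float, float]]  # metric -> (mean, sd)
    n_test: int
    lr: float = np.nan

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "mode": self.mode,
            "metrics": self.metrics,
            "bootstrap": {k: list(v) for k, v in self.bootstrap.items()},
            "n_test": self.n_test,
            "lr": self.lr,
        }


@dataclass
class InterchangeReport:
    task: str
    source_metrics: dict[str, float]  # OCT-embedding input
    swapped_metrics: dict[str, float]  # fundus-embedding input
    decay: dict[str, float]  # (source - swapped) / source, where source > 0

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "source_metrics": self.source_metrics,
            "swapped_metrics": self.swapped_metrics,
            "decay": self.decay,
        }


class ProbeHead(Module):
    """Single affine prediction layer plus the task's label encoding.

    Optionally standardizes its input features (and, for regression, the
    training targets) with statistics frozen from the training split; the
    scaling is a fixed affine input layer, so the head remains a single
    trainable fully connected layer.
    """

    def __init__(self, in_dim: int, task: ProbeTask, classes=None, seed: int = 0):
        self.task = task
        self.classes = None if classes is None else list(classes)
        out_dim = len(self.classes) if task.task_type == "multiclass" else 1
        rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
        self.lin = Linear(in_dim, out_dim, rng)
        self.x_mean = np.zeros(in_dim)
        self.x_sd = np.ones(in_dim)
        self.y_mean = 0.0
        self.y_sd = 1.0

    def set_scalers(self, X_train, y_train=None) -> None:
        X_train = np.asarray(X_train, dtype=float)
        self.x_mean = X_train.mean(axis=0)
        self.x_sd = np.maximum(X_train.std(axis=0), 1e-8)
        if y_train is not None and self.task.task_type == "regression":
            y = np.asarray(y_train, dtype=float)
            self.y_mean = float(y.mean())
            self.y_sd = float(max(y.std(), 1e-8))

    def standardize_target(self, y) -> np.ndarray:
        if self.task.task_type != "regression":
            return self.encode_labels(y)
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_sd

    def forward(self, E) -> Tensor:
        E = E if isinstance(E, Tensor) else Tensor(E)
        if E.shape[-1] != self.lin.in_dim:
            raise ValueError(f"head expects embedding dim {self.lin.in_dim}, got {E.shape[-1]}")
        E = (E - Tensor(self.x_mean)) * Tensor(1.0 / self.x_sd)
        return self.lin(E)

    def encode_labels(self, y) -> np.ndarray:
        y = np.asarray(y)
        if self.task.task_type == "multiclass":
            lut = {c: i for i, c in enumerate(self.classes)}
            return np.array([lut[v] for v in y], dtype=int)
        if self.task.task_type == "binary":
            return y.astype(float)
        return y.astype(float)

    def predict(self, E) -> np.ndarray:
        """Regression values, positive-class probabilities, or class-probability rows."""
        with no_grad():
            logits = self.forward(np.asarray(E, dtype=float)).data
        if self.task.task_type == "regression":
            return logits.ravel() * self.y_sd + self.y_mean
        if self.task.task_type == "binary":
            return 1.0 / (1.0 + np.exp(-logits.ravel()))
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=1, keepdims=True)


# ------------------------------------------------------------------- losses
def _task_loss(logits: Tensor, y: np.ndarray, task_type: str) -> Tensor:
    if task_type == "regression":
        return ((logits.reshape(logits.shape[0]) - Tensor(y)) ** 2.0).mean()
    if task_type == "binary":
        x = logits.reshape(logits.shape[0])
        # stable softplus(x) - y*x  ==  relu(x) + log(1 + exp(-|x|)) - y*x
        absx = x.relu() + (-x).relu()
        softplus = x.relu() + (1.0 + (-absx).exp()).log()
        return (softplus - Tensor(y) * x).mean()
    n = logits.shape[0]
    lse = logsumexp(logits, axis=1)
    picked = logits[np.arange(n), y.astype(int)]
    return (lse - picked).mean()


# ------------------------------------------------------------------ metrics
def weighted_one_vs_rest(per_class_values, supports) -> float:
    """Class-support-weighted mean of per-class one-vs-rest scores."""
    values = np.asarray(per_class_values, dtype=float)
    supports = np.asarray(supports, dtype=float)
    if values.shape != supports.shape:
        raise ValueError("values and supports must align")
    if supports.sum() <= 0:
        raise ValueError("supports must sum to a positive number")
    return float(np.sum(values * supports) / supports.sum())


def compute_metrics(predictions, labels, task_type: str) -> dict[str, float]:
    """Task-appropriate metric set.

    regression -> {r2, rmse}; binary/multiclass -> {auroc, ap} with
    support-weighted one-vs-rest scores in the multi-class case.
    """
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels)
    if predictions.shape[0] != labels.shape[0]:
        raise ValueError("predictions and labels must align")
    if task_type == "regression":
        y = labels.astype(float)
        ss_res = float(np.sum((y - predictions) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
        rmse = float(np.sqrt(np.mean((y - predictions) ** 2)))
        return {"r2": r2, "rmse": rmse}
    if task_type == "binary":
        y = labels.astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("AUROC undefined: test labels contain a single class")
        return {
            "auroc": float(roc_auc_score(y, predictions)),
            "ap": float(average_precision_score(y, predictions)),
        }
    if task_type == "multiclass":
        if predictions.ndim != 2:
            raise ValueError("multiclass predictions must be (n, n_classes) probabilities")
        classes = np.arange(predictions.shape[1])
        present = [c for c in classes if np.any(labels == c)]
        if len(present) < 2:
            raise ValueError("AUROC undefined: test labels contain a single class")
        aurocs, aps, supports = [], [], []
        for c in present:
            mask = (labels == c).astype(int)
            if len(np.unique(mask)) < 2:
                continue
            aurocs.append(roc_auc_score(mask, predictions[:, c]))
            aps.append(average_precision_score(mask, predictions[:, c]))
            supports.append(mask.sum())
        return {
            "auroc": weighted_one_vs_rest(aurocs, supports),
            "ap": weighted_one_vs_rest(aps, supports),
        }
    raise ValueError(f"unknown task_type {task_type!r}")


def bootstrap_eval(predictions, labels, metric, B: int = 1000, seed: int = 0):
    """Bootstrap mean and SD of a metric over test-set resamples.

    ``metric`` is a callable ``(predictions, labels) -> float``.  Resamples
    on which the metric is undefined (e.g. a single-class draw for AUROC)
    are skipped.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    n = labels.shape[0]
    if n == 0:
        raise ValueError("empty input")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    values = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(metric(predictions[idx], labels[idx]))
        except ValueError:
            continue
    if not values:
        raise ValueError("metric undefined on every bootstrap resample")
    values = np.asarray(values, dtype=float)
    return float(values.mean()), float(values.std())


# ----------------------------------------------------------------- training
def _forward_features(encoder, X, cache):
    if encoder is None:
        return Tensor(X) if cache is None else cache
    return encoder(Tensor(X))


def _fit_head(
    head: ProbeHead,
    data: dict,
    lr: float,
    config: ProbeConfig,
    encoder: Module | None = None,
    encoder_lr: float = 0.0,
) -> float:
    """Train the head (optionally with the encoder) and return best val loss.

    Restores the best-validation-epoch weights before returning.
    """
    task_type = head.task.task_type
    y_tr = head.standardize_target(data["y_train"])
    y_va = head.standardize_target(data["y_val"])
    X_tr, X_va = data["X_train"], data["X_val"]
    n = X_tr.shape[0]
    head_params = head.parameters()
    opt = AdamW(head_params, lr=lr, weight_decay=config.weight_decay)
    enc_opt = None
    if encoder is not None:
        enc_opt = AdamW(encoder.parameters(), lr=encoder_lr, weight_decay=config.weight_decay)
    plateau = ReduceLROnPlateau(opt, factor=config.plateau_factor, patience=config.plateau_patience)
    stopper = EarlyStopper(patience=config.patience)
    best_val = np.inf
    best_state = {k: v.copy() for k, v in head.state_dict().items()}
    best_enc_state = None if encoder is None else {k: v.copy() for k, v in encoder.state_dict().items()}
    for epoch in range(config.max_epochs):
        order = np.random.default_rng(
            np.random.SeedSequence([config.seed, 41, epoch])
        ).permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            feats = _forward_features(encoder, X_tr[sel], None)
            loss = _task_loss(head(feats), y_tr[sel], task_type)
            opt.zero_grad()
            if enc_opt is not None:
                enc_opt.zero_grad()
            loss.backward()
            opt.step()
            if enc_opt is not None:
                enc_opt.step()
        with no_grad():
            val_feats = _forward_features(encoder, X_va, None)
            val_loss = float(_task_loss(head(val_feats), y_va, task_type).data)
        if val_loss < best_val:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in head.state_dict().items()}
            if encoder is not None:
                best_enc_state = {k: v.copy() for k, v in encoder.state_dict().items()}
        plateau.step(val_loss)
        if stopper.update(val_loss):
            break
    head.load_state_dict(best_state)
    if encoder is not None and best_enc_state is not None:
        encoder.load_state_dict(best_enc_state)
    return best_val


def _select_classes(task: ProbeTask, y_train) -> list | None:
    if task.task_type != "multiclass":
        return None
    return sorted(set(np.asarray(y_train).tolist()))


def _report(head: ProbeHead, X_test, y_test, mode: str, lr: float, config: ProbeConfig,
            encoder: Module | None = None) -> ProbeReport:
    task = head.task
    if encoder is not None:
        with no_grad():
            X_test = encoder(Tensor(np.asarray(X_test, dtype=float))).data
    preds = head.predict(X_test)
    y_enc = head.encode_labels(y_test)
    metrics = compute_metrics(preds, y_enc, task.task_type)
    boot = {
        name: bootstrap_eval(
            preds, y_enc, lambda p, y, t=task.task_type, n=name: compute_metrics(p, y, t)[n],
            B=config.bootstrap_B, seed=config.seed,
        )
        for name in metrics
    }
    return ProbeReport(
        task=task.name, mode=mode, metrics=metrics, bootstrap=boot,
        n_test=len(y_enc), lr=lr,
    )


def linear_probe(
    E_train, y_train, E_val, y_val, E_test, y_test,
    task: ProbeTask,
    config: ProbeConfig | None = None,
) -> tuple[ProbeHead, ProbeReport]:
    """Train a single affine head on frozen-encoder embeddings."""
    config = config or ProbeConfig()
    E_train = np.asarray(E_train, dtype=float)
    if E_train.shape[0] != len(np.asarray(y_train)):
        raise ValueError("embedding/label length mismatch")
    classes = _select_classes(task, y_train)
    data = {"X_train": E_train, "y_train": y_train,
            "X_val": np.asarray(E_val, dtype=float), "y_val": y_val}
    best = None
    for lr in config.lr_grid:
        head = ProbeHead(E_train.shape[1], task, classes=classes, seed=config.seed)
        if config.standardize:
            head.set_scalers(E_train, y_train)
        val = _fit_head(head, data, lr, config)
        if best is None or val < best[1]:
            best = (head, val, lr)
    head, _, lr = best
    return head, _report(head, E_test, y_test, "linear_probe", lr, config)


def fine_tune(
    encoder: Module,
    X_train, y_train, X_val, y_val, X_test, y_test,
    task: ProbeTask,
    config: ProbeConfig | None = None,
    encoder_lr: float | None = None,
) -> tuple[ProbeHead, ProbeReport]:
    """Same protocol as linear probing with the encoder unfrozen.

    ``encoder_lr`` defaults to the head learning rate; with ``encoder_lr=0``
    this reduces exactly to a linear probe on the encoder's embeddings.
    """
    config = config or ProbeConfig()
    X_train = np.asarray(X_train, dtype=float)
    if X_train.shape[0] != len(np.asarray(y_train)):
        raise ValueError("input/label length mismatch")
    classes = _select_classes(task, y_train)
    data = {"X_train": X_train, "y_train": y_train,
            "X_val": np.asarray(X_val, dtype=float), "y_val": y_val}
    embed_dim = encoder.config.embed_dim
    init_state = encoder.state_dict()
    best = None
    for lr in config.lr_grid:
        encoder.load_state_dict(init_state)
        head = ProbeHead(embed_dim, task, classes=classes, seed=config.seed)
        if config.standardize:
            with no_grad():
                F0 = encoder(Tensor(X_train)).data
            head.set_scalers(F0, y_train)
        e_lr = lr if encoder_lr is None else encoder_lr
        val = _fit_head(head, data, lr, config, encoder=encoder, encoder_lr=e_lr)
        state = encoder.state_dict()
        if best is None or val < best[1]:
            best = (head, val, lr, state)
    head, _, lr, state = best
    encoder.load_state_dict(state)
    return head, _report(head, X_test, y_test, "fine_tune", lr, config, encoder=encoder)


def interchange_eval(
    head: ProbeHead,
    fundus_embeddings,
    labels,
    source_metrics: dict[str, float],
) -> InterchangeReport:
    """Feed fundus embeddings into an OCT-trained linear-probe head.

    ``source_metrics`` are the head's metrics on its own (OCT) embeddings;
    relative decay is reported per metric with a positive source value.
    """
    E = np.asarray(
        fundus_embeddings.values if hasattr(fundus_embeddings, "values") else fundus_embeddings,
        dtype=float,
    )
    if E.shape[1] != head.lin.in_dim:
        raise ValueError(f"embedding dim {E.shape[1]} does not match head dim {head.lin.in_dim}")
    preds = head.predict(E)
    y_enc = head.encode_labels(labels)
    swapped = compute_metrics(preds, y_enc, head.task.task_type)
    decay = {
        k: (source_metrics[k] - swapped[k]) / source_metrics[k]
        for k in swapped
        if k in source_metrics and source_metrics[k] > 0
    }
    return InterchangeReport(
        task=head.task.name,
        source_metrics=dict(source_metrics),
        swapped_metrics=swapped,
        decay=decay,
    )
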