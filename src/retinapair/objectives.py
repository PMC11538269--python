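"""Pre-training objectives: InfoNCE (CLIP), Hopfield-retrieved InfoLOOB
(CLOOB), NT-Xent (SimCLR), BYOL and VICReg.

All losses accept numpy arrays or autodiff :class:`~retinapair._autodiff.Tensor`
inputs and return a scalar Tensor, so the same code path serves evaluation and
gradient training.  Temperatures may be floats or (for learnable-temperature
training) Tensors.

Conventions frozen here:

* embeddings are l2-normalized before every contrastive similarity;
* InfoNCE is the symmetric mean of row-wise and column-wise cross-entropies
  of ``softmax(S / tau)`` against the diagonal;
* InfoLOOB excludes the positive from its denominator (leave-one-out), so the
  loss can go below zero;
* the CLOOB loss retrieves both modalities' embeddings from each modality's
  Hopfield memory before applying InfoLOOB, and sums the two directions;
* VICReg uses coefficients (25, 25, 1) and a 1e-4 variance epsilon.
"""

from __future__ import annotations

import math

import numpy as np

from ._autodiff import Tensor, as_tensor, clip_max, concatenate, l2_normalize, logsumexp
from .nn import Module, Parameter

__all__ = [
    "TemperatureParam",
    "similarity_matrix",
    "info_nce",
    "hopfield_retrieve",
    "info_loob",
    "cloob_loss",
    "nt_xent",
    "byol_loss",
    "vicreg_loss",
]


class TemperatureParam(Module):
    """Learnable softmax temperature, stored as log inverse temperature.

    Initialized at ``log(1/0.07)`` with the inverse temperature clamped to at
    most 100 during the forward pass (OpenCLIP convention).
    """

    def __init__(self, init_tau: float = 0.07, learnable: bool = True, max_inv: float = 100.0):
        if init_tau <= 0:
            raise ValueError("initial temperature must be positive")
        self.learnable = learnable
        self.max_inv = max_inv
        self.log_inv_tau = Parameter(np.array(math.log(1.0 / init_tau)))
        if not learnable:
            self.log_inv_tau.requires_grad = False

    def inv_tau(self) -> Tensor:
        """Clamped inverse temperature (differentiable when learnable)."""
        return clip_max(self.log_inv_tau.exp(), self.max_inv)

    @property
    def tau(self) -> float:
        return 1.0 / float(self.inv_tau().data)


def _check_paired(a: Tensor, b: Tensor) -> None:
    if a.shape != b.shape:
        raise ValueError(f"embedding shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("embeddings must be 2-D (n, d)")


def _inv_tau(tau) -> Tensor | float:
    if isinstance(tau, Tensor):
        return tau ** -1.0
    tau = float(tau)
    if tau <= 0:
        raise ValueError("temperature must be positive")
    return 1.0 / tau


def similarity_matrix(U, V) -> Tensor:
    """Pairwise inner products ``S[i, j] = u_i . v_j`` (cosines on unit rows)."""
    U, V = as_tensor(U), as_tensor(V)
    _check_paired(U, V)
    return U @ V.T


def _diag(S: Tensor) -> Tensor:
    n = S.shape[0]
    idx = np.arange(n)
    return S[idx, idx]


def info_nce(S, tau=1.0) -> Tensor:
    """Symmetric InfoNCE on a similarity matrix whose diagonal holds positives."""
    S = as_tensor(S)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    logits = S * _inv_tau(tau)
    pos = _diag(logits)
    row = (logsumexp(logits, axis=1) - pos).mean()
    col = (logsumexp(logits, axis=0) - pos).mean()
    return (row + col) * 0.5


def _softmax(t: Tensor, axis: int) -> Tensor:
    return (t - logsumexp(t, axis=axis, keepdims=True)).exp()


def hopfield_retrieve(stored, queries, beta: float) -> Tensor:
    """Modern-Hopfield retrieval: softmax(beta . stored @ q) combination of
    stored patterns, re-normalized to the unit sphere."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    stored, queries = as_tensor(stored), as_tensor(queries)
    if stored.shape[-1] != queries.shape[-1]:
        raise ValueError("stored and query dimensionality differ")
    attn = _softmax((queries @ stored.T) * float(beta), axis=1)
    return l2_normalize(attn @ stored, axis=-1)


def info_loob(A, B, tau=1.0) -> Tensor:
    """Leave-one-out InfoNCE bound; the positive is excluded from the
    denominator, so the loss has no ``log n`` floor and may be negative."""
    A, B = as_tensor(A), as_tensor(B)
    _check_paired(A, B)
    n = A.shape[0]
    if n < 2:
        raise ValueError("InfoLOOB needs at least 2 pairs (no negatives otherwise)")
    logits = (A @ B.T) * _inv_tau(tau)
    mask = np.zeros((n, n))
    np.fill_diagonal(mask, -np.inf)
    masked = logits + Tensor(mask)
    pos = _diag(logits)
    row = (logsumexp(masked, axis=1) - pos).mean()
    col = (logsumexp(masked, axis=0) - pos).mean()
    return (row + col) * 0.5


def cloob_loss(U, V, tau=1.0, beta: float = 8.0) -> Tensor:
    """CLOOB objective: InfoLOOB on Hopfield-retrieved embeddings, with each
    modality serving once as the memory, summed over the two directions."""
    U, V = as_tensor(U), as_tensor(V)
    _check_paired(U, V)
    if U.shape[0] < 2:
        raise ValueError("CLOOB needs at least 2 pairs")
    loss_u = info_loob(hopfield_retrieve(U, U, beta), hopfield_retrieve(U, V, beta), tau)
    loss_v = info_loob(hopfield_retrieve(V, U, beta), hopfield_retrieve(V, V, beta), tau)
    return loss_u + loss_v


def nt_xent(Z1, Z2, tau=1.0) -> Tensor:
    """SimCLR's normalized-temperature cross-entropy over 2n anchors."""
    Z1, Z2 = as_tensor(Z1), as_tensor(Z2)
    _check_paired(Z1, Z2)
    n = Z1.shape[0]
    if n < 2:
        raise ValueError("NT-Xent needs at least 2 samples per view")
    Z = l2_normalize(concatenate([Z1, Z2], axis=0), axis=-1)
    logits = (Z @ Z.T) * _inv_tau(tau)
    mask = np.zeros((2 * n, 2 * n))
    np.fill_diagonal(mask, -np.inf)
    masked = logits + Tensor(mask)
    idx = np.arange(2 * n)
    partner = (idx + n) % (2 * n)
    pos = logits[idx, partner]
    return (logsumexp(masked, axis=1) - pos).mean()


def byol_loss(pred, target) -> Tensor:
    """Mean of ``2 - 2 cos(pred_i, target_i)``; the target branch is detached."""
    pred, target = as_tensor(pred), as_tensor(target)
    _check_paired(pred, target)
    norms_p = np.linalg.norm(pred.data, axis=1)
    norms_t = np.linalg.norm(target.data, axis=1)
    if np.any(norms_p == 0) or np.any(norms_t == 0):
        raise ValueError("byol_loss requires nonzero-norm rows")
    p = l2_normalize(pred, axis=-1)
    t = l2_normalize(target.detach(), axis=-1)
    cos = (p * t).sum(axis=1)
    return (2.0 - 2.0 * cos).mean()


def vicreg_loss(
    Z1,
    Z2,
    lambda_inv: float = 25.0,
    mu_var: float = 25.0,
    nu_cov: float = 1.0,
    var_eps: float = 1e-4,
) -> Tensor:
    """Variance-Invariance-Covariance regularization loss.

    invariance: mean squared difference between the two batches;
    variance: hinge at std 1 per dimension, averaged over dimensions, summed
    over the two batches; covariance: squared off-diagonal covariance entries
    divided by the dimensionality, summed over the two batches.
    """
    Z1, Z2 = as_tensor(Z1), as_tensor(Z2)
    _check_paired(Z1, Z2)
    n, p = Z1.shape
    if n < 2:
        raise ValueError("VICReg needs at least 2 samples")
    inv = ((Z1 - Z2) ** 2.0).mean()

    def var_term(Z: Tensor) -> Tensor:
        var = ((Z - Z.mean(axis=0, keepdims=True)) ** 2.0).mean(axis=0)
        std = (var + var_eps).sqrt()
        return (1.0 - std).relu().mean()

    def cov_term(Z: Tensor) -> Tensor:
        Zc = Z - Z.mean(axis=0, keepdims=True)
        C = (Zc.T @ Zc) * (1.0 / (n - 1))
        off = (C ** 2.0).sum() - (_diag(C) ** 2.0).sum()
        return off * (1.0 / p)

    return (
        lambda_inv * inv
        + mu_var * (var_term(Z1) + var_term(Z2))
        + nu_cov * (cov_term(Z1) + cov_term(Z2))
    )
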