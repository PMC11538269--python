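"""Contrastive-objective oracles: hand-derived closed forms, brute-force
double-loop equivalence, and finite-difference gradient checks."""

import numpy as np
import pytest

from retinapair import objectives as obj
from retinapair._autodiff import Tensor


def unit_rows(a):
    a = np.asarray(a, dtype=float)
    return a / np.linalg.norm(a, axis=1, keepdims=True)


# ------------------------------------------------------------ similarity
def test_similarity_hand_case():
    U = np.array([[1.0, 0.0], [0.0, 1.0]])
    V = np.array([[1.0, 0.0], [np.sqrt(0.5), np.sqrt(0.5)]])
    S = obj.similarity_matrix(U, V).data
    assert np.allclose(S, [[1.0, np.sqrt(0.5)], [0.0, np.sqrt(0.5)]])


def test_similarity_identity_and_range(rng):
    U = unit_rows(rng.normal(size=(6, 4)))
    S = obj.similarity_matrix(U, U).data
    assert np.allclose(np.diag(S), 1.0)
    assert np.all(np.abs(S) <= 1.0 + 1e-12)


def test_similarity_dim_mismatch():
    with pytest.raises(ValueError):
        obj.similarity_matrix(np.eye(2), np.eye(3))


# ---------------------------------------------------------------- InfoNCE
def test_info_nce_identity_closed_form():
    loss = float(obj.info_nce(np.eye(2), 1.0).data)
    assert loss == pytest.approx(np.log(1 + np.exp(-1)), abs=1e-12)


def test_info_nce_nonnegative_and_uniform_limit(rng):
    S = rng.normal(size=(5, 5))
    assert float(obj.info_nce(S, 0.5).data) >= 0
    # random unit embeddings at large d: softmax near uniform -> loss ~ log N
    U = unit_rows(rng.normal(size=(64, 2048)))
    V = unit_rows(rng.normal(size=(64, 2048)))
    loss = float(obj.info_nce(U @ V.T, 1.0).data)
    assert loss == pytest.approx(np.log(64), rel=0.05)


def test_info_nce_rejects_bad_tau():
    with pytest.raises(ValueError):
        obj.info_nce(np.eye(2), 0.0)


# ---------------------------------------------------------------- Hopfield
def test_hopfield_beta_zero_returns_normalized_mean(rng):
    stored = unit_rows(rng.normal(size=(5, 4)))
    out = obj.hopfield_retrieve(stored, stored[:3], 0.0).data
    mean = stored.mean(axis=0)
    mean /= np.linalg.norm(mean)
    assert np.allclose(out, mean)


def test_hopfield_large_beta_returns_nearest_pattern():
    stored = np.eye(4)
    queries = unit_rows(np.eye(4)[:2] + 0.05)
    out = obj.hopfield_retrieve(stored, queries, 1e4).data
    assert np.allclose(out, np.eye(4)[:2], atol=1e-3)


def test_hopfield_output_unit_norm(rng):
    stored = unit_rows(rng.normal(size=(6, 8)))
    queries = unit_rows(rng.normal(size=(3, 8)))
    out = obj.hopfield_retrieve(stored, queries, 8.0).data
    assert np.allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-6)


def test_hopfield_rejects_negative_beta(rng):
    s = unit_rows(rng.normal(size=(3, 2)))
    with pytest.raises(ValueError):
        obj.hopfield_retrieve(s, s, -1.0)


# ---------------------------------------------------------------- InfoLOOB
def test_info_loob_aligned_orthonormal_equals_minus_one():
    A = np.eye(2)
    assert float(obj.info_loob(A, A, 1.0).data) == pytest.approx(-1.0, abs=1e-12)


def test_info_loob_matches_double_loop(rng):
    A = unit_rows(rng.normal(size=(4, 4)))
    B = unit_rows(rng.normal(size=(4, 4)))
    tau = 0.5
    n = 4
    rows = cols = 0.0
    for i in range(n):
        den_r = sum(np.exp(A[i] @ B[j] / tau) for j in range(n) if j != i)
        rows += -np.log(np.exp(A[i] @ B[i] / tau) / den_r)
        den_c = sum(np.exp(A[j] @ B[i] / tau) for j in range(n) if j != i)
        cols += -np.log(np.exp(A[i] @ B[i] / tau) / den_c)
    expected = 0.5 * (rows / n + cols / n)
    assert float(obj.info_loob(A, B, tau).data) == pytest.approx(expected, abs=1e-10)


def test_info_loob_can_go_below_zero_unlike_info_nce():
    # strongly aligned pairs with orthogonal negatives
    A = np.eye(6)
    loob = float(obj.info_loob(A, A, 0.1).data)
    nce = float(obj.info_nce(A @ A.T, 0.1).data)
    assert loob < 0 < nce


def test_info_loob_needs_two_pairs():
    with pytest.raises(ValueError):
        obj.info_loob(np.ones((1, 3)), np.ones((1, 3)), 1.0)


# ------------------------------------------------------------------- CLOOB
def test_cloob_equals_explicit_composition(rng):
    U = unit_rows(rng.normal(size=(5, 6)))
    V = unit_rows(rng.normal(size=(5, 6)))
    tau, beta = 0.3, 8.0
    expected = float(
        (
            obj.info_loob(
                obj.hopfield_retrieve(U, U, beta), obj.hopfield_retrieve(U, V, beta), tau
            )
            + obj.info_loob(
                obj.hopfield_retrieve(V, U, beta), obj.hopfield_retrieve(V, V, beta), tau
            )
        ).data
    )
    assert float(obj.cloob_loss(U, V, tau, beta).data) == pytest.approx(expected, abs=1e-10)


def test_cloob_finite_when_modalities_identical(rng):
    U = unit_rows(rng.normal(size=(4, 5)))
    assert np.isfinite(float(obj.cloob_loss(U, U, 0.5, 8.0).data))


def test_cloob_decreases_on_toy_training(rng):
    """Gradient descent on aligned latent data lowers the CLOOB loss."""
    from retinapair.nn import Linear
    from retinapair.optim import AdamW
    from retinapair._autodiff import l2_normalize

    Z = rng.normal(size=(32, 8))
    X = Z @ rng.normal(size=(8, 8))
    Y = Z @ rng.normal(size=(8, 8))
    fx = Linear(8, 6, np.random.default_rng(1))
    fy = Linear(8, 6, np.random.default_rng(2))
    opt = AdamW(fx.parameters() + fy.parameters(), lr=3e-3, weight_decay=0.0)
    losses = []
    for _ in range(30):
        U = l2_normalize(fx(Tensor(X)), axis=-1)
        V = l2_normalize(fy(Tensor(Y)), axis=-1)
        loss = obj.cloob_loss(U, V, 1 / 30, 8.0)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    assert losses[-1] < losses[0]


# ----------------------------------------------------------------- NT-Xent
def test_nt_xent_matches_brute_force(rng):
    Z1 = rng.normal(size=(4, 6))
    Z2 = rng.normal(size=(4, 6))
    tau = 0.7
    Z = unit_rows(np.concatenate([Z1, Z2], axis=0))
    n2 = 8
    total = 0.0
    for i in range(n2):
        partner = (i + 4) % n2
        den = sum(np.exp(Z[i] @ Z[j] / tau) for j in range(n2) if j != i)
        total += -np.log(np.exp(Z[i] @ Z[partner] / tau) / den)
    assert float(obj.nt_xent(Z1, Z2, tau).data) == pytest.approx(total / n2, abs=1e-10)


def test_nt_xent_closed_form_two_aligned_pairs():
    Z = np.eye(2)
    expected = np.log(1 + 2 * np.exp(-1))
    assert float(obj.nt_xent(Z, Z, 1.0).data) == pytest.approx(expected, abs=1e-12)


def test_nt_xent_nonnegative_and_min_batch(rng):
    assert float(obj.nt_xent(rng.normal(size=(3, 4)), rng.normal(size=(3, 4)), 1.0).data) >= 0
    with pytest.raises(ValueError):
        obj.nt_xent(np.ones((1, 3)), np.ones((1, 3)), 1.0)


# -------------------------------------------------------------------- BYOL
@pytest.mark.parametrize(
    "pred,target,expected",
    [
        (np.eye(3), np.eye(3), 0.0),
        (np.eye(3), -np.eye(3), 4.0),
        (np.eye(2), np.eye(2)[::-1], 2.0),
    ],
)
def test_byol_closed_forms(pred, target, expected):
    assert float(obj.byol_loss(pred, target).data) == pytest.approx(expected, abs=1e-10)


def test_byol_rejects_zero_rows():
    with pytest.raises(ValueError):
        obj.byol_loss(np.zeros((2, 3)), np.eye(2, 3))


def test_byol_target_detached(rng):
    t = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
    p = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
    obj.byol_loss(p, t).backward()
    assert p.grad is not None and t.grad is None


# ------------------------------------------------------------------ VICReg
def test_vicreg_zero_at_ideal_batch():
    # per-dimension std exactly 1 after the eps shift -> no hinge; orthogonal
    # dimensions -> zero covariance; identical views -> zero invariance
    scale = np.sqrt(1 - 1e-4)
    Z = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]]) * scale
    loss = float(obj.vicreg_loss(Z, Z).data)
    assert loss == pytest.approx(0.0, abs=1e-9)


def test_vicreg_constant_batch_variance_hinge():
    Z = np.ones((4, 3)) * 2.5
    # variance 0 -> std = sqrt(eps) = 0.01 -> hinge 0.99 per dim per batch
    expected = 25.0 * 2 * (1 - 0.01)
    assert float(obj.vicreg_loss(Z, Z).data) == pytest.approx(expected, abs=1e-9)


def test_vicreg_invariance_matches_double_loop(rng):
    Z1 = rng.normal(size=(5, 3))
    Z2 = rng.normal(size=(5, 3))
    inv = float(obj.vicreg_loss(Z1, Z2, lambda_inv=1.0, mu_var=0.0, nu_cov=0.0).data)
    acc = 0.0
    for i in range(5):
        for j in range(3):
            acc += (Z1[i, j] - Z2[i, j]) ** 2
    assert inv == pytest.approx(acc / 15, abs=1e-10)


# ------------------------------------------------- shared loss properties
LOSSES = {
    "info_nce": lambda A, B: obj.info_nce(obj.similarity_matrix(A, B), 0.5),
    "info_loob": lambda A, B: obj.info_loob(A, B, 0.5),
    "cloob": lambda A, B: obj.cloob_loss(A, B, 0.5, 8.0),
    "nt_xent": lambda A, B: obj.nt_xent(A, B, 0.5),
    "vicreg": lambda A, B: obj.vicreg_loss(A, B),
}


@pytest.mark.parametrize("name", list(LOSSES))
def test_losses_invariant_to_joint_permutation(name, rng):
    A = unit_rows(rng.normal(size=(6, 8)))
    B = unit_rows(rng.normal(size=(6, 8)))
    perm = rng.permutation(6)
    f = LOSSES[name]
    assert float(f(A, B).data) == pytest.approx(float(f(A[perm], B[perm]).data), abs=1e-10)


@pytest.mark.parametrize("name", list(LOSSES))
def test_loss_gradients_match_finite_differences(name, rng):
    A = unit_rows(rng.normal(size=(4, 8)))
    B = unit_rows(rng.normal(size=(4, 8)))
    f = LOSSES[name]
    tA = Tensor(A, requires_grad=True)
    f(tA, Tensor(B)).backward()
    eps = 1e-6
    for idx in [(0, 0), (1, 3), (3, 7)]:
        Ap, Am = A.copy(), A.copy()
        Ap[idx] += eps
        Am[idx] -= eps
        fd = (float(f(Tensor(Ap), Tensor(B)).data) - float(f(Tensor(Am), Tensor(B)).data)) / (2 * eps)
        denom = max(1.0, abs(fd))
        assert abs(tA.grad[idx] - fd) / denom < 1e-4


# -------------------------------------------------------------- temperature
def test_temperature_clamp_and_learnability():
    t = obj.TemperatureParam(0.07)
    assert t.tau == pytest.approx(0.07, rel=1e-6)
    t.log_inv_tau.data = np.array(10.0)  # exp(10) >> clamp
    assert float(t.inv_tau().data) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        obj.TemperatureParam(-1.0)
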