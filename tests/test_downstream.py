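"""Downstream adaptation: metric definitions, bootstrap resampling, the
probe/fine-tune training protocol and the modality-interchange evaluation."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from retinapair import downstream as ds
from retinapair.encoders import EncoderConfig, make_encoder
from retinapair.optim import AdamW, EarlyStopper, ReduceLROnPlateau
from retinapair.nn import Parameter

REG = ds.ProbeTask("reg", "regression", "y")
BIN = ds.ProbeTask("bin", "binary", "y")
MULTI = ds.ProbeTask("multi", "multiclass", "y")


# ----------------------------------------------------------------- metrics
def test_perfect_regression_metrics(rng):
    y = rng.normal(size=50)
    m = ds.compute_metrics(y, y, "regression")
    assert m["r2"] == pytest.approx(1.0) and m["rmse"] == pytest.approx(0.0)


def test_mean_predictor_r2_is_zero(rng):
    y = rng.normal(size=80)
    m = ds.compute_metrics(np.full_like(y, y.mean()), y, "regression")
    assert m["r2"] == pytest.approx(0.0, abs=1e-12)


def test_r2_can_go_negative(rng):
    y = rng.normal(size=40)
    m = ds.compute_metrics(-5 * y + 3, y, "regression")
    assert m["r2"] < 0


def test_weighted_one_vs_rest_hand_case():
    assert ds.weighted_one_vs_rest([1.0, 0.5, 0.75], [2, 1, 1]) == pytest.approx(0.8125)
    with pytest.raises(ValueError):
        ds.weighted_one_vs_rest([1.0], [1, 2])


def test_multiclass_matches_sklearn_weighted(rng):
    y = rng.integers(0, 3, size=60)
    P = rng.random((60, 3))
    P /= P.sum(axis=1, keepdims=True)
    m = ds.compute_metrics(P, y, "multiclass")
    expected = roc_auc_score(y, P, multi_class="ovr", average="weighted")
    assert m["auroc"] == pytest.approx(expected, abs=1e-12)


def test_binary_metrics_and_single_class_error(rng):
    y = np.array([0, 0, 1, 1])
    p = np.array([0.1, 0.4, 0.35, 0.8])
    m = ds.compute_metrics(p, y, "binary")
    assert m["auroc"] == pytest.approx(roc_auc_score(y, p))
    with pytest.raises(ValueError, match="single class"):
        ds.compute_metrics(p, np.zeros(4), "binary")


# --------------------------------------------------------------- bootstrap
def test_bootstrap_deterministic_and_consistent(rng):
    y = rng.integers(0, 2, size=120)
    p = np.clip(y * 0.6 + rng.normal(0, 0.3, size=120), 0, 1)
    metric = lambda pred, lab: ds.compute_metrics(pred, lab, "binary")["auroc"]
    a = ds.bootstrap_eval(p, y, metric, B=200, seed=1)
    b = ds.bootstrap_eval(p, y, metric, B=200, seed=1)
    assert a == b
    mean, sd = ds.bootstrap_eval(p, y, metric, B=1000, seed=2)
    point = metric(p, y)
    assert abs(mean - point) <= 2 * max(sd, 1e-3)


def test_bootstrap_perfect_predictions_zero_sd(rng):
    y = np.array([0, 1] * 20)
    metric = lambda pred, lab: ds.compute_metrics(pred, lab, "binary")["auroc"]
    mean, sd = ds.bootstrap_eval(y.astype(float), y, metric, B=100, seed=0)
    assert mean == pytest.approx(1.0) and sd == pytest.approx(0.0)


def test_bootstrap_rejects_empty():
    with pytest.raises(ValueError):
        ds.bootstrap_eval(np.array([]), np.array([]), lambda p, y: 0.0)


# ----------------------------------------------------- training protocol
def test_early_stopper_halts_within_patience_of_minimum():
    losses = [1.0, 0.8, 0.6, 0.55, 0.56, 0.57, 0.58, 0.59, 0.60, 0.4]
    stopper = EarlyStopper(patience=5)
    stopped_at = None
    for i, loss in enumerate(losses):
        if stopper.update(loss):
            stopped_at = i
            break
    assert stopped_at == 8  # five epochs after the minimum at index 3
    assert stopper.best == pytest.approx(0.55)


def test_plateau_scheduler_halves_lr():
    opt = AdamW([Parameter(np.zeros(2))], lr=1e-3)
    sched = ReduceLROnPlateau(opt, factor=0.5, patience=1)
    for loss in [1.0, 0.9, 0.9, 0.9]:
        sched.step(loss)
    assert opt.lr == pytest.approx(5e-4)


def _probe_data(rng, n=300, d=8, kind="linear"):
    E = rng.normal(size=(n, d))
    w = rng.normal(size=d)
    if kind == "linear":
        y = E @ w + 1e-3 * rng.normal(size=n)
    elif kind == "separable":
        score = E @ w
        keep = np.abs(score) > 0.5  # margin around the separating hyperplane
        E, score = E[keep], score[keep]
        y = (score > 0).astype(int)
        n = len(y)
        tr, va, te = slice(0, int(0.6 * n)), slice(int(0.6 * n), int(0.8 * n)), slice(int(0.8 * n), n)
        return (E[tr], y[tr], E[va], y[va], E[te], y[te])
    else:
        y = rng.integers(0, 2, size=n)
    tr, va = slice(0, 200), slice(200, 250)
    te = slice(250, n)
    return (E[tr], y[tr], E[va], y[va], E[te], y[te])


def test_probe_recovers_noiseless_linear_target(rng):
    parts = _probe_data(rng, kind="linear")
    _, rep = ds.linear_probe(*parts, REG, ds.ProbeConfig(bootstrap_B=50))
    assert rep.metrics["r2"] >= 0.99


def test_probe_no_signal_auroc_near_half(rng):
    parts = _probe_data(rng, kind="noise")
    _, rep = ds.linear_probe(*parts, BIN, ds.ProbeConfig(bootstrap_B=50, seed=1))
    assert 0.4 <= rep.metrics["auroc"] <= 0.6


def test_probe_separable_binary_high_auroc(rng):
    parts = _probe_data(rng, kind="separable")
    _, rep = ds.linear_probe(*parts, BIN, ds.ProbeConfig(bootstrap_B=50))
    assert rep.metrics["auroc"] >= 0.95


def test_probe_rejects_length_mismatch(rng):
    E = rng.normal(size=(10, 4))
    with pytest.raises(ValueError):
        ds.linear_probe(E, np.zeros(9), E, np.zeros(10), E, np.zeros(10), REG)


def test_multiclass_probe_report_shape(rng):
    n, d = 240, 6
    E = rng.normal(size=(n, d))
    W = rng.normal(size=(d, 3))
    y = np.array(["cat", "dog", "eel"])[np.argmax(E @ W, axis=1)]
    parts = (E[:160], y[:160], E[160:200], y[160:200], E[200:], y[200:])
    head, rep = ds.linear_probe(*parts, MULTI, ds.ProbeConfig(bootstrap_B=30))
    assert head.classes == ["cat", "dog", "eel"]
    assert rep.metrics["auroc"] > 0.8
    assert set(rep.bootstrap) == {"auroc", "ap"}


# ---------------------------------------------------------------- fine-tune
@pytest.fixture(scope="module")
def ft_material():
    rng = np.random.default_rng(3)
    X = rng.random((90, 32, 32))
    w = rng.normal(size=(32 * 32,))
    y = X.reshape(90, -1) @ w
    encoder = make_encoder(EncoderConfig("fundus2d", "tiny", 16, seed=0))
    return X, y, encoder


def test_fine_tune_one_epoch_wellformed(ft_material):
    X, y, encoder = ft_material
    parts = (X[:50], y[:50], X[50:70], y[50:70], X[70:], y[70:])
    cfg = ds.ProbeConfig(max_epochs=1, lr_grid=(1e-4,), bootstrap_B=20)
    _, rep = ds.fine_tune(encoder, *parts, REG, cfg)
    assert rep.mode == "fine_tune"
    assert np.isfinite(rep.metrics["rmse"]) and rep.n_test == 20


def test_fine_tune_zero_encoder_lr_equals_linear_probe(ft_material):
    X, y, encoder = ft_material
    from retinapair.encoders import embed

    E = {k: embed(v, encoder, l2norm=False).values for k, v in
         {"tr": X[:50], "va": X[50:70], "te": X[70:]}.items()}
    cfg = ds.ProbeConfig(max_epochs=8, lr_grid=(1e-3,), bootstrap_B=10)
    _, rep_probe = ds.linear_probe(E["tr"], y[:50], E["va"], y[50:70], E["te"], y[70:], REG, cfg)
    _, rep_ft = ds.fine_tune(
        encoder, X[:50], y[:50], X[50:70], y[50:70], X[70:], y[70:], REG, cfg, encoder_lr=0.0
    )
    assert rep_ft.metrics["rmse"] == pytest.approx(rep_probe.metrics["rmse"], abs=1e-9)
    assert rep_ft.metrics["r2"] == pytest.approx(rep_probe.metrics["r2"], abs=1e-9)


# --------------------------------------------------------------- interchange
def test_interchange_identical_embeddings_zero_decay(rng):
    E = rng.normal(size=(200, 8))
    w = rng.normal(size=8)
    y = (E @ w > 0).astype(int)
    parts = (E[:120], y[:120], E[120:160], y[120:160], E[160:], y[160:])
    head, rep = ds.linear_probe(*parts, BIN, ds.ProbeConfig(bootstrap_B=20))
    ic = ds.interchange_eval(head, E[160:], y[160:], rep.metrics)
    assert ic.decay["auroc"] == pytest.approx(0.0, abs=1e-12)
    assert ic.swapped_metrics == rep.metrics


def test_interchange_decay_formula(rng):
    E = rng.normal(size=(200, 8))
    w = rng.normal(size=8)
    y = (E @ w > 0).astype(int)
    parts = (E[:120], y[:120], E[120:160], y[120:160], E[160:], y[160:])
    head, rep = ds.linear_probe(*parts, BIN, ds.ProbeConfig(bootstrap_B=20))
    other = rng.normal(size=(40, 8))  # unrelated embeddings
    ic = ds.interchange_eval(head, other, y[160:], rep.metrics)
    src, swp = rep.metrics["auroc"], ic.swapped_metrics["auroc"]
    assert ic.decay["auroc"] == pytest.approx((src - swp) / src, abs=1e-12)
    assert 0.2 <= swp <= 0.8  # no transferable signal


def test_interchange_dim_mismatch(rng):
    E = rng.normal(size=(60, 8))
    y = np.array([0, 1] * 30)
    head, rep = ds.linear_probe(E[:30], y[:30], E[30:45], y[30:45], E[45:], y[45:],
                                BIN, ds.ProbeConfig(bootstrap_B=10))
    with pytest.raises(ValueError, match="dim"):
        ds.interchange_eval(head, rng.normal(size=(15, 4)), y[45:], rep.metrics)
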