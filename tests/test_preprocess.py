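"""Preprocessing stack: grayscale conversion, bilinear resize against a
brute-force oracle, ordered slice subsampling, whole-image normalization and
the stochastic augmentation policy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retinapair import preprocess as pp


# --------------------------------------------------------------- grayscale
def test_grayscale_idempotent_on_2d(rng):
    img = rng.random((5, 5))
    assert np.array_equal(pp.to_grayscale(img), img)


def test_grayscale_white_and_red():
    white = np.ones((2, 2, 3))
    assert np.allclose(pp.to_grayscale(white), 1.0, atol=1e-4)  # weights sum to ~1
    red = np.zeros((1, 1, 3))
    red[..., 0] = 1.0
    assert pp.to_grayscale(red)[0, 0] == pytest.approx(0.2989)


def test_grayscale_rejects_bad_channels(rng):
    with pytest.raises(ValueError):
        pp.to_grayscale(rng.random((4, 4, 2)))


# ------------------------------------------------------------------ resize
def brute_force_bilinear(img, target):
    """Half-pixel-center bilinear interpolation, plain loops."""
    h, w = img.shape
    th, tw = target
    out = np.empty(target)
    for i in range(th):
        for j in range(tw):
            sy = (i + 0.5) * h / th - 0.5
            sx = (j + 0.5) * w / tw - 0.5
            y0, x0 = int(np.floor(sy)), int(np.floor(sx))
            wy, wx = sy - y0, sx - x0
            acc = 0.0
            for dy, fy in ((0, 1 - wy), (1, wy)):
                for dx, fx in ((0, 1 - wx), (1, wx)):
                    yy = min(max(y0 + dy, 0), h - 1)
                    xx = min(max(x0 + dx, 0), w - 1)
                    acc += fy * fx * img[yy, xx]
            out[i, j] = acc
    return out


def test_resize_identity_at_same_size(rng):
    img = rng.random((16, 16))
    assert np.array_equal(pp.resize(img, (16, 16)), img)


def test_resize_constant_stays_constant():
    img = np.full((10, 14), 3.7)
    out = pp.resize(img, (7, 5))
    assert np.allclose(out, 3.7)


def test_resize_checkerboard_downsamples_to_mid_value():
    img = np.indices((64, 64)).sum(axis=0) % 2 * 1.0  # alternating pixels
    out = pp.resize(img, (32, 32))
    assert np.allclose(out, 0.5)


def test_resize_matches_brute_force_oracle(rng):
    img = rng.random((11, 7))
    for target in ((5, 9), (22, 14), (11, 7)):
        assert np.allclose(pp.resize(img, target), brute_force_bilinear(img, target), atol=1e-12)


def test_resize_rejects_empty_target(rng):
    with pytest.raises(ValueError):
        pp.resize(rng.random((4, 4)), (0, 3))


# ------------------------------------------------------------- subsampling
@pytest.mark.parametrize(
    "n_slices,n_keep,expected",
    [
        (20, 20, list(range(20))),
        (39, 20, list(range(0, 39, 2))),
    ],
)
def test_subsample_exact_cases(n_slices, n_keep, expected):
    assert pp.subsample_slices(n_slices, n_keep).tolist() == expected


@given(st.integers(1, 300), st.integers(1, 64))
@settings(max_examples=200, deadline=None)
def test_subsample_invariants(n_slices, n_keep):
    idx = pp.subsample_slices(n_slices, n_keep)
    assert len(idx) == n_keep
    assert idx[0] == 0
    if n_keep >= 2:
        assert idx[-1] == n_slices - 1
    assert np.all(np.diff(idx) >= 0)
    assert np.all((idx >= 0) & (idx < n_slices))


def test_subsample_rejects_invalid():
    with pytest.raises(ValueError):
        pp.subsample_slices(0, 20)


# --------------------------------------------------------------- normalize
def test_normalize_constant_is_zero():
    assert np.allclose(pp.normalize(np.full((4, 4), 9.0)), 0.0)


def test_normalize_moments(rng):
    x = rng.random((6, 6, 6)) * 50 + 3
    out = pp.normalize(x)
    assert abs(out.mean()) < 1e-6
    assert abs(out.std() - 1) < 1e-4


def test_normalize_affine_invariance(rng):
    x = rng.random((8, 8))
    assert np.allclose(pp.normalize(2.5 * x + 7.0), pp.normalize(x), atol=1e-10)


# ----------------------------------------------------------------- augment
def test_augment_identity_when_all_probabilities_zero(rng):
    policy = pp.AugmentationPolicy(p_crop=0, p_hflip=0, p_blur=0, p_contrast=0)
    img = rng.random((32, 32))
    assert np.array_equal(pp.augment(img, policy, rng), img)


def test_hflip_is_involution(rng):
    policy = pp.AugmentationPolicy(p_crop=0, p_hflip=1, p_blur=0, p_contrast=0)
    img = rng.random((16, 16))
    once = pp.augment(img, policy, np.random.default_rng(1))
    twice = pp.augment(once, policy, np.random.default_rng(2))
    assert np.allclose(twice, img)


def test_crop_deterministic_under_seed_and_preserves_shape(rng):
    policy = pp.AugmentationPolicy(p_crop=1, p_hflip=0, p_blur=0, p_contrast=0)
    img = rng.random((224, 224))
    a = pp.augment(img, policy, np.random.default_rng(3))
    b = pp.augment(img, policy, np.random.default_rng(3))
    assert a.shape == (224, 224)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, img)


def test_volume_augmented_slice_coherently(rng):
    policy = pp.AugmentationPolicy(p_crop=0, p_hflip=1, p_blur=0, p_contrast=0)
    vol = rng.random((4, 8, 8))
    out = pp.augment(vol, policy, np.random.default_rng(0))
    for s in range(4):
        assert np.allclose(out[s], vol[s][:, ::-1])


def test_two_views_differ_statistically(rng):
    img = rng.random((32, 32))
    policy = pp.AugmentationPolicy()
    master = np.random.default_rng(10)
    differing = sum(
        not np.array_equal(pp.augment(img, policy, master), pp.augment(img, policy, master))
        for _ in range(100)
    )
    assert differing > 50


def test_augment_policy_validation():
    with pytest.raises(ValueError):
        pp.AugmentationPolicy(p_crop=1.5).validate()
    with pytest.raises(ValueError):
        pp.AugmentationPolicy(blur_sigma=(2.0, 0.1)).validate()


# ---------------------------------------------------------------- pipeline
def test_full_volume_pipeline_default_shape(rng):
    vol = rng.random((37, 64, 48))
    out = pp.preprocess_volume(vol)
    assert out.shape == (20, 224, 224)
    assert abs(out.mean()) < 1e-6 and abs(out.std() - 1) < 1e-4


def test_fundus_pipeline_rgb_input(rng):
    img = rng.random((60, 70, 3))
    out = pp.preprocess_fundus(img, pp.PreprocessConfig(target_size=(32, 32)))
    assert out.shape == (32, 32)
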