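"""Synthetic cohort generator: determinism, label rules, render geometry and
the pairedness of the two modalities."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression

from retinapair import synthdata as sd


# ------------------------------------------------------------ cohort level
def test_cohort_counts_and_fields(small_cohort):
    scans, cfg = small_cohort
    patients = {s.patient_id for s in scans}
    assert len(patients) == cfg.n_patients
    for s in scans:
        assert s.eye in ("OD", "OS")
        assert s.fundus.shape == cfg.fundus_size
        assert cfg.n_slices_range[0] <= s.oct.shape[0] <= cfg.n_slices_range[1]
        assert s.oct.shape[1:] == cfg.oct_rows_cols
        assert np.all(s.fundus >= 0) and np.all(s.oct >= 0)


def test_cohort_deterministic_under_seed():
    cfg = sd.SyntheticCohortConfig(n_patients=4, seed=9)
    a = sd.generate_cohort(cfg)
    b = sd.generate_cohort(sd.SyntheticCohortConfig(n_patients=4, seed=9))
    for x, y in zip(a, b):
        assert np.array_equal(x.fundus, y.fundus)
        assert np.array_equal(x.oct, y.oct)
        assert x.labels == y.labels
    c = sd.generate_cohort(sd.SyntheticCohortConfig(n_patients=4, seed=10))
    assert not np.array_equal(a[0].fundus, c[0].fundus)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        sd.generate_cohort(sd.SyntheticCohortConfig(n_patients=0))
    with pytest.raises(ValueError):
        sd.SyntheticCohortConfig(n_slices_range=(5, 10)).validate()
    with pytest.raises(ValueError):
        sd.SyntheticCohortConfig(noise_sd=-0.1).validate()


# ------------------------------------------------------------------ labels
@pytest.mark.parametrize("n_inj,expected", [(16, "high"), (20, "high"), (5, "low"),
                                            (0, "low"), (6, "excluded"), (10, "excluded"),
                                            (15, "excluded")])
def test_treatment_need_thresholds(n_inj, expected):
    assert sd.categorize_treatment_need(n_inj) == expected


def test_treatment_need_rejects_negative():
    with pytest.raises(ValueError):
        sd.categorize_treatment_need(-1)


def test_label_consistency_across_cohort(small_cohort):
    scans, _ = small_cohort
    for s in scans:
        lab = s.labels
        assert lab.treatment_need == sd.categorize_treatment_need(lab.n_inj)
        assert lab.y_cst > 0
        assert lab.fluid in (0, 1) and lab.conversion in (0, 1)
        assert lab.disease in sd.DISEASE_CLASSES
        assert 0 <= lab.n_inj <= sd.NINJ_MAX


# ---------------------------------------------------------------- fundus
def test_fundus_zero_latent_is_fixed_template():
    a = sd.render_fundus(np.zeros(8), 0.0, (64, 64), noise_sd=0.0)
    b = sd.render_fundus(np.zeros(8), 0.0, (64, 64), noise_sd=0.0)
    assert np.array_equal(a, b)
    assert a.shape == (64, 64)


def test_fundus_shape_matches_config():
    img = sd.render_fundus(np.zeros(8), 0.0, (48, 56), noise_sd=0.0)
    assert img.shape == (48, 56)


def test_fundus_amplitude_difference_concentrates_in_blob_mask():
    z1 = np.zeros(8)
    for k in range(sd.LATENT_DIM):
        z2 = np.zeros(8)
        z2[k] = 1.5
        d = np.abs(
            sd.render_fundus(z2, 0.0, (64, 64)) - sd.render_fundus(z1, 0.0, (64, 64))
        )
        mask = sd.fundus_blob_mask(k, (64, 64))
        assert d[mask].sum() / d.sum() >= 0.9


def test_fundus_rejects_nonfinite_latent():
    with pytest.raises(ValueError):
        sd.render_fundus(np.full(8, np.nan), 0.0, (32, 32))


# -------------------------------------------------------------------- OCT
def test_oct_slice_count_and_shape(rng):
    v = sd.render_oct(np.zeros(8), 0, 25, rng=rng)
    assert v.shape == (25, 96, 64)


def test_oct_central_band_thickness_matches_label(rng):
    for i in range(50):
        z = rng.normal(size=8)
        v = sd.render_oct(z, 0, 23, rng=np.random.default_rng(100 + i))
        measured = sd.measure_central_band_thickness(v)
        assert abs(measured - sd.central_band_thickness(z, 96)) <= 1.0


def test_oct_fluid_darkens_blob_region():
    z = np.zeros(8)
    clear = sd.render_oct(z, 0, 25, rng=np.random.default_rng(3))
    fluid = sd.render_oct(z, 1, 25, rng=np.random.default_rng(3))
    mask = sd.oct_fluid_mask(clear.shape)
    assert fluid[mask].mean() < clear[mask].mean()


def test_oct_cst_thickness_monotone_in_latent_component():
    lo = sd.central_band_thickness(np.array([0, -1.0, 0, 0, 0, 0, 0, 0]), 96)
    mid = sd.central_band_thickness(np.zeros(8), 96)
    hi = sd.central_band_thickness(np.array([0, 1.0, 0, 0, 0, 0, 0, 0]), 96)
    assert lo < mid < hi


# -------------------------------------------------------------- pairedness
def test_latent_linearly_decodable_from_both_modalities(rng):
    """Noiseless renders of both modalities carry the full latent code:
    OLS readout achieves R^2 > 0.9 per component."""
    n = 250
    Z = rng.normal(size=(n, sd.LATENT_DIM))
    blob_amps, thicknesses = [], []
    for i in range(n):
        img = sd.render_fundus(Z[i], 0.0, (64, 64), noise_sd=0.0)
        feats = [img[sd.fundus_blob_mask(k, (64, 64))].mean() for k in range(sd.LATENT_DIM)]
        blob_amps.append(feats)
        vol = sd.render_oct(Z[i], 0, 21, rng=np.random.default_rng(7000 + i))
        thicknesses.append(sd.measure_band_thicknesses(vol))
    for features in (np.array(blob_amps), np.array(thicknesses)):
        for k in range(sd.LATENT_DIM):
            r2 = LinearRegression().fit(features, Z[:, k]).score(features, Z[:, k])
            assert r2 > 0.9, f"component {k}: R^2 = {r2:.3f}"


# ------------------------------------------------------------------- I/O
def test_save_load_roundtrip(tmp_path):
    scans = sd.generate_cohort(sd.SyntheticCohortConfig(n_patients=3, seed=2))
    manifest_path = sd.save_cohort(scans, str(tmp_path))
    manifest = pd.read_csv(manifest_path)
    assert list(manifest.columns) == sd.MANIFEST_COLUMNS
    assert len(manifest) == len(scans)
    loaded = sd.load_cohort(str(tmp_path))
    assert len(loaded) == len(scans)
    # volumes round-trip at float32; fundus is 8-bit-quantized but same shape
    assert np.allclose(loaded[0].oct, scans[0].oct, atol=1e-4)
    assert loaded[0].fundus.shape == scans[0].fundus.shape
    assert loaded[1].labels.treatment_need == scans[1].labels.treatment_need


def test_visit_drift_keeps_same_eye_closer(rng):
    """Same-eye visits stay nearer in latent space than other eyes."""
    cfg = sd.SyntheticCohortConfig(n_patients=20, visits_per_patient=(2, 2), seed=8)
    scans = sd.generate_cohort(cfg)
    by_patient = {}
    for s in scans:
        by_patient.setdefault(s.patient_id, []).append(s.latent.value)
    within = [np.linalg.norm(v[0] - v[1]) for v in by_patient.values()]
    firsts = [v[0] for v in by_patient.values()]
    between = [
        np.linalg.norm(firsts[i] - firsts[j])
        for i in range(len(firsts))
        for j in range(i + 1, len(firsts))
    ]
    assert np.mean(within) < np.mean(between)
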