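"""Synthetic paired fundus/OCT cohorts with shared latent structure.

Real multi-modal retinal cohorts pair a 2D fundus photograph and a 3D OCT
volume per (patient, eye, visit).  This module emulates that situation with a
fully documented generative model so that every downstream stage —
contrastive pre-training, retrieval, probing, modality interchange — is
exercisable and testable without any clinical data.

Generative model
----------------
Each eye draws a latent vector ``z ~ N(0, I_L)`` (default ``L = 8``) that
stands in for the unobserved anatomy shared by the two modalities; each visit
adds a small cumulative drift ``N(0, 0.1^2 I)`` so that same-eye visits stay
nearer in latent space than other eyes.  The fundus render places one
Gaussian blob per latent component on a ring over a disc-shaped background,
with blob amplitude linear in that component.  The OCT render draws one
horizontal bright band (retina-layer analog) per latent component whose
*thickness* is affine in that component; the central band's thickness is the
CST-style label.  Band brightness carries no latent information: bands are
mass-conserving (thicker bands are proportionally dimmer) and each band draws
a random multiplicative gain, a vertical position jitter, and a lateral gain
tilt per scan, with per-slice brightness wobble on top — acquisition-nuisance
analogs that are independent of the latent code and of the paired fundus
image.  A fluid-positive scan additionally has a dark ellipsoid carved into
the central slices.  Vendor tags add constant intensity offsets.  Remaining
noise scales with ``noise_sd``: i.i.d. voxel noise plus a smooth
low-frequency field (illumination variability analog), independent between
the two modalities.

None of this is anatomically realistic; it is a stand-in whose promise is
that the two modalities share a latent code readable from their rendered
structure (blob amplitudes, band thicknesses) while raw-intensity shortcuts
are suppressed by the multiplicative nuisance.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LatentFactors",
    "SyntheticCohortConfig",
    "DownstreamLabels",
    "PairedScan",
    "generate_cohort",
    "render_fundus",
    "render_oct",
    "categorize_treatment_need",
    "save_cohort",
    "load_cohort",
    "fundus_blob_mask",
]

LATENT_DIM = 8
VISIT_DRIFT_SD = 0.1

# ---- fundus rendering constants (normalized [0, 1]^2 coordinates) ----------
FUNDUS_BLOB_RING_RADIUS = 0.32
FUNDUS_BLOB_SIGMA = 0.07
FUNDUS_BLOB_AMP0 = 0.9      # amplitude intercept
# amplitude slope per latent unit; the CST-driving component (index 1) is the
# most visually prominent pathology analog in both modalities
FUNDUS_BLOB_AMP1 = np.array([0.45, 0.9, 0.45, 0.45, 0.45, 0.45, 0.45, 0.45])
FUNDUS_BG_LEVEL = 0.25
FUNDUS_DISC_AMP = 0.6
FUNDUS_DISC_SIGMA = 0.45

# ---- OCT rendering constants ------------------------------------------------
# Every latent component is coded *structurally*: band thickness is affine in
# its component.  Band brightness (multiplicative per-band gain) and vertical
# position (row jitter) vary randomly per scan, emulating acquisition
# gain/placement variability.  A linear functional of the voxels therefore
# sees mostly gain-confounded band mass, while the latent structure remains
# recoverable from band geometry.
OCT_THIN_BAND_CENTERS = (5 / 96, 14.5 / 96, 24 / 96, 33.5 / 96, 62.5 / 96, 72 / 96, 81.5 / 96)  # fraction of rows
OCT_THIN_T0 = 4.0           # voxels (at the 96-row native default)
OCT_THIN_T1 = 1.3           # voxels per latent unit
OCT_THIN_MIN = 1.0
OCT_THIN_MAX = 7.0
OCT_CST_BAND_CENTER = 0.5            # fraction of rows
OCT_CST_COMPONENT = 1       # latent component driving central-band thickness
OCT_CST_T0 = 7.0            # voxels
OCT_CST_T1 = 3.2            # voxels per latent unit
OCT_CST_MIN = 2.0
OCT_CST_MAX = 12.0
OCT_GAIN_SIGMA = 0.6        # lognormal (mean-one) per-band gain
OCT_ROW_JITTER = 1.0        # uniform +/- row jitter, thin bands
OCT_CST_JITTER = 3.5        # uniform +/- row jitter, central (CST) band
OCT_COLUMN_TILT = 0.5       # uniform +/- per-band lateral gain slope
OCT_SLICE_WOBBLE = 0.08     # per-slice multiplicative brightness sd
OCT_FLUID_ATTENUATION = 0.2

# ---- label coefficients (fixed, documented constants) -----------------------
# visual function correlates most strongly with central retinal thickness
# (latent component 1, the CST driver), with weaker contributions elsewhere
BCVA_COEF = np.array([0.3, 1.4, 0.25, 0.2, 0.2, 0.15, 0.15, 0.1])
BCVA_INTERCEPT = 70.0
BCVA_SCALE = 5.0
BCVA_NOISE_SD = 0.3
FLUID_COEF = np.array([0.0, 0.0, 1.8, 0.0, 0.0, 0.0, 0.0, 0.0])
CONVERSION_COEF = np.array([0.0, 0.0, 0.0, 0.9, 0.0, 0.0, 0.0, 0.0])
CONVERSION_INTERCEPT = -0.4
NINJ_INTERCEPT = 1.8
NINJ_SLOPE = 0.6            # on latent component 0
NINJ_MAX = 30
DISEASE_CLASSES = ("healthy", "DME", "iAMD", "RVO", "GA")
# 5 x 8 logit matrix; rows are classes, columns latent components
DISEASE_LOGITS = np.array(
    [
        [-0.8, 0.0, -0.5, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 1.2, 0.6, 0.0, 0.0, 0.0, 0.0],
        [0.9, 0.4, 0.0, 0.0, 0.5, 0.0, 0.0, 0.0],
        [0.0, -0.7, 0.0, 0.0, 0.0, 0.9, 0.3, 0.0],
        [0.0, 0.0, 0.0, 0.8, -0.4, 0.0, 0.0, 0.7],
    ]
)

DEFAULT_VENDORS = (("Spectralis", 0.0), ("Cirrus", 0.12), ("Topcon", 0.24), ("Nidek", 0.36))
MANIFEST_COLUMNS = [
    "patient_id",
    "eye",
    "visit",
    "vendor",
    "fundus_path",
    "oct_path",
    "y_bcva",
    "y_cst",
    "fluid",
    "disease",
    "n_inj",
    "treatment_need",
    "conversion",
]


@dataclass
class LatentFactors:
    """Latent anatomy code for one (patient, eye, visit)."""

    z: np.ndarray
    drift: np.ndarray

    @property
    def value(self) -> np.ndarray:
        """Effective latent vector at this visit (base + accumulated drift)."""
        return self.z + self.drift


@dataclass
class SyntheticCohortConfig:
    n_patients: int = 100
    visits_per_patient: tuple[int, int] = (1, 1)  # inclusive range
    fundus_size: tuple[int, int] = (64, 64)
    oct_rows_cols: tuple[int, int] = (96, 64)
    n_slices_range: tuple[int, int] = (21, 40)
    vendors: tuple[tuple[str, float], ...] = DEFAULT_VENDORS
    noise_sd: float = 0.1
    nuisance_scale: float = 3.0  # smooth-field sd = nuisance_scale * noise_sd
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.visits_per_patient[0] < 1 or self.visits_per_patient[1] < self.visits_per_patient[0]:
            raise ValueError("visits_per_patient must be a nonempty positive range")
        if min(self.fundus_size) <= 0 or min(self.oct_rows_cols) <= 0:
            raise ValueError("image sizes must be positive")
        lo, hi = self.n_slices_range
        if not (1 <= lo <= hi):
            raise ValueError("n_slices_range must be a valid positive range")
        if not (21 <= lo and hi <= 256):
            raise ValueError("default slice counts must stay within [21, 256]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class DownstreamLabels:
    y_bcva: float
    y_cst: float
    fluid: int
    disease: str
    n_inj: int
    treatment_need: str
    conversion: int


@dataclass
class PairedScan:
    patient_id: str
    eye: str
    visit_index: int
    vendor: str
    fundus: np.ndarray
    oct: np.ndarray
    labels: DownstreamLabels
    latent: LatentFactors | None = field(default=None, repr=False)


def categorize_treatment_need(n_inj: int) -> str:
    """Treatment-requirement category from the 2-year injection count.

    ``high`` for 16 or more injections, ``low`` for 5 or fewer, ``excluded``
    in between.
    """
    if n_inj < 0:
        raise ValueError("injection count must be non-negative")
    if n_inj >= 16:
        return "high"
    if n_inj <= 5:
        return "low"
    return "excluded"


def _smooth_field(shape: tuple[int, int], sd: float, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency nuisance field: coarse white noise, bilinearly upsampled."""
    if sd == 0:
        return np.zeros(shape)
    coarse = rng.normal(0.0, sd, size=(6, 6))
    from .preprocess import resize  # local import to avoid a cycle at import time

    return resize(coarse, shape)


def _fundus_blob_centers(size: tuple[int, int]) -> np.ndarray:
    """Blob centers (row, col) in pixel coordinates, one per latent component."""
    h, w = size
    angles = 2.0 * np.pi * np.arange(LATENT_DIM) / LATENT_DIM
    rows = (0.5 + FUNDUS_BLOB_RING_RADIUS * np.sin(angles)) * h
    cols = (0.5 + FUNDUS_BLOB_RING_RADIUS * np.cos(angles)) * w
    return np.stack([rows, cols], axis=1)


def fundus_blob_mask(component: int, size: tuple[int, int], n_sigma: float = 3.0) -> np.ndarray:
    """Boolean mask of the pixels within ``n_sigma`` of one blob's center."""
    h, w = size
    centers = _fundus_blob_centers(size)
    rr, cc = np.mgrid[0:h, 0:w]
    sigma = FUNDUS_BLOB_SIGMA * min(h, w)
    d2 = (rr - centers[component, 0]) ** 2 + (cc - centers[component, 1]) ** 2
    return d2 <= (n_sigma * sigma) ** 2


def render_fundus(
    z: np.ndarray,
    vendor_offset: float,
    size: tuple[int, int] = (64, 64),
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    nuisance_scale: float = 3.0,
) -> np.ndarray:
    """Render a 2D fundus analog: disc background plus latent-driven blobs."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("latent vector must be finite")
    h, w = size
    rr, cc = np.mgrid[0:h, 0:w]
    r2 = ((rr - (h - 1) / 2) / h) ** 2 + ((cc - (w - 1) / 2) / w) ** 2
    img = FUNDUS_BG_LEVEL + FUNDUS_DISC_AMP * np.exp(-r2 / (2 * FUNDUS_DISC_SIGMA**2))
    centers = _fundus_blob_centers(size)
    sigma = FUNDUS_BLOB_SIGMA * min(h, w)
    for k in range(LATENT_DIM):
        amp = FUNDUS_BLOB_AMP0 + FUNDUS_BLOB_AMP1[k] * z[k]
        d2 = (rr - centers[k, 0]) ** 2 + (cc - centers[k, 1]) ** 2
        img = img + amp * np.exp(-d2 / (2 * sigma**2))
    img = img + vendor_offset
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        img = img + _smooth_field(size, nuisance_scale * noise_sd, rng)
        img = img + rng.normal(0.0, noise_sd, size=size)
    return np.clip(img, 0.0, None)


ROW_SCALE_REF = 96  # native row count the voxel-unit constants refer to


def central_band_thickness(z: np.ndarray, n_rows: int = ROW_SCALE_REF) -> float:
    """CST analog in voxels: affine in one latent component, clipped."""
    s = n_rows / ROW_SCALE_REF
    t = (OCT_CST_T0 + OCT_CST_T1 * float(np.asarray(z)[OCT_CST_COMPONENT])) * s
    return float(np.clip(t, OCT_CST_MIN * s, OCT_CST_MAX * s))


def band_thicknesses(z: np.ndarray, n_rows: int = ROW_SCALE_REF) -> np.ndarray:
    """Thickness (voxels) of each latent component's band, CST component included."""
    z = np.asarray(z, dtype=float)
    s = n_rows / ROW_SCALE_REF
    out = np.clip((OCT_THIN_T0 + OCT_THIN_T1 * z) * s, OCT_THIN_MIN * s, OCT_THIN_MAX * s)
    out[OCT_CST_COMPONENT] = central_band_thickness(z, n_rows)
    return out


def _band_centers(n_rows: int) -> np.ndarray:
    """Nominal band center rows, CST component at the volume center."""
    centers = np.empty(LATENT_DIM)
    thin = iter(OCT_THIN_BAND_CENTERS)
    for k in range(LATENT_DIM):
        frac = OCT_CST_BAND_CENTER if k == OCT_CST_COMPONENT else next(thin)
        centers[k] = frac * n_rows
    return centers


def oct_fluid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal region carved out when the fluid biomarker is present.

    Placed off the central column so the CST measurement column is untouched.
    """
    s, h, w = shape
    ss, rr, cc = np.mgrid[0:s, 0:h, 0:w]
    center = (s / 2, OCT_CST_BAND_CENTER * h, 0.75 * w)
    radii = (max(2.0, 0.2 * s), 0.12 * h, 0.12 * w)
    d = (
        ((ss - center[0]) / radii[0]) ** 2
        + ((rr - center[1]) / radii[1]) ** 2
        + ((cc - center[2]) / radii[2]) ** 2
    )
    return d <= 1.0


def render_oct(
    z: np.ndarray,
    fluid: int,
    n_slices: int,
    rows_cols: tuple[int, int] = (96, 64),
    vendor_offset: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    nuisance_scale: float = 3.0,
) -> np.ndarray:
    """Render a 3D OCT analog: horizontal bright bands, one per latent
    component, with thickness affine in that component.

    The central band's thickness equals :func:`central_band_thickness` (the
    ``y_cst`` label).  Per-band multiplicative gains (lognormal, mean one)
    and small vertical jitters are drawn from ``rng`` per scan; they are
    acquisition nuisance, independent of the latent code and of the paired
    fundus image.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("latent vector must be finite")
    if rng is None:
        raise ValueError("render_oct draws per-scan band gains; rng is required")
    h, w = rows_cols
    centers = _band_centers(h)
    thick = band_thicknesses(z, h)
    gains = np.exp(rng.normal(-OCT_GAIN_SIGMA**2 / 2, OCT_GAIN_SIGMA, size=LATENT_DIM))
    jit_mag = np.full(LATENT_DIM, OCT_ROW_JITTER)
    jit_mag[OCT_CST_COMPONENT] = OCT_CST_JITTER
    jitter = rng.uniform(-jit_mag, jit_mag) * (h / ROW_SCALE_REF)
    tilts = rng.uniform(-OCT_COLUMN_TILT, OCT_COLUMN_TILT, size=LATENT_DIM)
    rr = np.arange(h, dtype=float)
    s = h / ROW_SCALE_REF
    slice_img = np.zeros((h, w))
    for k in range(LATENT_DIM):
        c = centers[k] + jitter[k]
        # anti-aliased edges: each voxel's intensity is its fractional overlap
        # with the band interval
        coverage = np.clip(
            np.minimum(rr + 0.5, c + thick[k] / 2) - np.maximum(rr - 0.5, c - thick[k] / 2),
            0.0,
            1.0,
        )
        # mass conservation: a band stretched over more depth is
        # proportionally dimmer, so total band mass equals the gain times the
        # nominal thickness regardless of the latent code.  Thickness is then
        # carried purely by band geometry, not by any integrated intensity.
        nominal = (OCT_CST_T0 if k == OCT_CST_COMPONENT else OCT_THIN_T0) * s
        amp = gains[k] * nominal / thick[k]
        # lateral gain tilt (beam alignment analog); unity at the center
        # column, where the CST measurement is taken
        xnorm = (np.arange(w) - (w - 1) / 2) / ((w - 1) / 2)
        tilt = 1.0 + tilts[k] * xnorm
        slice_img += amp * coverage[:, None] * tilt[None, :]
    vol = np.repeat(slice_img[None, :, :], n_slices, axis=0)
    # per-slice brightness wobble (illumination fluctuation across B-scans)
    wobble = 1.0 + OCT_SLICE_WOBBLE * rng.normal(size=n_slices)
    vol = vol * wobble[:, None, None]
    if fluid:
        mask = oct_fluid_mask((n_slices, h, w))
        vol = np.where(mask, vol * OCT_FLUID_ATTENUATION, vol)
    vol = vol + vendor_offset
    if noise_sd > 0:
        field = _smooth_field((h, w), nuisance_scale * noise_sd, rng)
        vol = vol + field[None, :, :]
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
    return np.clip(vol, 0.0, None)


def _run_thickness(column: np.ndarray, center: float, half_window: float) -> int:
    """Thickness of the band nearest ``center``: contiguous supra-half-peak
    run around the window's peak voxel (robust to per-band gain)."""
    h = len(column)
    lo = max(0, int(np.ceil(center - half_window - 0.5)))
    hi = min(h, int(np.floor(center + half_window + 0.5)) + 1)
    window = column[lo:hi]
    peak = int(np.argmax(window))
    if window[peak] <= 0:
        return 0
    thr = 0.5 * window[peak]
    left = peak
    while left > 0 and window[left - 1] > thr:
        left -= 1
    right = peak
    while right < len(window) - 1 and window[right + 1] > thr:
        right += 1
    return right - left + 1


def measure_central_band_thickness(vol: np.ndarray) -> int:
    """CST measurement: supra-half-peak run length at the center column of
    the central slice, inside a window around the central band."""
    n_slices, h, w = vol.shape
    column = vol[n_slices // 2, :, w // 2]
    s = h / ROW_SCALE_REF
    return _run_thickness(column, OCT_CST_BAND_CENTER * h, (OCT_CST_MAX / 2 + OCT_CST_JITTER - 0.5) * s)


def measure_band_thicknesses(vol: np.ndarray) -> np.ndarray:
    """Measured thickness of every component's band (see band layout)."""
    n_slices, h, w = vol.shape
    column = vol[n_slices // 2, :, w // 2]
    s = h / ROW_SCALE_REF
    centers = _band_centers(h)
    out = np.empty(LATENT_DIM)
    for k in range(LATENT_DIM):
        if k == OCT_CST_COMPONENT:
            half = OCT_CST_MAX / 2 + OCT_CST_JITTER - 0.5
        else:
            half = OCT_THIN_MAX / 2 + OCT_ROW_JITTER - 0.5
        lo = max(0, int(np.ceil(centers[k] - half * s - 0.5)))
        hi = min(h, int(np.floor(centers[k] + half * s + 0.5)) + 1)
        window = column[lo:hi]
        peak = window.max()
        # band mass / peak amplitude: exact thickness for anti-aliased bands,
        # independent of the band's multiplicative gain
        out[k] = window.sum() / peak if peak > 0 else 0.0
    return out


def _labels_from_latent(z: np.ndarray, n_rows: int, rng: np.random.Generator) -> DownstreamLabels:
    y_bcva = BCVA_INTERCEPT + BCVA_SCALE * (float(BCVA_COEF @ z) + rng.normal(0.0, BCVA_NOISE_SD))
    y_cst = central_band_thickness(z, n_rows)
    fluid = int(rng.random() < _sigmoid(float(FLUID_COEF @ z)))
    disease = DISEASE_CLASSES[int(np.argmax(DISEASE_LOGITS @ z))]
    lam = np.exp(NINJ_INTERCEPT + NINJ_SLOPE * z[0])
    n_inj = int(np.clip(rng.poisson(lam), 0, NINJ_MAX))
    conversion = int(rng.random() < _sigmoid(float(CONVERSION_COEF @ z) + CONVERSION_INTERCEPT))
    return DownstreamLabels(
        y_bcva=y_bcva,
        y_cst=y_cst,
        fluid=fluid,
        disease=disease,
        n_inj=n_inj,
        treatment_need=categorize_treatment_need(n_inj),
        conversion=conversion,
    )


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SyntheticCohortConfig) -> list[PairedScan]:
    """Generate one PairedScan per (patient, visit); deterministic under seed."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    scans: list[PairedScan] = []
    vendors = list(config.vendors)
    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        eye = "OD" if rng.random() < 0.5 else "OS"
        vendor, offset = vendors[p % len(vendors)]
        z_base = rng.normal(0.0, 1.0, size=LATENT_DIM)
        lo, hi = config.visits_per_patient
        n_visits = int(rng.integers(lo, hi + 1))
        n_slices = int(rng.integers(config.n_slices_range[0], config.n_slices_range[1] + 1))
        drift = np.zeros(LATENT_DIM)
        for v in range(n_visits):
            if v > 0:
                drift = drift + rng.normal(0.0, VISIT_DRIFT_SD, size=LATENT_DIM)
            latent = LatentFactors(z=z_base.copy(), drift=drift.copy())
            zv = latent.value
            labels = _labels_from_latent(zv, config.oct_rows_cols[0], rng)
            fundus = render_fundus(
                zv, offset, config.fundus_size, config.noise_sd, rng, config.nuisance_scale
            )
            oct_vol = render_oct(
                zv,
                labels.fluid,
                n_slices,
                config.oct_rows_cols,
                offset,
                config.noise_sd,
                rng,
                config.nuisance_scale,
            )
            scans.append(
                PairedScan(
                    patient_id=pid,
                    eye=eye,
                    visit_index=v,
                    vendor=vendor,
                    fundus=fundus,
                    oct=oct_vol,
                    labels=labels,
                    latent=latent,
                )
            )
    return scans


def cohort_manifest(scans: list[PairedScan], fundus_paths=None, oct_paths=None) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(scans):
        rows.append(
            {
                "patient_id": s.patient_id,
                "eye": s.eye,
                "visit": s.visit_index,
                "vendor": s.vendor,
                "fundus_path": fundus_paths[i] if fundus_paths else "",
                "oct_path": oct_paths[i] if oct_paths else "",
                "y_bcva": s.labels.y_bcva,
                "y_cst": s.labels.y_cst,
                "fluid": s.labels.fluid,
                "disease": s.labels.disease,
                "n_inj": s.labels.n_inj,
                "treatment_need": s.labels.treatment_need,
                "conversion": s.labels.conversion,
            }
        )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def save_cohort(scans: list[PairedScan], out_dir: str) -> str:
    """Write fundus PNGs (8-bit, per-image max scaling), OCT NPZ volumes and
    the manifest CSV.  Returns the manifest path.

    The 8-bit fundus quantization is lossy in absolute intensity; the
    preprocessing pipeline normalizes per image, so relative structure is
    what matters downstream.
    """
    from PIL import Image

    os.makedirs(out_dir, exist_ok=True)
    fundus_dir = os.path.join(out_dir, "fundus")
    oct_dir = os.path.join(out_dir, "oct")
    os.makedirs(fundus_dir, exist_ok=True)
    os.makedirs(oct_dir, exist_ok=True)
    fundus_paths, oct_paths = [], []
    for s in scans:
        stem = f"{s.patient_id}_{s.eye}_v{s.visit_index:03d}"
        fpath = os.path.join("fundus", stem + ".png")
        opath = os.path.join("oct", stem + ".npz")
        img = s.fundus
        scale = img.max() if img.max() > 0 else 1.0
        Image.fromarray(np.clip(img / scale * 255.0, 0, 255).astype(np.uint8)).save(
            os.path.join(out_dir, fpath)
        )
        np.savez_compressed(os.path.join(out_dir, opath), volume=s.oct.astype(np.float32))
        fundus_paths.append(fpath)
        oct_paths.append(opath)
    manifest = cohort_manifest(scans, fundus_paths, oct_paths)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def load_cohort(cohort_dir: str) -> list[PairedScan]:
    """Read a cohort written by :func:`save_cohort` back into PairedScan records."""
    from PIL import Image

    manifest = pd.read_csv(os.path.join(cohort_dir, "manifest.csv"))
    scans = []
    for _, row in manifest.iterrows():
        fundus = np.asarray(Image.open(os.path.join(cohort_dir, row["fundus_path"])), dtype=float) / 255.0
        oct_vol = np.load(os.path.join(cohort_dir, row["oct_path"]))["volume"].astype(float)
        labels = DownstreamLabels(
            y_bcva=float(row["y_bcva"]),
            y_cst=float(row["y_cst"]),
            fluid=int(row["fluid"]),
            disease=str(row["disease"]),
            n_inj=int(row["n_inj"]),
            treatment_need=str(row["treatment_need"]),
            conversion=int(row["conversion"]),
        )
        scans.append(
            PairedScan(
                patient_id=str(row["patient_id"]),
                eye=str(row["eye"]),
                visit_index=int(row["visit"]),
                vendor=str(row["vendor"]),
                fundus=fundus,
                oct=oct_vol,
                labels=labels,
            )
        )
    return scans
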