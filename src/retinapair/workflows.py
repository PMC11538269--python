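"""End-to-end experiment orchestration: schema-validated configs, manifest
validation, and the desk-scale demo tying all stages together.

The demo mirrors the two-phase layout of the framework: contrastive
pre-training of the two encoders (CLIP and CLOOB variants), followed by
cross-modal retrieval evaluation and downstream adaptation (a linear probe
per task plus the modality-interchange check), all on a synthetic paired
cohort.  Every source of randomness derives from one master seed.
"""

from __future__ import annotations

import json
import os
import time

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError

from . import downstream as ds
from . import pretrain as pt
from . import retrieval as rt
from . import splits as sp
from . import synthdata as sd
from .encoders import embed

__all__ = [
    "ExperimentConfig",
    "ManifestError",
    "default_demo_config",
    "run_demo",
    "validate_manifest",
]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSection(_Section):
    n_patients: int = 400
    visits_min: int = 1
    visits_max: int = 1
    noise_sd: float = 0.1
    nuisance_scale: float = 3.0
    n_slices_min: int = 21
    n_slices_max: int = 40


class PretrainSection(_Section):
    epochs: int = 30
    embed_dim: int = 32
    clip_batch_size: int = 16
    clip_lr: float = 3e-3
    clip_input_noise_sd: float = 0.4
    cloob_batch_size: int = 32
    cloob_lr: float = 1e-3
    cloob_input_noise_sd: float = 0.3
    hopfield_beta: float = 2.0


class EvalSection(_Section):
    ks: tuple[int, ...] = (1, 5, 10)
    bootstrap_B: int = 200
    probe_batch_size: int = 16


class ExperimentConfig(_Section):
    """Schema-validated demo/experiment configuration (unknown keys rejected)."""

    master_seed: int = 0
    ratios: tuple[float, float, float] = (0.5, 0.1, 0.4)
    cohort: CohortSection = CohortSection()
    pretrain: PretrainSection = PretrainSection()
    evaluation: EvalSection = EvalSection()


def default_demo_config(master_seed: int = 0) -> ExperimentConfig:
    """The canonical desk-scale demo: 200 training pairs (400 patients at a
    50/10/40 split, leaving a 160-pair evaluation pool), 30 epochs, tiny
    encoders at embedding dimension 32."""
    return ExperimentConfig(master_seed=master_seed)


def load_config(path: str) -> ExperimentConfig:
    """Read a YAML/JSON experiment config; schema errors list offending keys."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return ExperimentConfig(**raw)
    except ValidationError as err:
        raise ValueError(f"invalid experiment config {path}: {err}") from err


def _clip_config(cfg: ExperimentConfig) -> pt.PretrainConfig:
    p = cfg.pretrain
    return pt.PretrainConfig(
        objective="clip",
        epochs=p.epochs,
        batch_size=p.clip_batch_size,
        lr=p.clip_lr,
        embed_dim=p.embed_dim,
        input_noise_sd=p.clip_input_noise_sd,
        seed=cfg.master_seed,
    )


def _cloob_config(cfg: ExperimentConfig) -> pt.PretrainConfig:
    p = cfg.pretrain
    return pt.PretrainConfig(
        objective="cloob",
        epochs=p.epochs,
        batch_size=p.cloob_batch_size,
        lr=p.cloob_lr,
        embed_dim=p.embed_dim,
        hopfield_beta=p.hopfield_beta,
        input_noise_sd=p.cloob_input_noise_sd,
        seed=cfg.master_seed,
    )


def demo_materials(cfg: ExperimentConfig):
    """Generate the demo cohort and derived arrays/splits (deterministic)."""
    cohort_cfg = sd.SyntheticCohortConfig(
        n_patients=cfg.cohort.n_patients,
        visits_per_patient=(cfg.cohort.visits_min, cfg.cohort.visits_max),
        noise_sd=cfg.cohort.noise_sd,
        nuisance_scale=cfg.cohort.nuisance_scale,
        n_slices_range=(cfg.cohort.n_slices_min, cfg.cohort.n_slices_max),
        seed=cfg.master_seed + 11,
    )
    scans = sd.generate_cohort(cohort_cfg)
    manifest = sd.cohort_manifest(scans)
    data = pt.build_training_arrays(scans)
    split = sp.assign_splits(manifest, cfg.ratios, seed=cfg.master_seed + 11)
    idx = {name: pt._split_indices(data, split, name) for name in ("train", "val", "test")}
    return scans, manifest, data, split, idx


def _probe_embeddings(data, idx, encoder):
    return {s: embed(data["oct"][idx[s]], encoder, l2norm=False).values for s in idx}


def run_demo(config: ExperimentConfig | None = None, out_dir: str = "demo_out") -> dict:
    """Run the full desk-scale pipeline and write JSON reports.

    Steps: synthetic cohort -> patient-level split -> CLIP and CLOOB
    pre-training -> test-set retrieval reports -> BCVA regression probe and
    fluid-detection probe on OCT embeddings -> fundus-into-OCT-head
    interchange.  Returns the report bundle as a dict; each report is also
    written to ``out_dir`` as JSON along with a run log.
    """
    cfg = config or default_demo_config()
    os.makedirs(out_dir, exist_ok=True)
    t_start = time.time()
    log: dict = {"master_seed": cfg.master_seed, "stages": {}}

    t0 = time.time()
    scans, manifest, data, split, idx = demo_materials(cfg)
    log["stages"]["cohort"] = {
        "n_scans": len(scans),
        "split_sizes": {k: int(len(v)) for k, v in idx.items()},
        "seconds": round(time.time() - t0, 2),
    }

    bundle: dict = {}
    te = idx["test"]
    pids = data["patient_id"][te]
    results = {}
    for name, p_cfg in (("clip", _clip_config(cfg)), ("cloob", _cloob_config(cfg))):
        t0 = time.time()
        res = pt.pretrain(data, split, p_cfg)
        results[name] = res
        U = embed(data["fundus"][te], res.encoders["fundus2d"], ids=pids)
        V = embed(data["oct"][te], res.encoders["oct3d"], ids=pids)
        ks = tuple(k for k in cfg.evaluation.ks if k <= len(te))
        reports = rt.evaluate_retrieval(U, V, ks=ks, patient_ids=pids)
        bundle[f"retrieval_{name}"] = {d: r.to_dict() for d, r in reports.items()}
        log["stages"][f"pretrain_{name}"] = {
            "final_train_loss": float(res.history["train_loss"].iloc[-1]),
            "seconds": round(time.time() - t0, 2),
        }

    # downstream: probes on the CLIP OCT encoder, interchange with its fundus encoder
    clip_res = results["clip"]
    probe_cfg = ds.ProbeConfig(
        bootstrap_B=cfg.evaluation.bootstrap_B,
        batch_size=cfg.evaluation.probe_batch_size,
        seed=cfg.master_seed,
    )
    E = _probe_embeddings(data, idx, clip_res.encoders["oct3d"])

    y = manifest["y_bcva"].to_numpy()
    task = ds.ProbeTask("bcva_regression", "regression", "y_bcva")
    _, rep = ds.linear_probe(
        E["train"], y[idx["train"]], E["val"], y[idx["val"]], E["test"], y[idx["test"]],
        task, probe_cfg,
    )
    bundle["probe_bcva"] = rep.to_dict()

    fl = manifest["fluid"].to_numpy()
    taskf = ds.ProbeTask("fluid_detection", "binary", "fluid")
    headf, repf = ds.linear_probe(
        E["train"], fl[idx["train"]], E["val"], fl[idx["val"]], E["test"], fl[idx["test"]],
        taskf, probe_cfg,
    )
    bundle["probe_fluid"] = repf.to_dict()

    Ef_test = embed(data["fundus"][te], clip_res.encoders["fundus2d"], l2norm=False).values
    ic = ds.interchange_eval(headf, Ef_test, fl[te], repf.metrics)
    bundle["interchange_fluid"] = ic.to_dict()

    log["seconds_total"] = round(time.time() - t_start, 2)
    bundle["run_log"] = log
    for name, payload in bundle.items():
        with open(os.path.join(out_dir, f"{name}.json"), "w") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)
    return bundle


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


class ManifestError(ValueError):
    """Raised by validate_manifest; ``errors`` lists each problem."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("manifest validation failed:\n" + "\n".join(errors))


_LABEL_DOMAINS = {
    "eye": {"OD", "OS"},
    "fluid": {0, 1},
    "conversion": {0, 1},
    "disease": set(sd.DISEASE_CLASSES),
    "treatment_need": {"high", "low", "excluded"},
}


def check_manifest(path: str) -> tuple[pd.DataFrame, list[str]]:
    """Validate a cohort manifest; returns (frame, itemized error list)."""
    manifest = pd.read_csv(path)
    base = os.path.dirname(os.path.abspath(path))
    errors: list[str] = []
    for col in sd.MANIFEST_COLUMNS:
        if col not in manifest.columns:
            errors.append(f"missing column: {col}")
    if errors:
        return manifest, errors
    for i, row in manifest.iterrows():
        for col in ("fundus_path", "oct_path"):
            p = os.path.join(base, str(row[col]))
            if not os.path.exists(p):
                errors.append(f"row {i}: {col} does not exist: {row[col]}")
        for col, domain in _LABEL_DOMAINS.items():
            if row[col] not in domain:
                errors.append(f"row {i}: column {col} has out-of-domain value {row[col]!r}")
        if row["n_inj"] < 0:
            errors.append(f"row {i}: column n_inj is negative ({row['n_inj']})")
        if row["y_cst"] <= 0:
            errors.append(f"row {i}: column y_cst must be positive ({row['y_cst']})")
    return manifest, errors


def validate_manifest(path: str) -> pd.DataFrame:
    """Typed manifest on success; :class:`ManifestError` listing every problem."""
    manifest, errors = check_manifest(path)
    if errors:
        raise ManifestError(errors)
    return manifest
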