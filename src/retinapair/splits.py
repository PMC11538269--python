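"""Patient-level train/val/test partitioning and the per-epoch pair sampler.

Splits are always made at the patient level so that no patient contributes
scans to more than one partition.  Optional stratification keeps each split's
label proportions within one patient of the global proportions, using
per-stratum shuffling followed by largest-remainder allocation.

Pre-training consumes one randomly selected (fundus, OCT) pair per patient
per epoch; the selection is driven by an explicit epoch seed derived from the
master seed rather than wall-clock time, so runs are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SplitAssignment", "assign_splits", "epoch_pairs", "epoch_pair_indices"]

SPLIT_NAMES = ("train", "val", "test")


@dataclass
class SplitAssignment:
    assignment: dict[str, str]  # patient_id -> split name
    ratios: tuple[float, float, float]
    stratify_key: str | None
    seed: int

    def patients(self, split: str) -> list[str]:
        if split not in SPLIT_NAMES:
            raise ValueError(f"unknown split {split!r}")
        return [p for p, s in self.assignment.items() if s == split]

    def split_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": list(self.assignment), "split": list(self.assignment.values())}
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "SplitAssignment":
        df = pd.read_csv(path)
        return cls(
            assignment=dict(zip(df["patient_id"].astype(str), df["split"])),
            ratios=(np.nan, np.nan, np.nan),
            stratify_key=None,
            seed=-1,
        )


def _largest_remainder(n: int, ratios: np.ndarray) -> np.ndarray:
    """Integer allocation of n items proportional to ratios."""
    quotas = n * ratios
    base = np.floor(quotas).astype(int)
    remainder = n - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    for i in range(remainder):
        base[order[i]] += 1
    return base


def assign_splits(
    manifest: pd.DataFrame,
    ratios: tuple[float, float, float] = (0.8, 0.15, 0.05),
    stratify_key: str | None = None,
    seed: int = 0,
) -> SplitAssignment:
    """Partition patients into train/val/test, optionally stratified.

    ``manifest`` needs a ``patient_id`` column; with ``stratify_key`` given,
    each patient's stratum is the key's value on their first manifest row.
    Strata with fewer than 3 patients go entirely to train (with a warning).
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    ratios_arr = np.asarray(ratios, dtype=float)
    if ratios_arr.shape != (3,) or np.any(ratios_arr < 0):
        raise ValueError("ratios must be 3 non-negative numbers")
    if abs(ratios_arr.sum() - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if stratify_key is not None and stratify_key not in manifest.columns:
        raise KeyError(f"unknown stratify_key {stratify_key!r}")

    per_patient = manifest.drop_duplicates("patient_id", keep="first")
    patient_ids = per_patient["patient_id"].astype(str).to_numpy()
    if stratify_key is None:
        strata = {None: list(patient_ids)}
    else:
        values = per_patient[stratify_key].to_numpy()
        strata = {}
        for pid, v in zip(patient_ids, values):
            strata.setdefault(v, []).append(pid)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    assignment: dict[str, str] = {}
    for stratum in sorted(strata, key=str):
        members = np.array(strata[stratum])
        if stratify_key is not None and len(members) < 3:
            warnings.warn(
                f"stratum {stratum!r} has {len(members)} patient(s); assigning all to train",
                stacklevel=2,
            )
            for pid in members:
                assignment[pid] = "train"
            continue
        rng.shuffle(members)
        counts = _largest_remainder(len(members), ratios_arr)
        start = 0
        for name, c in zip(SPLIT_NAMES, counts):
            for pid in members[start : start + c]:
                assignment[pid] = name
            start += c
    return SplitAssignment(
        assignment=assignment,
        ratios=tuple(ratios_arr),
        stratify_key=stratify_key,
        seed=seed,
    )


def epoch_pair_indices(patient_ids, epoch_seed: int) -> np.ndarray:
    """One record index per patient, uniform over that patient's records.

    Patients keep their first-appearance order; the draw is deterministic
    under ``epoch_seed``.
    """
    patient_ids = np.asarray(patient_ids)
    if patient_ids.size == 0:
        raise ValueError("no records to sample from")
    rng = np.random.default_rng(epoch_seed)
    groups: dict = {}
    for i, pid in enumerate(patient_ids):
        groups.setdefault(pid, []).append(i)
    return np.array([g[rng.integers(len(g))] for g in groups.values()], dtype=int)


def epoch_pairs(records, epoch_seed: int) -> list:
    """One randomly selected record per patient for this epoch."""
    ids = [r.patient_id for r in records]
    idx = epoch_pair_indices(ids, epoch_seed)
    return [records[i] for i in idx]
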