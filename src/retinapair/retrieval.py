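"""Cross-modal retrieval evaluation.

Given paired fundus/OCT embeddings, ranks each query's candidates by cosine
similarity and reports directional top-k accuracies with exact
Clopper-Pearson 95% confidence intervals, the analytic chance level ``k/n``,
positive-pair cosine statistics, and the fraction of top-1 retrievals coming
from the query's own patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .encoders import EmbeddingMatrix

__all__ = [
    "RetrievalReport",
    "topk_accuracy",
    "chance_topk",
    "binomial_ci",
    "positive_pair_cosine_stats",
    "same_patient_fraction",
    "top1_indices",
    "evaluate_retrieval",
]

DIRECTIONS = ("fundus_to_oct", "oct_to_fundus")


@dataclass
class RetrievalReport:
    direction: str
    n: int
    topk: dict[int, float]
    ci: dict[int, tuple[float, float]]
    chance: dict[int, float]
    positive_cosine_mean: float
    positive_cosine_sd: float
    same_patient_fraction: float | None = None

    def __post_init__(self):
        for k, acc in self.topk.items():
            lo, hi = self.ci[k]
            assert 0.0 <= acc <= 1.0 and lo <= acc <= hi

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "n": self.n,
            "topk": {str(k): v for k, v in self.topk.items()},
            "ci": {str(k): list(v) for k, v in self.ci.items()},
            "chance": {str(k): v for k, v in self.chance.items()},
            "positive_cosine_mean": self.positive_cosine_mean,
            "positive_cosine_sd": self.positive_cosine_sd,
            "same_patient_fraction": self.same_patient_fraction,
        }


def _as_similarity(S) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    return S


def _ranks_of_truth(S: np.ndarray) -> np.ndarray:
    """Rank (0-based) of the true match in each row; ties broken by lowest
    candidate index, so equal-similarity candidates are ordered by index."""
    n = S.shape[0]
    diag = np.diag(S)
    better = (S > diag[:, None]).sum(axis=1)
    # ties rank ahead of the truth only when they have a lower index
    tie_idx = np.arange(n)[None, :] < np.arange(n)[:, None]
    ties_ahead = ((S == diag[:, None]) & tie_idx).sum(axis=1)
    return better + ties_ahead


def topk_accuracy(S, ks=(1, 5, 10), direction: str = "fundus_to_oct") -> dict[int, float]:
    """Fraction of queries whose true match ranks within the top k."""
    S = _as_similarity(S)
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if direction == "oct_to_fundus":
        S = S.T
    n = S.shape[0]
    ks = tuple(int(k) for k in ks)
    if any(k < 1 or k > n for k in ks):
        raise ValueError(f"each k must be in [1, {n}]")
    ranks = _ranks_of_truth(S)
    return {k: float(np.mean(ranks < k)) for k in ks}


def top1_indices(S, direction: str = "fundus_to_oct") -> np.ndarray:
    """Index of the highest-similarity candidate per query (ties: lowest index)."""
    S = _as_similarity(S)
    if direction == "oct_to_fundus":
        S = S.T
    return np.argmax(S, axis=1)


def chance_topk(n: int, k: int) -> float:
    """Expected top-k accuracy of an uninformative ranking: k/n."""
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    return k / n


def binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be within [0, n]")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


def positive_pair_cosine_stats(U, V) -> tuple[float, float]:
    """Mean and SD of the positive-pair cosine similarities (the diagonal)."""
    U = U.values if isinstance(U, EmbeddingMatrix) else np.asarray(U, dtype=float)
    V = V.values if isinstance(V, EmbeddingMatrix) else np.asarray(V, dtype=float)
    if U.shape != V.shape:
        raise ValueError("paired embeddings must share shape")
    if U.shape[0] == 0:
        raise ValueError("no pairs")
    diag = np.einsum("ij,ij->i", U, V)
    return float(diag.mean()), float(diag.std())


def same_patient_fraction(top1, query_patient_ids, pool_patient_ids=None) -> float:
    """Fraction of top-1 retrievals sharing the query's patient id."""
    top1 = np.asarray(top1)
    query = np.asarray(query_patient_ids)
    pool = query if pool_patient_ids is None else np.asarray(pool_patient_ids)
    if top1.shape[0] != query.shape[0]:
        raise ValueError("length mismatch between retrievals and queries")
    return float(np.mean(pool[top1] == query))


def evaluate_retrieval(
    U,
    V,
    ks=(1, 5, 10),
    patient_ids=None,
) -> dict[str, RetrievalReport]:
    """Directional retrieval reports for paired embeddings U (fundus), V (OCT)."""
    Ua = U.values if isinstance(U, EmbeddingMatrix) else np.asarray(U, dtype=float)
    Va = V.values if isinstance(V, EmbeddingMatrix) else np.asarray(V, dtype=float)
    if Ua.shape != Va.shape:
        raise ValueError("paired embeddings must share shape")
    n = Ua.shape[0]
    S = Ua @ Va.T
    cos_mean, cos_sd = positive_pair_cosine_stats(Ua, Va)
    reports = {}
    for direction in DIRECTIONS:
        accs = topk_accuracy(S, ks, direction)
        ci = {k: binomial_ci(int(round(a * n)), n) for k, a in accs.items()}
        spf = None
        if patient_ids is not None:
            spf = same_patient_fraction(top1_indices(S, direction), patient_ids)
        reports[direction] = RetrievalReport(
            direction=direction,
            n=n,
            topk=accs,
            ci=ci,
            chance={k: chance_topk(n, k) for k in accs},
            positive_cosine_mean=cos_mean,
            positive_cosine_sd=cos_sd,
            same_patient_fraction=spf,
        )
    return reports
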