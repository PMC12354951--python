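"""Metrics, split machinery, similarity-based redundancy filtering, and the
label-permutation significance test."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from scipy import stats

from .graph_builder import GuideRecord

__all__ = [
    "UndefinedMetricError",
    "MetricReport",
    "SplitPlan",
    "SimilarityReport",
    "PermutationResult",
    "spearman",
    "pearson",
    "mse",
    "metric_report",
    "make_folds",
    "make_holdout",
    "similarity",
    "filter_by_similarity",
    "permutation_test",
]


class UndefinedMetricError(ValueError):
    """Raised when a correlation is undefined (constant input, too few points)."""


def _check_xy(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("inputs must be 1-D vectors")
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.shape[0]}")
    return x, y


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x, y = _check_xy(x, y, 2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("rank correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    x, y = _check_xy(x, y, 2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def mse(x: Sequence[float], y: Sequence[float]) -> float:
    x, y = _check_xy(x, y, 1)
    return float(np.mean((x - y) ** 2))


@dataclass(frozen=True)
class MetricReport:
    spearman: float
    pearson: float
    mse: float
    n: int

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "spearman\tpearson\tmse\tn\n"
            f"{self.spearman:.6f}\t{self.pearson:.6f}\t{self.mse:.6f}\t{self.n}\n"
        )


def metric_report(preds: Sequence[float], labels: Sequence[float]) -> MetricReport:
    preds, labels = _check_xy(preds, labels, 2)
    return MetricReport(
        spearman=spearman(preds, labels),
        pearson=pearson(preds, labels),
        mse=mse(preds, labels),
        n=len(preds),
    )


# ---------------------------------------------------------------------------
# splits


@dataclass(frozen=True)
class SplitPlan:
    assignment: tuple[int, ...]  # fold index per record index
    k: int
    seed: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.array(self.assignment) == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.array(self.assignment) != fold)

    def to_text(self, path: str | Path) -> None:
        lines = [f"# k={self.k} seed={self.seed}", "index\tfold"]
        lines += [f"{i}\t{f}" for i, f in enumerate(self.assignment)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "SplitPlan":
        lines = Path(path).read_text().splitlines()
        header = dict(kv.split("=") for kv in lines[0].lstrip("# ").split())
        assignment = [int(ln.split("\t")[1]) for ln in lines[2:] if ln.strip()]
        return cls(assignment=tuple(assignment), k=int(header["k"]), seed=int(header["seed"]))


def make_folds(n: int, k: int, seed: int = 0) -> SplitPlan:
    """Seeded shuffle, then balanced partition into ``k`` folds (sizes differ
    by at most one)."""
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=np.int64)
    for fold, chunk in enumerate(np.array_split(order, k)):
        assignment[chunk] = fold
    return SplitPlan(assignment=tuple(int(a) for a in assignment), k=k, seed=seed)


def make_holdout(n: int, fraction: float, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Single seeded holdout split; returns (train_indices, test_indices).

    ``fraction`` is the test share; test size is ``round(n * fraction)``.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    n_test = int(round(n * fraction))
    if n_test == 0 or n_test == n:
        raise ValueError(f"degenerate holdout: n={n}, fraction={fraction}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return np.sort(order[n_test:]), np.sort(order[:n_test])


# ---------------------------------------------------------------------------
# sequence similarity

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = 0.0
_aligner.extend_gap_score = 0.0


def similarity(a: str, b: str) -> float:
    """Global-alignment identity in [0, 1].

    Optimal global alignment with unit match score and zero mismatch/gap
    scores (i.e. the longest common subsequence length), divided by the
    longer sequence length. Symmetric.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    score = _aligner.score(a.upper().replace("T", "U"), b.upper().replace("T", "U"))
    return float(score) / max(len(a), len(b))


@dataclass
class SimilarityReport:
    ids: list[str]
    max_identity: np.ndarray  # per test record
    keep: np.ndarray  # bool per test record
    threshold: float

    @property
    def redundancy_rate(self) -> float:
        return float(np.mean(~self.keep)) if len(self.keep) else 0.0

    def kept_records(self, records: Sequence[GuideRecord]) -> list[GuideRecord]:
        return [r for r, k in zip(records, self.keep) if k]

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"# threshold={self.threshold} redundancy_rate={self.redundancy_rate:.6f}"]
        lines.append("id\tmax_identity\tkeep")
        for rid, mi, k in zip(self.ids, self.max_identity, self.keep):
            lines.append(f"{rid}\t{mi:.6f}\t{int(k)}")
        Path(path).write_text("\n".join(lines) + "\n")


def filter_by_similarity(
    test: Sequence[GuideRecord],
    train: Sequence[GuideRecord],
    threshold: float = 0.9,
) -> SimilarityReport:
    """Drop test records whose maximum identity to any training record
    reaches ``threshold``."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if not train:
        raise ValueError("empty training set")
    max_id = np.zeros(len(test))
    for i, t in enumerate(test):
        best = 0.0
        for tr in train:
            s = similarity(t.sequence, tr.sequence)
            if s > best:
                best = s
                if best >= threshold:
                    break
        max_id[i] = best
    keep = max_id < threshold
    return SimilarityReport(
        ids=[t.id for t in test], max_identity=max_id, keep=keep, threshold=threshold
    )


# ---------------------------------------------------------------------------
# permutation test


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    B: int
    seed: int


def permutation_test(
    preds: Sequence[float],
    labels: Sequence[float],
    B: int = 999,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided label-permutation test of the Spearman statistic.

    Null distribution built from ``B`` seeded label shuffles;
    ``p = (1 + #{|null| >= |observed|}) / (B + 1)``.
    """
    preds, labels = _check_xy(preds, labels, 3)
    if B < 19:
        raise ValueError("B must be >= 19")
    if np.ptp(labels) == 0:
        raise UndefinedMetricError("constant labels: statistic undefined")
    observed = spearman(preds, labels)
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    shuffled = labels.copy()
    for b in range(B):
        rng.shuffle(shuffled)
        null[b] = spearman(preds, shuffled)
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (B + 1.0)
    return PermutationResult(observed=observed, null=null, p_value=float(p), B=B, seed=seed)
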