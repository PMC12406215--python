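"""Combining correlated network predictors.

Network predictors whose ASD conformal scores correlate across individuals are
grouped by hierarchical agglomerative clustering of the predictor-by-predictor
correlation matrix (average linkage on 1 - r), cut at k = 7 for groups and
k = 2 for the two large ensembles.  Within a group, per-class conformal scores
are merged with the quadratic-mean rule

    p_merged = min(1, sqrt(3) * sqrt(mean(p_i^2)))

which is a valid merged p-value under arbitrary dependence between the inputs
(the sqrt(3) factor is the validity constant of the quadratic-mean member of
the averaging family of merging functions).  Because the rule is conservative,
merged scores are thresholded at a more liberal 0.2 instead of the 0.05 used
for single networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .conformal import decide

__all__ = [
    "PredictorGrouping",
    "MergedScore",
    "correlate_nonconformity",
    "cluster_predictors",
    "merge_pvalues",
    "ensemble_decide",
]

#: validity factor of the quadratic-mean merging rule
QUADRATIC_MEAN_FACTOR = float(np.sqrt(3.0))

DEFAULT_ALPHA_ADJUSTED = 0.2


@dataclass
class PredictorGrouping:
    """Correlation structure and partition of network predictors."""

    correlation: np.ndarray          # (n_predictors, n_predictors)
    groups: list[list[int]]          # partition of predictor indices
    k: int

    @property
    def labels(self) -> np.ndarray:
        lab = np.empty(self.correlation.shape[0], dtype=int)
        for g, members in enumerate(self.groups):
            lab[members] = g
        return lab


@dataclass
class MergedScore:
    """A merged per-class conformal score for a predictor group."""

    p_merged: float
    members: list[int] = field(default_factory=list)
    rule: str = "quadratic-mean"
    alpha_adjusted: float = DEFAULT_ALPHA_ADJUSTED


def correlate_nonconformity(scores: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of per-individual scores across predictors.

    ``scores`` is (n_individuals, n_predictors).  Constant columns have
    undefined correlations; these are set to 0 with a warning (diagonal 1).
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[0] < 3:
        raise ValueError("scores must be 2-D with at least 3 individuals")
    sd = S.std(axis=0)
    constant = sd == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant predictor column(s); correlations set to 0",
            stacklevel=2,
        )
    Z = (S - S.mean(axis=0)) / np.where(constant, 1.0, sd)
    C = Z.T @ Z / S.shape[0]
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def cluster_predictors(correlation: np.ndarray, k: int) -> list[list[int]]:
    """Cut the average-linkage tree on 1 - correlation at ``k`` clusters.

    Returns the partition as lists of predictor indices, ordered by first
    member.  Deterministic.
    """
    C = np.asarray(correlation, dtype=float)
    n = C.shape[0]
    if C.shape != (n, n) or not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation must be a symmetric square matrix")
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in 1..{n}, got {k}")
    if k == n:
        return [[i] for i in range(n)]
    D = np.clip(1.0 - C, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    groups: dict[int, list[int]] = {}
    for i, c in enumerate(raw):
        groups.setdefault(c, []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def merge_pvalues(
    p: np.ndarray | list[float],
    members: list[int] | None = None,
    alpha_adjusted: float = DEFAULT_ALPHA_ADJUSTED,
) -> MergedScore:
    """Quadratic-mean merge of possibly dependent p-values.

    p_merged = min(1, sqrt(3) * quadratic mean of the inputs).  Valid for any
    finite number of inputs under arbitrary dependence.  Note a singleton
    input is still inflated by sqrt(3): merging is not the identity on
    single-member groups.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot merge an empty list of p-values")
    if np.isnan(arr).any() or arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("p-values must lie in [0, 1]")
    merged = min(1.0, QUADRATIC_MEAN_FACTOR * float(np.sqrt(np.mean(arr**2))))
    return MergedScore(
        p_merged=merged,
        members=list(members) if members is not None else list(range(arr.size)),
        alpha_adjusted=alpha_adjusted,
    )


def merge_pvalues_matrix(P: np.ndarray, axis: int = -1) -> np.ndarray:
    """Vectorised quadratic-mean merge along ``axis`` (no validation)."""
    return np.minimum(
        1.0, QUADRATIC_MEAN_FACTOR * np.sqrt(np.mean(np.asarray(P, float) ** 2, axis=axis))
    )


def arithmetic_mean_merge(p: np.ndarray | list[float]) -> float:
    """2 x arithmetic mean merge; internal variant used only as a cross-check."""
    arr = np.asarray(p, dtype=float)
    return min(1.0, 2.0 * float(arr.mean()))


def ensemble_decide(
    merged_asd: MergedScore,
    merged_ntc: MergedScore,
    alpha_adjusted: float = DEFAULT_ALPHA_ADJUSTED,
) -> str:
    """Dual-threshold rule on merged scores at the adjusted threshold."""
    if merged_asd.members != merged_ntc.members:
        raise ValueError("merged ASD and NTC scores come from different member sets")
    return decide(merged_asd.p_merged, merged_ntc.p_merged, alpha=alpha_adjusted)
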