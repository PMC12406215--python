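"""From raw network maps to subtype-similarity features.

Three steps, applied per network and per prediction event (the transductive
contract: the unclassified individual is pooled with the reference sample
before any of them, so residuals, subtypes and features all depend on which
individual is being scored and must never be cached across individuals):

1. ``residualize`` — ordinary least squares removal of the group-level average
   connectivity (intercept) and the linear effects of age and head motion from
   each spatial unit, keeping the residuals.
2. ``extract_subtypes`` — hierarchical agglomerative clustering (average
   linkage) of individuals under the distance 1 - Pearson spatial correlation
   of their residual maps, cut at k = 5 subtypes; each subtype is summarised
   by the unweighted mean residual map of its members.
3. ``project_features`` — an individual's feature vector is the Pearson spatial
   correlation of their residual map with each subtype-average map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ResidualMaps",
    "SubtypeModel",
    "residualize",
    "extract_subtypes",
    "project_features",
]


@dataclass
class ResidualMaps:
    """Residual connectivity maps for one network, plus the design used."""

    residuals: np.ndarray            # (n_individuals, n_units)
    regressors_used: list[str]       # subset of ["intercept", "age", "motion"]

    def check(self, design: np.ndarray | None = None, atol: float = 1e-8) -> None:
        """Assert the least-squares orthogonality invariants."""
        if "intercept" in self.regressors_used:
            m = np.abs(self.residuals.mean(axis=0)).max()
            if m >= atol:
                raise AssertionError(f"residual column means not ~0 (max |mean| = {m:.2e})")
        if design is not None:
            g = np.abs(design.T @ self.residuals).max() / max(len(self.residuals), 1)
            if g >= atol * max(1.0, np.abs(design).max()):
                raise AssertionError("residuals not orthogonal to design")


def build_design(
    covariates: pd.DataFrame, regressors: tuple[str, ...] = ("age", "motion")
) -> tuple[np.ndarray, list[str]]:
    """Intercept + requested covariate columns, dropping constant regressors."""
    cols = [np.ones(len(covariates))]
    names = ["intercept"]
    for r in regressors:
        x = covariates[r].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            warnings.warn(f"regressor {r!r} is constant; dropped from the design", stacklevel=3)
            continue
        cols.append(x)
        names.append(r)
    return np.column_stack(cols), names


def ols_residuals(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Exact least-squares residuals of every column of Y on the design X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def residualize(
    maps: np.ndarray,
    covariates: pd.DataFrame,
    regressors: tuple[str, ...] = ("age", "motion"),
) -> ResidualMaps:
    """OLS residuals of per-unit connectivity on intercept + age + motion.

    ``maps`` is (n_individuals, n_units) for a single network; ``covariates``
    must align row-wise and contain the requested regressor columns.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2:
        raise ValueError("maps must be 2-D (individuals, units); pass one network at a time")
    if len(covariates) != maps.shape[0]:
        raise ValueError(
            f"covariates rows ({len(covariates)}) != individuals ({maps.shape[0]})"
        )
    X, names = build_design(covariates, regressors)
    return ResidualMaps(residuals=ols_residuals(maps, X), regressors_used=names)


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows centred and scaled to unit norm; zero-variance rows become 0.

    Returns (standardised rows, boolean mask of zero-variance rows).
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    scale = np.maximum(np.abs(X).max(axis=1), 1.0)
    degenerate = norms <= 1e-10 * scale * np.sqrt(X.shape[1])
    norms[degenerate] = 1.0
    out = Xc / norms[:, None]
    out[degenerate] = 0.0
    return out, degenerate


def pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of the rows of A with the rows of B.

    Zero-variance rows yield correlation 0 (with a warning), so degenerate
    inputs propagate as "no similarity" instead of NaN.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    Sa, da = _standardize_rows(A)
    Sb, db = _standardize_rows(B)
    if da.any() or db.any():
        warnings.warn("zero-variance map(s); their correlations set to 0", stacklevel=3)
    return np.clip(Sa @ Sb.T, -1.0, 1.0)


@dataclass
class SubtypeModel:
    """k subtype-average residual maps for one network."""

    subtype_maps: np.ndarray         # (k, n_units)
    assignments: np.ndarray          # cluster label (0..k-1) per training individual
    linkage_matrix: np.ndarray
    linkage_spec: str = "average linkage on 1 - Pearson spatial correlation"

    @property
    def k(self) -> int:
        return self.subtype_maps.shape[0]


def correlation_linkage(maps: np.ndarray) -> np.ndarray:
    """Agglomerative tree (average linkage) on 1 - Pearson correlation."""
    C = pearson_rows(maps, maps)
    D = np.clip(1.0 - C, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    return linkage(squareform(D, checks=False), method="average")

def extract_subtypes(residuals: np.ndarray | ResidualMaps, k: int = 5) -> SubtypeModel:
    """Cut the agglomerative tree at ``k`` clusters and average members.

    Deterministic: agglomerative clustering has no random initialisation.
    """
    if isinstance(residuals, ResidualMaps):
        residuals = residuals.residuals
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} individuals, got {n}")
    Z = correlation_linkage(residuals)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel clusters 0..k-1 in order of first appearance, for stable output
    order = {c: i for i, c in enumerate(pd.unique(raw))}
    labels = np.array([order[c] for c in raw])
    maps = np.vstack([residuals[labels == c].mean(axis=0) for c in range(labels.max() + 1)])
    return SubtypeModel(subtype_maps=maps, assignments=labels, linkage_matrix=Z)


def project_features(map_: np.ndarray, model: SubtypeModel) -> np.ndarray:
    """Spatial similarity of one residual map with each subtype-average map."""
    map_ = np.asarray(map_, dtype=float)
    if map_.ndim != 1 or map_.shape[0] != model.subtype_maps.shape[1]:
        raise ValueError(
            f"map has shape {map_.shape}, subtype maps expect "
            f"({model.subtype_maps.shape[1]},)"
        )
    return pearson_rows(map_[None, :], model.subtype_maps)[0]
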