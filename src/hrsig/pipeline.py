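"""The transductive scoring engine.

``transductive_scores`` runs the full per-individual pipeline: for every
target individual (UCI) and every requested network it

1. pools the UCI with the reference sample and removes, by exact OLS, the
   group-level average connectivity and the linear age and motion effects
   (recomputed for every UCI — the group mean and slopes change when the UCI
   joins the pool, so nothing is cached across individuals);
2. clusters the pooled residual maps into k = 5 connectivity subtypes and
   projects every individual onto the subtype-average maps;
3. fits the two class-weighted logistic models and computes the ASD and NTC
   conformal scores of the UCI by rank among the reference class.

The OLS step reuses the reference block of the normal equations (X'X, X'Y) and
adds the UCI's rank-one contribution — algebraically identical to refitting
from scratch, which the tests verify, but an order of magnitude faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import conformal, ensemble, features
from .synth import CohortDataset

__all__ = ["PipelineConfig", "transductive_scores", "score_dataset", "ensemble_decisions"]


@dataclass(frozen=True)
class PipelineConfig:
    """Stage parameters shared by bootstrap evaluation and validation runs."""

    networks: tuple[int, ...] | None = None      # None = all networks
    k_subtypes: int = 5
    scorer: conformal.ScorerSpec = field(default_factory=conformal.ScorerSpec)
    alpha: float = 0.05                          # single-network threshold
    alpha_ensemble: float = 0.2                  # merged-score threshold
    k_groups: int = 7
    k_ensembles: int = 2
    n_predict: int | None = None                 # prediction resample size (None = full)


def _design(cov: pd.DataFrame) -> np.ndarray:
    return np.column_stack(
        [np.ones(len(cov)), cov["age"].to_numpy(float), cov["motion"].to_numpy(float)]
    )


def transductive_scores(
    reference: CohortDataset,
    targets: CohortDataset,
    networks: np.ndarray | list[int] | None = None,
    k_subtypes: int = 5,
    scorer: conformal.ScorerSpec | None = None,
) -> np.ndarray:
    """Conformal scores of every target against the reference cohort.

    Returns an array of shape (n_targets, n_networks_requested, 2) holding
    (p_asd, p_ntc); NaN where a logistic fit failed (the individual abstains).
    """
    scorer = scorer or conformal.ScorerSpec()
    if networks is None:
        networks = np.arange(reference.n_networks)
    networks = np.asarray(networks, dtype=int)
    labels_ref = np.where(reference.is_asd, "ASD", "NTC")
    Xr = _design(reference.phenotype)
    Xt = _design(targets.phenotype)
    n_ref = reference.n_individuals
    XtXr = Xr.T @ Xr
    out = np.full((targets.n_individuals, networks.size, 2), np.nan)

    for jn, j in enumerate(networks):
        Y = reference.connectivity[:, j, :]
        XtYr = Xr.T @ Y
        for t in range(targets.n_individuals):
            xu = Xt[t]
            yu = targets.connectivity[t, j, :]
            XtX = XtXr + np.outer(xu, xu)
            XtY = XtYr + xu[:, None] * yu[None, :]
            try:
                beta = np.linalg.solve(XtX, XtY)
            except np.linalg.LinAlgError:
                beta, *_ = np.linalg.lstsq(
                    np.vstack([Xr, xu[None, :]]), np.vstack([Y, yu[None, :]]), rcond=None
                )
            R = np.empty((n_ref + 1, Y.shape[1]))
            np.subtract(Y, Xr @ beta, out=R[:n_ref])
            R[n_ref] = yu - xu @ beta
            sub = features.extract_subtypes(R, k=k_subtypes)
            F = features.pearson_rows(R, sub.subtype_maps)
            p_asd, p_ntc = conformal.conformal_scores(
                F[n_ref], F[:n_ref], labels_ref, scorer
            )
            out[t, jn, 0] = p_asd
            out[t, jn, 1] = p_ntc
    return out


def score_dataset(
    reference: CohortDataset,
    targets: CohortDataset,
    config: PipelineConfig,
    networks: np.ndarray | list[int] | None = None,
) -> pd.DataFrame:
    """Long-format per-network conformal scores and single-network decisions."""
    nets = networks if networks is not None else config.networks
    if nets is None:
        nets = np.arange(reference.n_networks)
    nets = np.asarray(nets, dtype=int)
    S = transductive_scores(
        reference, targets, nets, k_subtypes=config.k_subtypes, scorer=config.scorer
    )
    rows = []
    ids = targets.phenotype["id"].to_numpy()
    for t in range(targets.n_individuals):
        for jn, j in enumerate(nets):
            p_asd, p_ntc = S[t, jn]
            rows.append(
                {
                    "id": ids[t],
                    "predictor_id": f"network{j:02d}",
                    "p_asd": p_asd,
                    "p_ntc": p_ntc,
                    "decision": conformal.decide(p_asd, p_ntc, config.alpha)
                    if np.isfinite([p_asd, p_ntc]).all()
                    else conformal.ABSTAIN,
                }
            )
    return pd.DataFrame(rows)


def loo_scores(
    dataset: CohortDataset,
    networks: np.ndarray | list[int] | None = None,
    k_subtypes: int = 5,
    scorer: conformal.ScorerSpec | None = None,
) -> np.ndarray:
    """Leave-one-out transductive scores of every individual vs the rest.

    Shape (n, n_networks_requested, 2).  Used to estimate the correlation
    structure between network predictors on a reference cohort.
    """
    n = dataset.n_individuals
    if networks is None:
        networks = np.arange(dataset.n_networks)
    networks = np.asarray(networks, dtype=int)
    out = np.full((n, networks.size, 2), np.nan)
    all_idx = np.arange(n)
    for i in range(n):
        rest = dataset.subset(np.delete(all_idx, i))
        uci = dataset.subset([i])
        out[i] = transductive_scores(rest, uci, networks, k_subtypes, scorer)[0]
    return out


def ensemble_decisions(
    scores: np.ndarray,
    members: list[int],
    alpha_ensemble: float = 0.2,
) -> pd.DataFrame:
    """Merged per-class scores and decisions for one predictor group.

    ``scores`` is (n_targets, n_networks_scored, 2); ``members`` indexes its
    network axis.  A target with any undefined member score abstains.
    """
    sub = scores[:, members, :]
    ok = np.isfinite(sub).all(axis=(1, 2))
    merged_asd = np.where(ok, ensemble.merge_pvalues_matrix(sub[:, :, 0]), np.nan)
    merged_ntc = np.where(ok, ensemble.merge_pvalues_matrix(sub[:, :, 1]), np.nan)
    decisions = [
        conformal.decide(a, c, alpha_ensemble) if f else conformal.ABSTAIN
        for a, c, f in zip(merged_asd, merged_ntc, ok)
    ]
    return pd.DataFrame(
        {"p_asd": merged_asd, "p_ntc": merged_ntc, "decision": decisions}
    )
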