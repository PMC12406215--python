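"""Within-site propensity-score matching of cases to controls.

Cases (ASD) and controls (NTC) are matched on age and head motion separately
within each acquisition site, by greedy nearest-neighbour pairing on the
propensity-score logit, without replacement.  The propensity model is a
main-effects logistic regression of case status on age and motion; sites where
the model does not converge (e.g. perfect separation in tiny sites) fall back
to Euclidean nearest-neighbour matching on standardised covariates.

Matching without replacement yields equal-sized groups per site; pairs farther
apart than the caliper, and sites containing only one diagnostic group, are
excluded rather than matched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synth import CohortDataset

__all__ = ["MatchResult", "propensity_match", "greedy_match"]

#: default caliper as a multiple of the within-site SD of the propensity logit
DEFAULT_CALIPER_SD = 0.2


@dataclass
class MatchResult:
    """Outcome of within-site matching.

    matched_ids  : list of (case_id, control_id) pairs
    excluded_ids : ids not retained in the analysis sample
    propensity   : per-individual fitted probability of case status
                   (NaN where the fallback distance matcher was used)
    balance      : standardised mean differences per covariate, before/after
    """

    matched_ids: list[tuple[str, str]]
    excluded_ids: list[str]
    propensity: pd.Series
    balance: pd.DataFrame
    fallback_sites: list[str] = field(default_factory=list)

    @property
    def matched_flat(self) -> list[str]:
        return [i for pair in self.matched_ids for i in pair]

    def select(self, dataset: CohortDataset) -> CohortDataset:
        """Subset ``dataset`` to the matched individuals (original row order)."""
        keep = set(self.matched_flat)
        idx = [i for i, x in enumerate(dataset.phenotype["id"]) if x in keep]
        return dataset.subset(idx)


def greedy_match(
    case_scores: pd.Series,
    control_scores: pd.Series,
    caliper: float,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Greedy nearest-neighbour pairing without replacement on a 1-D score.

    Cases are processed in descending score order (ties broken by smallest id);
    each takes the closest still-available control, provided the absolute score
    difference is <= ``caliper``.  Returns (pairs, unmatched ids).
    """
    if caliper < 0:
        raise ValueError("caliper must be >= 0")
    case_order = sorted(case_scores.items(), key=lambda kv: (-kv[1], kv[0]))
    avail = dict(sorted(control_scores.items()))
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for cid, cs in case_order:
        if not avail:
            unmatched.append(cid)
            continue
        best_id = min(avail, key=lambda k: (abs(avail[k] - cs), k))
        if abs(avail[best_id] - cs) <= caliper:
            pairs.append((cid, best_id))
            del avail[best_id]
        else:
            unmatched.append(cid)
    unmatched.extend(avail)
    return pairs, unmatched


def _smd(x: pd.Series, case: np.ndarray) -> float:
    a, b = x[case], x[~case]
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0 or np.isnan(pooled):
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def _fit_propensity(covs: pd.DataFrame, case: np.ndarray) -> np.ndarray | None:
    """Fitted P(case | age, motion), or None if the fit is unusable."""
    X = sm.add_constant(covs[["age", "motion"]].to_numpy(), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(case.astype(float), X).fit(disp=0, maxiter=100)
        if not res.mle_retvals.get("converged", False):
            return None
        p = np.asarray(res.predict(X))
    except Exception:
        return None
    eps = 1e-12
    if not np.isfinite(p).all() or p.min() < eps or p.max() > 1 - eps:
        # saturated fit (separation): logits unusable as a matching scale
        return None
    return p


def propensity_match(
    dataset: CohortDataset,
    caliper: float | None = None,
) -> MatchResult:
    """Match cases to controls on age and motion within each site.

    ``caliper`` is an absolute distance on the propensity-logit scale; if None
    it defaults per site to 0.2 x SD of the logit (the same multiplier is
    applied to the Euclidean distances of the fallback matcher).
    """
    if dataset.n_individuals == 0:
        raise ValueError("cannot match an empty dataset")
    phen = dataset.phenotype
    propensity = pd.Series(np.nan, index=phen["id"], name="propensity")
    pairs: list[tuple[str, str]] = []
    excluded: list[str] = []
    fallback_sites: list[str] = []

    for site, sub in phen.groupby("site", sort=True):
        case = (sub["diagnosis"] == "ASD").to_numpy()
        if case.all() or (~case).all():
            warnings.warn(
                f"site {site!r} has only one diagnostic group; all "
                f"{len(sub)} individuals excluded",
                stacklevel=2,
            )
            excluded.extend(sub["id"])
            continue
        p = _fit_propensity(sub, case)
        if p is not None:
            propensity.loc[sub["id"]] = p
            score = pd.Series(np.log(p / (1 - p)), index=sub["id"])
        else:
            fallback_sites.append(str(site))
            z = sub[["age", "motion"]].apply(
                lambda c: (c - c.mean()) / (c.std(ddof=1) or 1.0)
            )
            # 1-D greedy matcher needs a scalar score; project standardised
            # covariates on their first principal axis (deterministic sign)
            zz = z.to_numpy()
            _, _, vt = np.linalg.svd(zz - zz.mean(0), full_matrices=False)
            axis = vt[0] * np.sign(vt[0][np.argmax(np.abs(vt[0]))])
            score = pd.Series(zz @ axis, index=sub["id"])
        sd = float(score.std(ddof=1))
        cal = caliper if caliper is not None else DEFAULT_CALIPER_SD * (sd if sd > 0 else 1.0)
        site_pairs, site_unmatched = greedy_match(
            score[sub.loc[case, "id"]], score[sub.loc[~case, "id"]], cal
        )
        pairs.extend(site_pairs)
        excluded.extend(site_unmatched)

    matched = {i for pr in pairs for i in pr}
    keep = phen["id"].isin(matched).to_numpy()
    case_all = (phen["diagnosis"] == "ASD").to_numpy()
    balance = pd.DataFrame(
        {
            "smd_before": [_smd(phen[c], case_all) for c in ("age", "motion")],
            "smd_after": [
                _smd(phen.loc[keep, c], case_all[keep]) if keep.any() else np.nan
                for c in ("age", "motion")
            ],
        },
        index=pd.Index(["age", "motion"], name="covariate"),
    )
    return MatchResult(
        matched_ids=pairs,
        excluded_ids=excluded,
        propensity=propensity,
        balance=balance,
        fallback_sites=fallback_sites,
    )
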