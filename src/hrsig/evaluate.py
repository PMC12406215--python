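"""Performance assessment, bootstrap estimation, and population-risk translation.

The predictor only ever issues positive (ASD) flags, so abstentions on true
cases count as false negatives and abstentions on true controls as true
negatives; that accounting is what makes sensitivity = tp / n_cases and
specificity = tn / n_controls for an abstaining classifier.

Metrics with a zero denominator are reported as missing (NaN), never as 0, and
bootstrap repetitions with an undefined PPV are excluded from the PPV summary
with the exclusion count reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import features, pipeline
from .synth import CohortDataset

__all__ = [
    "ConfusionTable",
    "PerformanceReport",
    "PopulationRisk",
    "FlaggedSummary",
    "confusion_metrics",
    "bootstrap_evaluate",
    "population_ppv",
    "covariate_audit",
    "characterize_flagged",
]

METRICS = ("sensitivity", "specificity", "ppv", "rr", "or_", "dice")
PERCENTILES = (5, 25, 75, 95)


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_decisions(cls, is_case: np.ndarray, flagged: np.ndarray) -> "ConfusionTable":
        is_case = np.asarray(is_case, dtype=bool)
        flagged = np.asarray(flagged, dtype=bool)
        return cls(
            tp=int((flagged & is_case).sum()),
            fp=int((flagged & ~is_case).sum()),
            tn=int((~flagged & ~is_case).sum()),
            fn=int((~flagged & is_case).sum()),
        )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(t: ConfusionTable) -> dict[str, float]:
    """Sensitivity, specificity, PPV, risk ratio, odds ratio, Sorensen-Dice.

    RR is the risk among flagged vs non-flagged individuals; OR the
    corresponding odds ratio.  Zero denominators propagate as NaN.
    """
    risk_flagged = _ratio(t.tp, t.tp + t.fp)
    risk_unflagged = _ratio(t.fn, t.fn + t.tn)
    return {
        "sensitivity": _ratio(t.tp, t.tp + t.fn),
        "specificity": _ratio(t.tn, t.tn + t.fp),
        "ppv": risk_flagged,
        "rr": _ratio(risk_flagged, risk_unflagged)
        if np.isfinite(risk_flagged) and np.isfinite(risk_unflagged)
        else float("nan"),
        "or_": _ratio(t.tp * t.tn, t.fp * t.fn),
        "dice": _ratio(2 * t.tp, 2 * t.tp + t.fp + t.fn),
        "n_flagged": float(t.tp + t.fp),
    }


@dataclass(frozen=True)
class PopulationRisk:
    """Prevalence-adjusted risk conferred by a positive flag."""

    prevalence: float
    adjusted_ppv: float
    fold_increase: float
    flagged_fraction: float          # total fraction of the population flagged
    false_flag_fraction: float       # (1 - specificity) * (1 - prevalence)


def population_ppv(
    sensitivity: float, specificity: float, prevalence: float = 1.0 / 90.0
) -> PopulationRisk:
    """Translate case-control sensitivity/specificity to population risk.

    adjusted_ppv = sens*prev / (sens*prev + (1-spec)*(1-prev))  (Bayes).
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    true_flag = sensitivity * prevalence
    false_flag = (1.0 - specificity) * (1.0 - prevalence)
    flagged = true_flag + false_flag
    adjusted = true_flag / flagged if flagged > 0 else float("nan")
    return PopulationRisk(
        prevalence=prevalence,
        adjusted_ppv=adjusted,
        fold_increase=adjusted / prevalence if prevalence > 0 else float("nan"),
        flagged_fraction=flagged,
        false_flag_fraction=false_flag,
    )


@dataclass
class PerformanceReport:
    """Per-repetition bootstrap metrics and their summary."""

    per_rep: pd.DataFrame            # one row per repetition
    n_ppv_excluded: int = 0          # repetitions with undefined PPV
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Median and 5/25/75/95 percentile bands across repetitions."""
        cols = [c for c in self.per_rep.columns if c != "rep"]
        rows = {}
        for c in cols:
            x = self.per_rep[c].dropna().to_numpy()
            if x.size == 0:
                rows[c] = {"median": np.nan, **{f"p{q}": np.nan for q in PERCENTILES},
                           "n_reps": 0}
                continue
            rows[c] = {
                "median": float(np.median(x)),
                **{f"p{q}": float(np.percentile(x, q)) for q in PERCENTILES},
                "n_reps": int(x.size),
            }
        return pd.DataFrame(rows).T

    def median(self, metric: str) -> float:
        return float(self.per_rep[metric].median())


def bootstrap_evaluate(
    dataset: CohortDataset,
    config: pipeline.PipelineConfig,
    members: list[int],
    B: int = 100,
    seed: int = 0,
) -> PerformanceReport:
    """Bootstrap performance of one (possibly single-network) predictor group.

    Each repetition draws two independent with-replacement resamples of the
    full dataset — one reference, one prediction — runs the transductive
    pipeline, merges the member networks' scores (single members are decided
    at ``config.alpha`` without merging), and records the confusion metrics
    plus the correlation of the merged ASD score with age and motion (the
    covariate audit).  Deterministic given ``seed``.

    ``config.n_predict`` caps the number of prediction individuals scored per
    repetition; metrics are computed on the scored subset.
    """
    rng = np.random.default_rng(seed)
    n = dataset.n_individuals
    n_pred = min(config.n_predict or n, n)
    rows = []
    n_excluded = 0
    for b in range(B):
        ref = dataset.subset(rng.integers(0, n, size=n))
        pred = dataset.subset(rng.integers(0, n, size=n)[:n_pred])
        S = pipeline.transductive_scores(
            ref, pred, members, k_subtypes=config.k_subtypes, scorer=config.scorer
        )
        if len(members) == 1:
            dec = pipeline.ensemble_decisions(S, [0], config.alpha)
        else:
            dec = pipeline.ensemble_decisions(
                S, list(range(len(members))), config.alpha_ensemble
            )
        flagged = (dec["decision"] == "ASD").to_numpy()
        table = ConfusionTable.from_decisions(pred.is_asd, flagged)
        row = {"rep": b, **confusion_metrics(table)}
        if np.isnan(row["ppv"]):
            n_excluded += 1
        score = dec["p_asd"].to_numpy()
        for cov in ("age", "motion"):
            x = pred.phenotype[cov].to_numpy()
            ok = np.isfinite(score)
            if ok.sum() > 2 and np.std(score[ok]) > 0 and np.std(x[ok]) > 0:
                row[f"r_{cov}"] = float(np.corrcoef(score[ok], x[ok])[0, 1])
            else:
                row[f"r_{cov}"] = np.nan
        rows.append(row)
    return PerformanceReport(
        per_rep=pd.DataFrame(rows),
        n_ppv_excluded=n_excluded,
        meta={"B": B, "members": list(members), "n_predict": n_pred, "seed": seed},
    )


def covariate_audit(audit: pd.DataFrame) -> pd.DataFrame:
    """Summarise per-bootstrap score-covariate correlations.

    ``audit`` is long-format with columns rep, score and one column per
    covariate.  Returns, per covariate, the per-repetition Pearson r
    summarised by median and percentile bands; repetitions with a constant
    score are excluded (correlation undefined).
    """
    covs = [c for c in audit.columns if c not in ("rep", "score")]
    per_rep = {}
    for cov in covs:
        rs = []
        for _, grp in audit.groupby("rep"):
            s = grp["score"].to_numpy()
            x = grp[cov].to_numpy()
            ok = np.isfinite(s) & np.isfinite(x)
            if ok.sum() > 2 and np.std(s[ok]) > 0 and np.std(x[ok]) > 0:
                rs.append(float(np.corrcoef(s[ok], x[ok])[0, 1]))
        per_rep[cov] = np.asarray(rs)
    rows = {}
    for cov, rs in per_rep.items():
        if rs.size == 0:
            rows[cov] = {"median": np.nan, **{f"p{q}": np.nan for q in PERCENTILES},
                         "n_reps": 0}
        else:
            rows[cov] = {
                "median": float(np.median(rs)),
                **{f"p{q}": float(np.percentile(rs, q)) for q in PERCENTILES},
                "n_reps": int(rs.size),
            }
    return pd.DataFrame(rows).T


@dataclass
class FlaggedSummary:
    """Residual-connectivity and severity profile of flagged individuals."""

    status: str                                  # "ok" or "no individuals flagged"
    n_flagged: int
    mean_residual_maps: dict[int, np.ndarray]    # network -> mean residual map
    frac_below_average: dict[int, float]         # network -> fraction of units < 0
    severity_r: float = float("nan")
    severity_p: float = float("nan")


def characterize_flagged(
    dataset: CohortDataset,
    flagged: np.ndarray,
    scores: np.ndarray | None = None,
    networks: list[int] | None = None,
) -> FlaggedSummary:
    """Characterise the individuals flagged by a predictor.

    For each requested network, the mean residual map (after the usual
    intercept + age + motion regression over the whole sample) of the flagged
    individuals, and the fraction of its units below the sample average
    (residual < 0).  If per-individual ASD conformal ``scores`` are given and
    severity is available, also their Pearson correlation with severity.
    """
    flagged = np.asarray(flagged, dtype=bool)
    networks = list(networks) if networks is not None else list(range(dataset.n_networks))
    sev_r = sev_p = float("nan")
    if scores is not None:
        sev = dataset.phenotype["severity"].to_numpy(float)
        s = np.asarray(scores, dtype=float)
        ok = np.isfinite(sev) & np.isfinite(s)
        if ok.sum() > 2 and np.std(s[ok]) > 0 and np.std(sev[ok]) > 0:
            sev_r, sev_p = stats.pearsonr(sev[ok], s[ok])
    if not flagged.any():
        return FlaggedSummary(
            status="no individuals flagged",
            n_flagged=0,
            mean_residual_maps={},
            frac_below_average={},
            severity_r=sev_r,
            severity_p=sev_p,
        )
    maps: dict[int, np.ndarray] = {}
    frac: dict[int, float] = {}
    for j in networks:
        res = features.residualize(dataset.connectivity[:, j, :], dataset.phenotype)
        m = res.residuals[flagged].mean(axis=0)
        maps[j] = m
        frac[j] = float(np.mean(m < 0))
    return FlaggedSummary(
        status="ok",
        n_flagged=int(flagged.sum()),
        mean_residual_maps=maps,
        frac_below_average=frac,
        severity_r=float(sev_r),
        severity_p=float(sev_p),
    )
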