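"""Model/results interface over the full high-risk-signature workflow.

``HighRiskSignature`` is built from a :class:`~hrsig.synth.CohortDataset` (or
raw arrays) and ``fit()`` runs the complete discovery workflow:

1. within-site propensity matching of cases to controls on age and motion;
2. leave-one-out transductive conformal scoring of the matched cohort for
   every network predictor;
3. clustering of the predictor correlation matrix into groups (k = 7) and
   ensembles (k = 2);
4. bootstrap evaluation (reference/prediction resample pairs) of each
   ensemble, with the high-risk signature (HRS) taken as the ensemble with
   the higher bootstrap-median PPV.

The returned :class:`HighRiskSignatureResults` carries the grouping, the
bootstrap distributions, the covariate audit, and ``predict()`` for scoring an
independent cohort transductively against the matched discovery sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ensemble as ens
from . import evaluate, matching, pipeline
from .synth import CohortDataset

__all__ = ["HighRiskSignature", "HighRiskSignatureResults"]


class HighRiskSignature:
    """High-confidence case predictor over network connectivity maps.

    Parameters
    ----------
    cohort : CohortDataset
        Discovery cohort (connectivity + phenotype).
    config : PipelineConfig, optional
        Stage parameters (thresholds, k's, scorer, prediction-set size).
    match : bool
        Whether to propensity-match the cohort before fitting (default True).
    caliper : float, optional
        Matching caliper on the propensity-logit scale (None = 0.2 SD).
    """

    def __init__(
        self,
        cohort: CohortDataset,
        config: pipeline.PipelineConfig | None = None,
        match: bool = True,
        caliper: float | None = None,
    ) -> None:
        self.cohort = cohort
        self.config = config or pipeline.PipelineConfig()
        self.match = match
        self.caliper = caliper

    @classmethod
    def from_arrays(
        cls, connectivity: np.ndarray, phenotype: pd.DataFrame, **kwargs
    ) -> "HighRiskSignature":
        return cls(CohortDataset(connectivity=connectivity, phenotype=phenotype), **kwargs)

    def fit(self, B: int = 100, seed: int = 0) -> "HighRiskSignatureResults":
        cfg = self.config
        if self.match:
            match_result = matching.propensity_match(self.cohort, caliper=self.caliper)
            matched = match_result.select(self.cohort)
        else:
            match_result = None
            matched = self.cohort
        nets = np.asarray(
            cfg.networks if cfg.networks is not None else range(matched.n_networks),
            dtype=int,
        )

        loo = pipeline.loo_scores(
            matched, nets, k_subtypes=cfg.k_subtypes, scorer=cfg.scorer
        )
        corr = ens.correlate_nonconformity(loo[:, :, 0])
        groups = ens.cluster_predictors(corr, min(cfg.k_groups, nets.size))
        ensembles = ens.cluster_predictors(corr, min(cfg.k_ensembles, nets.size))

        reports = []
        for e, members in enumerate(ensembles):
            rep = evaluate.bootstrap_evaluate(
                matched, cfg, [int(nets[m]) for m in members], B=B, seed=seed + e
            )
            reports.append(rep)
        medians = [r.median("ppv") for r in reports]
        hrs_index = int(np.nanargmax(medians))
        return HighRiskSignatureResults(
            model=self,
            matched=matched,
            match_result=match_result,
            networks=nets,
            loo_scores=loo,
            predictor_correlation=corr,
            groups=[[int(nets[m]) for m in g] for g in groups],
            ensembles=[[int(nets[m]) for m in g] for g in ensembles],
            ensemble_reports=reports,
            hrs_index=hrs_index,
        )


@dataclass
class HighRiskSignatureResults:
    """Fitted high-risk-signature results."""

    model: HighRiskSignature
    matched: CohortDataset
    match_result: matching.MatchResult | None
    networks: np.ndarray
    loo_scores: np.ndarray
    predictor_correlation: np.ndarray
    groups: list[list[int]]
    ensembles: list[list[int]]
    ensemble_reports: list[evaluate.PerformanceReport]
    hrs_index: int
    _extra: dict = field(default_factory=dict)

    @property
    def hrs_members(self) -> list[int]:
        return self.ensembles[self.hrs_index]

    @property
    def hrs_report(self) -> evaluate.PerformanceReport:
        return self.ensemble_reports[self.hrs_index]

    def predict(
        self,
        cohort: CohortDataset,
        members: list[int] | None = None,
        return_scores: bool = False,
    ) -> pd.DataFrame | tuple[pd.DataFrame, np.ndarray]:
        """Score an independent cohort against the matched discovery sample.

        Every individual is scored transductively (pooled one at a time with
        the discovery cohort); member scores are merged and thresholded at the
        adjusted ensemble threshold.  Returns one row per individual with the
        merged scores, the decision, and the true diagnosis.
        """
        members = members if members is not None else self.hrs_members
        cfg = self.model.config
        S = pipeline.transductive_scores(
            self.matched, cohort, members, k_subtypes=cfg.k_subtypes, scorer=cfg.scorer
        )
        alpha = cfg.alpha if len(members) == 1 else cfg.alpha_ensemble
        dec = pipeline.ensemble_decisions(S, list(range(len(members))), alpha)
        dec.insert(0, "id", cohort.phenotype["id"].to_numpy())
        dec["diagnosis"] = cohort.phenotype["diagnosis"].to_numpy()
        dec["mean_p_asd"] = S[:, :, 0].mean(axis=1)  # graded ASD conformality
        if return_scores:
            return dec, S
        return dec

    def population_risk(
        self, prevalence: float = 1.0 / 90.0, report: evaluate.PerformanceReport | None = None
    ) -> evaluate.PopulationRisk:
        """Prevalence-adjusted risk from the bootstrap-median sens/spec."""
        rep = report or self.hrs_report
        return evaluate.population_ppv(
            rep.median("sensitivity"), rep.median("specificity"), prevalence
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = ["High-risk signature fit", "=" * 24]
        if self.match_result is not None:
            lines.append(
                f"matched sample: {self.matched.n_individuals} individuals "
                f"({len(self.match_result.matched_ids)} pairs, "
                f"{len(self.match_result.excluded_ids)} excluded)"
            )
        lines.append(f"networks scored: {list(map(int, self.networks))}")
        lines.append(f"groups (k={len(self.groups)}): {self.groups}")
        for e, (members, rep) in enumerate(zip(self.ensembles, self.ensemble_reports)):
            tag = "  <- HRS" if e == self.hrs_index else ""
            s = rep.summary()
            lines.append(
                f"ensemble {e + 1} {members}: "
                f"median PPV={s.loc['ppv', 'median']:.3f} "
                f"sens={s.loc['sensitivity', 'median']:.3f} "
                f"spec={s.loc['specificity', 'median']:.3f} "
                f"(B={rep.meta['B']}, {rep.n_ppv_excluded} PPV-undefined reps){tag}"
            )
        pr = self.population_risk()
        lines.append(
            f"population (prev={pr.prevalence:.4f}): adjusted PPV={pr.adjusted_ppv:.3f}, "
            f"fold increase={pr.fold_increase:.1f}, flagged fraction={pr.flagged_fraction:.4f}"
        )
        return "\n".join(lines)

    # ----- plotting ---------------------------------------------------------

    def plot_bootstrap(self, metric: str = "ppv", ax=None):
        """Median + percentile-band plot of a bootstrap metric per ensemble."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        for e, rep in enumerate(self.ensemble_reports):
            s = rep.summary().loc[metric]
            ax.errorbar(
                [e + 1],
                [s["median"]],
                yerr=[[s["median"] - s["p5"]], [s["p95"] - s["median"]]],
                fmt="o",
                capsize=4,
                label=f"ensemble {e + 1}",
            )
        ax.set_xticks(range(1, len(self.ensemble_reports) + 1))
        ax.set_xlabel("ensemble")
        ax.set_ylabel(metric)
        ax.legend()
        return ax

    def plot_audit(self, ax=None):
        """Covariate-audit bands (score vs age/motion correlations)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        rep = self.hrs_report
        for i, cov in enumerate(("age", "motion")):
            x = rep.per_rep[f"r_{cov}"].dropna().to_numpy()
            if x.size == 0:
                continue
            med = np.median(x)
            ax.errorbar(
                [i],
                [med],
                yerr=[[med - np.percentile(x, 5)], [np.percentile(x, 95) - med]],
                fmt="o",
                capsize=4,
            )
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xticks([0, 1], ["age", "motion"])
        ax.set_ylabel("r(ASD score, covariate)")
        return ax
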