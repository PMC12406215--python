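"""Reference study configurations: end-to-end synthetic experiments.

These functions bundle the package's canonical desk-scale experiments so that
tests, the acceptance script and users run exactly the same procedures:

* ``planted_signature_study`` — discovery + replication cohorts with a planted
  minority carrier signature; fits the high-risk signature on the matched
  discovery cohort, bootstraps its performance, and validates it on the
  independently drawn replication cohort.
* ``null_calibration_study``  — a cohort with no planted signal; leave-one-out
  conformal scoring of every individual checks the validity (calibration) of
  the conformal scores.
* ``null_audit_study``        — bootstrap covariate audit on a null cohort.

Problem sizes are desk-scale: cohorts of a few hundred individuals and a few
dozen bootstrap repetitions, chosen so a full study runs in minutes on one
CPU.  Sizes are parameters, so larger runs are one call away.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import conformal, evaluate, matching, pipeline
from .model import HighRiskSignature
from .synth import GeneratorConfig, generate_cohort

__all__ = ["planted_signature_study", "null_calibration_study", "null_audit_study"]


def _spawn(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31, derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def planted_signature_study(
    seed: int = 0,
    n_per_site_per_group: int = 20,
    n_sites: int = 10,
    n_networks: int = 18,
    n_units: int = 200,
    carrier_fraction: float = 0.1,
    signature_networks: tuple[int, ...] = tuple(range(9)),
    signature_shift: float = -0.3,
    B: int = 25,
    n_predict: int = 100,
) -> dict:
    """Discovery/replication recovery of a planted high-risk signature.

    Generates a multi-site discovery cohort in which 10% of cases carry an
    underconnectivity signature across half the networks, fits the full
    workflow (matching, per-network conformal prediction, 2-ensemble
    clustering, bootstrap evaluation), then scores an independently generated
    replication cohort against the matched discovery sample.
    """
    s_disc, s_rep, s_fit = _spawn(seed, 3)
    cfg = GeneratorConfig(
        n_per_site_per_group=n_per_site_per_group,
        n_sites=n_sites,
        n_networks=n_networks,
        n_units=n_units,
        carrier_fraction=carrier_fraction,
        signature_networks=signature_networks,
        signature_shift=signature_shift,
        seed=s_disc,
    )
    discovery = generate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = HighRiskSignature(
            discovery, config=pipeline.PipelineConfig(n_predict=n_predict)
        ).fit(B=B, seed=s_fit)

        replication = generate_cohort(cfg.replicate(s_rep))
        rep_matched = matching.propensity_match(replication).select(replication)
        pred = results.predict(rep_matched)

    flagged = (pred["decision"] == "ASD").to_numpy()
    table = evaluate.ConfusionTable.from_decisions(rep_matched.is_asd, flagged)
    rep_metrics = evaluate.confusion_metrics(table)
    pop = evaluate.population_ppv(rep_metrics["sensitivity"], rep_metrics["specificity"])

    hrs_summary = results.hrs_report.summary()
    # severity is audited against the mean per-network ASD conformality (the
    # capped merged score saturates at 1 and carries no graded information)
    flagged_summary = evaluate.characterize_flagged(
        rep_matched,
        flagged,
        scores=pred["mean_p_asd"].to_numpy(),
        networks=list(signature_networks),
    )
    carriers = rep_matched.phenotype["carrier"].to_numpy(bool)
    return {
        "config": cfg,
        "results": results,
        "replication": rep_matched,
        "prediction": pred,
        "confusion": table,
        "hrs_members": results.hrs_members,
        "signature_in_hrs": sorted(set(results.hrs_members) & set(signature_networks)),
        "discovery_ppv_median": float(hrs_summary.loc["ppv", "median"]),
        "discovery_ppv_band": (
            float(hrs_summary.loc["ppv", "p5"]),
            float(hrs_summary.loc["ppv", "p95"]),
        ),
        "discovery_sensitivity_median": float(hrs_summary.loc["sensitivity", "median"]),
        "discovery_specificity_median": float(hrs_summary.loc["specificity", "median"]),
        "replication_metrics": rep_metrics,
        "replication_n_flagged": int(flagged.sum()),
        "replication_carriers_flagged": int(carriers[flagged].sum()),
        "population_risk": pop,
        "flagged_summary": flagged_summary,
    }


def null_calibration_study(
    seed: int = 0,
    n_per_site_per_group: int = 50,
    n_sites: int = 6,
    n_units: int = 200,
    network: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Conformal validity on a cohort with no planted signal.

    Every individual is scored leave-one-out against the rest on a single
    network predictor; under exchangeability the NTC conformal scores of true
    controls are (super)uniform and the ASD-prediction rate among them stays
    at or below the critical threshold.
    """
    cfg = GeneratorConfig(
        n_per_site_per_group=n_per_site_per_group,
        n_sites=n_sites,
        n_networks=2,
        n_units=n_units,
        carrier_fraction=0.0,
        signature_networks=(),
        signature_shift=0.0,
        seed=_spawn(seed, 1)[0],
    )
    cohort = generate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = pipeline.loo_scores(cohort, [network])[:, 0, :]
    decisions = np.array(
        [
            conformal.decide(a, c, alpha) if np.isfinite([a, c]).all() else conformal.ABSTAIN
            for a, c in scores
        ]
    )
    ntc = ~cohort.is_asd
    return {
        "config": cfg,
        "scores": scores,
        "p_ntc_true_ntc": scores[ntc, 1],
        "asd_rate_in_ntc": float((decisions[ntc] == "ASD").mean()),
        "n_ntc": int(ntc.sum()),
        "alpha": alpha,
    }


def null_audit_study(
    seed: int = 0,
    n_per_site_per_group: int = 50,
    n_sites: int = 6,
    n_units: int = 200,
    network: int = 0,
    B: int = 30,
    n_predict: int = 80,
) -> dict:
    """Bootstrap covariate audit of ASD conformal scores on a null cohort."""
    s_gen, s_boot = _spawn(seed, 2)
    cfg = GeneratorConfig(
        n_per_site_per_group=n_per_site_per_group,
        n_sites=n_sites,
        n_networks=2,
        n_units=n_units,
        carrier_fraction=0.0,
        signature_networks=(),
        signature_shift=0.0,
        seed=s_gen,
    )
    cohort = generate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = evaluate.bootstrap_evaluate(
            cohort,
            pipeline.PipelineConfig(n_predict=n_predict),
            members=[network],
            B=B,
            seed=s_boot,
        )
    summary = report.summary()
    return {
        "config": cfg,
        "report": report,
        "audit": {
            cov: {
                "median": float(summary.loc[f"r_{cov}", "median"]),
                "p5": float(summary.loc[f"r_{cov}", "p5"]),
                "p95": float(summary.loc[f"r_{cov}", "p95"]),
            }
            for cov in ("age", "motion")
        },
    }
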