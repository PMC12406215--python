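"""Confusion metrics, population-risk translation, bootstrap and audits."""

import numpy as np
import pandas as pd
import pytest

from hrsig import (
    ConfusionTable,
    GeneratorConfig,
    PipelineConfig,
    bootstrap_evaluate,
    characterize_flagged,
    confusion_metrics,
    covariate_audit,
    generate_cohort,
    population_ppv,
)


class TestConfusionMetrics:
    def test_replication_style_counts(self):
        """212 cases / 212 controls, 10 flagged of whom 9 are cases."""
        m = confusion_metrics(ConfusionTable(tp=9, fp=1, tn=211, fn=203))
        assert m["ppv"] == pytest.approx(0.90)
        assert m["sensitivity"] == pytest.approx(9 / 212)
        assert m["specificity"] == pytest.approx(211 / 212)

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionTable(tp=50, fp=0, tn=50, fn=0))
        assert m["ppv"] == m["sensitivity"] == m["specificity"] == m["dice"] == 1.0

    def test_random_tables_match_direct_arithmetic(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 50, size=4))
            m = confusion_metrics(ConfusionTable(tp, fp, tn, fn))
            assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
            assert m["specificity"] == pytest.approx(tn / (tn + fp))
            assert m["ppv"] == pytest.approx(tp / (tp + fp))
            assert m["rr"] == pytest.approx((tp / (tp + fp)) / (fn / (fn + tn)))
            assert m["or_"] == pytest.approx(tp * tn / (fp * fn))
            assert m["dice"] == pytest.approx(2 * tp / (2 * tp + fp + fn))
            # identity: dice is the harmonic mean of ppv and sensitivity
            assert m["dice"] == pytest.approx(
                2 * m["ppv"] * m["sensitivity"] / (m["ppv"] + m["sensitivity"])
            )

    def test_zero_denominators_yield_missing_not_zero(self):
        m = confusion_metrics(ConfusionTable(tp=0, fp=0, tn=10, fn=5))
        assert np.isnan(m["ppv"]) and np.isnan(m["or_"])
        assert m["sensitivity"] == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTable(tp=-1, fp=0, tn=0, fn=0)

    def test_from_decisions_abstention_accounting(self):
        is_case = np.array([True, True, False, False])
        flagged = np.array([True, False, False, False])  # one abstained case
        t = ConfusionTable.from_decisions(is_case, flagged)
        assert (t.tp, t.fp, t.tn, t.fn) == (1, 0, 2, 1)


class TestPopulationPPV:
    def test_printed_replication_arithmetic(self):
        pr = population_ppv(9 / 212, 211 / 212, 1 / 90)
        assert pr.adjusted_ppv == pytest.approx(9 / 98)       # 9.2% unrounded
        assert round(100 * pr.adjusted_ppv, 1) == 9.2
        assert pr.fold_increase >= 7

    def test_case_control_identity_at_half_prevalence(self):
        sens, spec = 0.3, 0.9
        pr = population_ppv(sens, spec, prevalence=0.5)
        assert pr.adjusted_ppv == pytest.approx(sens / (sens + 1 - spec))

    def test_monte_carlo_population_oracle(self, rng):
        sens, spec, prev = 9 / 212, 211 / 212, 1 / 90
        n = 10**6
        case = rng.uniform(size=n) < prev
        flag = np.where(case, rng.uniform(size=n) < sens, rng.uniform(size=n) < 1 - spec)
        empirical = case[flag].mean()
        pr = population_ppv(sens, spec, prev)
        se = np.sqrt(empirical * (1 - empirical) / flag.sum())
        assert abs(empirical - pr.adjusted_ppv) < 3 * se

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            population_ppv(1.2, 0.9)


def _null_config(seed=13):
    return GeneratorConfig(
        n_per_site_per_group=15, n_sites=2, n_networks=2, n_units=60,
        carrier_fraction=0.0, signature_networks=(), signature_shift=0.0, seed=seed,
    )


class TestBootstrapEvaluate:
    def test_deterministic_given_seed(self, null_cohort):
        cfg = PipelineConfig(n_predict=15)
        a = bootstrap_evaluate(null_cohort, cfg, members=[0], B=3, seed=5)
        b = bootstrap_evaluate(null_cohort, cfg, members=[0], B=3, seed=5)
        pd.testing.assert_frame_equal(a.per_rep, b.per_rep)

    def test_null_cohort_flags_almost_nothing(self, null_cohort):
        cfg = PipelineConfig(n_predict=20)
        rep = bootstrap_evaluate(null_cohort, cfg, members=[0], B=6, seed=1)
        assert rep.median("sensitivity") <= 0.1
        assert rep.per_rep["n_flagged"].median() <= 2

    def test_summary_invariant_to_repetition_order(self, null_cohort):
        cfg = PipelineConfig(n_predict=15)
        rep = bootstrap_evaluate(null_cohort, cfg, members=[0], B=4, seed=2)
        shuffled = rep.per_rep.sample(frac=1, random_state=0).reset_index(drop=True)
        for col in ("sensitivity", "specificity"):
            assert shuffled[col].median() == rep.per_rep[col].median()


class TestCovariateAudit:
    def test_score_equal_to_age_gives_unit_correlation(self, rng):
        frames = []
        for b in range(5):
            age = rng.uniform(8, 35, 30)
            frames.append(
                pd.DataFrame({"rep": b, "score": age, "age": age,
                              "motion": rng.uniform(0, 1, 30)})
            )
        summary = covariate_audit(pd.concat(frames))
        assert summary.loc["age", "median"] == pytest.approx(1.0)

    def test_constant_scores_excluded_as_undefined(self, rng):
        df = pd.DataFrame(
            {"rep": 0, "score": 0.5, "age": rng.uniform(8, 35, 20),
             "motion": rng.uniform(0, 1, 20)}
        )
        summary = covariate_audit(df)
        assert summary.loc["age", "n_reps"] == 0
        assert np.isnan(summary.loc["age", "median"])

    def test_independent_scores_band_encloses_zero(self, rng):
        frames = []
        for b in range(40):
            frames.append(
                pd.DataFrame({"rep": b, "score": rng.uniform(size=40),
                              "age": rng.uniform(8, 35, 40),
                              "motion": rng.uniform(0, 1, 40)})
            )
        summary = covariate_audit(pd.concat(frames))
        for cov in ("age", "motion"):
            assert abs(summary.loc[cov, "median"]) < 0.1
            assert summary.loc[cov, "p5"] < 0 < summary.loc[cov, "p95"]


class TestCharacterizeFlagged:
    def test_no_flagged_returns_explicit_status(self, null_cohort):
        s = characterize_flagged(null_cohort, np.zeros(null_cohort.n_individuals, bool))
        assert s.status == "no individuals flagged"
        assert s.n_flagged == 0 and s.mean_residual_maps == {}

    def test_planted_carriers_show_underconnectivity(self):
        cfg = GeneratorConfig(
            n_per_site_per_group=40, n_sites=2, n_networks=4, n_units=150,
            signature_networks=(0, 1), signature_shift=-0.3, carrier_fraction=0.15,
            seed=3,
        )
        d = generate_cohort(cfg)
        carriers = d.phenotype["carrier"].to_numpy(bool)
        s = characterize_flagged(d, carriers, networks=[0, 1, 2])
        assert s.frac_below_average[0] > 0.5
        assert s.frac_below_average[1] > 0.5
        # non-signature network shows no systematic underconnectivity
        assert abs(s.frac_below_average[2] - 0.5) < 0.2

    def test_severity_link_recovered_in_scores(self):
        """Scores proportional to carrier status correlate positively with severity."""
        cfg = GeneratorConfig(
            n_per_site_per_group=150, n_sites=2, n_networks=2, n_units=20,
            carrier_fraction=0.3, severity_link=0.4, signature_networks=(0,), seed=8,
        )
        d = generate_cohort(cfg)
        carriers = d.phenotype["carrier"].to_numpy(bool)
        rng = np.random.default_rng(0)
        scores = 0.5 * carriers + 0.2 * rng.uniform(size=d.n_individuals)
        s = characterize_flagged(d, carriers, scores=scores)
        se = 1.0 / np.sqrt(d.n_individuals - 3)
        assert s.severity_r > 0
        assert s.severity_r > 0.4 * 0.5 - 3 * se  # attenuated link, same sign
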