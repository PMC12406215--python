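# Methods

## Problem setting

The package targets case-control studies of resting-state functional
connectivity (FC) in which the scientific goal is not average classification
accuracy but *high-confidence positives*: flag only those individuals whose
connectivity is so atypical for a neurotypical control (NTC) that a positive
ASD prediction carries high positive predictive value (PPV), and abstain on
everyone else.  The data are per-individual, per-network connectivity maps —
for each of `n_networks` brain networks, the correlation of the network's
average signal with `n_units` spatial units — plus a phenotype table with
diagnosis, age, head motion, acquisition site and (optionally) a symptom
severity score.

## Transductive conformal prediction

For one unclassified individual (UCI) and one network predictor:

1. **Pooling.** The UCI is pooled with the reference cohort.  Everything below
   is recomputed for every UCI: adding one individual changes the group mean
   and the nuisance regression, so residuals, subtypes and features are never
   cached across UCIs (the transductive contract).
2. **Nuisance regression.** Per spatial unit, ordinary least squares removes
   the pooled-sample mean connectivity and the linear effects of age and head
   motion; residual maps are kept.  The implementation reuses the reference
   block of the normal equations (`X'X`, `X'Y`) and adds the UCI's rank-one
   contribution — algebraically identical to a from-scratch fit (tested to
   1e-12) but roughly 10x faster, which matters because the engine performs
   ~1e5 such fits in a bootstrap study.
3. **Subtype features.** The pooled residual maps are clustered by
   hierarchical agglomerative clustering (average linkage on the distance
   1 − Pearson spatial correlation), cut at k = 5 connectivity subtypes.
   Average linkage was chosen for robustness to cluster-size imbalance;
   agglomerative clustering has no random initialisation, so the whole
   pipeline is deterministic.  Each individual's feature vector is the
   Pearson correlation of their residual map with each subtype-average map.
4. **Class-weighted scoring.** Assuming the ASD label for the UCI, a logistic
   model predicting ASD is fitted to the pooled sample with ASD examples
   (including the UCI) weighted by a very large factor; the ASD conformal
   score is the fraction of ASD *reference* individuals whose fitted value is
   less than or equal to the UCI's.  The NTC score mirrors this with NTC as
   the assumed and weighted class.  Validity of these scores follows from the
   symmetric treatment of the UCI and the reference members of the assumed
   class, whatever the scoring model does.
5. **Decision.** Predict ASD iff the NTC label is rejected
   (`p_ntc < alpha`) and the ASD label is not (`p_asd >= alpha`), with
   `alpha = 0.05` for single-network predictors; abstain otherwise.

### Numerical choices

* The nominal class weight is 1e16; the solver normalises sample weights to
  mean one and caps the effective per-class ratio at 1e8, which is
  numerically indistinguishable in rank terms but keeps the loss on a
  float-safe scale.
* Ranks are computed on the **linear predictor**, not the sigmoid output:
  with the extreme weight the fitted probabilities saturate at 1 − O(1e-8)
  and tie at double precision, while ranks are invariant under any monotone
  link.  Ties are compared with `<=`.
* The fit is a ridge-penalised (1e-6 on slopes, none on the intercept) damped
  Newton iteration with step halving; a non-convergent fit is retried at 1e4
  times the penalty, and a still-failing fit yields NaN scores and an
  abstention rather than an exception.
* Zero-variance maps get correlation 0 (with a warning) so degenerate inputs
  propagate as "no similarity" instead of NaN.

### A note on what the class weight does

The weighting is motivated as a false-positive-minimising device.  In
simulation we find — as conformal theory predicts — that the *rate* of
false-positive flags among controls is bounded by the decision threshold for
any scoring model, weighted or not; the weight instead changes *which*
individuals are flagged, concentrating flags on members of coherent case
subgroups.  The test suite therefore asserts validity under extreme weighting
and non-inferiority to an unweighted scorer, not a directional reduction in
false positives.

## Combining correlated predictors

Per-network predictors built on functionally related networks produce
correlated conformal scores.  The predictor-by-predictor Pearson correlation
matrix of ASD scores (estimated by leave-one-out scoring of the reference
cohort) is clustered (average linkage on 1 − r) into k = 7 groups and k = 2
ensembles; both k's are configuration parameters.  Within a group, per-class
scores are merged with the quadratic-mean rule

    p_merged = min(1, sqrt(3) * sqrt(mean(p_i^2)))

whose sqrt(3) factor makes the merged value a valid p-value under arbitrary
dependence (the r = 2 member of the averaging family of merging functions,
whose general valid form is (r+1)^(1/r) times the r-mean).  The constant is
cross-checked in the tests by a Monte-Carlo oracle at both dependence
extremes.  Because the rule is conservative — a singleton group is already
inflated by sqrt(3) — merged scores are thresholded at the more liberal
`alpha_ensemble = 0.2`.  The ensemble with the higher bootstrap-median PPV is
taken as the high-risk signature (HRS).

## Propensity matching

Cases and controls are matched on age and head motion within each site:
a main-effects logistic propensity model per site, greedy nearest-neighbour
pairing without replacement on the propensity logit (cases processed in
descending propensity order, ties broken by smallest id), pairs farther than
the caliper rejected.  The default caliper is 0.2 x SD of the within-site
logit, standard practice where no value is prescribed.  Sites with a single
diagnostic group are excluded with a warning; sites where the logistic model
does not converge (e.g. separation in tiny sites) fall back to greedy
matching on the first principal axis of the standardised covariates.
Matching without replacement guarantees equal group sizes per site.

## Evaluation

The predictor only issues positive flags, so abstentions on true cases count
as false negatives and abstentions on true controls as true negatives;
sensitivity, specificity, PPV, risk ratio (flagged vs non-flagged risk), odds
ratio and the Sørensen–Dice coefficient follow the standard definitions, with
zero-denominator metrics reported as missing (never zero).  Bootstrap
evaluation draws, per repetition, two independent with-replacement resamples
of the matched cohort — one reference, one prediction — runs the full
transductive pipeline, and summarises metrics by the median and 5/25/75/95
percentile bands; repetitions with an undefined PPV are excluded from the PPV
summary and counted.  Population translation uses Bayes' rule:
`PPV_pop = sens*prev / (sens*prev + (1-spec)*(1-prev))` with prevalence
defaulting to 1/90, plus the flagged fraction and the fold increase over
baseline risk.

The covariate audit reports, per bootstrap repetition, the Pearson
correlation of ASD conformal scores with age and motion; a well-behaved
predictor has bands enclosing zero.  Flagged-individual characterisation
reports the mean residual map of flagged individuals per network with the
fraction of units below the sample average, and the correlation of symptom
severity with the mean per-network ASD conformal score.  The *merged* score
is not used for this audit: the capped sqrt(3)xRMS merge saturates at 1 for
typical individuals and carries no graded information.

## The synthetic cohort generator

The generator emulates the data regime downstream of fMRI preprocessing; it
does not simulate time series, atlases or scanners.  Per individual and
network, a map is the sum of

* a network-specific baseline pattern (N(0.25, 0.10) per unit, drawn once per
  population);
* linear age and motion effects (defaults −0.002/year and −0.1/mm on
  centred covariates; ages uniform on 8–35 years, motion log-normal with
  median 0.15 mm — ranges typical of public multi-site autism imaging cohorts) and a per-site offset (SD 0.03);
* a low-rank shared component: networks are split into two fixed families
  and each individual has 5 latent loadings per family (SD 0.06) on 5 latent
  spatial patterns.  Within-family sharing gives the 2-ensemble clustering
  real structure to find, emulating the unimodal/transmodal organisation of
  cortical networks; the 5 patterns give the 5-subtype clustering structure
  to find;
* for carriers — an exact-count fraction (default 0.1) of cases — an
  additive shift on the signature networks, `signature_shift` times per-unit
  exponential weights of mean 1.  The mean shift equals `signature_shift`
  (default −0.3, i.e. underconnectivity), but the pattern is spatially
  structured: a spatially *uniform* shift would be invisible to the
  correlation-based features, which de-mean every map;
* i.i.d. Gaussian noise (SD 0.15), then clipping to [−1, 1] (correlation
  scale).

Severity is Gaussian (mean 5, SD 2, clipped to 0–10) with a point-biserial
correlation `severity_link` (default 0.3) with carrier status.  Carriers are
restricted to cases by construction.  `GeneratorConfig.replicate(seed)` draws
a new cohort from the *same* population (baseline, latent patterns and
signature weights fixed; individuals resampled), which is what makes
discovery/replication experiments meaningful.

What the generator does **not** emulate: site-specific covariance structure
(site effects are additive scalars), non-linear age effects, diagnosis-wide
connectivity differences outside the carrier subgroup, missing data, and
scanner artefacts.  Passing tests therefore show that the pipeline recovers a
coherent minority signature under realistic nuisance structure — not that it
would attain any particular performance on real multi-site data.

## Reference study sizes

The bundled studies (`hrsig.studies`) run at desk scale, the package's own
choice for routine verification: discovery and replication cohorts of 200
cases + 200 controls across 10 sites (~260 individuals after matching), 18
networks of 200 units with the signature planted in 9, B = 25 bootstrap
repetitions with 100 prediction individuals scored per repetition; the null
calibration and audit studies use 300 + 300 individuals.  A full planted
study takes a few minutes on one CPU; all sizes are function parameters.

## Known limitations

* The per-network reading of subtype clustering is adopted (clustering
  residual maps within each network separately), consistent with per-network
  predictors.
* The caliper and tie-breaking rules of the matching stage, and the k = 7 /
  k = 2 cluster counts, are conventions where the procedure leaves them open;
  all are parameters.
* Greedy matching is locally optimal only; no optimal (global) matching.
* The bootstrap treats the matched cohort as the population; individuals may
  appear in both the reference and prediction resamples of a repetition.
* With ~23-260 reference individuals per class, conformal scores have
  resolution 1/n_class; thresholds below that resolution cannot reject.
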