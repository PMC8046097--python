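# Methods

This note documents the statistical model behind each stage of the
pipeline, the parameters that matter, what the synthetic-data generators do
and do not emulate, and the numerical choices made where the design was
genuinely open.

## Left-censored imputation

Untargeted LC–MS intensities go missing preferentially when the underlying
abundance sits near the detection limit. The imputer therefore models
missing cells as draws from the *low tail* of the observed distribution:
within a scope unit (default: one sample) with observed log-intensity mean
μ and SD σ (ddof = 1), missing cells are replaced by draws from
𝒩(μ − *s*·σ, (*w*·σ)²) with shift *s* = 2.5 and width *w* = 0.5 by
default. Two choices deserve comment:

* **Log scale.** Moments are estimated on log intensities and draws
  exponentiated back. A downshifted normal fitted on raw peak areas could
  produce negative intensities; on the log scale positivity is automatic.
  A floor (smallest observed positive value × 10⁻³) clips the residual
  extreme tail.
* **Scope.** The per-sample scope is the default because detection limits
  are a property of the injection, and it matches standard left-censored
  imputation practice in proteomics/metabolomics; per-metabolite and
  global scopes are available (`ImputeParams.scope`). Whether the SD should
  be computed on raw or log intensities is genuinely ambiguous in the
  verbal description of this procedure in the literature; both are
  supported (`log_scale`), log being the default for the positivity
  argument above.

Observed cells are never altered; the imputation mask is returned so the
missingness filter can reference *original* missingness (after imputation
nothing is missing, so filtering must come from the mask; the chain is
impute → filter by mask → normalize → log).

The filter retains metabolites with missing fraction strictly below 25%;
ties at exactly 25% are dropped.

## Total-intensity normalization

Correction factor *f*ᵢ = Tᵢ / minⱼ Tⱼ, every cell of sample *i* divided by
*f*ᵢ. Exact post-conditions, asserted in tests: all sample totals equal the
minimum original total to 10⁻¹⁰ relative tolerance; min *f* = 1; and
within-sample ratios are preserved exactly (normalization is a per-column
scalar). The assumption — equal total serum intensity across samples — is
the standard volume-difference correction; it is *not* robust to a single
dominating peak, which is one reason the synthetic benchmark below shows
residual cross-metabolite correlation.

Log transformation is always applied before linear models, PLS-DA and
distance computations; "if necessary" conditions found in verbal protocol
descriptions have no operational trigger, so this package always
transforms and says so.

## PLS-DA, VIP and PCA

Two-class PLS-DA is PLS1: the response is a single centred 0/1 dummy.
For two classes this spans the same solution space as a two-column
indicator block and gives the simpler VIP expression. Extraction is
sequential NIPALS (for a single response column the inner loop converges in
one pass): w = Xᵀy/‖Xᵀy‖, t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflate
X ← X − tpᵀ. Features are centred and scaled to unit variance (ddof = 1)
by default. Sign indeterminacy is resolved by making the
largest-magnitude weight entry of each component positive. The test suite
pins scores, weights and loadings to an independent NIPALS implementation
(scikit-learn's `PLSRegression`) at 10⁻⁶ up to sign.

VIP uses the response sum of squares per component, SSₐ = qₐ²·tₐᵀtₐ, and
unit-norm weights; mean(VIP²) = 1 is an algebraic identity and is asserted
on every fit. The number of components defaults to 2 (the conventional
default of discriminant-PLS tooling). VIP from a 1- vs 2-component model
differs little when the first component carries the response (the test
suite exercises both); the default is not silently data-dependent.

PCA is a plain SVD of the centred (optionally scaled) matrix with the same
sign convention, checked against the eigendecomposition of the covariance
matrix.

## Rank tests and multiple-testing control

Rank-sum (Mann–Whitney) p-values are exact by enumeration when both groups
have ≤ 12 observations and the pooled sample is tie-free; otherwise the
normal approximation with tie and continuity corrections is used. The
signed-rank test is exact for ≤ 15 non-zero differences without tied
magnitudes; zero differences are dropped (classical Wilcoxon convention)
and an all-zero vector returns p = 1 with a warning. The exact/asymptotic
thresholds are desk-scale enumeration limits; the two branches agree within
0.02 at the boundary (tested). BH and Bonferroni adjustments come from
statsmodels.

Case–control contrasts are OLS on log levels with age and BMI covariates;
the fold change is deliberately computed on the raw (normalized, non-log)
scale as mean(case)/mean(control), so FC and adjusted p coexist on
different scales, as is conventional in metabolomics tables.

## Differential-response selection and its error profile

Selection at each follow-up time: VIP > 1 from PLS-DA on log-ratios
(treatment vs placebo) **and** rank-sum p < 0.05 on the ratios, with the
union over follow-up times reported alongside per-time membership. The
rule is monotone in both thresholds (tested).

An important property, measured by the acceptance machinery rather than
assumed: **this dual criterion is a screen, not an error-controlled
selection.** With *m* ≈ 1000 metabolites of which only a few dozen truly
respond, the rank-sum branch alone admits ≈ 0.05·*m* chance selections,
and the VIP branch cannot veto them: PLS weights are proportional to
sample correlations with the class label, so a null metabolite whose
in-sample arm difference is large enough for p < 0.05 necessarily also
carries non-trivial VIP. Since the total squared correlation mass is
bounded (≈ number of true responders + m·𝔼[r²_null]), the VIP > 1 cutoff
corresponds to a *weaker* correlation threshold than p < 0.05 at these
sample sizes. Consequently sensitivity is high (≳ 0.95 at one log2 unit of
planted effect, 30 subjects/arm) but the false-discovery proportion of the
selection sits near 0.05·m/(0.05·m + true positives) — about 0.85 for 20
responders in 1000 metabolites — for *any* effect size and noise level.
This mirrors the behaviour of VIP-and-p screens on real serum data, where
typically nothing survives FDR correction yet ~10% of metabolites pass the
screen. Downstream stages (clustering, case–control confirmation) are the
error control.

Null calibration is verified across independent simulations, with the
Monte-Carlo SE taken *across seeds* because metabolite-level tests within
one simulated cohort are positively correlated (shared subjects, shared
residual normalization error).

## Divisive clustering and the tree cut

DIANA follows Kaufman & Rousseeuw: repeatedly split the active cluster of
largest diameter by seeding a splinter group with the object of maximal
average dissimilarity and migrating objects while their average
dissimilarity to the remainder exceeds that to the splinter (largest
positive gain first, ties by smallest index). Split heights (parent
diameters) are non-increasing, so cutting at height *h* equals applying
all splits above *h*. The divisive coefficient is mean(1 − d(i)/diam) with
d(i) the diameter of the last non-singleton cluster containing *i*. The
implementation matches R's `cluster::diana` (divisive coefficient to
10⁻⁸; identical partitions at every untied cut level) on random instances,
and that cross-check runs in the test suite.

Distances for response-pattern clustering are 1 − Pearson correlation
between arm × time *mean* response profiles (2 arms × 4 time points, the
baseline entry ≡ 1), matching the convention of plotting group mean
trajectories; per-subject profiles would weight subject noise into the
metabolite distance and are not the default.

**Tree cut.** A cut rule of the form (1 − DC) × tree height was considered
and rejected: for tight, well-separated blocks DC → 1 drives the cut to
zero and splinters every block (observed: DC = 0.99995 on a two-block
fixture ⇒ zero retained clusters). The default rule instead cuts inside
the largest *relative* gap of the distinct split-height sequence
(geometric midpoint of the widest ratio between consecutive heights):
between-group separations sit orders of magnitude above within-group
splinter heights, so the ratio peaks at the group/noise boundary.
Candidate cuts are capped at n/min_cluster_size clusters, since finer cuts
cannot produce retainable clusters. An explicit `cut_fraction` override
and the reported DC keep the rule inspectable. Clusters below
`min_cluster_size` (default 10) are discarded, not merged.

## Synthetic-data generators

`simulate_rct` draws log intensities additively: metabolite baseline
𝒩(15, 2²) (intensities spanning ~4 orders of magnitude, as in serum
LC–MS), subject effect 𝒩(0, 0.8²), residual 𝒩(0, 0.5²), a per-sample
log-scale factor 𝒩(0, 0.2²) for volume differences, and a planted
arm × time effect (±effect_log2·ln 2, treatment arm, all follow-up visits)
on a chosen subset. Censoring is Bernoulli with logistic probability in
the *latent* (pre-scale) log intensity — steepness 1.2, midpoint 11 —
which makes the left-censoring assumption of the imputer literally true
and yields ~5–8% overall missingness concentrated in low-abundance
metabolites. Defaults give 1232 metabolites, 34 subjects/arm, visits at
months 0/3/6/12.

`simulate_cohort` adds clinical covariates with plausible
elderly-female defaults (age 78 ± 1.7 y, height 162.5 ± 6.1 cm, BMI
24.4 ± 3.6 kg/m², weight = BMI·height²) and a latent tibia vBMD
(212 ± 40 mg/cm³) with cross-sectional gradients −5 mg/cm³ per year of age
and +2.5 per BMI unit, so that extreme-phenotype selection induces
covariate imbalance for matching to repair. Marker metabolites shift with
the standardized bone component at a slope calibrated through
truncated-normal tail means so the *expected* low-vs-high extreme contrast
equals the planted log2 effect; `confounder_strength` couples *all*
metabolites to age/BMI, biasing unadjusted contrasts by design. Group
labels are assigned downstream by selection + matching, never by the
generator.

Not emulated: batch structure, instrument drift, adduct/isotope artifacts,
correlated metabolite modules beyond the planted signals, non-logistic
missingness, and departures from log-normality. Passing tests therefore
demonstrate correctness of the *procedures* under a clean generative
model, not robustness to every pathology of real acquisitions. The
missingness mechanism of real serum data is unobserved; logistic
left-censoring is an explicit assumption of this artifact.

## Matching and the random forest

Propensity scores come from a maximum-likelihood logistic regression on
age, height, weight and BMI; matching is 1:1 greedy nearest-neighbour on
the logit scale without replacement, processing cases in descending
propensity order (hardest first). Greedy matching is the simplest
well-understood variant; an optimal-assignment matcher would change little
at these pool sizes. A caliper (in logit SD units) is available but off by
default. Balance is reported as standardized mean differences and
two-sample t p-values, pre and post.

The forest is bagged CART: each of n_trees (default 1000) trees fits a
bootstrap of the training split with √p features per node. Building the
bagging layer explicitly (over scikit-learn decision trees) makes per-tree
out-of-bag indices first-class, so importance is computed exactly as
*mean decrease in accuracy*: the across-tree mean of (OOB accuracy − OOB
accuracy with feature j permuted). Impurity-based importance is not used —
it is biased toward high-cardinality features and is not the quantity the
name refers to. ROC and AUC (trapezoid) are computed on the held-out 30%
only, never on OOB votes; the split is stratified so both partitions carry
both classes, and validation scores are case-vote fractions. Permutation
importance uses one permutation per tree applied per feature column.

## Enrichment

Over-representation is the one-sided hypergeometric tail
P(X ≥ k | N, K, n) with N the mappable background (all filter-surviving
measured metabolites by default — the background is configurable because
published tables rarely state theirs), K the pathway's mappable members, n
the query size; BH across pathways. Pathway *impact* is Σ betweenness
centrality of hit nodes / Σ over all nodes on a user-supplied pathway
graph — a documented approximation of the topology measures used by
web-based metabolomics tools; a graph whose centralities are all zero
falls back to the hit fraction so saturation still reports 1. Pathway
content is always a user input; nothing is fetched.

## Determinism and problem sizes

All randomness flows through NumPy PCG64 generators seeded explicitly; the
pipeline drivers derive fixed per-stage substreams from one run seed
(SeedSequence spawn keys), so toggling one stage never perturbs another's
draws. Reported simulation sizes — 10–25 seeds for selection recovery, 100
cohorts for matching balance, 50 label permutations for the classifier
null, 1000 metabolites × 30 subjects/arm per trial simulation — were
chosen to keep Monte-Carlo SEs comfortably below the margins being tested
while remaining desk-scale; they are stated in the tests and the
acceptance script rather than hidden in defaults.

## Known limitations

* The dual VIP/p screen's false-discovery proportion is large by
  construction at realistic signal densities (see above); it is reported,
  not suppressed.
* Total-intensity normalization leaves a small correlated residual across
  metabolites when a few peaks dominate the total; tests that depend on
  cross-metabolite independence use across-simulation replication instead.
* DIANA cut selection is heuristic; the cut parameter is exposed and the
  divisive coefficient reported so analysts can override it.
* The matcher assumes the logistic propensity model is adequate for four
  smooth covariates; no covariate interactions are modelled.
* No batch/drift correction is implemented; inputs are assumed to be
  platform-normalized upstream.
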