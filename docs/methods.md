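# Methods

## Territories and constellation classification

Lesion topology is recorded as a non-negative lesion count per vascular
supply territory. Nine territories are modelled: anterior (ACA), middle
(MCA) and posterior (PCA) cerebral artery territories coded per
hemisphere, left and right cerebellum, and a single midline brainstem
region. Fixed anatomical attributes drive all derived flags: ACA/MCA are
anterior circulation, PCA/cerebellum/brainstem posterior; ACA/MCA/PCA are
supratentorial, cerebellum/brainstem infratentorial.

A patient is a **multiple-acute-lesion (MAL)** case iff the total lesion
count exceeds one — multiplicity within a single territory counts. The
constellation category encodes the multiset of per-territory statuses
(a territory is "single" if it hosts exactly one lesion, "multiple" if
two or more). Bilaterality is evaluated over the eight lateralized
territories only; the midline brainstem can never make a patient
bilateral. The anterior+posterior and supratentorial+infratentorial flags
are logically independent (MCA+PCA is anterior+posterior but purely
supratentorial; PCA+cerebellum spans compartments within the posterior
circulation) and the tests exercise both directions.

Per-territory tabulation is **territory-local**: within each territory a
patient counts as "single" or "multiple" by the count in *that*
territory, not by global MAL status. Rationale: in the published cohort
table the per-territory "single" column sums exceed the number of
globally single-lesion patients, which is only possible under the
territory-local rule. Percentages are half-up rounded to one decimal,
matching clinical-table style; territories without patients report an
undefined (NaN) percentage. Watershed/border-zone lesions are not
representable — the input format forces each lesion into one territory.

## Group-comparison battery

Continuous variables use two-sample *t*-tests (Welch by default; a
pooled-variance option exists), binary variables two-sided Fisher exact
tests (sum of hypergeometric probabilities no larger than the observed
table's). Volume-like variables are summarized as median (IQR) but
tested on their stated scale with *t*-tests, because the battery is
defined in terms of *t*-tests and Fisher tests only; a rank-based
alternative is deliberately out of scope. Multi-level etiology (CCS
categories) is dichotomized one-vs-rest, one test per level. All raw
p-values of a battery are adjusted jointly by Benjamini–Hochberg step-up
FDR (the standard default where the correction method is otherwise
unspecified); significance means adjusted p < 0.05. Missingness is
complete-case per variable, with the analysed n reported per variable.
A continuous variable with zero variance in both groups yields p = 1
with a warning instead of aborting the battery. Note that BH-adjusted
p-values are *not* idempotent under re-adjustment (e.g. [1.0, 0.25] →
[1.0, 0.5]); the tests therefore check the step-up formula directly
rather than an idempotence property.

## Hierarchical interaction models

Both models share the structure

    outcome_i ~ F(alpha_{g(i)} + beta_{g(i)} * ln V_i)
    alpha_g ~ Normal(mu_alpha, tau_alpha),  beta_g ~ Normal(mu_beta, tau_beta)
    mu_alpha, mu_beta ~ Normal(0, 10)
    tau_alpha, tau_beta ~ HalfNormal(10),   sigma ~ HalfNormal(10)  (linear only)

with F Gaussian (identity link) for NIHSS and Bernoulli (logit link) for
mRS > 2. Priors are weakly informative and config-exposed; they are this
package's own defaults, chosen to be broad relative to the plausible
effect scales (slopes of a 0–42 score on log-ml are O(1)). The NIHSS
likelihood is Gaussian on the integer 0–42 scale without truncation — an
approximation adequate for slope inference but one that interacts with
the generator's rounding/clipping (below). Volumes are floored at a
configurable epsilon (default 0.01 ml) before the natural log.

**Sampling.** The linear model is sampled by block Gibbs: each group's
(intercept, slope) pair has a conjugate bivariate-normal full
conditional (computed from per-group sufficient statistics, so a scan is
O(1) in sample size); the hyper-means are conjugate normals; the scales
tau_alpha, tau_beta, sigma are updated by stepping-out/shrinkage slice
sampling on the log scale (Jacobian included), bounded to log-scale
[-7, 7] so degenerate zero-variance outcomes cannot drive sigma into an
improper spike at zero. The logistic model replaces the conjugate group
block with an independence Metropolis–Hastings update: the proposal is a
bivariate Student-t (df 10) centred on the group's maximum-likelihood
estimate with 1.2× the Laplace covariance, computed once per fit;
observed acceptance is ~0.55–0.7 and is reported in the diagnostics.
Defaults: 4 chains × 1,000 retained draws after 1,000 warmup scans,
seeded per chain from the configured seed, giving 4,000 aligned draws.
Identical spec + seed reproduces results exactly.

**Diagnostics.** Rank-normalized split R-hat (arviz) across chains for
the four group-level parameters; a fit with max R-hat ≥ 1.01 is flagged
non-converged (`usable = False`) and surfaces as a pipeline warning.
Gibbs/MH samplers have no divergence concept; the MH acceptance
fractions play the analogous health-check role for the logistic model.
An independent MCMC route (an affine-invariant ensemble sampler run on
the same log-posterior) is used as a cross-check oracle in the test
suite, alongside per-group OLS/ML agreement in the large-n limit.

**Decision rule.** The slope difference (single − multiple) is formed
draw-wise from the aligned posterior draws. The HPDI is the shortest
contiguous window over the sorted draws containing ⌈mass·n⌉ of them
(first window on ties); default mass 0.90. "Substantial" is the binary
verdict that this interval excludes zero — no Bayes factors.

**Strata.** Anterior stratum: patients whose lesions all lie in ACA/MCA
territories; posterior: all in PCA/cerebellum/brainstem. Patients
spanning both circulations (~2% of cohorts like this) are excluded from
both strata, a choice this package makes explicitly since no published
handling exists. Lacunar patients are excluded from the anterior stratum
by default (the lacunar definition — a single small subcortical
supratentorial lesion — precludes multiplicity); an override flag keeps
them. Groups with fewer than 10 complete rows refuse to fit with an
informative error rather than returning an unstable posterior.

## Synthetic cohort generator

The generator emulates the marginal structure of a large multi-center
stroke MRI cohort; all parameters sit in one `GeneratorConfig`:

* **Constellation categories** (default shares): single-in-one 0.497,
  multiple-in-one 0.374, two-singles 0.032, single+multiple 0.041,
  two-multiples 0.056. Involved territories are drawn without
  replacement with weights proportional to published per-territory
  patient counts (MCA-dominant); a "multiple" territory hosts
  2 + Poisson(0.8) lesions. The joint distribution of multi-territory
  involvement is an independence assumption — no published joint
  structure exists.
* **Volumes**: total DWI volume per group is log-normal with location
  ln(median) and scale solved numerically (Brent) so the distribution's
  IQR matches the printed group IQR — single: median 1.7 ml, IQR 11.2
  (σ ≈ 2.83); multiple: 7.7/30.4 (σ ≈ 2.12). WMH burden likewise
  (6.1/14.4 single, 5.3/11.3 multiple). Volumes are drawn at patient
  level (total volume), since all models consume totals.
* **Outcomes**: NIHSS = round-clip₀₋₄₂(α_g + β_g·ln V + Normal(0, σ)),
  with stratum-specific defaults echoing the published posterior means
  (anterior β ≈ 1.56/1.57; posterior β ≈ 0.21/0.39; σ = 4; intercepts
  3.8/3.1 anterior and 3.5/3.5 posterior chosen to land the group mean
  NIHSS near 4.6/6.3). Patients spanning both circulations follow the
  anterior model. The rounding/clipping floor at 0 attenuates fitted
  slopes relative to the planted coefficients when many small-volume
  patients sit near the floor — visible in whole-cohort fits and
  documented in the README example. mRS > 2 is drawn from
  logit P = α_g + β_g·ln V with equal-slope defaults (−1.5, 0.35),
  matching the published null group difference for functional outcome;
  the integer mRS value is then drawn conditional on the indicator.
* **Covariates**: age truncated-Normal(63.4, 14.8) on [18, 100], 39%
  female, comorbidity flags and CCS etiology drawn independently per
  group at the published prevalences. Joint covariate correlation is
  deliberately not modelled (unspecified in the source material).
* **Lacunar flag**: structurally eligible patients (single lesion in one
  supratentorial territory with volume < 1.77 ml ≈ a 1.5 cm sphere) are
  flagged with probability 0.149; the volume threshold proxies the
  diameter definition and the probability proxies the unobservable
  subcortical criterion.
* **Missingness**: completely at random; severity variables (volume and
  NIHSS, masked jointly) retained at ~41% and mRS at ~30.3%,
  reproducing the published analysis-subset proportions. MCAR is an
  assumption — no mechanism is published.

What passing tests on these cohorts do *not* show: robustness to
informative missingness, covariate confounding of the volume–outcome
relation, measurement error in segmented volumes, or territory
misassignment at watershed borders — none of which the generator
simulates.

`plant_fixture` builds exact-count cohorts: category counts map to fixed
territory patterns, per-territory (single, multiple) cells map to
one-territory patients, and requested bilateral / supra+infra /
ant+post totals are realized by assigning territory *pairs* — every
combination of the three flags is achievable by some pair, so a greedy
overlap assignment (triple overlap first, then pairwise, then singles)
realizes any flag totals whose maximum does not exceed the number of
multi-territory patients; infeasible requests raise an error naming the
violated constraint.

## Numerical and design notes

* Percent rounding: decimal half-up, one decimal (`round_half_up`), as
  printed tables do. Two printed cells of the published territory table
  (Right Cereb 55.0, Brainstem 18.6) are inconsistent with their own
  printed counts (100/182 → 54.9; 61/337 → 18.1); the tabulators report
  the computed ratios.
* HPDI ties broken toward the lowest window; width is non-increasing in
  mass; the interval contains the median for unimodal draws (tested).
* Problem sizes: the recovery suites use 20 seeded replicates at
  n = 500/group (linear, σ = 2 and σ = 1 designs) and 5 replicates at
  n = 1,000/group (logistic), with calibration checks at n = 20,000 —
  sizes at which the data-draw standard error of a slope (~0.075 for
  the linear design) is small relative to the stated tolerances.
* Zero-lesion records, empty cohorts, constant predictors, single-class
  logistic outcomes, zero-variance comparisons, out-of-range schema
  values and infeasible fixtures all raise typed errors with enough
  context to locate the offending record.

## Known limitations

* With only two groups the hierarchy's scale parameters are weakly
  identified; they act as regularizers and their posteriors largely
  reflect the priors. Group-level inferences are insensitive to this at
  the sample sizes used (checked against per-group OLS/ML).
* The Gaussian NIHSS likelihood ignores the bounded integer support.
* The independence-MH proposal assumes the group-conditional logistic
  posterior is well approximated by a Student-t at the MLE; extreme
  class imbalance degrades acceptance (reported, and R-hat flags it).
* The simulator's independence assumptions (covariates, territories,
  MCAR) make it a calibration target, not a clinical emulator.
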