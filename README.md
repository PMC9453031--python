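# mal-profiler

Profiling of **multiple acute ischemic lesions (MAL)** in stroke MRI
cohorts. About half of patients with acute ischemic stroke show more than
one topographically discrete lesion on diffusion-weighted imaging (DWI),
either within one vascular territory or spread over several. This package
implements, as a tested and reusable pipeline, the analysis layer such a
study needs:

1. **Constellation classification** — each patient's per-territory lesion
   counts (nine territories: left/right ACA, MCA, PCA, cerebellum, plus
   the midline brainstem) are classified into lesion-topology categories
   (single lesion; multiple lesions in one territory; k-territory
   patterns of single/multiple involvement) with derived flags for
   bilaterality, supra- plus infratentorial spread, and anterior plus
   posterior circulation involvement; cohort-level tabulations report
   category shares and per-territory single/multiple counts.
2. **Group-comparison battery** — baseline-table contrasts between
   single- and multiple-lesion patients: Welch/pooled two-sample
   *t*-tests for continuous variables, two-sided Fisher exact tests for
   binary variables, one-vs-rest dichotomization of etiology categories,
   and joint Benjamini–Hochberg FDR adjustment with significance at
   adjusted *p* < 0.05.
3. **Bayesian hierarchical interaction models** — the scientific core.
   With V the total DWI lesion volume (ml) and g ∈ {single, multiple}:

   linear (stroke severity):      NIHSS_i ~ Normal(α_g(i) + β_g(i)·ln V_i, σ)
   logistic (unfavorable outcome): logit P(mRS_i > 2) = α_g(i) + β_g(i)·ln V_i

   with hierarchical priors α_g ~ Normal(μ_α, τ_α), β_g ~ Normal(μ_β, τ_β),
   weakly-informative hyperpriors, and MCMC posterior sampling. Because
   both group slopes live in one model, their draw-wise **difference
   distribution** (single − multiple) is directly available; a group
   difference is called *substantial* when the 90% highest posterior
   density interval (HPDI) of that difference excludes zero. Fits can be
   stratified to anterior- or posterior-circulation-only patients, with
   lacunar strokes (single small subcortical supratentorial lesion)
   excluded from the anterior stratum by default.
4. **Synthetic cohort generator** — patient-level data of this kind are
   shared only on request, so a first-class simulator emulates the
   published marginal structure (constellation shares, MCA-dominant
   territory weights, log-normal group volume distributions calibrated to
   printed medians/IQRs, covariate prevalences, outcome models with
   configurable group slopes, missingness) and can also *plant* exact
   counts for arithmetic fixtures.

A `mal-profiler` CLI orchestrates simulate → classify → tabulate →
compare → fit → report with schema-validated CSV I/O, manifests and
deterministic seeding.

## Worked example

```python
from mal_profiler import (
    GeneratorConfig, generate_cohort, label_cohort, constellation_frequencies,
    HierModelSpec, StratumSpec, stratify_cohort, fit_hier_linear,
)

cohort = label_cohort(generate_cohort(GeneratorConfig(n_patients=2466, seed=42)))
freqs = constellation_frequencies(cohort)
print(freqs["categories"]["single-in-one-territory"])   # {'count': 1246, 'percent': 50.5}
print(freqs["marginals"]["mal"])                        # {'count': 1220, 'percent': 49.5}

anterior = stratify_cohort(cohort, StratumSpec("anterior"))
res = fit_hier_linear(anterior, HierModelSpec(seed=1))
print(res.slope_single.mean, res.slope_multiple.mean)   # 1.23  1.37
print(res.difference.mean, res.substantial)             # -0.137  False
```

At seed 42 the simulated cohort has 1,246/2,466 single-lesion patients
(50.5%, target share 49.7%). In the anterior stratum the severity slopes
on log volume are 1.23 (90% HPDI 1.10–1.36) for single and 1.37
(1.19–1.53) for multiple lesions; their difference distribution
(−0.137, 90% HPDI −0.358 to 0.069) overlaps zero, so the volume–severity
association is *not substantially different* between groups — the
qualitative pattern the models are designed to detect. The fitted slopes
sit below the generator's planted anterior coefficients (≈1.56) because
simulated NIHSS is rounded and clipped to the 0–42 scale, which flattens
the relation at very small volumes; see `docs/methods.md`.

Command-line equivalent:

```bash
mal-profiler simulate --n 2466 --seed 42 --out cohort.csv
mal-profiler classify --input cohort.csv --output labels.csv
mal-profiler fit --input labels.csv --model linear --stratum anterior --seed 1 --out fit.csv
mal-profiler run --n 2466 --seed 42 --out-dir mal_run   # full pipeline + report
```

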