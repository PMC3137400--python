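# wcohort

Weighted-cohort survival analysis for family-based studies of rare,
high-risk mutations — with a synthetic pedigree generator that reproduces
the ascertainment problem the method exists to solve.

## The problem

Studies of risk modifiers in carriers of rare mutations (for example, BMI in
early adulthood and colorectal-cancer risk in carriers of mismatch-repair
gene mutations causing Lynch syndrome) cannot recruit carriers at random:
families enter through an affected proband seen at a family cancer clinic or
reported to a cancer registry, and relatives are then tested for the
family's mutation. The resulting sample over-represents affected subjects at
every age, so a naive Cox regression of disease on an exposure is biased.

The weighted-cohort correction addresses this with external age-specific
incidence rates: within each age stratum, affected and unaffected subjects
receive sampling weights

    w_affected,k   = p_k · n_k / d_k
    w_unaffected,k = (1 − p_k) · n_k / (n_k − d_k)

where `n_k` and `d_k` are the sampled and affected counts in stratum *k* and
`p_k` is the proportion of the reference population expected to be affected
by that age (derived from the external rates). The weighted affected
proportion in each stratum then equals the population expectation, and the
weighted Cox partial likelihood

    ℓ(β) = Σ_events w_i [ x_i'β − log Σ_{j ∈ R(t_i)} w_j exp(x_j'β) ]

(age as the time scale, entry at birth, Breslow ties) yields approximately
unbiased hazard ratios when the external rates are correct. Statistical
imprecision is quantified with a Huber–White sandwich covariance
`A⁻¹ B A⁻¹`, with score residuals summed within families before the outer
product to absorb familial correlation.

The package provides, from the partial likelihood up:

- `simulate_families` / `ascertain` — multi-generation pedigrees segregating
  a rare dominant mutation, piecewise-exponential onset hazards modified
  multiplicatively by covariates (BMI at age 20, smoking, alcohol, sex),
  competing censoring (polypectomy, other cancer, death, last contact), and
  clinic- or registry-style proband-driven recruitment with known true
  hazard ratios;
- `build_cohort` — exposure definitions (BMI = kg/m², WHO categories),
  exclusion accounting, and the censoring rules of a cohort-from-birth
  design, including a pooled cancer-or-polyp outcome for sensitivity
  analyses;
- `compute_weights` — the age-stratum calibration above, stratified by
  interview age, with an optional competing-censoring discount of `p_k`;
- `fit`, `robust_variance`, `schoenfeld_test`, `wald_interaction` — the
  weighted Cox engine with family-clustered sandwich variance,
  scaled-Schoenfeld proportional-hazards diagnostics and robust Wald
  interaction tests;
- `best_fp_vs_linear` — fractional-polynomial dose–response checks
  (powers {−2, −1, −0.5, 0, 0.5, 1, 2, 3});
- `run_study` — the orchestrated study: per-gene and heterodimer subgroups,
  WHO-category and per-site analyses, sex-specific models, interaction
  tests, sensitivity analyses, descriptive tables, and a reproducibility
  manifest.

## Worked example

```python
import numpy as np
import wcohort as wc
from wcohort.simulate import marginal_incidence

cfg = wc.SimConfig(n_families=300, beta_bmi5=np.log(1.3), seed=42)
families = wc.simulate_families(cfg)          # 4069 subjects
cohort = wc.ascertain(families, cfg)          # 1162 retained via probands

build = wc.build_cohort(cohort)               # 1045 records, 117 missing BMI
carriers = build.records.query("carrier == 'carrier'").reset_index(drop=True)

incidence = marginal_incidence(cfg, carrier=True)   # the true carrier rates
wt = wc.compute_weights(carriers, incidence)
weighted = wc.assign_weights(carriers, wt, incidence)

spec = wc.ModelSpec(exposure="bmi5", covariates=("sex", "smoke20", "alcohol20"))
f = wc.fit(weighted, spec, weight_col="weight")
print(f.summary().round(3))
```

```
            coef     hr  robust_se  hr_ci_low  hr_ci_high      z      p
bmi5       0.263  1.300      0.114      1.041       1.625  2.313  0.021
sex       -0.129  0.879      0.178      0.620       1.245 -0.727  0.467
smoke20    0.164  1.179      0.200      0.797       1.744  0.822  0.411
alcohol20  0.548  1.729      0.197      1.175       2.544  2.781  0.005
```

The generating hazard ratio per 5 kg/m² of BMI was 1.30; the weighted fit
recovers HR 1.300 (95% CI 1.041–1.625) on this cohort while the unweighted
fit gives 1.281. Diagnostics on the same fit:

```python
wc.schoenfeld_test(f).loc["bmi5"]          # chi2=0.122, p=0.727 — PH holds
wc.best_fp_vs_linear(weighted, spec, weight_col="weight")
                                           # best powers (0.5,), p=0.898 — linear
```

The same analysis runs from the shell:

```sh
wcohort simulate --out sim/ --seed 42
wcohort build --cohort sim/cohort.tsv --out built/
wcohort fit --records built/records.tsv --out fit.tsv
wcohort study --config run.yaml --out study/ --seed 42
```

## Scope and caveats

The bundled incidence tables are illustrative (shaped like published
Lynch-syndrome penetrance and general-population colorectal-cancer rates);
real analyses must supply externally estimated rates. See `docs/methods.md`
for the model, the weighting construction and its assumptions, and known
limitations.
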