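# Methods

This note records the statistical model behind `wcohort`, the design
decisions taken where the method left room, and what the validation studies
do and do not demonstrate.

## Study design being modelled

The package targets retrospective family cohorts of the kind assembled by
clinic- and registry-based cancer family registries: probands are either
attendees of a family cancer clinic (typically from multiple-case families)
or recently diagnosed cases reported to a population-complete registry;
relatives are recruited and tested for the proband's mutation. Each subject
is treated as under observation from birth; follow-up ends at the first of
disease diagnosis, polypectomy, diagnosis of another cancer, death, or last
contact. Because recruitment conditions on disease in the family, affected
subjects are over-represented at every age, and covariate–disease
associations estimated naively on such samples are biased.

## Cohort construction

BMI at age 20 is weight at 20 (kg) divided by height (m) squared, entered in
models per 5 kg/m² so that `exp(β)` is the hazard ratio per 5-unit
increment, or as WHO categories (≤18.49 underweight; 18.50–24.99 normal,
the referent; 25.00–29.99 overweight; ≥30.00 obese). BMI is rounded
half-even to two decimals before the category lookup so the printed interval
bounds tile the line exactly. Subjects missing height or weight are excluded
and counted; exclusion counts satisfy the identity
`n_input = n_records + n_missing_bmi + n_no_ages (+ n_unverified)` on every
run, and the builder is invariant to input order.

Ties between an event and a censoring age resolve to the event: censoring
"at diagnosis" would delete true cases and is conservative in the wrong
direction for risk estimation. In the pooled "colorectal neoplasia"
sensitivity outcome, the event is the earlier of cancer and polypectomy and
polypectomy no longer censors. When several censoring causes share one age,
the cause is assigned in the fixed order polypectomy, other cancer, death,
last contact.

## The weighting correction

Let `F(a) = 1 − exp(−∫₀ᵃ λ(u) du)` be the cumulative incidence implied by
external age-specific rates `λ` (5-year strata). Subjects are classified
into age strata and affected/unaffected cells; cell weights are chosen so
the weighted affected proportion in each stratum equals the external
expectation `p_k`:

    w_affected,k   = p_k n_k / d_k
    w_unaffected,k = (1 − p_k) n_k / (n_k − d_k)

giving mean weight one per stratum (weighted totals preserved) and weighted
affected proportion exactly `p_k` — both hold to 1e−10 on every
non-degenerate stratum and are enforced by property tests.

Two constructions in this correction are genuinely underdetermined by the
method's usual description, and both matter:

**Classification age.** Subjects are stratified by *interview age* (age at
last contact), not by exit age. Among population members interviewed at age
`a`, the proportion already diagnosed is close to the cumulative incidence
near `a`, so `p_k = F(upper bound of k)` is the right calibration target.
Among subjects *exiting* in stratum `k`, by contrast, the affected
proportion depends strongly on the censoring distribution — event exits
cluster at young ages and censoring exits at interview ages — and is far
from `F`. In simulations with known truth, exit-age stratification leaves
the weighted estimate as biased as (or more than) the unweighted one, while
interview-age stratification removes the bias; exit-age stratification
remains available via `stratify_by="exit"`.

**Observable versus net incidence.** A diagnosis enters a study's records
only if it precedes polypectomy, other-cancer and death censoring, so the
*observable* affected proportion among subjects interviewed at age `a` is

    p(a) = ∫₀ᵃ S_c(u) exp(−H(u)) dH(u)

with `S_c` the survival from competing censoring causes — strictly below the
net incidence `F(a)` whenever competing censoring exists. `S_c` is estimated
from the cohort itself by Nelson–Aalen (treating competing censor reasons as
events); this is valid on ascertainment-distorted samples because the
censoring hazards are shared by affected and unaffected subjects. With
roughly half of censorings due to competing causes — as in the registry
cohorts this package emulates — calibrating to the net `F` leaves the
weighted fit essentially as biased as the unweighted one; the
competing-adjusted `p_k` (the default) removes the bias.
`competing_adjust=False` restores the plain net-incidence construction.

Degenerate strata (no affected, or no unaffected) fall back to unit weights
and are flagged; `p_k = 1` with unaffected subjects present is an error
naming the incidence table, since no finite weight can calibrate it.
Optional stabilisations: `merge_degenerate` pools degenerate strata upward;
`min_stratum_count` pools until each group has that many subjects of each
status. Both default off — in the simulation studies below they brought no
reliable improvement at realistic sizes.

Non-carriers are weighted identically against general-population rates
(mutations are rare enough that population rates stand in for non-carrier
rates). Weights are recomputed within every analysis subgroup, because
sampling fractions are properties of the sample they calibrate; this is
recorded in the run manifest.

## Weighted Cox engine

The weighted partial log-likelihood (Breslow ties; Efron available)

    ℓ(β) = Σ_events w_i [ x_i'β − log Σ_{j: t_j ≥ t_i} w_j exp(x_j'β) ]

is maximised by Newton–Raphson with step-halving; steps never decrease the
log-likelihood (asserted by tests). Convergence: relative log-likelihood
change < 1e−9 or max |Δβ| < 1e−8, at most 50 iterations. Monotone
likelihoods are detected two ways: a coefficient passing |β| > 40 during
iteration, or a linear-predictor spread above 20 at convergence
(quasi-separation — the stopping rule would otherwise report an arbitrary
large finite value); both raise an error carrying the likelihood trace, and
the pipeline converts them to "not estimable" rows.

Variance: naive covariance is the inverse observed information; the
family-clustered Huber–White sandwich `A⁻¹ B A⁻¹` builds `B` from
weight-multiplied score residuals summed within families. With singleton
families and unit weights this is the textbook model-robust sandwich
(verified against an independent implementation); duplicating every family
k times scales the robust covariance by exactly 1/k. No small-sample
correction is applied by default (`cluster_correction` adds the g/(g−1)
factor). Confidence intervals are `exp(β̂ ± 1.96·SE_robust)`; all p-values
are two-sided at α = 0.05 with no multiplicity adjustment.

Proportional hazards are tested per covariate by regressing scaled
Schoenfeld residuals on event age: the score `Σ w_k (g_k − ḡ_w) s_k` is
referred to a chi-square with variance `Σ w_k²(g_k − ḡ_w)² · A_jj / Σ w_k`
(the average risk-set covariance approximated by the information matrix,
with the squared weights carrying each event's contribution). Interactions
are tested by adding the product term and Wald-testing its coefficients
against the robust covariance; the test is symmetric in the pair order and
spans multiple columns for categorical factors.

Fractional polynomials use the conventional power set
{−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 = log; a repeated power multiplies by
log x), with the exposure pre-scaled by its sample geometric mean so model
selection is invariant to measurement units. All degree-1 (optionally
degree-2) models are fitted by weighted Cox; the best by partial
log-likelihood is compared with the linear model by a robust Wald test on
its non-linear terms added to the linear model — if the best polynomial *is*
the linear model the comparison p is 1 by construction. A deviance-based
comparison sits behind `method="deviance"`.

## Synthetic cohort generator

Families start from a founder couple (one founder carrier by default, i.e.
conditioning on a segregating family); children per couple are Poisson
(mean 3) over 3 generations; children of one carrier parent inherit with
probability 1/2 (verified against binomial tolerance); spouses who marry in
are non-carrier non-subjects. Disease onset follows the genotype's
piecewise-constant incidence table times `exp(β_bmi5·(BMI−22.5)/5 + Σβ_c x_c)`,
drawn by inversion of the piecewise-exponential cumulative hazard; empirical
cumulative incidence matches the closed form at every stratum boundary
within Monte-Carlo error. Covariates are drawn independently of genotype —
deliberately, so that proband-driven recruitment is the *only* mechanism
that can distort the exposure–disease association. Defaults: BMI normal
(mean 22.5, sd 3.8, truncated to [14, 45]); height sex-specific normal with
weight derived from BMI; smoking (48% ever) and alcohol (65% ever) at age
20; country mix 72/22/6 (ANZ/USA/Canada); mutated gene per family at
38/49/9/4 (MLH1/MSH2/MSH6/PMS2); 10% missing body size; 90% of case reports
verified. These figures mirror the descriptive composition of the large
Lynch-syndrome registry cohorts the generator emulates.

Competing censoring (polypectomy 0.005/py, other cancer 0.004/py, death
0.0004/py) begins at age 20 — polyps, second cancers and registry-recorded
deaths are adult phenomena — and interview (last-contact) ages are uniform
on 25–75; together these approximate the observed censoring mix of such
registries, where competing causes account for roughly half of censorings.
Ascertainment: clinic mode keeps families with ≥ 2 affected members and
marks a random affected member as proband; population mode keeps families
with a case diagnosed within 5 years of interview; other relatives are
retained with probability 0.8 (a single recruitment probability — real
registries used per-centre rules that are not modelled). With the defaults,
roughly 35–40% of retained carriers are affected, versus ~20% in the
simulated population.

`marginal_incidence(config)` returns the covariate-averaged incidence the
simulated population actually experiences (fixed-seed Monte Carlo over the
covariate distribution). Because covariates act multiplicatively, this
marginal table — not the baseline table — is what "correctly specified
external rates" means, matching the fact that published reference rates are
marginal over the population's covariate mix.

What the generator does **not** emulate: familial frailty or polygenic
background (outcomes are independent given genotype and covariates),
covariate–genotype correlation, recall error in self-reported body size,
calendar-period trends, de-novo mutations, genotyping error, pedigree
loops, per-centre recruitment rules. Passing validation therefore shows the
estimator removes *ascertainment* bias under a correctly specified external
table; it does not certify behaviour under frailty-driven residual
correlation (the sandwich variance is validated separately under an ad-hoc
frailty simulation) or misspecified rates.

## Validation studies and their sizes

Chosen to exercise each claim at meaningful precision while keeping the full
suite at a few minutes on one CPU:

- engine agreement: ≥ 20 random cohorts (n ≤ 50), weighted estimates vs
  golden-section maximisation of the definitional likelihood to 1e−6;
  unweighted fits vs an established implementation to 1e−6;
- weight calibration: exact (1e−10) on 40 random cohorts plus a
  property-based suite;
- bias removal: 500 replicates of ~300 families, clinic ascertainment, true
  HR 1.30 — |mean weighted bias| < |mean unweighted bias| and robust-CI
  coverage within 95 ± 2.5% (typical values: weighted bias ≈ −0.015 on the
  log scale against −0.045 unweighted; coverage 93–95%; the small residual
  reflects weight estimation in finite samples and vanishes by ~20 000
  families);
- null calibration: 500 replicates of 2000 families with β = 0 — the Wald,
  interaction, PH and FP tests each reject at 5 ± 2%. At a few hundred
  families the cluster-robust Wald tests run anticonservative (6–9%), a
  known finite-sample property of sandwich inference with few effective
  events — most visible in the interaction test, whose information comes
  from the rare non-carrier cases; levels are therefore verified in the
  regime where the asymptotic approximation holds, and small-study p-values
  near 0.05 should be read with this in mind;
- frailty: robust SE > naive SE in >90% of replicates, CI coverage of the
  marginal limit at 95% within binomial tolerance, duplication scaling
  exact. Shared gamma frailty attenuates the marginal hazard ratio
  (conditional 0.4 → marginal ≈ 0.32 in the test design), so coverage is
  assessed against the marginal limit, the estimand a marginal Cox model
  targets.

## Known limitations

- The calibration target `p_k` ignores the dependence of interview age on
  disease status within a stratum (a 5-year-width approximation); residual
  bias of order a few percent of the effect remains at realistic sizes.
- Weights are treated as fixed in the variance; the extra variability from
  estimating `n_k, d_k` and the censoring survival is not propagated.
- The interaction model places carriers and non-carriers on one baseline
  hazard with a proportional carrier effect; the groups' true age-shapes
  differ, which is absorbed by the robust variance but not modelled.
- No left truncation (entry is birth by design), no time-varying
  covariates, no parametric survival models.
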