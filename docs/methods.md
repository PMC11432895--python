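# Methods

This note documents the models implemented in `bimast`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
world can and cannot establish.

## 1. The problem

Type-2 diabetics in primary care carry a high burden of undetected liver
fibrosis from metabolic dysfunction-associated steatotic liver disease
(MASLD). First-tier blood scores in guideline pathways (FIB-4, the NAFLD
fibrosis score, ELF) were derived in secondary/tertiary cohorts and miss a
large fraction of community cases (spectrum effect). The package implements
the full computational workflow for evaluating a community-derived
alternative — the BIMAST score, a linear function of BMI and AST — from
cohort simulation through score derivation/validation to a cost-utility
comparison of screening strategies.

Because no patient-level data are public, every analysis runs on synthetic
cohorts produced by the package's own generator.

## 2. Synthetic cohort generator (`bimast.cohort`)

Each subject carries a latent fibrosis state drawn from
{none_or_mild, significant, advanced, cirrhosis} with default prevalences
(0.83, 0.06, 0.08, 0.03), chosen so that P(LSM ≥ 8.1 kPa) = 0.17 and
P(LSM ≥ 12.1 kPa) = 0.11 — the prevalence structure of a primary-care
diabetic screening population. Conditional on state, the nine biomarkers
(age, BMI, waist, AST, ALT, platelets, albumin, ELF, LSM) are drawn from a
Gaussian copula:

* marginals are truncated normals (BMI, waist, age, platelets, albumin) or
  truncated log-normals (AST, ALT, ELF, LSM — right-skewed labs), with the
  location parametrised by the median;
* Spearman rank-correlation targets (e.g. BMI–waist 0.8, AST–ALT 0.7,
  AST–LSM 0.35) are converted to copula correlations via
  r = 2 sin(πρ/6) and repaired to positive-definite if needed;
* LSM is drawn from disjoint per-state bands ([2, 8.0], [8.1, 12.0],
  [12.1, 25.0], [25.1, 75] kPa), so the stiffness value and the state label
  can never disagree — an invariant, not a post-hoc filter.

Fibrotic states share the high-stiffness group's biomarker locations
(BMI 36.8 kg/m², waist 120 cm, AST 37 IU/L; non-fibrotic 30.3 / 105 / 26),
so pooled group medians converge to those targets by construction. Scale
parameters are not identified by published medians alone; they were fixed
once at values giving clinically plausible IQRs and are documented in
`cohort._default_group_params`.

The MASLD flag is 1 for every fibrotic subject (the fibrosis of interest is
MASLD fibrosis) and Bernoulli(0.64) otherwise — a documented simplification
that makes overall MASLD prevalence ≈ 0.70 rather than 0.64. All subjects
are diabetic (inclusion criterion), so the NFS diabetes term is always 1.

Randomness: one cohort seed; every variable family draws from a
deterministic sub-stream (`default_rng([seed, k, ...])`), so identical
specs give bit-identical cohorts and adding a variable cannot silently
reshuffle another.

**Spectrum shift.** `spectrum_shift(spec, factor)` up-weights fibrotic
prevalences by (1 + factor) and renormalises, scales AST/ALT medians by
(1 + 0.1·factor), and slides each LSM median toward the top of its band
(`hi − (hi − med)/(1 + 0.2·factor)`), emulating referral-centre case mix.
`spectrum_factor_for_prevalence` inverts the (analytic, monotone)
prevalence map by bisection; e.g. factor ≈ 3.54 reproduces a 48%
(105/218) high-stiffness referral cohort.

**What a green test does not establish.** The generator reproduces the
published marginal prevalences and group medians and a plausible
correlation structure; it does not model ethnicity, treatment history,
measurement failure, or the true joint distribution of labs. Diagnostic
accuracies estimated on synthetic cohorts are properties of the generator,
not estimates of any real score's field performance.

## 3. Scores and strategies (`bimast.scores`)

BIMAST = 0.17·BMI + 0.054·AST − 8.771, screening-positive strictly above
0.063 (significant fibrosis) or 0.102 (advanced). FIB-4 =
age·AST/(platelets·√ALT), positive > 1.3; NFS uses the standard published
coefficients (pinned, overridable), positive > −1.45, with albumin
converted g/L → g/dL at the interface; ELF positive ≥ 9.8 (one referral
pathway uses > 9.5; the threshold is overridable); elastography positive
≥ 8.1 kPa. Strict versus inclusive comparisons follow the published
strategy definitions.

US+LFTs and standard of care (SOC) have no patient-level rule and are
modelled as probabilistic classifiers: one Bernoulli per subject at fixed
sensitivity/specificity (0.35/0.65 for US+LFTs; SOC defaults to a
placeholder 0.175/0.825, i.e. a 50% uptake mix of abnormal-LFTs screening
and no screening), independent of biomarkers given disease status.

## 4. Derivation statistics (`bimast.derivation`)

* **Split**: seeded shuffle, derivation size round(2n/3) (n = 287 → 191/96;
  a published 194/93 split of the same n is not exactly 2:1 and its
  allocation scheme is unknown, so the clean rule is used).
* **Univariate screen**: Mann-Whitney U (asymptotic, tie-corrected) for
  continuous, Pearson chi-square for categorical predictors.
* **Logistic fit**: hand-written Newton/IRLS. Convergence when the score
  vector's max-norm < 1e-8, cap 100 iterations; steps are damped to
  max-norm 50 to survive separation; perfect separation (every response
  fitted to within 1e-4) is flagged non-converged with a warning, and the
  last iterate is returned. Standard errors from (XᵀWX)⁻¹. Cross-checked
  against `statsmodels.Logit` in the tests.
* **Calibration**: Brier score; Hosmer-Lemeshow over 10 equal-count risk
  deciles with statistic Σ (O−E)²/(E(1−E/n_g)) and χ²(groups−2) reference.
  Degenerate bins (expected count 0 or n_g) merge into a neighbour. The
  g−2 reference is the in-sample distribution for a fitted model — the
  calibration simulation in the tests fits before testing.
* **AUROC**: Mann-Whitney concordance with ties counted ½; variance and
  95% CI via DeLong structural components (placements), asymptotic-normal
  bounds clipped to [0, 1]. The paired DeLong test uses the 2×2 placement
  covariance. DeLong's variance equals the leave-one-out jackknife up to a
  factor n/(n−1) (verified in tests); the z-test is mildly liberal at
  n ≈ 200 (measured type-I error ~0.054–0.06 at α = 0.05).
* **Cut-off**: Youden's J operationalises "maximise sensitivity and
  specificity" (no criterion is named in the source material); ties break
  toward higher sensitivity, the screening-appropriate direction.

## 5. Cost-utility model (`bimast.health_econ`)

**Decision tree.** One-off screening splits the cohort by true group
(MLD 0.83 / SLD 0.14 / CC 0.03) and test result: diseased positives →
`SLD_dx`/`CC_dx`, diseased negatives → `SLD_fn`/`CC_fn` (false negatives),
non-diseased → `MLD`, with false positives (fraction 1−specificity of the
MLD mass) incurring a one-off specialist work-up cost and then following
MLD dynamics. Upfront cost per person = test cost + referral cost ×
positive fraction.

**Markov chain.** Nine states — the four disease strata with SLD/CC split
by diagnosis status, plus decompensated cirrhosis (DC), hepatocellular
carcinoma (HCC), liver transplant (LT) and absorbing DEAD. Splitting by
diagnosis status makes "managed disease progresses more slowly" a
parameter constraint (fn row ≥ dx row, destination by destination,
validated at load) rather than a special case. Annual cycles over a
40-year horizon; costs and QALYs accrue at cycle start discounted by
(1+r)^−t with r = 3.5%/year; no half-cycle correction by default
(switchable, `half_cycle_correction`). Background non-liver mortality is an
age-independent annual probability p_bg composed multiplicatively:
effective row = (1−p_bg)·disease row + p_bg·DEAD, which keeps rows
stochastic under any parameter draw.

**Outcomes.** Discounted life-years and QALYs (cohort of 287), lifetime
discounted cost per person, correct-diagnosis rate sens·prev +
spec·(1−prev), and the ICER vs SOC = Δcost·cohort / ΔQALY_cohort.
Dominant/dominated/zero-ΔQALY cases return flags, never signed ratios.
One-way sensitivity re-runs the full pipeline over a parameter grid
addressed by dotted path (`transitions.SLD_fn.CC_fn`, `horizon`, …).

**PSA/CEAC.** Joint draws with common random numbers across strategies:
beta for probabilities and utilities, gamma for costs (standard families),
plus a degenerate `fixed` family for testing. The CEAC reports, at each
willingness-to-pay λ, the fraction of draws in which a strategy maximises
net monetary benefit λ·QALY − cost; probabilities sum to 1 across
compared strategies.

**Placeholder parameters.** The packaged `data/default_econ.yaml` is
explicitly a placeholder set: the study-specific transition, cost and
utility tables live in a supplement that is not redistributed here.
Values were chosen once to satisfy every structural invariant and to sit
in the qualitative regime such models report — early diagnosis buys
health but is not cost-saving, because diagnosed disease carries
management/surveillance costs (SLD_dx £800/y vs undetected £150/y;
CC_dx £3,500/y vs £400/y) while undetected disease progresses faster to
expensive end-stage states (DC £12,000/y, HCC £15,000/y). On these
placeholders all six strategies gain QALYs over SOC, elastography (the
reference standard, sens = spec = 1) gains most, and base-case ICERs fall
between roughly £4,000 and £7,000/QALY — under the £20,000/QALY
threshold. These numbers characterise the placeholder world only;
transcribing a published parameter set over the YAML is the supported
path to reproducing its table.

Strategy operating points in the config default to published primary-care
values where printed (BIMAST 0.94/0.44, US+LFTs 0.35/0.65, TE 1/1, FIB-4
sensitivity 0.62 and ELF sensitivity 0.46 from their reported
false-negative rates); the unprinted specificities (FIB-4 0.80, NFS
0.60/0.70, ELF 0.85) and the SOC mix are placeholders.

## 6. Numerical choices and degenerate inputs

* All RNG streams derive from explicit integer seeds; seeds are masked to
  < 2³¹.
* Cohort CSV round-trips at 6 significant digits; readers validate the
  header, numeric types, lab positivity and the LSM/state coupling, and
  report the first offending 1-based data row.
* `n = 0` cohorts are legal (empty frame); splits need n ≥ 3;
  single-class outcomes raise rather than return degenerate statistics;
  zero-denominator diagnostic ratios return NaN flags rather than raising.
* Transition rows are validated to 1e-12; occupancy conservation holds to
  1e-10 over the horizon.

## 7. Known limitations

* The generator's per-state scales and correlations are plausible, not
  estimated; external-validation behaviour is emulated only through the
  prevalence/location shift, not through genuinely different case mix.
* Background mortality is age-independent; no age/sex life tables.
* SOC's composition (abnormal-LFT screening vs no screening) is a single
  fixed operating point, not an explicit mixture model.
* PSA draws vary a configured subset of parameters; correlations between
  parameters are not modelled.
* Cardiovascular co-outcomes and individual-level microsimulation are out
  of scope.
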