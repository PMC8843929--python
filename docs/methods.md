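# Methods

`ssrrm` implements a genetic evaluation of residual feed intake (RFI) from
daily feeder records, in two model forms, with pedigree or combined
pedigree+genomic relationship matrices, and a forward-validation harness to
compare the four configurations. This note records the models, the
numerical choices, and what the synthetic data generator does and does not
emulate.

## Models

**Animal (repeatability-free) model.** One record per boar — average daily
feed intake (ADFI) over the retained test period:

```
ADFI_ijlk = mu + YS_i + pen_j + b1*ADG_k + b2*BFA_k + b3*SBW_k + b4*MBW_k
            + litter_l + a_k + e_ijlk
```

with year–season and pen fixed effects; average daily gain, adjusted
back-fat, start weight and metabolic body weight (mean body weight^0.75) as
fixed regressions; random litter and additive effects, `a ~ N(0, A sigma_a^2)`
(or `H sigma_a^2`). Regressing feed intake on its energy sinks makes the
additive effect an RFI breeding value.

**Random regression model (RRM).** One record per boar-day of daily feed
intake (DFI), with random curves in normalised Legendre polynomials
`phi_m(t*) = sqrt((2m+1)/2) P_m(t*)` of standardised age
`t* = 2(t - t_min)/(t_max - t_min) - 1`:

```
DFI_ijkt = YS_i + pen_j + (covariate regressions as above)
           + sum_m litter_lm phi_m(t) + sum_m a_km phi_m(t)
           + sum_m pe_km phi_m(t) + e_ijkt
```

Additive coefficient vectors have covariance `Ka (x) A` (animal-major
ordering), permanent-environment and litter coefficient vectors are i.i.d.
with covariances `Kpe` and `Klitter`; the residual is homogeneous and
time-independent. Default orders are p=2 (additive), q=1 (pe), n=1
(litter), selectable by BIC over a grid.

The normalisation constant is the Kirkpatrick convention, making the basis
orthonormal on [-1, 1] so coefficient variances are interpretable as
variance contributions; the age-standardisation bounds are stored on the
`ModelSpec` (population bounds 99–172 d by default) so basis evaluation is
reproducible across fits.

## Relationship matrices

* `A` by the tabular method with inbreeding; `A^-1` by Henderson's rules
  with inbreeding coefficients (and `log|A| = sum log d_i`, needed by the
  restricted likelihood) from the Meuwissen–Luo recursion. Both are
  cross-checked against each other and against dense oracles in the tests.
* `G` by VanRaden method 1, `G = ZZ'/(2 sum p_j (1-p_j))`, with observed
  allele frequencies by default (the frequency source is an argument);
  monomorphic markers contribute nothing.
* Single-step: `H^-1 = A^-1 + [0 0; 0 tau*(alpha*G + beta*A22)^-1 - omega*A22^-1]`
  on the genotyped block, defaults `(alpha, beta, tau, omega) =
  (0.95, 0.05, 1, 1)`. The alpha/beta blend is also the invertibility
  guard; no additional diagonal loading is applied. `A22` is taken by
  sub-setting the full `A` (exact, simple at these scales).

## Mixed-model equations and REML

Henderson's MME are assembled sparse:
`C = W'W/sigma_e^2 + blockdiag(0, kron(Rinv_t, Kinv_t))` per random term,
where `Rinv` is `A^-1`/`H^-1` for the additive term and identity otherwise.
BLUP solutions come from a sparse LU factorisation; prediction-error
(co)variances from the dense inverse of `C` (problems here stay below ~4k
equations, where a dense Cholesky + LAPACK `dpotri` is fast and exact).

Variance components are estimated by EM-REML with average-information (AI)
acceleration:

* EM updates `K_t <- (U' Rinv U + trace-block(Cinv)) / n_levels` and
  `sigma_e^2 <- y'e / (N - rank(X))` are monotone in the restricted
  likelihood and keep every `K` inside the PSD cone.
* After a short EM warm-up, AI-Newton steps are proposed using gradients
  assembled from the same MME-inverse quantities and the standard
  `f = V-dot P y` working vectors; a step is accepted only if it does not
  decrease the likelihood (step halving, then EM fallback). After repeated
  rejections — which happen when the optimum sits on the PSD-cone boundary,
  e.g. an over-parameterised grid cell driving `Kpe` singular — AI is
  retried only every third iteration.
* Convergence: relative parameter change < `tol` (denominator floored at
  1e-6 of the phenotypic-variance scale), or likelihood change <
  `logl_tol`. The second criterion is what terminates boundary cases,
  where EM approaches the singular optimum only geometrically; for BIC
  comparisons a `logl_tol` of 1e-3 leaves the likelihood far closer to the
  plateau than any BIC spacing of interest.
* `-2 logL = N log sigma_e^2 + sum_t [k_t log|R_t| + L_t log|K_t|]
  + log|C| + y'Py + const`, with `log|A|` from the Meuwissen–Luo `d_i`.

`BIC = -2 logL + k ln N` with `k` the free (co)variance parameters
(vech of each `K` plus the residual); order selection reports the full
table and breaks ties by fewest parameters, then lexicographic (p, q, n).

Component estimates used with `H` are those estimated with `A` (the
evaluation-pipeline convention this package mirrors).

## EBVs, reliabilities, deregression, validation

* RRM EBV: average of `phi(t)' a_k` over the animal's retained test days;
  animals without records use the population-common retained-age grid. In
  forward validation *all* animals are averaged on the common grid: window
  heterogeneity otherwise puts EBVs on animal-specific scales and
  measurably decorrelates training EBVs from full-data deregressed proofs.
* Reliability: `r^2 = 1 - PEV/var_a` clipped to [0, 1]; for the RRM both
  terms are quadratic forms `m' (.) m` in the mean basis vector `m` over
  the grid (PEV block from the MME inverse, `var_a = m' Ka m`).
* Deregression (Garrick-style, parent-average removal): with
  `lambda = (1-h^2)/h^2`, `alpha = 1/(0.5 - r2_PA)`,
  `delta = (0.5 - r2_PA)/(1 - r2_i)`,

  ```
  Z'Z_PA = lambda (0.5 alpha - 4) + 0.5 lambda sqrt(alpha^2 + 16/delta)
  Z'Z_i  = delta Z'Z_PA + 2 lambda (2 delta - 1)
  DRP    = EBV + 2 lambda (EBV - PA)/Z'Z_i
  w      = (1 - h^2) / ((c + (1 - r2_DRP)/r2_DRP) h^2),  c = 0.5 default
  ```

  Animals below the reliability floor (0.10 default) are flagged and
  excluded, not errors. For the RRM the `h^2` entering `lambda` is taken
  on the scale of the averaged trait (residual shrunk by the mean number
  of test days), consistent with what the EBV represents. Note the DRP
  *point values* are invariant to `h^2` (the lambdas cancel); only the
  weights depend on it.
* Forward validation: animals born after the cutoff date are the
  validation set; their records are masked in four training fits
  (animal/RRM x A/H). Accuracy is the Pearson correlation of their
  training EBVs with DRP from the full-data pedigree fit of the matching
  model; dispersion is `|1 - b|` for the regression of DRP on EBV.

**A caveat established empirically here:** with permanent-environment or
litter curves in the model, an animal's own records cannot cleanly separate
its Mendelian-sampling deviation, and DRP then tracks true breeding values
*worse* than the parent average does (the two-information-source
deregression over-credits own-record information). In the pure
additive+residual regime the expected ordering holds, and the test suite
checks it there.

## Synthetic data generator

The generator emulates a performance-tested boar population at reduced
scale: non-overlapping generations with random mating from the previous
generation (sexes alternate deterministically so both sexes always exist);
one litter of full sibs per mating; gene-dropped biallelic SNPs from
Hardy–Weinberg founders with uniform MAF in (0.05, 0.5); per-animal test
windows drawn inside ages 99–172 d with 48–74 recorded days so at least 34
survive the one-week adaptation cut; covariates drawn around published
descriptive statistics (start weight 49.2 ± 10.4 kg, ADG 0.91 ± 0.13 kg/d,
back fat 12.2 ± 2.4 mm); body weight growing linearly within the window.

Breeding-value curves are **marker-determined by default**: every SNP
carries a small (p+1)-vector effect, scaled so founder coefficient vectors
are N(0, Ka); transmission then realises the parent-average +
Mendelian-sampling recursion through actual allele inheritance, and the
marginal coefficient covariance is `Ka (x) A`. This matters: if breeding
values are instead drawn by the pedigree recursion independently of the
markers (`genomic_additive=False`, available for experiments that do not
involve G), realized genomic relationships are uninformative about the
simulated genetics and single-step evaluation can only lose accuracy —
the generator would contradict the phenomenon the package exists to show.

Covariance defaults `Ka = diag(0.023, 0.03, 0.035)`,
`Kpe = diag(0.04, 0.002)`, `Klitter = diag(0.02, 0.002)`,
`sigma_e^2 = 0.135` (all (kg/d)^2) reconcile the trait's anchors jointly:
a U-shaped daily heritability in [0.13, 0.46], a test-average
(ADFI-scale) heritability near 0.3, and a flat permanent-environment
variance of visible magnitude. The anchors genuinely interact — most
daily genetic variance sits in the slope/curvature terms that average out
over the window, so the h2 curve and the test-average h2 constrain
different combinations of the same matrices and no single anchor
suffices. The visit layer splits each daily intake
into 3–12 visits (Dirichlet shares, exact sums), quantises visit weights
to 0.5 kg scale readings, attaches Poisson(0.2) daily error counts and
perturbs observed intake by -0.05 kg per error, which the preprocessing
stage re-estimates and removes.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure (independent loci — G quality, not LD realism, is what
downstream stages consume), selection across generations, seasonal intake
curves, missing feeder days, or the visit-level error taxonomy of real
equipment. Passing tests therefore validate the statistical machinery, not
robustness to those real-data features.

## Problem sizes and numerical settings in the shipped experiments

Test-suite and acceptance-script experiments use reduced scales chosen so
each estimator is tested where it has statistical power: variance-component
recovery on 600 phenotyped animals in 100 litters of 6 across two
phenotyped generations (phenotyped parent-offspring pairs are what
separate additive from permanent-environment curves), ~34 retained days
each; BIC order selection on ~120 animals
with long (65–74 d) windows, 10 replicates; the four-configuration
validation on ~200 phenotyped animals, 600 SNPs, 70% genotyped, 20
replicates; REML tolerances `tol=1e-3, logl_tol=2e-4` in these loops
(the default `1e-8` is used for small closed-form checks where exactness
is the point).

## Known limitations

* EM/AI-REML converges slowly when the optimum is on the PSD boundary;
  such fits are reported with `converged=False` and are excluded from BIC
  selection rather than silently used.
* Reliability for the RRM is the quadratic-form PEV construction described
  above; published RRM reliability approximations differ in detail.
* The error-count adjustment assumes a linear, count-proportional intake
  perturbation with a random animal intercept (statsmodels `MixedLM`), the
  simplest model consistent with its purpose.
* `A22` by sub-setting dense `A` and dense inversion of the genotyped
  block cap the practical genotyped-set size at a few thousand animals —
  appropriate for this package's scale, not for national evaluations.
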