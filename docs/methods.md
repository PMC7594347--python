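# Methods

## Model and assumptions

`ultravar` fits a single-record animal model per trait-by-laboratory cell:
the phenotype is the sum of an overall mean, a random technician effect, a
random contemporary-group (CG) effect nested within technician, a random
additive-genetic effect for every pedigree animal, and a residual.  The
only fixed effect is the mean; age at scan is handled solely by the
breed-specific eligibility window (Angus 320–460 d, Simmental 270–500 d,
Hereford 301–530 d, closed intervals), not as a covariate.  The model
assumes one record per animal × trait (no permanent-environment effect),
CGs scanned by exactly one technician, and technicians reporting to
exactly one laboratory; `validate_structure` enforces all three.
Technician and CG are treated as random because the study's question is
how much variance they carry, and because technicians are a sample from a
certified pool.

The additive covariance is `A σ²_a` with `A` the numerator relationship
matrix.  `A` and its sparse inverse support both sire–dam and
sire–maternal-grandsire pedigrees; the sire–MGS rules use relationship
weights (0.5, 0.25) and Mendelian-sampling variances 11/16, 3/4, 15/16, 1
for (both / sire only / MGS only / neither) known, with inbreeding ignored
(the maternal line is untracked).  One deliberate choice: `build_A`
without inbreeding (and always in sire–MGS mode) uses the diagonal
recurrence `a_ii = d_i + k'A_pp k` rather than forcing `a_ii = 1`, so that
the tabular matrix and Henderson's sparse inverse are an exact inverse
pair on every pedigree; for the usual case of unrelated non-inbred
founders the diagonal is 1 anyway.

## Restricted likelihood and optimization

−2 log L is evaluated via the mixed-model equations:
`log|R| + log|G| + log|C| + y'Py`, with terms constant in the variance
components (log|A|, 2π) dropped.  The coefficient matrix is factorized
with SuperLU under a symmetric minimum-degree ordering
(`MMD_AT_PLUS_A`, symmetric mode); the unsymmetric default ordering fills
in badly on the dense mean row.  The scale-invariance identity (scaling
records by k and all variances by k² shifts −2 log L by (n−1) log k²) and
a dense GLS oracle are used as correctness checks in the tests.

Estimation is derivative-free: Nelder–Mead over log-variances (positivity
by construction, with a floor of 1e−8 × the phenotypic variance), stopping
when the variance of −2 log L across simplex vertices is below 1e−10
(configurable).  Two safeguards address known simplex pathologies:

- **Re-inflation.** A collapsed simplex can satisfy the f-variance rule
  away from the optimum, especially in the 15-parameter trivariate
  problem.  After each converged run the search restarts from the
  incumbent with a fresh, progressively smaller simplex until −2 log L
  stops improving.
- **Multi-start confirmation.** `fit_univariate` repeats the search from
  0.5× and 2× the starting components and records how many restarts agree
  in −2 log L (default agreement tolerance 1e−6), as evidence of a global
  maximum.

EBVs and the mean come from the MME solution at the final components; the
prediction-error variance is the corresponding diagonal of the inverse
coefficient matrix (× σ²_e in the residual-scaled form) and accuracy is
`sqrt(1 − PEV/σ²_a)`, clipped to [0, 1].

Standard errors of the percentage partitions and of h² are a delta method
on the inverse of a central-difference Hessian of −2 log L at the optimum
(observed information).  This is standard asymptotic REML practice; the
original software's SE method is not documented, so these SEs are not
claimed to reproduce published ones.

## Trivariate lab-as-trait model

Records from the three labs are stacked with one fixed mean per lab.
Technician, CG and residual blocks are diagonal across labs — no
technician, CG or animal record spans labs, so those cross-covariances are
structurally absent — while the genetic block is `A ⊗ G₀`.  G₀ is
parameterized by its Cholesky factor (log-diagonal), which keeps it
positive semidefinite throughout the search; per-lab variances and factor
entries give 15 free parameters.  Starting values come from the three
univariate fits, with off-diagonal genetic covariances started at a
neutral correlation of 0.5 (0 for null scenarios).  An optional staged
search first optimizes the six G₀ parameters at fixed nuisance variances —
the genetic covariances are the flattest directions, and this gets them
near their optimum cheaply — before the full 15-parameter polish.  A lab
pair with no common sire among recorded animals has a structurally
unidentifiable genetic covariance; the fit warns and flags such pairs.

Genetic correlations are `r_g = σ_a(i,j)/√(σ²_ai σ²_aj)`.  Their standard
errors use the accuracy-based formula (README) over the sires with ≥ 1
recorded progeny in each lab of the pair, accuracies averaged
arithmetically; the same sire set feeds the Spearman rank correlation of
sire EBVs.  Sire EBVs and accuracies for these diagnostics come from the
per-lab univariate fits ("EBVs for the trait as interpreted by lab i").
The z-test of `r_g` against 1 is two-sided at the 1.959964 normal
quantile; sidedness is a convention choice.  The printed SE formula's
grouping is typographically ambiguous in the source material; the
reconstruction used here is the one that reduces algebraically to the
classical `(1 − r_g²)/√(N − 1)` at unit accuracies (verified symbolically
in the tests).

## Diagnostics

Bartlett's homogeneity test runs on residuals defined as record minus its
CG mean, grouped by technician; CGs with a single record are dropped
(counted).  CG-mean centering is an interpretive choice for "correction
for contemporary-group effects" — BLUP residuals would be an alternative.
The statistic is the classical one with the Box correction (via
scipy.stats.bartlett, hand-formula oracle in the tests); a zero-variance
group yields an infinite statistic, flagged explicitly.  Between-lab
dispersion is `100·(max − min)/mean` of the per-lab component estimates.
Within-CG heritability `σ²_a/(σ²_a + σ²_e)` deliberately excludes
technician and CG variance from the denominator, so it always exceeds the
additive percentage of total phenotypic variance.

## Synthetic data generator

`simulate_dataset` emulates the study structure exactly: technicians
assigned to one lab, CGs to one technician, each animal recorded in one
lab; founders (sires, dams, optionally grandparents for three-generation
pedigrees) unrelated; recorded animals from random sire × dam matings
giving paternal half-sib families; breeding values by gene dropping
(founders N(0, G₀); offspring = parent average + Mendelian deviation with
variance 1/2, 3/4 or 1 of G₀ for two/one/no known parents); technician,
CG and residual effects drawn i.i.d. normal at the configured variances;
ages uniform in the breed window.  One seed drives three split RNG
streams (structure, breeding values, environmental effects) so changing
one configuration field perturbs only that component.  `sire_sharing`
sets the fraction of sires usable in every lab and hence the
identifiability of between-lab genetic covariances; `dams_unknown` yields
pure paternal half-sib pedigrees; `cg_size_dispersion` draws
negative-binomial CG sizes for skewed group-size distributions.

Default scenarios use the published component estimates as generating
truths: `angus_lab1_lma_config` (one lab, 10 technicians × 8 CGs × 10
animals, 80 sires, mean 78.2 cm²) and `lab_as_trait_config` (three labs,
10 technicians × 8 CGs × 12 animals per lab, 300 sires shared across
labs, dams unknown, per-lab Angus LMA truths with configurable `r_g`).
The trivariate family sizes (~10 progeny per shared sire) were set by a
Monte-Carlo pilot: below ~8 progeny the `r_g` likelihood at these variance
ratios is nearly flat and single-replicate estimates range from 0.45 to
1.0 even at verified convergence.

What the generator does *not* emulate: selection, assortative mating,
overlapping generations, genotype data, skewed technician workloads,
missing parents in recorded generations, or trait-specific recording
gaps.  Passing recovery tests therefore show the estimator is correct and
calibrated under the model's own assumptions at desk scale — not that
real breed-association data meet those assumptions.

## Problem sizes and numerical settings

Test and acceptance runs use scaled-down studies chosen as the smallest
designs at which each estimand is identifiable: univariate recovery at
800 records per replicate (20 replicates), trivariate recovery at 2,880
records with ~300 shared sires (10 replicates, simplex f-variance
tolerance 1e−8 with the staged search), Bartlett calibration at 1,000
null simulations of 5 × 20 observations, and the end-to-end smoke study
at 3 technicians × 4 CGs × 6 animals per lab for three traits.  At these
scales the between-lab genetic correlation carries a standard error of
roughly 0.15–0.2 per replicate — the flat-likelihood regime the original
analysis reports for its least-informative breed — so only means over
replicates are meaningful.

## Known limitations

- Heterogeneous-residual models are assessed (Bartlett) but not fitted.
- No EM/AI-REML gradients; the simplex is the only optimizer.
- Percentage/heritability SEs are asymptotic and can be NaN when the
  Hessian is indefinite at a boundary optimum.
- The sire–MGS inverse follows the standard rules; whether the original
  software used the same formulation is unknown.
- Animals without records are always carried in the genetic block
  (standard animal-model practice); dropping them is not offered.
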