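# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the limitations of `twinace`.

## The biometric model

The classical twin design rests on three assumptions: monozygotic (MZ)
twins share all segregating genes while dizygotic (DZ) twins share half on
average; MZ and DZ twins are equally correlated for shared environmental
exposures (the equal-environment assumption); and mating is random with
respect to the traits.  Under these, the covariance of a trait pair within
and across twins identifies an additive-genetic (A), common-environment
(C) and unique-environment (E) decomposition.

`twinace` implements the bivariate case with trait 1 a binary disease
status and trait 2 a continuous score.  Per sex `s`, three 2×2
lower-triangular path matrices `a_s, c_s, e_s` generate the component
covariances `Σ_X = x xᵀ`, guaranteeing positive semi-definiteness.  The
within-person covariance is `Σ_A + Σ_C + Σ_E`; cross-twin blocks are
`Σ_A + Σ_C` (MZ), `0.5 Σ_A + Σ_C` (same-sex DZ), and
`a_M G a_Fᵀ + c_M H c_Fᵀ` for opposite-sex pairs, where the 2×2 matrices
G and H hold the cross-sex factor correlations.  Under the null of no
qualitative sex differences G = 0.5·I and H = I, the values same-sex DZ
pairs imply; the qualitative variants free all four entries of G
(`HetACEg`) or H (`HetACEc`), releasing 4 parameters each and reproducing
the 4-df likelihood-ratio tests of the ladder.  Opposite-sex pairs are
ordered male-first throughout so the cross-block orientation is
unambiguous.

### Liability threshold and identification

The binary trait is the indicator that a latent standard-normal liability
exceeds a threshold `t_s + β·age` (β in liability SD per year, shared
across sexes by default; configurable).  The liability scale is fixed by
the constraint `a11² + c11² + e11² = 1` per sex.  Internally the
constraint is imposed by a spherical reparameterization —
`(a11, c11, e11) = (sinθ₁cosθ₂, sinθ₁sinθ₂, cosθ₁)` with θ ∈ [0, π/2] —
so the optimizer works on a plain box and the diagonal-path sign
convention (diagonals ≥ 0) holds by construction.  The continuous trait's
scale is free: its residual variance per sex is carried by the e-paths
(and the other trait-2 paths) rather than fixed by pre-standardization,
so sex differences in residual variance are part of the model.

### Degrees of freedom and AIC

Free parameters are counted nominally: 9 Cholesky paths per sex (one set
total under `HomoACE`), one threshold and one continuous-trait mean per
sex, one shared age slope, plus 4 when G or H is free.  The unit-liability
constraint is treated as a scale convention, not as removing a counted
parameter.  Degrees of freedom follow the observed-statistics convention
`df = (number of non-missing observed data values) − (free parameters)`,
and `AIC = −2LL − 2·df`.  Under this convention the qualitative
constraints release exactly 4 parameters each and equating the sexes
removes exactly 9, matching the published ladder arithmetic this package
is designed to reproduce.

## The FIML likelihood

Each family (twin pair or singleton) contributes the marginal likelihood
of its observed elements of `(d₁, y₁, d₂, y₂)`.  Writing the observed
continuous elements `y` and binary elements `d`:

* `y` contributes its multivariate normal density (dimension ≤ 2, closed
  form);
* conditional on `y`, the liabilities of the observed binary elements are
  normal with analytically known mean and covariance, so `d` contributes a
  1- or 2-dimensional normal orthant probability — no integral beyond the
  bivariate normal CDF is ever required;
* missing elements are simply dropped (FIML under missing-at-random,
  stated here explicitly as the package's contract).

Families are compiled into blocks sharing a zygosity-sex group and
missingness pattern; within a block the covariance and conditional
correlation are constant and only conditional means and age-dependent
thresholds vary, so a full −2LL evaluation is a handful of vectorized
operations.

### Bivariate normal probabilities

The bivariate normal CDF is computed by Gauss–Legendre quadrature on the
arcsine-transformed correlation integral (6/12/20 nodes by |r|), switching
to the transformed tail expansion for |r| ≥ 0.925 — the
Drezner–Wesolowsky/Genz approach.  Agreement with scipy's independent
implementation is at machine precision for moderate correlations and
better than 1e-8 throughout, well inside the 1e-8 budget assumed by the
likelihood; the test suite asserts this directly and also checks the
family likelihood against brute-force adaptive quadrature of the joint
density (|Δ log L| < 1e-6 over random families).  Orthant probabilities
are floored at 1e-300 before the log; `norm.logcdf` handles the
single-binary case without underflow.

## Optimization

Bound-constrained quasi-Newton (L-BFGS-B) on the reparameterized vector.
Numerical-gradient step `eps = 1e-6` (the default 1e-8 sits below the
objective's relative noise floor at −2LL ≈ 2·10⁴ and stalls line
searches); `ftol = 1e-9`, `gtol = 1e-6`, at most 600 iterations per
start.  Starting values: equal-thirds variance split (θ₁ = arccos(1/√3),
θ₂ = π/4, cross-paths 0), thresholds at the normal quantile of the
observed prevalence per sex, continuous means/scales from the observed
residuals.  Five jittered restarts by default, stopping early once two
starts agree within 1e-4; a fit that exhausts its iteration budget is
returned with `converged=False` rather than raising.

`fit_ladder` warm-starts `HetACEg`/`HetACEc` at the `HetACE` optimum with
G/H at their null values (and `HomoACE` at the across-sex average), which
both speeds the ladder up and guarantees the nesting inequality
−2LL(richer) ≤ −2LL(nested) structurally.  Model selection prefers the
more parsimonious model when its constraint is non-significant at α = .05
or when AIC favours it by ≥ 10; a constrained model must survive every
comparison that tests it, and if all constraints are rejected the jointly
retained full models are reported together.

Non-positive-definite implied covariances (possible when G or H is free)
are handled by returning a large penalty value, keeping the optimizer
inside the feasible region.

## Confidence intervals

Latent correlations (tetrachoric, polyserial) and model parameters get
profile-likelihood intervals: the bounds where the profile −2LL (nuisance
parameters re-optimized) rises by the χ²₁ quantile, 3.84 at 95%.  These
respect the [−1, 1] and [0, 1] boundaries and reproduce the one-sided
intervals typical of variance components estimated near 0; on an exactly
quadratic likelihood they coincide with Wald intervals (asserted to 1e-3
in the tests).  Pearson correlations use the standard Fisher-z interval.
Clustering of twins within families is ignored by the plain phenotypic
correlations (an explicit limitation, below).

## The synthetic cohort generator

The generator emulates the study conditions of a South-Asian adult twin
register: ~1980 twin pairs (MZM 420, MZF 426, DZM 290, DZF 299, DZOS 542 —
sexes split near-evenly within zygosity, which real registers only
approximate) plus 2019 singletons; ages truncated-normal with mean 43.0,
SD 14.3 on [18, 90], shared within a pair; disease prevalence ≈ 7.9% at
the mean age with a default threshold slope of −0.015 liability SD per
year (prevalence rising with age).  Default variance components are the
sex-limitation estimates the fitting module is designed to recover:
liability trait 77/8/15 (a²/c²/e², %) in females and 82/12/6 in males;
continuous trait 23/13/64 in females and 7/22/71 in males; genetic
correlation 0.53 (F) and 0.38 (M).  The environmental correlations are
not published anywhere to our knowledge; the defaults set rC = 0 and
solve the bridge identity `r_ph = Σ √(x²₁x²₂)·rX` so the within-person
cross-trait correlation equals 0.15 (F) and 0.06 (M), giving
rE ≈ −0.236 (F) and −0.151 (M).

Latent pair vectors are drawn directly from the model-implied 4×4
covariance per group (so the generator and the likelihood share their
moment algebra but not their sampling or integration code; the tests
check the moments against empirical covariances of large simulated
samples).  The continuous trait is emitted as a BDI-like score
`clip(round(exp(m_s + σ·x) − 1), 0, 63)` with log-scale means 1.25 (M) /
1.45 (F) and σ = 0.85, chosen to give a realistic mean (~4.5–5), a
positive skew, and a raw-score kurtosis well above the residual kurtosis
after the log transform — so the preprocessing stage is exercised
end-to-end.  The rounding adds a small unshared measurement-error
component (a few percent of the log-scale variance), which mildly
attenuates recovered covariances; this is deliberate, as real ordinal
scores behave the same way.

What the generator does **not** emulate: biomarker values conditional on
disease duration or treatment, assortative mating, gene–environment
interaction, age correlation between unrelated family members, item-level
BDI structure, or informative missingness.  Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to their violation in real data.

## Recovery studies and problem sizes

`twinace.recovery.female_recovery_study` simulates female two-group
cohorts (MZ + DZ pairs) at the published female components, runs the full
pipeline, and averages the recovered standardized estimates over
replicates.  The design uses 2000 MZ and 1500 DZ pairs: at a few hundred
pairs per group the ML genetic correlation piles up at the rA = 1
boundary (the trait-2 specific genetic path estimates to 0) in a
non-trivial fraction of replicates — genuine small-sample ML behaviour —
which inflates the replicate mean; at the chosen size the boundary mass is
negligible and replicate means are unbiased.  The acceptance script runs
30 replicates; the test suite 10.  `polyserial_recovery_study` draws
bivariate-normal samples (n = 5000), dichotomizes one margin at its
empirical 92nd percentile, and averages the polyserial ML estimate over
50 replicates.

## Known limitations

* ADE models, dominance, sibling interaction, and >2 traits are out of
  scope; the ladder covers exactly the four ACE sex-limitation variants.
* Phenotypic-correlation CIs do not adjust for twin clustering.
* The threshold age slope is equated across sexes and zygosity groups by
  default (configurable), and the continuous trait enters only through
  its age/sex-residualized value.
* FIML assumes missing-at-random; no sensitivity analysis is provided.
* Profile CIs for *derived* quantities (e.g. standardized proportions)
  are supported only through the internal parameterization; intervals for
  named internal parameters are first-class.
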