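# Methods

## The model

All evaluations fit the single-trait animal model

    y = Xβ + Za + e,    a ~ N(0, K σ²ₐ),    e ~ N(0, I σ²ₑ)

where `y` are trait records, `X` carries an intercept plus full-rank dummy
codings of sex and feed room (first level as reference, factors additive,
no interaction), `Z` allocates records to individuals, and `K` is one of

* **A** — the pedigree numerator relationship matrix, built by the tabular
  method with `1 + Fᵢ` on the diagonal.  Pedigrees must list parents before
  offspring; the container rejects anything cyclic or unordered at
  construction.
* **G** — VanRaden's genomic relationship, `G = ZZ′ / 2Σ pᵢ(1−pᵢ)` with
  `Z = M − 2pᵢ` and `pᵢ` the *observed* allele frequency of the genotyped
  set.  Monomorphic markers contribute zero and are excluded from the
  denominator.  Missing calls are mean-imputed to `2pᵢ` only at matrix
  construction; the stored codes keep their missingness.
* **H** — the single-step blend, used through its inverse
  `H⁻¹ = A⁻¹ + [[0,0],[0, G⁻¹ − A₂₂⁻¹]]` so genotyped and ungenotyped
  individuals are evaluated jointly.

Heritability is `h² = σ²ₐ/(σ²ₐ+σ²ₑ)`.

## Numerical choices

**G regularization.** Duplicated animals or n > m make raw G singular, so
wherever G serves as the kinship of a model fit it is blended as
`G* = (1−w)G + wI` with default `w = 0.01` (recorded on the result,
configurable, `w = 0` allowed).  Applying the same blend in the GBLUP and
single-step paths is what makes the two fits agree exactly when every
individual is genotyped.  No G-to-A₂₂ rescaling step is applied (a config
hook exists, default off).

**REML.** Average-information REML with EM fallback: the AI step is
step-halved toward the interior up to five times and otherwise replaced by
the (always-positive) EM update.  Convergence is declared when the
parameter change drops below 1e-8 relative to the phenotypic variance —
relative to the scale, not to the parameter itself, so a variance heading
to the boundary cannot stall the criterion — with a 200-iteration cap.  K
is eigendecomposed once, which diagonalizes V and makes each iteration
O(n); if the AI/EM loop still has not converged (very low-information
fits, e.g. a handful of markers), the profiled restricted likelihood —
exact for this two-component model — is maximized directly over h² by
bounded scalar search and the AI matrix is recomputed at that optimum.
The SE of h² comes from the delta method on the inverse AI matrix.

**Solvers.** Henderson's mixed-model equations (coefficient-matrix form,
needs K⁻¹) and the algebraically identical V-form
`â = σ²ₐ K Z′V⁻¹(y − Xβ̂)` (needs K, tolerates a singular one) are both
provided.  Model fits use the V-form, which keeps GBLUP *exactly* equal to
its SNP-BLUP ridge reformulation at `w = 0`; the Henderson form backs the
ssGBLUP tests where H⁻¹ is the natural object.  Individuals in K without
records are predicted through their relationships — this is also how
cross-validation masks phenotypes without removing animals.

**Variance components in CV** are re-estimated on each training fold to
avoid leakage.

## Bayesian-alphabet samplers

All five families share `y = Xβ + Wα + e` with `W = M − 2p` centered by
*training-set* frequencies (centering, not standardization, consistent
with the G construction) and differ in the prior on each marker effect
`αⱼ`.  Throughout, **π is the probability of a NON-zero effect** (the
convention can be the opposite elsewhere); when estimated it has a uniform
prior and a Beta conditional.

* **BayesB** — spike at zero with probability 1−π, else a scaled t
  implemented by variance augmentation: normal effect with a per-marker
  scaled-inverse-χ² variance, ν = 4 by default (configurable; the scale is
  solved from an expected-genetic-variance prior at h² = 0.5).
* **BayesCπ** — spike/normal with one common slab variance.
* **BayesN** — nested mixture: windows tile each chromosome from its first
  bp in 0.2 Mb steps (by construction only non-empty windows exist); one
  indicator per window gates BayesCπ-style per-marker indicators inside.
  The window indicator is sampled conditionally on the retained
  within-window effects (exact Gibbs on the augmented joint state); while
  a window is off, its latent per-marker state is refreshed from the
  prior.  This is a faithful two-level reading of "nested mixture", not a
  clone of any particular implementation.
* **BayesS** — slab variance coupled to MAF as `(2pⱼ(1−pⱼ))^S σ²`; S gets
  a N(0, 1) prior and a random-walk Metropolis step within Gibbs whose
  step size defaults to the prior SD (small enough for realistic
  posteriors, large enough that a flat-likelihood chain mixes across the
  prior).  The marker variance σ² uses a scale-free (Jeffreys) conditional
  here, which keeps S identifiable — with an informative σ² prior, S and
  σ² would be partially confounded whenever MAF varies little.
* **BayesR** — four normal components with variances `γₖ·σ²`,
  `γ = (0, 0.01, 0.1, 1)`; component membership is a categorical
  conditional computed in log space (never NaN), weights get a
  Dirichlet(1,1,1,1) conditional, and σ² is the sampled marker-variance
  parameter, updated every iteration.

Fixed effects are sampled under a flat prior, the residual variance from a
scaled-inverse-χ² conditional (ν = 4, scale at half the phenotypic
variance).  The chain protocol defaults to 21,000 iterations, 1,000
burn-in, thinning 10 — exactly 2,000 retained samples.  One chain per fit;
a split-chain check on σ²ₐ logs a warning (never a failure) if the two
halves drift by more than one posterior SD.  The single-site marker sweep
is compiled with numba, and the compiled RNG is seeded from the config, so
identical inputs give bit-identical posteriors.  GEBVs are
`(M − 2p_train)·E[α|y]`, with training-set centering reused for validation
animals.

## Evaluation machinery

Fivefold cross-validation partitions the genotyped-and-phenotyped set into
folds whose sizes differ by at most one (941 ids → 189/188/188/188/188,
i.e. 753-or-752 training animals).  Validation animals keep their place in
the relationship structure with phenotypes masked (BLUP family) or are
held out of the sampler and predicted from posterior-mean effects (Bayes
family).  Reliability is the mean over folds of the squared Pearson
correlation between predictions and **adjusted phenotypes** `y − Xβ̂`,
with β̂ from one full-data fit.  "Adjusted" is reconstructed here as:
fixed effects estimated by GLS jointly with a polygenic term when a
relationship matrix is supplied (plain OLS otherwise), intercept included,
estimated once and shared by every model on a trait so the comparison
target is identical.  Models are compared by a two-sided paired t-test
across traits; a zero-variance difference vector is reported as p → 0
(constant shift) or p = 1 (identical tables) with a log note.

The density experiment subsamples the panel without replacement at each
density of the grid {0.5, 1, 3, 5, 10, 50, 100, 500} K — scaled
proportionally when the panel is smaller than the ~1 M it was designed
for, capped at the available markers — rebuilds G, and repeats the
fivefold GBLUP CV (30 repeats by default).  Fold seeds and subsampling
seeds come from two independent streams, so all repeats share folds and
only the marker panel varies; the full-density point is deterministic and
not re-randomized.  *Predictive capability* of a density is its mean
reliability divided by that of the largest density (1 at full density by
construction).

## The synthetic generator

The generator emulates the structure of an F2 cross between two divergent
duck lines at desk scale:

* **Founders** — two lines whose per-marker allele frequencies are drawn
  independently from U(maf_low, maf_high) (line divergence arises from the
  independent draws); haplotypes come from a Gaussian-copula AR(1) process
  whose latent correlation decays as `exp(−rate·distance)`, giving
  marginally-correct frequencies with distance-decaying LD.  Default decay
  5e-7 per bp puts substantial r² between markers within ~1 Mb.
* **Cross** — gene dropping with a Poisson crossover process (default
  1e-8 per bp ≈ 1 cM/Mb) through recorded F1 and F2 matings; Mendelian
  consistency is guaranteed by construction and checked exhaustively in
  tests.
* **Architectures** — one per prior family: dense normal (polygenic),
  n-QTL scaled-t (sparse), π-mixture normal, MAF-coupled with exponent S,
  and the four-component mixture with variances (0, 0.01, 0.1, 1)·σ².
* **Phenotypes** — `y = μ + sex/room shifts + g + e` with
  `g = (M−2p)α`; the residual variance is set from the *realized* var(g)
  of the sample, `var(e) = var(g)(1−h²)/h²`, so realized heritability
  matches the target tightly and parameter-recovery tests are sharp at
  moderate n.  h² = 0 zeroes the genetic term and uses a unit residual.
* **Derived traits** — `ADG_a–b = (BW_b − BW_a)/(b − a + 1)` g/day (the
  +1 in the divisor is an empirical reconstruction validated against the
  published trait means of the motivating duck study; how day-1 weight
  enters the denominator is not stated there) and `BMV = KL × BMW × BMT`.

The default miniature study is 600 F2 ducks with 2,000 SNPs on 5
chromosomes of 50 Mb; heritabilities are configurable across the 0.18–0.72
range of the traits being emulated, with 0.5 as the working default.

**What the synthetic experiments do not show.**  The generator has no
genotyping error, no sequencing-depth structure, no dominance or
epistasis, no maternal or permanent-environment effects, no selection, and
its LD comes from a one-parameter stationary process rather than a
demographic history.  Passing tests therefore demonstrate that the
estimators and samplers are correct and behave in the expected directions
(GBLUP over pedigree BLUP, single-step over GBLUP when ungenotyped
phenotypes exist, sparse-prior samplers over GBLUP on few-QTL traits,
density saturation), not that any particular real-data reliability value
would be reproduced.

## Problem sizes in the shipped checks

The end-to-end property checks and `scripts/acceptance.py` use: 20
replicate populations of n = 1000, m = 2000 for REML recovery; 10
replicate fixtures of n = 600 (30% ungenotyped) for the model-ordering
check; 10 + 10 replicates with reduced chains (2,100 iterations, 100
burn-in, thin 1) for the BayesB/GBLUP architecture contrast; and an
m = 5000 panel with 10 repeats per density for the saturation curve —
sizes at which each property is comfortably resolved by desk hardware.

## Known limitations

Univariate analyses only (no multi-trait REML or genetic correlations);
dense linear algebra throughout (no Henderson sparse A⁻¹ rules, no APY),
appropriate up to a few thousand individuals; per-marker QC only; no
imputation beyond mean fill; no unknown-parent groups or metafounders; the
BayesN within-window scheme is a reconstruction from its verbal
description; the scaled-t degrees of freedom (BayesB) and S-prior SD
(BayesS) are conventions, not published values, and are exposed as
configuration.
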