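# Methods

## The problem

Two-sample Mendelian randomization (MR) estimates the causal effect θ of an
exposure X on an outcome Y from per-SNP GWAS association summaries
(β̂_Xj, σ̂_Xj) and (β̂_Yj, σ̂_Yj) measured in non-overlapping cohorts. Each
association's *sign* depends on which allele of SNP j is counted — the
coding, or orientation. Flipping SNP j's coding negates β_Xj, β_Yj and the
direct (pleiotropic) effect α_j simultaneously. MR-Egger's consistency
rests on the InSIDE condition — zero (weighted) sample covariance between
the α_j and the β_Xj — and that condition is *coding-specific*: if it holds
under one ("oracle") orientation, it generally fails under any other,
including the exposure-increasing "default" orientation that popular MR
software applies. This package exists to quantify that sensitivity.

## Generating model

Individual-level data are drawn from the structural model

    X = Σ_j β_Xj G_j + U + ε_X,
    Y = Σ_j α_j G_j + θ X + U + ε_Y,

with m mutually independent biallelic genotypes G_j ~ Binomial(2, maf),
a shared confounder U and independent errors, all standard normal by
default. Defaults (maf = 0.3, unit SDs, non-overlapping cohorts of
n = 100,000, m = 100) are the study conditions throughout.

Per-SNP effects are drawn once per replication:

* **β_Xj** i.i.d. uniform over a scenario-specific support —
  (a) (−0.2,−0.1) ∪ (0.1,0.2), symmetric, mean 0;
  (b) (−0.1,−0.03) ∪ (0.1,0.2), mixed signs, nonzero mean;
  (c) (0.1,0.3), all positive, where the default coding *is* the oracle
  coding. Union supports are sampled uniformly over the union set, i.e.
  the interval is chosen with probability proportional to its width
  (scenario (b): P(negative interval) = 0.07/0.17).
* **α_j** = 0 on valid instruments; on the invalid fraction
  (round(prop_invalid·m) SNPs, flags exchangeable by construction),
  α_j ~ N(0, 0.1²) (*balanced*) or N(0.1, 0.1²) (*directional*).

Because β_X and α are drawn independently, the across-replication average
of their sample covariance is zero — the "weak" InSIDE condition — under
the generating (oracle) orientation, while any individual replication's
covariance is a mean-zero random quantity.

Summary statistics are simple-regression slopes
β̂_j = cov̂(trait, G_j)/var̂(G_j) with the usual slope SE (n−2 residual
denominator), exposure side from cohort 1, outcome side from cohort 2. A
`nome_exact` toggle substitutes the true β_Xj (σ̂_Xj = 0) to separate
orientation-induced InSIDE violation from measurement-error (NOME)
attenuation.

## Estimators

All estimators treat β̂_Xj as fixed covariates and weight by
w_j = 1/σ̂²_Yj (Radial-Egger: first-order weights w_j = β̂²_Xj/σ̂²_Yj).

* **IVW**: θ̂ = Σ w_j β̂_Xj β̂_Yj / Σ w_j β̂²_Xj — the zero-intercept
  weighted regression. FE variance 1/Σ w_j β̂²_Xj; RE multiplies it by the
  overdispersion σ̂²_I = weighted RSS/(m−1). Numerator and denominator are
  sign-invariant term by term, so IVW is exactly orientation-invariant.
* **MR-Egger**: the same regression with a free intercept r (the weighted
  mean pleiotropic effect). Slope = cov_w(β̂_Y, β̂_X)/var_w(β̂_X) with
  probability limit θ + cov_w(α, β_X)/var_w(β_X); the second term is the
  orientation-dependent asymptotic bias, exposed as `egger_plim` and
  recorded per replication.
* **Radial-Egger**: unweighted regression of θ̂_j√w_j on √w_j with
  intercept, θ̂_j = β̂_Yj/β̂_Xj. Its implicit InSIDE condition is tied to
  the exposure-increasing orientation, so it tracks default-coding Egger.

Inference conventions (the source analyses do not pin these down; they are
this package's choices): overdispersion scales are floored at 1 — the model
declares σ² ≥ 1, so SEs are never deflated below their fixed-effect value —
and two-sided p-values use the t distribution with the residual df (m−1 for
IVW, both variants; m−2 for Egger-type fits), standard practice for
multiplicative random-effects MR.

## Codings

A coding scheme is a ±1 vector. Since s and −s give identical Egger slopes
(and intercepts of opposite sign), schemes are canonicalized to a leading
+1 when uniqueness matters (random sampling, exhaustive enumeration),
giving 2^(m−1) equivalence classes; the "999 unique random codings plus the
default" style scan is therefore well defined. Exact zeros in β̂_X map to
sign +1 (deterministic tie rule; zeros have probability 0 in simulation).
The random-coding arm of a scenario uses one fresh scheme per replication
so no single arbitrary orientation dominates the summary.

## Diagnostics

* InSIDE covariance: Σ w_j (α_j−ᾱ)(β_Xj−β̄_X)/Σ w_j, with the printed
  sum-of-weights (1/m-type) denominator, no m−1 correction; an equal-weight
  mode supports the common-MAF algebraic identities.
* NOME: Q = Σ (β̂_Xj−β̄̂_X)²/σ̂²_Xj with the 1/σ̂²_X-weighted mean, and
  I² = (Q−(m−1))/Q. I² estimates the attenuation factor of the Egger slope
  under exposure-side measurement error. Q = 0 yields an undefined I²
  (NaN + warning); negative values (Q < m−1) are reported as computed with
  a warning rather than truncated, for transparency. The default coding
  *provably* minimizes Q — hence I² — over all codings: Q(s) =
  Σ w b² − (Σ w s_j b_j)²/Σ w is minimal when s_j = sign(b_j); the test
  suite also checks this exhaustively.
* Intercept test: two-sided t(m−2) test of H0: r = 0.

## Study drivers

`run_scenario` replicates draw → simulate → (coding × method) fits,
recording estimates, Q/I², the true-effect InSIDE covariance and the
analytic `egger_plim` per (replication, coding). One root seed spawns a
SeedSequence per replication, which spawns separate streams for effects,
cohorts and coding sampling; replications that hit a monomorphic SNP are
retried (max 3) on fresh sub-streams with the retry count reported.
`coding_sensitivity` re-fits Egger over the default plus k distinct random
coding classes. `irrelevant_iv_experiment` pads the instrument set with m0
zero-strength SNPs in three arms (none / pleiotropic α / α = 0) sharing the
per-replication cohort stream, so m0 = 0 is an exact no-op; it records the
padded and unpadded covariances and the induced oracle-coding Egger bias.
A noteworthy subtlety verified here: when the padding SNPs' α follows the
*same* directional law as the relevant instruments, the full-set covariance
is nonzero in any given dataset but averages to ≈0 across replications
(the padded means ᾱ, β̄ shift in a way that cancels to first order); the
expectation is bounded away from zero for α = 0 padding whenever both mean
instrument strength and mean pleiotropy are nonzero
(≈ m·m0·μ_α·μ_β/(m+m0)²), and vanishes when Σβ_X = 0.

## Numerical choices

* Genotypes are sampled as the sum of two Bernoulli(maf) draws realized by
  thresholding full-range 32-bit uniform integers at round(maf·2³²): exact
  to 2⁻³² per allele and several-fold faster than generic binomial
  sampling, which dominates run time at n = 10⁵.
* Per-SNP regressions are computed in float64 via column moment sums
  (no per-SNP loops); SSE is clipped at 0 to absorb last-ulp negatives on
  exact fits. Fits agree with normal-equations/statsmodels oracles to
  1e−12 on fixed inputs.
* TSV serialization uses 17 significant digits and round-trip float
  parsing, so write → read is the identity on doubles.
* Degenerate inputs raise typed errors: monomorphic SNPs, all-zero β̂_X
  (IVW), constant β̂_X (Egger), zero β̂_Xj (radial Wald ratio), zero
  σ̂_X (I² under exact NOME).

## Problem sizes

Replicated studies are scaled-down re-runs of 1000-replication designs:
the shipped acceptance script and acceptance tests use 200 replications at
full cohort size (m = 100, n = 100,000 per cohort), which puts the
Monte-Carlo SE of mean slopes at ~2–6×10⁻³ and of mean I² below 10⁻³ —
small against the effects of interest (default-coding biases of order
10⁻¹). Analysis drivers default to 100 replications at n = 20,000 and
accept flags for full-size runs. Calibration checks (type-I error of the
intercept test) use 400–500 replications at small n, which is adequate
because the null holds at any n when all instruments are valid and θ = 0.

## What the simulations do and do not show

The generator reproduces the mechanism of interest — coding-specific InSIDE
violation with confounding, pleiotropy and finite-sample measurement error —
under idealized conditions: independent SNPs (no LD), a common MAF,
homoscedastic normal errors, quantitative traits, no sample overlap, no
correlated pleiotropy (the α are independent of the confounder path), and
effects i.i.d. within a replication. Passing tests therefore demonstrate
properties of the estimators under these assumptions, not robustness to
LD pruning artefacts, allele-harmonization errors, winner's-curse selection
of instruments, or binary outcomes. Real-data coding scans are supported
through the TSV interface (`read_summary_tsv` + `coding_sensitivity`), but
no external GWAS results are bundled or asserted.

## Known limitations

* No harmonization against a reference panel, strand/palindromic-SNP
  logic, or LD handling: orientation here is purely the sign convention of
  the association estimates.
* Only first-order radial weights; no mode/median/outlier-robust
  estimators; no multivariable MR.
* I² is averaged per replication (not pooled) in scenario summaries.
* The coding-selection problem itself (finding the oracle coding from
  data) is out of scope; the tooling quantifies sensitivity, it does not
  resolve it.
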