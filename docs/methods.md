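# Methods

## Model and hypotheses

For a single response `y = (y_1, …, y_N)` and M covariate sets
`X⁽¹⁾, …, X⁽ᴹ⁾` (each `N × J_m`), the working model is a linear
random-effects regression

    E(y_n) = α + Σ_m Σ_j β_j⁽ᵐ⁾ x_nj⁽ᵐ⁾,    β⁽ᵐ⁾ ~ N(0, τ_m I),

with the sets' coefficient vectors independent of each other.  Nothing is
ever *fitted* under the alternative: the package tests

    H0: τ_1 = … = τ_M = 0    vs.    Ha: some τ_m ≠ 0

with a score test, which only needs the null fit (OLS of `y` on an
intercept and optional confounders).  Confounders enter the null design, so
their effect is projected out of both the response and, for the moments and
the spectral null, the covariates.

The assumptions that matter: samples are exchangeable under H0 (for the
permutation null), and errors are i.i.d. gaussian (for the weighted-χ²
null, where the law is exact in finite samples, not just asymptotically).
An identity link and a continuous response are assumed throughout; count
and survival responses are out of scope.

## The statistic

With `r` the null residuals, the single-set statistic is the ratio of
quadratic forms

    Q(X) = r' X X' r / r' r  =  ‖X'r‖² / r'r,

large when residual variation aligns with directions in which the covariate
set (co)varies.  It is location-invariant (given the intercept), scales as
`Q(cX) = c²Q(X)`, and because `X X'` carries the covariates' full covariance
structure, the test has most power in directions where the merged sets have
the most covariance *and* association with `y`.

Three combinations over sets are implemented:

* `sum` (default): `Σ_m w_m Q_m`.  With unit weights this equals `Q` of the
  column-merged matrix exactly — the identity is enforced by test to
  1e-10 relative error — so the joint test is a single-set global test on
  the union set.  The weight `w_m` realises the prior constant η relating
  the effect variances of the sets (defaults to 1, the choice used for
  genome-wide screens).
* `centered_squared`: `Σ_m w_m (Q_m − E[Q_m])²`, the squared norm of the
  score vector, whose components are the centered per-set statistics.
* `standardized_sum`: `Σ_m w_m T_m` with `T_m = (Q_m − E[Q_m])/√Var[Q_m]`,
  for sets of very different size or scale.

Per-set column standardisation (center/unit-variance) is available but off
by default; raw covariates match the default genome-wide analysis, and the
option is exposed because either convention is defensible.

Null moments use the rotation-invariant (spherical) null: conditional on
`‖r‖`, the residual direction is uniform on the unit sphere of the
`d = N − rank(design)`-dimensional residual space.  With `A` the projected
`X X'` (traces computed through the `J × J` Gram matrix),

    E[Q] = tr(A)/d,
    Var[Q] = 2 (d·tr(A²) − tr(A)²) / (d² (d+2)).

These are *not* the exact permutation moments — the permutation group is a
finite subgroup of the rotation group — and on a 4-sample toy the full
24-permutation enumeration mean differs from `tr(A)/d` by up to ~25 %.
Since inference defaults to permutation p-values, the moments serve
standardisation and diagnostics only; the discrepancy is checked and
documented by the test suite.

## Null distributions

**Permutation (default).**  The response is permuted across samples
(`B` draws keyed by a mandatory seed), the statistic recomputed, and

    p = (1 + #{Q* ≥ Q_obs}) / (1 + B),

so `p ∈ (0, 1]` and ties count against rejection.  Under an intercept-only
null, permuting `y` and permuting the residual vector coincide, and the
implementation permutes residuals; with confounders the residual
permutation is the usual approximation (the residuals are exchangeable only
approximately).  When `N! ≤ B` and there are no confounders, all `N!`
orderings are enumerated and the p-value is the exact tail fraction.
Permuted statistics for the joint and all individual tests come from one
stream, so a response's CN, ME and joint p-values are mutually consistent.
In batch runs the stream is keyed by `(global seed, response id)` (CRC32,
kept below 2³¹), making results independent of execution order and of which
other responses are in the run.

**Ratio of weighted χ² (exact under gaussian errors).**  Writing the
residual direction in the eigenbasis of the projected quadratic form,

    Q  ~  Σ_i λ_i χ²₁,ᵢ / Σ_{j=1..d} χ²₁,ⱼ,

with `λ_i` the nonzero eigenvalues of the projected Gram matrix of the
(weight-scaled, merged) covariates — computed in `J`-space, never `N × N`.
The tail is evaluated as

    P(Q ≥ q) = P( Σ_i (λ_i − q) χ²₁,ᵢ − q Σ_{zero dims} χ²₁ ≥ 0 )

by Imhof's characteristic-function inversion at zero, using adaptive
quadrature (`scipy.integrate.quad`, absolute/relative tolerance 1e-9,
up to 500 subintervals; coefficients rescaled by their maximum, which
leaves the integral invariant).  Against the closed-form single-covariate
law — `Q/λ₁ ~ Beta(1/2, (N−2)/2)` — the integration is accurate to ~1e-13,
far inside the 1e-6 target.  Support edges short-circuit: `q ≤ 0 → 1`,
`q ≥ λ_max → 0`.  This route only applies to the `sum` combination (the
only mode with a single-matrix representation); other modes use
permutation, which also sidesteps any one- vs. two-sided ambiguity for the
squared-score mode.

Eigenvalues below `1e-10 × λ_max` are treated as zero.  A response whose
residual sum of squares falls below `1e-12 · N · Var(y)` is declared
degenerate (constant response, or confounders explaining it exactly) and
flagged rather than tested.

## Cis windows

A probe joins a gene's covariate set iff it is on the same chromosome and
`|pos − TSS| ≤ flank` — a closed interval ("within" read inclusively), with
strand ignored (the window is symmetric by construction; a test enforces
strand-invariance).  Defaults: 1 Mb for copy number, 50 Kb for methylation,
reflecting the usual reach of cis-regulatory effects of each profile; both
are configuration knobs, and a whole-chromosome flank turns the builder
into a trans screen.  Chromosome names are case-folded with any `chr`
prefix stripped.  BED inputs (0-based, half-open) are converted on read:
point probes use `start + 1`, interval probes their midpoint (no standard
exists; the midpoint is the least surprising single coordinate).  Genes
with empty windows are flagged, never dropped — the other platform's
individual test still runs.  Probes at identical positions are retained
(deduplication is the annotation's responsibility).  Within a set, probes
are ordered by position, ties by id, so output is deterministic.

## The simulation study generator

`simulator` reproduces the canonical benchmarking design for joint
covariate-set tests:

* **Linkage design**: `X_j ~ N(1, 2.25)` i.i.d., `Z_k = ±X_k + W_k`,
  `W_k ~ N(0, var_w)` — matched-pair correlation
  `±√(2.25/(2.25+var_w))`: 0.83 for `var_w = 1` ("strong"), 0.56 for
  `var_w = 5` ("weak"), −0.83 for the negative sign; cross-pair
  correlations zero.
* **Empirical-covariance design**: `(X, Z)` drawn jointly from a
  multivariate normal with a user-supplied covariance (e.g. estimated from
  tumour data); PSD is validated by eigenvalue check (tolerance
  −1e-8·λ_max), and Cholesky/eigen square roots are interchangeable.
* **Four region types**, the first `n_associated` response probes carrying
  the effect and the rest pure noise: *x only* (`Y = b·x̄`), *additive*
  (`b·x̄ + b·z̄`), *multiplicative* (the additive terms plus `b·x̄·z̄`),
  and *split-samples / complementary* (`b·x̄` for the first ⌈N/2⌉ samples,
  `b·z̄` for the rest — a deterministic first/second-half split).  Here
  `x̄_i` is the mean of covariates in a window of half-width 2 around probe
  `i`, so the signal is spread over a small set rather than one probe,
  exercising the set-based power argument.

Defaults `b = 0.5`, `noise_sd = 1`, half-width 2 are this package's own
calibration (all exposed in `RegionConfig`); the generator's guarantees are
therefore *properties and orderings* — type-I calibration at zero effect,
higher joint-test AUC under strong positive linkage than weak in the x-only
region, joint test beating the weaker individual test in the complementary
region — not numeric ROC values.  Power evaluations in the test suite and
the acceptance script run at reduced scale (200 probes, 100–200 samples,
500 permutations), which preserves the rankings while keeping runs in
seconds.

What the generator does *not* emulate: genomic autocorrelation along the
probe axis within X or Z (probes are exchangeable), segmental copy-number
structure (except in the miniature fixture bundle, which adds a shared
per-chromosome segment factor precisely so that window means carry
signal), bounded methylation beta values, heavy tails, batch effects, or
missingness.  Passing tests on these data certify the statistic's
calibration and relative power patterns, not performance on any particular
real platform.

## Selection and interpretation summaries

Selection is `p ≤ α` (closed comparison) on raw p-values — cross-test and
cross-dataset comparisons are cleaner without multiplicity adjustment —
with Benjamini–Hochberg adjustment available as a utility for actual
discovery claims.  For a joint test against an individual test `a`:

    overlap  = |joint ∧ a| / |joint|       (how much the joint test merely
                                            re-finds the individual signal)
    new discoveries = 1 − overlap          (joint-only findings)
    dilution = |a ∧ ¬joint| / |a|          (individual signal lost when the
                                            other set contributes noise)

Empty denominators yield explicit missing values, never 0.  Reports
aggregate genome-wide and per chromosome arm; per-arm counts sum to the
genome-wide counts by construction.  ROC curves sweep the unique p-values
with ties grouped; the trapezoidal AUC equals the Mann–Whitney statistic
with ties counted ½ (delegated to scikit-learn, cross-checked against an
all-pairs oracle).

## Numerical and design choices

* Gram-space computation throughout (`X'X`, `X'r`); memory and time scale
  with `Σ J_m`, not `N²`.
* Permutation tie tolerance `1e-12 · max(1, |Q_obs|)` so bit-level jitter
  cannot break the `p = 1` saturation of constant covariates.
* Missing values are a hard error at `CovariateSet` construction; optional
  column-mean imputation (`impute_column_mean`) logs a warning — silent
  imputation hides platform problems.
* Sample alignment across files is id-driven (intersection, response-file
  order) with dropped samples logged; positional alignment is never used.
* Matrices on disk are features-in-rows TSV (the convention of array
  pipelines), transposed to samples-in-rows internally; reads use
  round-trip float parsing so write→read is bit-identical.
* Seeds: mandatory, ≤ 2³¹; a run's JSON-lines log echoes the full config.

## Known limitations

* Gaussian identity-link responses only; no GLM or proportional-hazards
  extension.
* The residual-permutation scheme with confounders is approximate;
  confounded designs with strong confounder effects should prefer the
  weighted-χ² route (exact under gaussianity).
* The weighted-χ² null is unavailable for the `centered_squared` and
  `standardized_sum` combinations.
* Exhaustive enumeration is only engaged for confounder-free nulls.
* The per-response eigendecomposition makes the asymptotic route slower
  than permutation for genome-wide screens with large windows; permutation
  is the default for exactly this reason.
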