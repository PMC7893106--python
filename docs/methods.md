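# Methods

## The contribution model

A DNA pool built from `n` individuals ideally contains fraction `1/n` of
each individual's DNA. Write `w_ij` for individual *i*'s realized weight in
pool *j* (`Σ_i w_ij = 1`) and `g_is ∈ {0, 0.5, 1}` for the individual
allele frequency (dosage/2) at SNP *s*. Ignoring measurement error, the
pool's allele frequency is the mixture `y_js = Σ_i w_ij g_is`. Writing
`w_ij = 1/n + δ_ij` gives

```
y_js = ḡ_s + Σ_i δ_ij g_is + e_js,
```

so regressing the pool's frequencies on the individual genotype covariates
with a per-animal random coefficient recovers the contribution deviations.
The fitted model per pool is

* fixed part: intercept plus a fixed regression on `ḡ_s`. The random
  coefficients are zero-mean, while the equal-contribution expectation of
  `y_s` is `ḡ_s` itself; without the `ḡ_s` covariate that signal would be
  absorbed by the random effects and inflate `σ_u`. With it, `u_i` is
  interpretable as `δ_i` (and because `Z·1 = n ḡ` lies in the fixed-effect
  space, the BLUPs satisfy `Σ_i û_i = 0` exactly).
* random part: `u_i ~ N(0, σ_u²)` i.i.d. across animals, residual
  `e_s ~ N(0, σ_e²)` homoskedastic across SNPs.

`σ_u` is reported on the covariate scale (covariate = dosage/2), i.e.
directly as the SD of weight deviations; estimated weights are reported as
`1/n + û_i`.

### Estimation

REML via the error-contrast form. With `X = [1, ḡ]` (QR basis `Q`) and `Z`
the m×n covariate matrix, one thin SVD of `Z − QQᵀZ` separates the
restricted likelihood over singular directions; the residual variance
profiles out in closed form, leaving a one-dimensional problem in the
variance ratio `γ = σ_u²/σ_e²`. We scan a 61-point log-spaced grid on
`γ ∈ [1e-10, 1e6]` and refine with bounded Brent minimization
(`xatol = 1e-10` in log-γ). `γ̂ = 0` boundary solutions (no detectable
contribution variance) are reported with a boundary flag, never raised as
errors; a zero-residual degenerate input yields a flagged degenerate fit.
Fixed effects and BLUPs are evaluated at the REML estimates through the
Woodbury identity on the n×n system (`û = σ_u² Zᵀ V⁻¹ (y − Xβ̂)`).

The dense-matrix evaluation of the same restricted likelihood (an
independent O(m³) code path in `poolcheck.dense`, using the identity
`log|AᵀVA| = log|V| + log|XᵀV⁻¹X| − log|XᵀX|` for an orthonormal contrast
basis `A`) is used throughout the tests and the acceptance script to verify
the fast path to ≤1e-8 and the arg-max to ≤1e-4 relative.

### Bivariate fits

Two pools share `Z`, so the stacked 2m×2m covariance block-diagonalizes
into 2×2 blocks `V_s = λ_s Σ_u + Σ_e` under the same decomposition, with
`Σ_u` the 2×2 animal-effect covariance (correlation `r_u`, the quantity of
interest) and `Σ_e` the per-SNP residual covariance. Parameters are
optimized on transformed coordinates (log variances, atanh correlations,
|atanh r| ≤ 8) with L-BFGS-B, max 200 iterations, `ftol = 1e-12`, starting
from the univariate fits (the protocol of fitting pools two at a time with
univariate starting values; joint fits of more than two pools are excluded
by design — they add little, since the bivariate marginal `σ_u`'s track the
univariate ones closely). The returned likelihood never falls below the
starting value; fits with `|r̂_u| ≥ 0.999` carry a boundary flag.

A residual cross-pool correlation `r_e` is estimated by default: two array
measurements of the same SNP can share technical artifacts, and the
parameter is identifiable because the animal-effect block is modulated by
the spectrum of `Z` while the residual block is not. A switch fixes
`r_e = 0`. Per-pair failures are recorded, not fatal; downstream, a failed
pair's correlation is imputed from the mean of successful correlations in
the same method-pair class, with a warning.

## Contamination flagging

Flag rule: standardized BLUP `û_i/σ̂_u > 3` (one-sided, configurable);
pools with any flagged animal are excluded, with reasons recorded. A
`σ̂_u = 0` boundary fit produces no flags by construction.

A known property of this conventional 3-SD rule under Gaussian contribution
deviations: for a *clean* pool the standardized BLUPs are approximately
standard normal across animals (BLUP accuracy is high at array scale), so
the maximum of n = 50 scores exceeds 3 with probability ≈ 1 − Φ(3)⁵⁰ ≈ 6%.
Exact retained-pool bookkeeping is therefore a property of a given dataset
(such as the canonical contamination scenario below), not of every random
replicate. Conversely, a contaminated animal whose random base weight drew
low can carry a genuinely small contamination deviation and escape the
threshold while still ranking first; detection is accordingly evaluated
both as a top-rank rate over replicates and as exact flag recovery on the
canonical scenario.

## The synthetic generator

The generator emulates the *net* effect of pool construction on weights —
not hematology counts, pipetting volumes or extraction chemistry as
physical processes. Per method `M` with SD `σ_M` and within-method
correlation `ρ_M`:

```
w̃_ij = max(0, 1/n + s_i + a_i^(M) + b_ij),   a^(M) ~ N(0, ρ_M σ_M²),  b ~ N(0, (1−ρ_M) σ_M²)
```

optionally multiplied by a contamination factor for targeted animals, then
renormalized to sum to one. Measured frequencies add homoskedastic Gaussian
array noise on the frequency scale, clipped to [0, 1]; binomial sampling
noise is not separately modeled. The construction/extraction replicate
hierarchy is collapsed into the single `ρ_M` (the two tiers are not
separately identifiable from within-method correlation summaries; the split
is an extension point). `s_i` (`shared_sd`, default 0) is an optional
animal effect common to all methods, available to induce nonzero
between-method correlations.

Defaults of the study-scale design (50 animals, 4 methods × 3 constructed
pools × 3 extractions = 36 pools): `σ_CBC = σ_Spec = 0.003`,
`σ_Fluor = 0.006`, `σ_Volume = 0.012` on the weight scale (target weight
0.02), `ρ_M = 0.95`, array noise SD 0.003, SNP allele frequencies uniform
on [0.05, 0.95], dosages from two independent allele draws. These magnitudes
are generator defaults chosen to reproduce the qualitative structure of
such experiments — volume pooling worst, fluorometry intermediate,
cell-count and spectrophotometric pooling best and similar, within-method
correlations near 1 — **not** estimates from any real data set. The default
SNP count for desk-scale work is 5,000 (a stand-in for a ~50K array).

The canonical contamination scenario injects a 3× multiplier on three
adjacent animals in pool `CBC 3-3` and on one animal in `Fluor 3-3`; with
the scenario's fixed generator stream this yields exactly 34 retained pools
(8/8/9/9 by method) and 561 pair analyses.

Limitations relative to real data: Gaussian weight deviations (real
quantification error may be skewed or heavy-tailed), homoskedastic array
noise (real intensity-derived frequencies have frequency-dependent error),
no LD or relatedness structure among animals, no SNP-level QC artifacts.
Passing recovery tests shows the estimators are correct under the stated
generative model, not that the model captures every feature of array data.

## Comparison stage

* **Distances**: default `d = 1 − r` (simplest monotone map);
  `√(2(1 − r))` is offered because it is Euclidean-embeddable. Both are
  tested; they induce the same pair ranking.
* **PERMANOVA** (one factor: method): pseudo-F from the standard partition
  of the total sum of squared distances (`SS_T = Σ_{i<j} d²_ij / N`) into
  within- and among-group components; Monte-Carlo p =
  `(1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` with all randomness from the
  run's permutation substream. When the label multiset admits ≤ 1e5
  distinct assignments the full enumeration is used instead (exact p).
  Permutations that merely rename groups or preserve the partition tie with
  the observed statistic and are counted, so the attainable p floor on a
  perfectly separated design is the partition multiplicity over the
  assignment count, not `1/(n_perm+1)`. Default 9,999 permutations in the
  pipeline (999 in tests); a constant distance matrix reports F undefined,
  p = 1, with a warning.
* **Kruskal-Wallis** on one contribution SD per pool — the univariate
  estimates, one value per experimental unit, avoiding the
  pseudo-replication of the 33 bivariate estimates each pool appears in
  (those are summarized descriptively instead). Tie-corrected H with the
  χ² approximation (df = methods − 1), optional permutation p; all-equal
  input returns H = 0, p = 1 by the full-tie convention.

## Reproducibility

One root seed per pipeline run is split by `numpy.random.SeedSequence` into
named substreams (simulation, permutations), so changing the permutation
count never perturbs the simulated data. Fitting is deterministic; result
tables are byte-identical under identical config + seed. The run manifest
records config, per-stage output digests, warnings (boundary fits,
low-information designs, weight truncation) and every exclusion with its
reason.

Problem sizes used by the test suite and acceptance script — 5,000 SNPs,
20-seed recovery studies, 100-seed detection study, 500-replicate type-I
study — are the package's desk-scale defaults; estimates at these sizes are
already tight (e.g. contribution-SD recovery within a few percent).
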