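# Methods

## The causal model

`steromr` estimates the causal effect of a continuous exposure (for example a
circulating hormone level, standardized) on a binary outcome (a stroke
subtype, on the log-odds scale) from two independent sets of GWAS summary
statistics. Genetic variants serve as instrumental variables: for SNP *j*,
γ̂_j is its estimated per-allele effect on the exposure (SE σ_xj) and Γ̂_j
its estimated effect on the outcome (SE σ_yj), aligned to the same effect
allele. Under the instrumental-variable assumptions — the SNP is associated
with the exposure, unconfounded with the outcome, and affects the outcome
only through the exposure — every Wald ratio Γ̂_j/γ̂_j estimates the same
causal effect θ.

Three estimators combine the ratios, each robust to a different violation:

* **IVW** — the inverse-variance-weighted mean of Wald ratios with weights
  w_j = γ̂_j²/σ_yj², equal to the slope of a weighted least-squares fit of
  Γ̂ on γ̂ through the origin. Most efficient when all instruments are
  valid; biased if any are pleiotropic.
* **MR-Egger** — the same weighted regression with a free intercept. The
  slope remains consistent under directional pleiotropy if instrument
  strength is independent of the direct effects (InSIDE); the intercept
  estimates the average pleiotropic effect, and a non-zero intercept is the
  directional-pleiotropy test.
* **Weighted median** — the 50th weighted percentile of the ratio estimates,
  consistent when valid instruments carry more than half the total weight.

## Numerical conventions

* Wald-ratio SE: first-order delta method σ_yj/|γ̂_j| (the standard
  two-sample default). A second-order option adds Γ̂_j²σ_xj²/γ̂_j⁴ under the
  square root.
* IVW default is a multiplicative random-effects model: the fixed-effects SE
  1/√Σw_j is inflated by max(1, √(Q/(J−1))) with Q Cochran's heterogeneity
  statistic, and never shrinks below the fixed-effects SE. Both models are
  available; p-values use the normal reference.
* MR-Egger coefficient SEs apply the analogous multiplicative overdispersion
  max(1, √(RSS_w/(J−2))) to the unit-variance covariance, with t(J−2)
  p-values. The regression is computed after `orient_positive`, which
  relabels alleles so every γ̂_j ≥ 0: Wald ratios, IVW and the weighted
  median are invariant to this, MR-Egger is not (a documented asymmetry of
  the estimator itself).
* Weighted median: ratios are sorted, cumulative midpoint percentiles
  p_j = Σ_{i≤j} w'_i − w'_j/2 formed from normalized weights, and the
  estimate is linear interpolation at p = 0.5 (clamped at the extremes). The
  SE is the standard deviation of the point estimate over `n_boot` (default
  1000) parametric-bootstrap replicates γ̂*_j ~ N(γ̂_j, σ_xj²),
  Γ̂*_j ~ N(Γ̂_j, σ_yj²), driven by a mandatory seed; bootstrap draws that
  produce γ̂*_j = 0 are excluded from that replicate.
* Odds ratios: OR = exp(β) with 95% CI exp(β ± 1.96·SE); the level is fixed
  at 95% in all reports.
* Ties in clumping (equal p-values) are broken by (chromosome, position,
  SNP id); the clumping window is a closed interval |Δpos| ≤ window_kb·1000
  on the same chromosome. This makes the retained set independent of input
  record order.
* Per-SNP variance explained uses the standardized-effect approximation
  R² = 2f(1−f)β² / (2f(1−f)β² + 2f(1−f)·SE²·n), and instrument strength
  F = (N−K−1)·R²/(K(1−R²)). The per-SNP F (K = 1) drives the weak-instrument
  filter at F > 10; the aggregate F is reported. The study this pipeline
  follows names R² without fixing its formula, so the formula is exposed and
  users may substitute their own values.
* Empirical p-values (MR-PRESSO) use the add-one rule
  (1 + #{T* ≥ T})/(n_sim + 1) and are never exactly zero.

## Sensitivity procedures

* **Cochran's Q**: Q = Σ w_j (β_j − β_IVW)² against χ²(J−1), heterogeneity
  flagged at p < 0.05. When the multiplicative scale exceeds 1, Q equals
  (J−1) times the squared ratio of random- to fixed-effects IVW SEs.
* **MR-PRESSO**: each SNP's residual is taken against its leave-one-out IVW
  prediction and standardized by σ_yj, so the observed RSS is scale-free.
  `n_sim` (default 1000) parametric datasets are simulated under the
  no-pleiotropy model (Γ*_j centred on the leave-one-out prediction) and
  processed identically; the global p is the empirical tail probability of
  the observed RSS. Per-SNP empirical p-values are Bonferroni-multiplied by
  J and capped at 1; SNPs below the significance level are outliers, and
  IVW is recomputed without them. Note the resolution constraint: with J
  SNPs the smallest achievable adjusted p is J/(n_sim+1), so n_sim must
  exceed J/sig for any SNP to be flaggable. The distortion test compares the
  corrected-minus-full estimate shift against shifts from random subsets of
  the same size (two-sided empirical p); it is reported but never gates the
  corrected estimate, which is always emitted when outliers exist.
* **Leave-one-out**: IVW on each J−1 subset in input order; a single-SNP
  subset falls back to the fixed-effects model (the Wald ratio itself).

## Significance scheme

The grid runner labels each exposure–outcome cell from its IVW p-value:
*significant* below 0.05/n_exposures, *suggestive* between that threshold
and 0.05, *none* otherwise. The Bonferroni denominator counts exposures
only — with five hormone exposures the corrected threshold is exactly 0.01 —
not exposures × outcomes. This is a deliberate convention of the analysis
design this package reproduces and is surfaced prominently because it is
laxer than the usual per-test correction.

## Synthetic data: what it emulates and what it does not

The generator produces matched exposure/outcome summary-statistic tables
from the model γ̂_j = γ_j + ε_xj, Γ̂_j = θγ_j + α_j (+ outlier shift) + ε_yj
with per-SNP standard errors 1/√(2f_j(1−f_j)n). Defaults: J = 30 SNPs,
n = 50,000 (exposure) / 100,000 (outcome), θ = 0.2, effect-allele
frequencies uniform on (0.1, 0.9), and true instrument effects
γ_j ~ N(0.15, 0.05²). The effect-size scale mirrors instruments that small
hormone meta-analyses (a few thousand samples) can detect — per-allele
effects of roughly 0.1–0.3 on a standardized trait — and keeps the spread of
true effects large relative to exposure sampling noise (I²_GX ≈ 0.99), the
regime in which MR-Egger's intercept estimates average pleiotropy without
appreciable regression dilution. Pleiotropy α_j is zero, balanced
(zero-mean normal) or directional (shifted normal); outliers add a fixed
shift to chosen SNPs; `zero_noise=True` gives the infinite-sample limit in
which all three estimators return θ exactly.

Randomness is organized as one counter-based substream per SNP from a single
seed, so enlarging a panel never changes earlier SNPs and every fixture is
bit-reproducible.

Deliberately not modelled: individual-level genotypes, case-control
ascertainment, winner's curse (instrument effects are not conditioned on
passing the significance filter), sample overlap between the two GWAS, and
LD beyond the idealized block fixture (uniform within-block r², zero
between blocks, used only to exercise clumping). Passing tests on this
generator demonstrate correctness of the estimators and diagnostics under
their own assumptions — not robustness to winner's curse or overlapping
samples in real consortium data.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the stochastic checks at
100 replicates (parameter recovery, pleiotropy recovery, outlier power) and
200 replicates (null calibration of the MR-PRESSO global test at
n_sim = 200; power runs use n_sim = 500), sizes at which each Monte-Carlo
band in the checks is informative while the whole suite stays fast.

## Known limitations

* The weighted-median bootstrap ignores between-SNP correlation (fine for
  clumped, approximately independent instruments).
* MR-PRESSO's simulation calibration assumes normal sampling errors with
  known σ; heavy-tailed real summary statistics would inflate its global
  rejection rate.
* The palindromic "infer" policy is frequency-based and unsafe near
  eaf 0.5; the default remains "drop".
* Harmonization resolves strand complements before declaring mismatches;
  pipelines that drop complement-coded SNPs outright will retain fewer
  variants. Every correction is logged so the difference is auditable.
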