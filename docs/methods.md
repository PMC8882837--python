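# Methods

This note records the statistical model behind `mrscan`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Two-sample MR model

Genetic variants serve as instrumental variables: a SNP robustly associated
with an exposure, affecting the outcome only through that exposure, and
unconfounded by virtue of random allele segregation, identifies the causal
effect θ of the exposure on the outcome.  In the two-sample design the
SNP-exposure coefficients `bXG_j ± σ_xj` and SNP-outcome coefficients
`bYG_j ± σ_yj` come from separate, non-overlapping GWAS, so only summary
statistics are needed and the sampling errors of the two sides are
independent.

Identification assumptions per estimator:

- **IVW fixed-effect** (main method) assumes all instruments valid; it is
  the weighted least-squares slope of `bYG` on `bXG` through the origin
  with weights `1/σ_y²`, equivalently the precision-weighted average of the
  per-SNP Wald ratios.  The fixed-effect SE `(Σ w_j)^{-1/2}` takes the
  weights as known ("no measurement error" in `bXG`), standard at the
  instrument strengths enforced by selection.
- **MR-Egger** relaxes exclusion to the InSIDE condition (pleiotropic
  effects independent of instrument strength): the regression intercept
  consistently estimates the mean directional pleiotropic effect and the
  slope the causal effect.  SNPs are oriented `bXG ≥ 0` first, since the
  intercept is only meaningful relative to a fixed allele orientation.
- **Weighted median** is consistent while valid instruments carry ≥ 50% of
  the delta-method inverse-variance weight; **weighted mode** while the
  largest homogeneous cluster of ratio estimates is valid.

## Tunable parameters

| parameter | default | units / scale | rationale |
|---|---|---|---|
| `p_primary` | 5e-8 | GWAS p | genome-wide significance |
| `p_fallback` | 5e-6 | GWAS p | engaged when < 10 SNPs pass the primary bar |
| `fallback_below` | 10 | SNP count | the "fewer than ten" rule |
| `r2_max` | 0.1 | LD r² | independence bar for greedy pruning |
| `palindromic_eaf_window` | 0.08 | allele frequency | drop A/T, C/G SNPs with eaf in (0.42, 0.58): strand unresolvable; common two-sample MR practice |
| outcome-significance filter | on, 5e-8 | outcome p | removes instrument SNPs genome-wide significant for the outcome; configurable off |
| `n_boot` | 1000 | draws | bootstrap SE for median/mode; seeded, reproducible |
| `bandwidth_factor` | 1.0 | multiplier | scales the rule-of-thumb mode bandwidth `0.9·min(sd, IQR/1.349)·k^{-1/5}` |
| `family_alpha` | 0.05 | probability | Bonferroni numerator; denominator = exposures in the current scan config, a property of the design being run, not a constant |

Instrument strength: per-SNP `R²` from the β/SE/MAF/N formula (MAF derived
as `min(eaf, 1−eaf)`, since files carry effect-allele frequency); instrument
`R²` is the **sum** of per-SNP values, treating pruned SNPs as independent;
`F` uses the largest per-SNP GWAS N in the set (matching the convention of
quoting an instrument's maximum sample size).  "Strongest effect" for LD
tie-breaking means smallest p-value, with |β| then rsid as tie-breakers —
p combines effect size and precision, as in standard clumping.  Pruning runs
after threshold (and fallback) evaluation.  An absent LD matrix warns and
skips pruning rather than failing: many single-digit-SNP instruments are
curated to be independent already.

## Synthetic generator

`simulate_two_sample` draws, per SNP: MAF uniform on `maf_range`; true
exposure effects `b_j` half-normal with scale `exposure_effect_sd`, the
effect allele oriented to the exposure-increasing allele.  This orientation
is deliberate: with zero-mean signed effects and allele-independent
pleiotropy, "directional" pleiotropy cancels under IVW weighting
(`E[b·α] = 0`) and the Egger intercept estimates zero after `bXG ≥ 0`
orientation, so the directional model would be unable to generate the bias
it is meant to model.  Orienting to the trait-increasing allele is the usual
GWAS reporting convention and preserves `E[b²] = sd²`, so the R²/F algebra
is unaffected.

True outcome effects are `γ_j = θ·b_j + α_j` with `α_j` per pleiotropy
model (`none`, `balanced`, `directional`, `correlated`; the last draws
`α_j` with correlation `inside_correlation` to standardized `b_j`,
violating InSIDE).  `pleiotropy_fraction` restricts pleiotropy to a random
subset of instruments, expressing invalid-minority designs (e.g. 40%
invalid) without changing any other default.  Observed coefficients add
independent noise with the closed-form SE for a standardized trait,
`σ = [2N·v·MAF(1−MAF)]^{-1/2}` (`v = 1` continuous,
`v = cf(1−cf)` binary on the log-odds scale); p-values are two-sided
normal.  Observed allele frequencies get sampling noise of SD
`[eaf(1−eaf)/2N]^{1/2}` so palindromic orientation logic faces realistic
inputs.  LD is an annotation (block-diagonal r² matrix), not a haplotype
simulation: instrument pruning is its only consumer.  Null SNPs (default
10× the instrument count) give the p-thresholding something to reject.

Defaults describe a well-powered modern design: 100 instrument SNPs,
`exposure_effect_sd = 0.05` (total exposure R² ≈ 10%, typical of
anthropometric/metabolite instruments), GWAS sizes 100 000 per sample, MAF
0.05–0.5, 20% palindromic SNPs.  Corruption rates default to zero;
harmonization tests switch them on.

What the generator does **not** emulate: individual-level genotypes,
population structure, relatedness, sample overlap between the two GWAS,
winner's-curse correlation between discovery and instrument effect sizes
(instrument SNPs are known by construction), multi-allelic variants, and
indels.  Passing tests therefore demonstrate estimator- and pipeline-level
correctness under the stated sampling model, not robustness to those
real-data phenomena.

## Numerical choices

- IVW with a single SNP returns the Wald ratio's `bYG/bXG` and `|σ_y/bXG|`
  verbatim (not via the weight algebra) so the k = 1 equivalence is exact in
  floating point.
- The Wald SE is first-order delta method only; at the instrument strengths
  selection enforces (F ≫ 10) the second-order term is negligible.
- Egger SEs are scaled by `max(1, √(Q_res/(k−2)))` — multiplicative random
  effects floored at unity; p-values are two-sided normal throughout (no
  small-sample t correction).
- Weighted-median interpolation is linear over cumulative-weight midpoints;
  ties in ratios are harmless (interpolation is exact there).
- Weighted-mode maximization: coarse 512-point grid over the ratio range
  padded by 3 bandwidths, then bounded scalar refinement within one grid
  step with an x-tolerance proportional to the step, keeping the estimator
  exactly scale-equivariant; a zero-spread degenerate case returns the
  common ratio directly.
- Bootstrap SEs resample `bXG, bYG` from their normal sampling
  distributions with a caller-supplied seed; the scan derives per-exposure
  seeds from `(config seed, crc32(exposure id))` so results for one exposure
  are invariant to which other exposures share the config.
- DerSimonian–Laird truncates τ² at zero, reducing exactly to fixed-effect
  pooling when `Q ≤ m − 1`.
- Harmonization never raises on a problem SNP: every SNP receives exactly
  one audit action, and the actions partition the instrument set.
  Palindromic SNPs with missing frequency on either side are dropped.
- Report files contain no timestamps; identical config + seed reproduce
  byte-identical outputs.

## Design decisions on genuinely open points

- The outcome-significance filter is read as removing instrument SNPs
  genome-wide significant *for the outcome* (reported p first, recomputed
  from `bYG/σ_y` when missing); it is on by default and switchable off.
- The combined (cross-cohort) column pools per-cohort primary log-ORs by
  fixed-effect inverse variance; random-effects pooling is a flag.  Pooling
  operates on per-cohort estimates, not per-SNP meta-analysis; no
  cross-cohort scale harmonization is applied silently — cohorts reported on
  different outcome scales are the analyst's responsibility to align.
- No proxy-SNP substitution for instruments missing from an outcome table
  (no LD reference panel in scope); such SNPs are dropped with
  `dropped_missing`.

## Test and experiment sizes

Monte-Carlo suites run at 100–200 replicates with 40–120 SNPs per replicate
and GWAS sizes of 50 000–200 000 — large enough that the checked bands
(e.g. CI coverage in [0.92, 0.98], type-I error in [0.02, 0.08], Egger
intercept within 0.01 of truth) are comfortably outside Monte-Carlo noise,
and small enough that the whole suite runs in seconds.  Robustness and
Egger-recovery experiments use instruments at post-selection strength
(effect SD 0.1–0.15, N ≥ 50 000): with weak instruments the `bXG ≥ 0`
orientation misjudges signs and attenuates the Egger intercept — a real
phenomenon of the estimator, not of the implementation, and one reason the
pipeline enforces genome-wide-significant instruments.

## Known limitations

- Multivariable MR, MR-PRESSO, Steiger filtering, contamination-mixture
  models are out of scope.
- The LD matrix is consumed as given; the package never computes LD from
  genotypes.
- Winner's curse: selecting instruments and estimating their effects in the
  same simulated GWAS attenuates causal estimates when true effects sit
  near the significance threshold; the estimator suite is calibrated for
  instruments of post-selection strength.
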