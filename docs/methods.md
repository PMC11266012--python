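# Methods

## Model and procedure

All analyses operate on GWAS summary statistics: per-SNP effect sizes,
standard errors, alleles and frequencies, one table per trait. The causal
model is the standard instrumental-variable one — a SNP is a valid
instrument for exposure X on outcome Y when it (i) associates with X,
(ii) shares no confounder with Y, and (iii) affects Y only through X.
Estimation is two-sample: exposure and outcome associations come from
different, non-overlapping GWAS.

The pipeline per exposure–outcome pair:

1. **Instrument selection.** SNPs below a significance ladder (5e-8,
   relaxed to 5e-6 and then 5e-5 when fewer than `min_snps` survive —
   default 3, the floor at which MR-Egger retains a residual degree of
   freedom), then greedy LD clumping: repeatedly keep the most significant
   remaining SNP and discard same-chromosome SNPs within 10 Mb whose r²
   with it exceeds 0.001. Ordering ties are broken by (p, chromosome,
   position, id), making the output invariant to input order.
2. **Harmonization.** Outcome betas are aligned to the exposure's effect
   allele (direct match, allele swap with sign flip, or strand
   complement). Palindromic SNPs are oriented by allele frequency alone
   (labels cannot distinguish swap from strand flip) and kept only when
   both frequencies fall on the same side of 0.5 and outside ±0.08 of it;
   frequency-missing or ambiguous palindromic SNPs are dropped. All drops
   are audited.
3. **Estimation.** IVW (headline), MR-Egger, weighted median, simple and
   weighted mode; per-SNP Wald ratios for k = 1.
4. **Sensitivity.** Cochran's Q (IVW about the fixed-effects fit, df k−1;
   Egger about its own fit, df k−2), the Egger intercept test for
   directional pleiotropy, and — when the IVW p lands in (0.04, 0.05) —
   a leave-one-out scan refitting IVW k times.
5. **Classification.** IVW p < 0.05 with OR > 1 → risk factor; OR < 1 →
   protective; otherwise null. No multiple-testing correction gates the
   classification (an informational Benjamini–Hochberg column is emitted).

Multivariable MR regresses outcome betas on an instrument-union matrix of
exposure betas (no intercept, weights 1/se_out²) after joint clumping with
each SNP prioritized by its best p across exposures. Rank deficiency of
the exposure matrix raises an error naming the collinear pair rather than
silently dropping a column.

Two-step mediation estimates beta_all (X→Y), beta1 (X→M) and beta2 (M→Y)
by IVW, deleting from the mediator's instruments every SNP already used in
step 1 so the two steps use disjoint instruments, and decomposes
beta12 = beta1·beta2, beta_dir = beta_all − beta12,
beta_per = beta12/beta_all. Mediation is declared only when both step
p-values are below 0.05. Derived quantities are carried at full precision
and rounded (3 decimals) only at serialization; the delta-method SE
sqrt(beta1²·se2² + beta2²·se1²) accompanies the product. With beta_all = 0
the proportion is flagged undefined, not raised. Re-deriving the published
four-chain decomposition table from its own printed step estimates
reproduces every mediated effect and proportion at display precision with
two exceptions that are arithmetically inconsistent with their own row's
inputs (a direct effect printed as 0.267 where the formula gives 0.152,
duplicating the row below, and a proportion printed as 0.158 where the
formula gives 0.157); the package reports the recomputed values.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| ladder | 5e-8, 5e-6, 5e-5 | instrument significance thresholds, relaxed in order |
| min_snps | 3 | fewest instruments before relaxing the ladder |
| clump window / r² | 10 Mb / 0.001 | greedy LD-clumping parameters |
| palindrome window | 0.08 | half-width of the EAF ambiguity band around 0.5 |
| effects_model | multiplicative_random | IVW SE scaled by max(1, √(Q/(k−1))) |
| n_boot | 1000 | parametric-bootstrap replicates for median/mode SEs |
| phi | 1.0 | mode-estimator bandwidth multiplier (× Silverman rule) |

## Numerical choices

* IVW and Cochran's Q use closed forms; the random-effects factor never
  shrinks the SE below the fixed-effects value, and Q is always computed
  about the fixed-effects estimate so the overdispersion factor is not
  self-referential.
* MR-Egger and MVMR fits go through weighted least squares (statsmodels);
  the reported SEs replace the estimated scale with the one-sided factor
  max(1, √(Q/df)). Egger re-orients instruments so all exposure betas are
  non-negative before fitting. Egger and MVMR p-values use t references
  (df k−2 and k−m) — conservative at small k; IVW uses the normal.
* Wald-ratio SEs use the first-order delta approximation se_out/|β_exp|,
  standard for genome-wide-significant (strong) instruments.
* Weighted-median interpolation follows cumulative mid-weights
  p_i = Σ_{j≤i} w_j − w_i/2, evaluated at 0.5.
* Mode estimator: Gaussian kernel on a 512-point grid spanning
  mean(r) ± 4·sd(r), bandwidth phi·0.9·min(sd, IQR/1.349)·k^(−1/5).
  All-identical ratios short-circuit to the common value; a zero IQR with
  nonzero spread falls back to the sd-based bandwidth.
* Clumping with no LD source treats all within-window pairs as correlated
  (conservative distance-only clumping); with a sparse LD source, absent
  pairs count as unlinked (r² = 0), matching sparse exports that omit
  below-threshold pairs.
* Bootstrap and batch seeds derive from a single `numpy` SeedSequence, so
  identical configs and seeds reproduce identical outputs bit for bit.

## The synthetic generator

`simulate_two_sample` draws, per SNP: MAF ~ U(0.05, 0.5); instrument
effect γ_j ~ N(0.2, 0.05²) (strong instruments, as survive genome-wide
selection); pleiotropy α_j = 0, N(0, sd²) (balanced) or N(mean, sd²)
(directional), optionally with a component proportional to γ_j to violate
InSIDE; true outcome association Γ_j = β·γ_j + α_j. Observed betas add
Gaussian noise with the standardized-trait GWAS standard error
(2·n·maf·(1−maf))^(−1/2); defaults n_exp = 300 000 and n_out = 200 000
match large European-ancestry GWAS of anthropometric and lipid traits.
`simulate_mediation_chain` composes two such models so that a SNP's outcome
effect is direct_effect·γ_x + β2·(β1·γ_x + δ), with the mediator's own
instruments δ disjoint from the exposure's except for a configurable
overlap that flows only through the causal path — exactly the structure
the step-2 instrument deletion assumes.

What the generator deliberately omits: LD between instruments (clumping is
tested against hand-built LD fixtures instead), sample overlap between the
two GWAS, case-control SE structure (binary outcomes reuse the continuous
SE form on the log-odds scale), weak instruments, and allele-frequency
estimation error. Passing calibration and recovery tests therefore shows
the estimators behave correctly under the model's own assumptions, not
that real-data violations of those assumptions are handled.

## Problem sizes used in the test suite

Calibration: 1000 null replicates (k = 100) for the IVW type-I error, 500
for Q/df and for the balanced-pleiotropy Egger intercept rate. Recovery:
200 replicates at true β = 0.3 for all five estimators (bootstrap SEs are
not needed for point-estimate recovery, so those loops use minimal
bootstrap counts), 50 replicates for two-exposure MVMR, one seeded
end-to-end mediation chain (k = 50 + 50, overlap 10). These sizes hold the
Monte-Carlo error well below the tolerances being asserted.

## Known limitations

* No proxy-SNP lookup when an instrument is missing from the outcome GWAS;
  it is dropped (audited).
* No instrument-strength (F-statistic) filtering or conditional-F
  diagnostics for MVMR; no MR-PRESSO/robust variants; no funnel or
  forest graphics — tabular outputs only.
* The LD interface consumes user-supplied r² (sparse or dense); the
  package never computes LD from genotypes.
* Positions are 1-based and build-agnostic; no liftover.
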