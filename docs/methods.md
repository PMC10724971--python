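# Methods

## Statistical model

For one exposure–outcome pair, the input after harmonization is k variants
with marginal effect estimates β_Xj ± σ_Xj on the exposure and β_Yj ± σ_Yj
on the outcome, aligned to a common effect allele.  Under the instrumental
conditions (relevance, no confounding of the variant–outcome relation, no
direct outcome effect), β_Yj = θ·β_Xj and every ratio β_Yj/β_Xj estimates
the causal effect θ of a 1-SD change in the exposure.

The estimators combine the ratios as described in the README.  Reference
distributions: standard normal for the Wald ratio, IVW, weighted median and
maximum likelihood; Student t with k − 2 df for both MR-Egger coefficients.
All p-values are two-sided.

### Estimator details and numerical choices

- **Wald ratio SE** uses the first-order delta method σ_Y/|β_X| only; the
  second-order term is negligible at the instrument strengths the selection
  pipeline admits (F ≥ 10).
- **IVW** defaults to multiplicative random effects: the fixed-effect SE is
  scaled by max(1, √(Q/(k−1))).  The floor means the estimator reduces
  exactly to the fixed-effect model when there is no excess heterogeneity,
  and the scaling leaves the point estimate untouched.  The fixed model
  remains available (`model="fixed"`).
- **MR-Egger** first orients every pair so β_Xj ≥ 0 (flipping both betas of
  a pair, which leaves ratios unchanged); the intercept is only
  interpretable in that orientation.  The weighted residual variance factor
  is floored at 1, mirroring the IVW convention.  k ≥ 3 is required: at
  k = 2 the model has zero residual degrees of freedom, so pairs with two
  instruments get IVW + Q but no Egger/median/ML sensitivity row.
- **Weighted median** interpolates the sorted ratios against the centred
  cumulative weights S_j = Σ_{i≤j}w_i − w_j/2 at S = ½ and clamps to the
  extreme ratios outside [S_1, S_k].  The SE is a parametric bootstrap
  (default 1000 replicates) resampling both beta vectors from
  N(β, σ²); it is seeded, and scan-level seeds are derived per pair from
  the run seed so result tables are byte-identical across reruns.
- **Maximum likelihood** maximizes the joint normal likelihood over θ and
  the k true SNP–exposure effects ξ_j.  The inner maximization is available
  in closed form, giving the exact profile deviance
  Σ (β_Yj − θβ_Xj)²/(σ_Yj² + θ²σ_Xj²), which is minimized by Brent search
  (xtol 1e-10) started from the IVW estimate; the SE comes from the
  θ-component of the inverse observed information of the *joint* model at
  the optimum (Schur complement over the diagonal ξ block).
- **p = 0 inputs** are clamped to the smallest positive double on read so
  −log10 transforms stay finite; this is logged.
- **Degenerate inputs**: β_X = 0 raises a degenerate-instrument error in
  every ratio-based estimator; monomorphic panel variants yield r² = 0 with
  a warning; clumping ties on p are broken lexicographically by variant id,
  making the output invariant to input order.

### Selection pipeline

Steps run strictly in order: (a) exposure p < 5×10⁻⁸; (b) greedy LD
clumping at r² < 0.001 within ±10,000 kb (window inclusive, distance on
positions; variants absent from the panel are dropped rather than presumed
independent); (c) presence in the outcome with allele-set match, accepting
the strand complement; (d) per-SNP F = (β/σ)² ≥ 10 — a per-variant
statistic, each instrument must qualify individually; (e) exclusion of
variants with outcome p ≤ 5×10⁻⁸.  The attrition log records counts dropped
at each step and always sums to the input size.

Note a structural consequence of step (e) exercised by the simulations: for
a genuinely causal exposure the *strongest* instruments acquire outcome
associations ∝ θ·β_X and are the first to be excluded.  Effect sizes whose
per-SNP outcome signal approaches genome-wide significance therefore lose
instruments to their own causality.

### Harmonization of palindromic variants

A/T and C/G variants read identically on both strands, so orientation is
inferred from effect-allele frequency: if either dataset's frequency is
missing or falls inside [0.42, 0.58] the variant is dropped; otherwise the
frequency sides are matched.  The window is configurable and a strict
drop-all-palindromic mode exists.  The synthetic generator emits no
palindromic allele pairs, so this path is exercised by unit tests only.

### Multiplicity

Forward scans use α divided by the number of exposures actually tested
(those with ≥ 1 surviving instrument) — the denominator is data-dependent.
Reverse scans default to the full pair count (every blood-pressure trait ×
every metabolite), the conservative choice when per-trait testability
varies; an override is available.  Significance is strict (p < threshold).
0.05/703 prints as 7.11×10⁻⁵ and 0.05/2182 as 2.29×10⁻⁵; note that
0.05/707 is 7.07×10⁻⁵ — the package always reports the computed quotient.

## Synthetic worlds

The generator reproduces the *statistical shape* of a two-sample
metabolome-MR study at desk scale: an exposure cohort of 8,000 (all
metabolite phenotypes measured on the same sample, as in a metabolomics
cohort), an outcome cohort of 20,000, a 500-individual LD panel, and ~2,000
SNPs in 100 LD blocks.

- **Genotypes**: Hardy–Weinberg draws per haplotype from a latent AR(1)
  Gaussian (correlation ρ, default 0.8) thresholded at the allele-frequency
  quantile.  Blocks share a base MAF (per-SNP jitter 0.01) — tightly linked
  variants have similar frequencies, and grossly different MAFs would cap
  the attainable r².  Dosage-scale correlation is attenuated relative to the
  latent ρ by the liability thresholding (adjacent r² ≈ 0.25 at ρ = 0.8,
  ≈ 0.55 at ρ = 0.95).  Blocks are separated by 25 Mb, beyond the 10,000 kb
  clumping window, so at most one instrument can survive per block and
  clumping truth is known by construction.
- **Effects**: causal SNPs (one per block) get per-allele effects on the
  standardized-genotype scale (α ∝ 1/√(2p(1−p))) with dispersed magnitudes
  (factor U(0.6, 1.4)), jointly explaining `exposure_h2` of the unit-variance
  exposure.  Dispersion matters: the MR-Egger intercept is identified by
  variation in instrument strength (I²_GX); with nearly equal strengths the
  intercept absorbs θ(1 − I²_GX)·mean|β_X| — a known finite-strength
  attenuation, visible in early versions of the pleiotropy world.
- **Outcome**: Y = θ·X + Σ γ_j s_j G_j + ε with γ the direct (pleiotropic)
  effects per exposure-increasing allele (s_j = sign α_j), so a positive
  mean γ is directional pleiotropy in the Egger sense; residual variance is
  set to keep Var(Y) ≈ 1.  Summary statistics are per-SNP marginal simple
  regressions computed separately in each (disjoint) sample, so LD induces
  correlated betas within blocks — deliberately, so the pipeline's clumping
  is load-bearing rather than decorative.

### Canonical scenario presets

These freeze the stated worlds used by `tests/test_acceptance.py`:

| preset | key settings | purpose |
|---|---|---|
| `calibration_config` | θ = 0, k = 20, h² = 0.3, independent SNPs | IVW type-I error; Q ~ χ²(19).  Expected per-SNP F ∈ [41, 223]; m_snps reduced to the causal set so 2000 replicates stay cheap |
| `recovery_config(θ)` | k = 10, h² = 0.5 (expected per-SNP F ≈ 140–550) | bias/coverage at θ = ±0.3.  Strong instruments keep regression-dilution (∝ 1/F) an order of magnitude below the Monte-Carlo band |
| `balanced_pleiotropy_config` | θ = 0, γ ~ N(0, 0.02²) on all causal SNPs, h² = 0.5 | Egger intercept unbiasedness under InSIDE, isolated from the θ·(1−I²_GX) attenuation |
| `directional_pleiotropy_config` | θ = 0.1, γ ~ N(0.06, 0.02²) | intercept power; the mean direct effect is ≈ 3.4 intercept SEs (SE ≈ 0.018 at these sizes), i.e. clearly detectable pleiotropy |
| `metabolome_config` | 100 traits, 5 causal with &#124;θ&#124; = 0.12, k = 8, 30% of traits without GWS SNPs | end-to-end scan truth |

The metabolome θ was calibrated analytically, not by trial: each causal
SNP's outcome association must stay clearly below the 5×10⁻⁸ exclusion
threshold (per-SNP z ≈ 3.3 at θ = 0.12) or a causal trait is stripped of
its own best instruments (see the step-(e) note above), while the pooled
IVW signal (z ≈ √k·3.3 ≈ 9–10) retains essentially full power against the
metabolome-wide Bonferroni threshold (z ≈ 3.4).  Causal traits draw their
instrument blocks from a reserved pool disjoint from all null traits'
blocks, so a null trait can never be flagged through LD with a causal one —
family-wise false positives then occur at the nominal Bonferroni rate
(~4.5% of scans), which is why the end-to-end criterion is "flagged set
equals planted set in ≥ 95% of runs" rather than "always".

Calibration tests use the fixed-effect IVW (whose nominal level the
criterion checks; the random-effects scale is deliberately conservative
under the null), while recovery/coverage tests use the default
random-effects model, which absorbs the θ²σ_X² component of ratio variance
that fixed-effect weights ignore — at θ = ±0.3 the fixed model genuinely
undercovers (≈ 0.92).

### What a green suite does and does not establish

The generator draws clean normal phenotypes, exact HWE genotypes, a single
homogeneous population, disjoint samples, and no metabolite–metabolite
correlation.  Green tests establish the *pipeline's* correctness and the
estimators' frequentist behavior in that world; they say nothing about
population stratification, sample overlap, winner's-curse selection of
instruments from the same data, non-normal phenotypes, or genome-scale SNP
counts.  Headline counts from real cohort analyses are not reproducible at
desk scale and are not targets of the suite.

## Known limitations

- Per-SNP F is the standard squared-z approximation; no joint instrument
  F-statistic is computed.
- No Steiger directionality filtering, MR-PRESSO outlier removal, FDR
  procedures, multivariable MR or mode-based estimators.
- The weighted-median bootstrap ignores between-instrument correlation
  (instruments are clumped to near-independence, so this is second-order).
- VCF panels must carry hard-call genotypes; dosage/imputation-quality
  fields are ignored.  Positions are assumed build-consistent across
  exposure, outcome and panel; there is no liftover.
- At k = 2 sensitivity estimators are unavailable by design (zero residual
  df for the Egger intercept); the scan config can lower the weighted
  median/ML threshold to k ≥ 2 separately if desired.
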