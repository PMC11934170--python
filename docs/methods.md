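# Methods

## The screen

The pipeline treats each candidate protein as an exposure in a two-sample
Mendelian-randomization design: SNP effects on the protein come from one
study population, SNP effects on a renal outcome from another. Under the
instrumental-variable assumptions (relevance, independence from
confounders, no direct path to the outcome), the ratio of outcome to
exposure effects identifies the causal effect of the protein level on the
outcome.

### Instrument selection

Per exposure table, in order:

1. **Significance filter.** Keep SNPs with p < 5×10⁻⁸; when none survive,
   relax to 5×10⁻⁶ (the threshold actually used is recorded in the audit).
2. **Confounder blocklist.** A user-supplied rsid list (the pipeline does
   not attempt to reconstruct which traits count as confounders); removed
   SNPs are audited as `confounder`.
3. **LD clumping.** Greedy: the lowest-p unprocessed SNP indexes a clump
   and removes same-chromosome SNPs with r² > 0.01 within a two-sided
   10,000 kb window; ties on p break by (chrom, pos, rsid). Missing LD
   entries are treated as r² = 0; a distance check on a pair with unknown
   positions is a configuration error rather than a silent skip.
4. **Weak-instrument filter.** Per-variant variance explained defaults to
   r²ⱼ = t²/(t² + n − 2) with t = β/se, which needs no allele frequency;
   2·eaf(1−eaf)β² is available for standardized traits. Set-level
   R² = Σr²ⱼ (independence is a fair approximation after clumping at
   r² ≤ 0.01), capped at 0.999. The set-level
   F = R²(n−k−1)/(k(1−R²)) must reach 10; otherwise the variant with the
   smallest r²ⱼ is dropped (audited `low_F`) and F is recomputed, until the
   set passes or empties. A per-variant-F mode is exposed for the reading
   in which each SNP must individually reach F ≥ 10.

### Harmonization

Outcome records are aligned to the exposure's effect allele: identical
alleles pass through; swapped alleles negate the outcome beta and reflect
its frequency; alleles matching only after base complement are treated as
strand flips. Palindromic SNPs (A/T, C/G) cannot be resolved by letters:
they are dropped when either allele frequency is missing or within
0.5 ± 0.08 (the band is a parameter), otherwise aligned so both
frequencies fall on the same side of 0.5. Reported p-values are checked
for factor-2 consistency with 2Φ(−|β/se|) at load time to catch scrambled
columns.

### Estimators

With per-SNP ratios θⱼ = β̂_Yⱼ/β̂_Xⱼ, first-order se θⱼ = se_Yⱼ/|β̂_Xⱼ| and
weights wⱼ = 1/se²(θⱼ):

* **Wald ratio** (k = 1): θ with the first-order delta SE (a second-order
  correction is switchable).
* **IVW**: precision-weighted mean; fixed-effect SE 1/√Σwⱼ for k ≤ 3,
  multiplicative random effects (SE scaled by max(1, √(Q/(k−1)))) for
  k ≥ 4. The auto rule is config-overridable.
* **MR-Egger** (k ≥ 3, reported at k ≥ 5): weighted least squares of β̂_Y
  on β̂_X with an intercept, pairs oriented so β̂_X ≥ 0, weights 1/se²_Y.
  Slope and intercept p-values use the t distribution with k − 2 df; a
  nonzero intercept indicates directional pleiotropy.
* **Weighted median** (k ≥ 3): order θⱼ, form cumulative standardized
  weights sⱼ = (Σᵢ≤ⱼwᵢ − wⱼ/2)/Σw, linearly interpolate at s = 0.5. SE by
  parametric bootstrap (θⱼ* ~ N(θⱼ, seⱼ), 1000 reps, seeded).
* **Weighted / simple mode** (k ≥ 3): argmax of a Gaussian kernel density
  over θⱼ (bandwidth = Silverman's rule × a configurable factor; IVW
  weights for the weighted variant), bootstrap SE as above. The point
  estimate uses a 512-point grid; bootstrap replicates use 128 points,
  which is well below the kernel bandwidth and only feeds the SE.
* **Cochran's Q**: Σwⱼ(θⱼ − β̂_IVW)², chi-square with k − 1 df.

**Outlier handling.** Heterogeneity outliers are pruned by leave-one-out Q
minimization: while the Q p-value is below 0.05 and k > 2, drop the
variant whose removal most reduces Q, logging each removal. This is the
simplest deterministic reading of "remove outliers to resolve detected
heterogeneity"; radial-MR and MR-PRESSO style diagnostics are out of
scope.

All two-sided p-values are normal-based except Egger's (t, k − 2 df). ORs
are exp(β) with symmetric 95% intervals exp(β ± 1.96·se) on the log scale
(the printed intervals in the replay tables are consistent with this
convention).

### Multiple testing and classification

The headline estimate per protein–dataset pair is the Wald ratio (k = 1)
or IVW (k ≥ 2). Benjamini–Hochberg q-values are computed within each
outcome dataset across proteins (the per-dataset family is what the
replayed tables imply: q varies within a dataset column); a global family
is available. Tiers: p ≥ 0.05 none, p < 0.05 ≤ q suggestive, q < 0.05
strong.

Voting uses raw p < 0.05 (a strict-q mode exists). *Candidate*: at least
`min_datasets_per_category` (default 1) significant datasets in **each**
of eGFR/UAE/creatinine. *Core*: significant in ≥ 2 of the 3 categories
with a conflict-free direction. Direction votes: β > 0 on creatinine/UAE
or β < 0 on eGFR → risk; the opposite signs → resistance; any mix →
conflict (excluded from the core set); no significant call →
indeterminate. The source descriptions of the intersection rule are not
mutually consistent (all-three-categories for candidates, two-of-three for
core, six-of-nine datasets elsewhere); the category-level reading is the
default because it reproduces the published membership, and
`min_datasets_per_category` / `min_total_datasets` expose the alternatives
rather than resolving the discrepancy.

When replaying the packaged printed estimates, every listed protein is
treated as having already passed the candidate stage (the published
candidate screen ran on the full upstream results, which the tables do not
contain), so only the core/direction rules are applied.

## Expression validation

* **Merge**: gene-symbol intersection across matrices, samples
  concatenated; no imputation.
* **Batch correction**: the parametric empirical-Bayes location–scale
  model (ComBat). Genes are standardized against a design containing batch
  indicators and the control/DN group covariate — the covariate is always
  included so biology is not absorbed into batch means. Per-batch per-gene
  location γ̂ and scale δ̂² estimates are shrunk with a normal prior on γ
  and an inverse-gamma prior on δ² (method-of-moments hyperparameters per
  batch), iterating the standard fixed-point updates to 1e-4 (cap 100
  iterations). A single batch is a warned no-op; a batch with one sample
  is an error (scale inestimable). The implementation agrees with
  `sva::ComBat` to ~1e-14 on test fixtures.
* **Gene-set scoring**: per gene, a Gaussian-kernel cross-sample CDF
  statistic (bandwidth = SD/4, so the statistic is exactly invariant to
  per-gene positive affine rescaling); per sample, genes are ranked by the
  statistic and walked Kolmogorov–Smirnov style — set genes add the
  symmetric rank weight |G/2 − pos + ½|^τ (τ = 1, normalized over the
  set), non-set genes subtract 1/(G−|set|); the score is the maximum
  positive plus the minimum negative running deviation. This is
  GSVA-inspired but deliberately self-contained and not bit-compatible
  with the R gsva package. Scoring uses the full control+DN cohort by
  default (a DN-only switch exists); the source is silent on which cohort
  the published scores used.
* **Risk enrichment** = score(risk set) − score(resistance set); exactly
  antisymmetric under swapping the sets.
* **Median split** of DN samples: above the median → high; at or below →
  low (deterministic tie rule chosen for reproducibility).
* **Moderated t**: per gene, the pooled two-group variance s²_g (d_g df)
  is shrunk toward a prior s₀² whose df d₀ comes from moment-matching on
  log s²_g (digamma/trigamma closed forms, trigamma inverted by Newton
  iteration); moderated t = logFC/(s̃_g·√(1/n₁+1/n₂)) with d₀ + d_g df and
  BH q over all genes. `prior_df=0` disables shrinkage (ordinary t);
  `prior_df=inf`-like values pool completely. Matches `limma::eBayes` to
  ~1e-14 on test fixtures.

## Synthetic study conditions

The generators define the conditions under which the statistical
guarantees are tested; they emulate the shape of the real inputs, not
their content.

* **Summary statistics**: maf ~ U(0.05, 0.5); se = 1/√(2·maf(1−maf)·n)
  exactly; exposure n = 50,000 and outcome n = 200,000 (large-biobank
  scale); true SNP effects on the protein |N(0, 0.15²)| — effect alleles
  are coded as the exposure-increasing alleles, the usual convention for
  protein-QTL instruments, which gives directional pleiotropy a
  well-defined sign; β̂_Y = θβ_X + αⱼ + noise with αⱼ ~ N(μ_α, σ_α²)
  (defaults 0: no pleiotropy unless a test injects it); optional
  block-diagonal LD with constant within-block r², matching what clumping
  needs and nothing richer. Alleles are drawn from non-palindromic pairs
  so harmonization attrition does not confound power calculations.
* **Instrument counts**: J defaults to 4 SNPs per protein, mirroring the
  replayed tables where most pairs rest on 1–3 instruments; recovery
  experiments that exercise the five-estimator tier use J = 8–50
  explicitly.
* **Panel**: 50 proteins, 20% risk / 20% resistance / 60% null; the truth
  class sets the sign pattern of θ (= ±0.1) across the three categories
  (+creatinine, +UAE, −eGFR for risk); three replicate datasets per
  category with independent sampling noise.
* **Expression**: baseline N(8, 1) log2 values; additive batch shift 2.0
  (and optional multiplicative scale); half the DN samples per batch form
  a high-risk subgroup with +1 on risk-set genes and −1 on
  resistance-set genes; 30-gene sets in a 1000-gene matrix.

What passing tests show — and do not show. The simulations have exact
normal sampling noise, independent SNPs across blocks, no allele-frequency
mismatch between studies, no sample overlap, and gene-level expression
with homoscedastic noise. Recovery/type-I results under these conditions
verify the estimators and the plumbing; they do not certify performance
under real-world LD misspecification, winner's curse, probe-level
artifacts, or confounded batches.

Problem sizes in the test suite (200 replicates for ±3·SE parameter
recovery, 2000 for the type-I rate, 20 panel replicates, 50 null DE
replicates) were chosen to give binomial margins comfortably inside the
asserted bounds while keeping the default run a few minutes long.

## Numerical choices and edge cases

* p-values are floored at 1e-300; the load-time consistency check between
  p and β/se compares log p with a factor-2 tolerance after flooring.
* Clumping tie-breaks, the median-split tie rule, and the greedy outlier
  pruning order make every stage deterministic; all bootstraps take
  explicit seeds, and the pipeline derives per-stage seeds from the global
  one, so a config + seed reproduces the report bundle byte for byte.
* Degenerate inputs: empty instrument sets are legal and skipped with a
  logged reason; a gene set covering every gene scores 0 with a warning
  (the complement step is undefined); constant genes get an uninformative
  kernel-CDF statistic of 0.5; zero sample variances are floored at 1e-12
  before the inverse-gamma moment match.
* Reports round betas to 4 decimals and ORs to 3 for display, with a
  parallel full-precision file.

## Known limitations

* No proxy-SNP lookup, liftover, or LD estimation from reference panels:
  LD is an input.
* MR-PRESSO/radial outlier diagnostics, multivariable MR, colocalization
  and Steiger filtering are out of scope.
* The confounder blocklist is taken as given.
* The gene-set score is not numerically interchangeable with the R gsva
  package, and probe-to-gene collapsing for specific microarray platforms
  is not provided.
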