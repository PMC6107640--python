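# Methods

## Scope and data model

`germdrug` analyses a cell-line pharmacogenomic screen represented by four
sample-aligned objects: a samples × variants germline dosage matrix with
per-variant metadata (chromosome, 1-based position, alleles, frequency), a
samples × markers binary somatic matrix (mutations, copy-number events,
fusions — no positional/LD semantics), a drugs × samples phenotype table in
1-AUC units bounded to [0, 1], and per-sample tissue labels. All
coordinates are 1-based inclusive, as in VCF.

## Association models

Somatic markers are tested per drug with an ordinary linear model

    y = 1·mu + W·alpha + x_s·beta_s + psi,     psi ~ N(0, sigma_e^2 I)

and germline dosages with a linear mixed model adding a polygenic random
effect

    y = 1·mu + W·alpha + x_g·beta_g + g + psi,  g ~ N(0, sigma_g^2 K)

whose covariance is the realized-relatedness matrix
K = Z Zᵀ / M over standardized dosages Z_ij = (d_ij − 2·af_j)/√(2·af_j(1−af_j)),
scaled so the mean diagonal is 1. The random effect absorbs
population/lineage structure, which in a drifted panel would otherwise
confound every frequency-differentiated variant.

Choices that matter:

* **Maximum likelihood, not REML**, for both null and alternative fits, so
  the likelihood-ratio statistic 2·ΔlogL is internally consistent and
  nonnegative by construction; P values come from χ²(1).
* **Variance-ratio profiling.** In the eigenbasis K = U diag(λ) Uᵀ the
  rotated model has independent errors with variances σ_g²(λ_i + δ),
  δ = σ_e²/σ_g². β and σ_g² are profiled in closed form; δ is maximized on
  a 50-point log-spaced grid over [1e−5, 1e5] with bounded golden-section
  refinement between the best grid point's neighbours. The alternative
  model's grid always includes the null's optimum, which guarantees
  LR ≥ 0. A δ estimate at either grid end is flagged (`delta_boundary`).
* **Batch scans.** `lmm_scan` residualizes the rotated phenotype and every
  variant against the weighted covariates per grid point (one QR per δ), so
  the per-variant fit is two scalar products. This is what makes
  permutation-based error control affordable; the scan omits the
  golden-section refinement of the single-variant path, a discrepancy of
  order the grid spacing in log δ that is negligible for P values (the two
  paths are cross-checked in the tests at rel. 1e−3).
* **Phenotype scale.** Phenotypes are quantile-normalized to a standard
  Gaussian before testing — rank-based inverse-normal transform
  Φ⁻¹((rank − 0.5)/n), average ranks for ties, constant input mapping to
  zeros with a warning. Effect sizes are re-estimated by refitting the same
  model on the raw 1-AUC scale, so reported betas are in interpretable
  response units while P values stay outlier-robust.
* **Covariates.** Tissue enters as one-hot minus an alphabetical reference
  level plus an explicit intercept. Variants collinear with the covariates
  are flagged and given NaN P values rather than dropped silently.
* K is computed from the LD-filtered variant set; leave-one-chromosome-out
  kinship is not applied (exposed through the API by passing any K).
* Somatic copy-number markers enter the linear model as binary indicators.

## Multiple-testing correction

Somatic tests (hundreds of markers, no LD) use Bonferroni. Germline tests
use a permutation scheme that respects LD:

1. Per drug, the sample axis of one chromosome's genotype block is permuted
   as a whole — LD among variants is preserved, genotype–phenotype and
   genotype–covariate linkage is broken; y, W and K stay fixed (so the null
   model, which does not involve genotypes, is unchanged). The mixed-model
   scan is rerun and the minimum P recorded; default 100 permutations.
2. Each chromosome-level minimum is mapped to the genome-wide scale by the
   quantile transform p_gw = 1 − (1 − p_chr)^(1/C), where
   C = (genome length)/(chromosome length) (≈15.6 for chromosome 3 on
   GRCh37). If the chromosome minimum is the smallest of E effective
   uniform tests, its CDF is 1 − (1−t)^E and the genome minimum's is
   1 − (1−t)^(E·C); matching quantiles gives the transform above,
   independently of E, with small-p behaviour p_chr/C. (The superficially
   similar map 1 − (1−p)^C answers a different question — the probability
   that the minimum of C tests falls below a *single* observed p — and
   using it to build the null makes the null minima stochastically far
   larger than true genome-wide minima, so every observed minimum would
   rank below the whole null; the quantile direction is also the one
   consistent with a calibrated false-positive rate, which the acceptance
   suite verifies on a global-null panel. A `linear` method, p/C, is
   available as the tail approximation.)
3. Extrapolated minima are pooled across permutations and drugs into one
   empirical null; the adjusted P of a drug's observed genome-wide minimum
   is the add-one rank estimate (1 + #{null ≤ obs})/(1 + N), which cannot
   be zero and is monotone.
4. A germline lead is only called significant (FWER < 5%) if it also passes
   the post-hoc LD confirmation: some other variant within ±100 kb on the
   same chromosome with r² ≥ 0.4. Observed minima come from the full
   genome-wide scan and are not themselves extrapolated.

## Variant filters

`allele_frequency` averages non-missing dosages/2; variants with more than
10% missing dosages are dropped before filtering, and r² uses
pairwise-complete observations (a constant vector yields r² = 0 with a
flag, so bulk scans can pass monomorphic variants). The authenticity
filter retains a variant iff its maximum r² against the nearest 50
surviving variants on the same chromosome — pooled across both sides,
nearest by base-pair distance first, fewer near chromosome ends — reaches
0.4, after a MAF > 2% cut. Sortedness by (chromosome, position) is
required and checked. Reference-population concordance compares
minor-allele-aligned frequencies, so a flipped allele coding still scores
as concordant. The optional imputation-quality column filter is a plain
numeric threshold (score computation is upstream of this package).

## Two-step prediction model

Stage 1 fits an elastic net on somatic markers; its **in-sample training
predictions** are subtracted from the (tissue-residualized) phenotype;
stage 2 fits an elastic net on germline dosages against those residuals.
Joint test predictions are the sum of the stages. "Regressed out" is
implemented as literal subtraction, not re-estimation of a slope on the
stage-1 predictions; whether stage-1 predictions during stage-2 training
should instead be inner-fold out-of-sample is an open modelling choice —
in-sample is implemented and flagged for sensitivity analysis.

Hyperparameters (mixing grid {0.1, 0.5, 0.9} × a 30-point logarithmic
penalty path) are chosen by 3-fold inner CV strictly on training data;
feature scalers are learned on training folds only; zero-variance features
are excluded with a warning. Performance is the Pearson correlation
between concatenated out-of-sample predictions and the observed phenotype
per repeat of k-fold CV (defaults k = 5, 10 repeats, identical folds for
both models within a repeat; constant predictions score r = 0). The
germline-component call is one-sided: mean(r_joint − r_somatic) >
2 × SD_repeats(r_joint − r_somatic), the difference-based rule implied by
an error bar on the difference of correlations; a component-based variant
(r_germline > 2 × its repeat SD) is available via `rule="component"`. The
implied confidence level of the 2-SD one-sided rule is Φ(2) = 97.72%.

## Downstream analyses

* **Colocalization**: Pearson correlation of matched −log₁₀ P profiles
  over the shared variant set (±1 Mb window matched by id intersection);
  colocalized iff r > 0.8; constant profiles give NaN and a negative call.
* **Proxy selection**: the candidate with maximum r² to the lead within the
  window; none if best r² < threshold (default 0.8); the lead itself wins
  at r² = 1; ties go to the smallest position.
* **Replication**: candidate (variant, drug) pairs are re-tested with the
  same association machinery, BH-adjusted jointly, and replicate iff
  adjusted P < FDR (default 20%) with effect-direction concordance when a
  discovery direction is supplied; untestable pairs (variant absent,
  MAF < 2%, drug missing) are skipped, not failed. Screen-level
  replication over a handful of attempted tests uses Bonferroni.
* **Interaction**: LR test of the expression × genotype product term in a
  linear model containing intercept, covariates and both main effects. The
  genotype is coded by default as a binary functional group — carriers of
  a functional allele (dosage < 2) vs loss-of-function homozygotes —
  because a loss-of-function variant plausibly only abolishes function in
  the homozygous state; additive 0/1/2 coding is a flag. The exact
  interaction model is not uniquely determined by a stratified figure;
  main-effects-plus-product is the standard inference. Stratified profiles
  use pooled-sample quantile bins of expression (type-7 quartile
  convention throughout, also for the box-plot outlier rule
  x < Q1 − 1.5·IQR or x > Q3 + 1.5·IQR).

## Synthetic-panel generator

The generator is first-class, tested code; its defaults define the study
conditions for all calibration experiments.

* **Genotypes.** Variants come in contiguous blocks (default 10 variants)
  sharing one ancestral allele frequency drawn uniformly from the MAF
  range (default 2–50%). Haplotypes are latent-Gaussian AR(1) chains
  thresholded at Φ⁻¹(freq); a sample's dosage is the sum of two
  independent haplotypes. The latent correlation is calibrated by solving
  the bivariate-normal orthant probability so that the realized
  binary-allele correlation equals the requested `within_block_r`; because
  dosages are sums of two iid haplotypes, the realized adjacent dosage
  correlation matches the target (the suite checks `within_block_r = 0.8`
  realizes a median adjacent r² of ~0.64). Blocks are mutually
  independent; variants are laid out at 5-kb spacing with blocks assigned
  round-robin to chromosomes.
* **Population structure.** Subpopulation allele frequencies drift from
  the block's ancestral frequency by a Balding–Nichols beta draw
  controlled by `fst_like_divergence`; membership is balanced and
  recorded. This reproduces exactly the confounding that the mixed model's
  random effect must absorb. With nonzero divergence a variant's realized
  MAF can drift outside the configured range (drift SD √(F·p(1−p))
  exceeds binomial sampling error), so the MAF-range invariant is
  enforced/tested at zero divergence.
* **Molecular layers.** Somatic markers are Bernoulli per marker with
  prevalence drawn from a configurable range (default 5–30%), independent
  of the germline layer. Expression per gene is a per-tissue mean plus
  unit Gaussian noise and is independent of every germline variant by
  construction (interaction variants do not move their partner gene's
  expression).
* **Phenotypes.** Raw response = tissue offsets + Σ β_g · standardized
  dosage + Σ β_s · marker + optional β · (standardized dosage ×
  standardized expression) + polygenic draw N(0, sd²K) + Gaussian noise,
  then squashed onto [0, 1] by an affine rescale of the 0.1–99.9
  percentile range, clipped; the (lo, hi) pair is recorded per drug so the
  transform is invertible on the bulk. Effects on standardized dosages
  mean a plan's variance contribution is Σβ² when causal variants are
  uncorrelated, which the variance-decomposition test verifies
  analytically.
* **Not emulated**: real human haplotype structure and recombination maps,
  chromosome-scale LD decay, copy-number segments, dosage-imputation error
  models beyond optional Gaussian jitter, missingness mechanisms, and any
  relationship between tissue and subpopulation. Passing calibration tests
  on these panels therefore demonstrates correctness of the statistical
  machinery under its stated assumptions, not robustness to everything
  real screens contain.

## Calibration experiments and problem sizes

The acceptance suite and `scripts/acceptance.py` run the same experiment
designs; sizes are the package's own choices balancing statistical
resolution against a desk-scale run:

* Type-I error: 10,000 unconfounded tests (20 null phenotypes × 500
  variants, n = 500) and 2,000 structure-confounded tests (two
  subpopulations, F ≈ 0.1, phenotype shifted by subpopulation, kinship
  from 2,000 background variants).
* Genome-wide FWER: 50 null drugs on a 5,000-variant LD-block panel
  (n = 300, two subpopulations, 20 chromosomes), 100 permutations of the
  largest chromosome per drug.
* Recovery/power: 200 replicates each; ±2-SE coverage at n = 500 (nominal
  coverage of a 2-SE interval is Φ(2) − Φ(−2) = 95.45%, so with 200
  replicates the empirical rate is checked against that nominal value
  minus two binomial SDs); power for an effect explaining 7% of variance
  at n = 890 against a permutation-derived genome-wide threshold.
* Two-step model: germline-component recovery for a planted single-variant
  effect explaining 5% of residual variance at n = 900 among 200 germline
  features (the analytic out-of-sample benchmark is r = √0.05 ≈ 0.22; a
  single strong causal variant keeps estimation shrinkage small, which a
  diffuse many-variant plant of the same total variance would not); null
  calibration over 200 germline-null drugs whose phenotypes carry a real
  somatic component (n = 120, 8 somatic / 30 germline features). These
  calibration runs use 5 CV repetitions rather than the pipeline default
  of 10 — a runtime choice that is conservative for the false-call check,
  since a noisier repeat SD makes the 2-SD rule fire more often, not
  less. Under a strict global null (no somatic signal at all) the rule
  fires more often than its nominal level at desk-scale n: the somatic
  baseline's out-of-sample r carries a negative fold-mean bias while
  chance germline correlations of order √(2·log p / n) are stable across
  repeats; the germline-null-with-somatic-signal design is the scenario
  the rule is meant for.
* Filter operating characteristics: 2,000 samples, 300 block variants
  (target adjacent r 0.8) plus 30 planted LD-free variants.

## Degenerate inputs and numerical conventions

Constant phenotype → quantile normalization returns zeros (warning).
Constant dosage vector → r² reported 0 with flag; collinear variant →
NaN P with `collinear` flag. All-missing variant → error. Empty null
distribution → error. Zero repeat SD with zero improvement → not
significant. Kinship matrices are validated symmetric PSD to 1e−8 and
symmetrized; eigenvalues are clipped at zero. Missing dosages enter the
kinship as population-mean imputed (standardized zero). RSS values are
floored at 1e−300 before logs. Seeds: every stochastic routine takes an
explicit seed or derives child seeds via `numpy` SeedSequence spawning,
and the pipeline manifest records the seed and a config hash.

## Known limitations

* The LMM optimizes a single variance ratio on a grid; extremely
  ill-conditioned kinship spectra could need a wider grid than
  [1e−5, 1e5].
* The batch scan's δ is grid-only (see above).
* Stage-1 residuals are in-sample; with very small somatic feature sets
  this slightly optimistic residualization is absorbed by the
  cross-validated comparison but remains a modelling choice.
* The genome extrapolation assumes the target chromosome's variant
  density and LD are genome-representative; the generator satisfies this
  by construction, real genomes only approximately.
* PLINK bed/bim/fam input is not supported; use VCF or the TSV dosage
  dialect.
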