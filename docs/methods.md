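# Methods

## Model

The pipeline assumes each modality's subjects × voxels matrix is a noisy
linear mixture

    X_k = A · S_k + Σ_c γ_c · z_c · m_{c,k}ᵀ + E_k ,   k ∈ {1, 2}

with a *shared* subject-loading matrix `A` (subjects × sources), modality
specific spatial sources `S_k`, covariate confounds (covariate vector
`z_c`, effect size `γ_c`, random effect map `m_{c,k}`) and iid Gaussian
noise `E_k`. One loading column is correlated with an external
per-subject reference — a polygenic risk score — and the scientific goal
is to recover that column and its spatial maps, then use them as
transferable features.

### Supervised decomposition

With `A_k` the loading matrix of modality k, the objective is

    max Σ_{k,j=1..2} { ‖corr(A_k, A_j)‖² + 2λ‖corr(A_k, ref)‖² }

(corr column-wise). Implementation:

1. **PCA reduction** per modality to `pca_rank` components (default =
   number of extracted components M). Exact SVD below ~4e6 matrix
   entries, seeded randomized SVD above.
2. **MCCA with reference.** Components are extracted one at a time
   (deflation: each new loading column is constrained to the orthogonal
   complement of the previous columns *within its modality*). For one
   component the objective restricted to unit-norm centered columns
   a₁, a₂ is `2·corr(a₁,a₂)² + 4λ·[corr(a₁,ref)² + corr(a₂,ref)²]` (the
   reference term appears once per (k, j) pair, hence the factor 4λ for
   two modalities). Each alternating update maximizes this exactly over
   one modality's column by a rank-2 symmetric eigenproblem on the
   subspace basis, so the objective is non-decreasing; iteration stops
   when the gain drops below `tol` (1e-6) or at `max_iter` (200).
   Initialization is the top singular pair of the two subspace bases,
   which solves the λ = 0 problem exactly at the first step. Near
   degenerate optima (several equally cross-correlated directions, e.g.
   under a permuted reference) the objective can keep crawling by more
   than `tol` for many iterations; the fit is then flagged unconverged
   and a single warning emitted — the answer is not materially affected.
3. **Back-reconstruction.** Component maps are `pinv(A_k) · X_k,c` with
   `X_k,c` the centered rank-reduced data.
4. **Joint ICA.** One Infomax ICA (logistic nonlinearity, natural-gradient
   full-batch updates, learning rate halved on blowup) on the
   M × (V₁+V₂) concatenated maps after whitening. `n_ica_restarts`
   seeded restarts are matched pairwise by maximal |correlation|
   (Hungarian assignment) and the restart with the highest mean matched
   |correlation| is kept; this stability is reported. Final loadings are
   `A_k · W⁻¹` with `W` the unmixing.
5. **Selection.** Loading-reference correlations get two-sided Fisher-z
   p-values; Benjamini-Hochberg FDR across all 2M tests; a component is
   selectable when significant in *both* modalities, and among those the
   one maximizing the *smaller* |r| wins. One sign per joint component:
   the selected component is flipped, maps and loadings together, so its
   reference correlations are positive.

λ defaults to 0.5. The supervision weight matters exactly when the
number of extracted components is smaller than the number of latent
sources and `pca_rank` exceeds M — then λ decides whether the
reference-associated direction enters the retained subspace; when M
covers all sources the ICA rotation recovers the planted component at
any λ (including 0), and measured associations saturate.

### Networks and features

Z-maps standardize a selected map over in-mask voxels using the
population SD (the map's voxels are the entire population of interest, so
a two-voxel map {4, −4} scores to {+1, −1}). Feature *tables* use the
sample SD (n−1), the usual convention for subject samples. Networks are
the strict sign partitions (Z = 0 voxels belong to neither). Per-network
PCA feature bases are fitted on the designated training cohort only and
transferred frozen — the conservative choice where per-cohort refitting
would leak test information.

### Null-pattern permutation test

The test statistic is the worst-modality |corr(loading, reference)| of
the decomposition's top component, recomputed by rerunning the entire
supervised fusion per permuted reference; the add-one (valid at finite
n_perm) empirical p-value is `(1 + #{null ≥ observed})/(n_perm + 1)`.
This statistic is exchangeable under permutation, so the p-value is
uniform when the reference carries no signal — the calibration the
acceptance suite checks. The spatial similarity of each permuted-run
pattern to the observed one is reported alongside (it is characteristically
low, the "random pattern is dissimilar" observation), but similarity to
the observed pattern is not itself a valid test statistic: the observed
run's self-similarity is 1 by construction, so a p-value built from it
could never calibrate.

### Statistics layer

Welch t-tests by default (pooled-variance mode available, under which the
two-group ANOVA F equals t² exactly); BH-FDR via statsmodels; power of
the Pearson test via the Fisher-z normal approximation
`Φ(z_r√(n−3) − z_{1−α/2}) + Φ(−z_r√(n−3) − z_{1−α/2})`, which returns α
exactly at r = 0 and agrees with Monte-Carlo rejection rates of the exact
t-based test to < 0.01 at the sizes tested. Linear SVM (C = 1) with
stratified seeded 10-fold CV, features standardized inside each training
fold, ROC/AUC from decision values pooled across folds.

## Synthetic data

What it emulates:

* **Genotypes** — per-SNP minor allele frequencies uniform in a
  configurable range; LD blocks via a latent Gaussian copula (two
  haplotypes, block-constant latent correlation ρ = 0.6, thresholded at
  the MAF quantile), so dosages are Hardy-Weinberg consistent and
  within-block correlated — the structure clumping is designed for.
  Within-block SNP spacing 5 kb, inter-block gaps 1 Mb, so a 200-kb
  window spans one block and never two.
* **GWAS weights** — a configurable fraction (default 0.2) of SNPs carry
  ln-odds-ratio weights ~ N(0, 0.15); association p-values are
  2Φ(−|β|/0.02), spreading planted SNPs across the three conventional
  thresholds; null SNPs get null-distributed p-values.
* **Imaging** — unit-variance Laplace source maps (super-Gaussian, so the
  ICA stage is identifiable), loadings iid normal except the planted
  column, which is a Gram-Schmidt mix of the standardized PRS with
  orthogonalized noise — the target correlation is imposed *exactly*
  in-sample. Confound effects are linear in age/sex/site/motion, hence
  exactly removable by OLS; noise is iid Gaussian (default SD 1, i.e.
  5:1 signal variance at 5 sources).

What it does not emulate: spatial autocorrelation of brain maps, site-
specific noise covariance, genotype-imaging sample overlap artifacts, or
coalescent-realistic allele-frequency spectra. Passing tests therefore
demonstrate algorithmic correctness and statistical calibration under the
generative model, not robustness to real-data violations of it.

**Effect-size regime.** Population-scale studies report reference
correlations near r ≈ 0.07 at n > 20,000 — detectable there because
power approaches 1, but far below detectability at desk scale. The
simulations match the *power regime*, not the effect size: r = 0.3 at
n = 500–2000 sits at a comparable detection margin while keeping test
runtimes in seconds. The analytic-power computation covers the small-r,
huge-n case directly.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `PrsConfig.p_snp_threshold` | 5e-8 | GWAS significance cutoff (alternates 1e-4, 0.05) |
| `PrsConfig.r2_threshold` / `clump_window` | 0.1 / 200 kb | greedy LD pruning |
| `MotionThresholds.fd_max` | 1.0 mm | mean-FD exclusion |
| `MotionThresholds.rotation_max` | 1.0° | stricter of the two conventional values (2.5° available); the looser value is common in older protocols, so it is configurable and the choice is logged |
| `FusionConfig.n_components` | 5 | extracted joint components M |
| `FusionConfig.lambda_ref` | 0.5 | supervision weight λ |
| `FusionConfig.n_ica_restarts` | 10 | ICA stability restarts |
| `SimConfig.target_ref_correlation` | 0.3 | planted loading-reference r |
| `SimConfig.noise_sd` | 1.0 | voxel noise SD |

## Numerical choices

* Ties in clumping break by (p-value, chromosome, position) under a
  stable sort — the retained set is deterministic.
* Missing dosages are mean-imputed per SNP after QC, keeping scores
  defined for all subjects (the standard scoring-tool behavior).
* Effect-allele alignment flips dosages (2 − d) when the weight's effect
  allele is the panel's other allele; strand-ambiguous (A/T, C/G) SNPs
  are dropped with a warning; anything else is an error naming the SNPs.
* LD r² comes from the sample's own dosages (squared Pearson r), avoiding
  a reference-panel dependency.
* MCCAR sign convention: modality-1 loadings correlate nonnegatively with
  the reference (with the other modality when λ = 0).
* All random streams derive from a single seed through independent
  numpy `SeedSequence` keys; no stage shares a bit generator.

## Problem sizes

Test and acceptance runs use n = 2000 × 3000 voxels (parameter recovery,
20 seeds), n = 500 × 1000 voxels (permutation calibration, 420 fusion
reruns), and n = 100–300 for the feature-level stages — sizes chosen so
the full suite completes in minutes on one CPU while keeping every
statistical check adequately powered.

## Known limitations

* Exactly two modalities (the objective's pair structure is hard-coded).
* No MDL/variance-based automatic choice of M; it is a config knob with a
  documented default.
* The alternating-eigenproblem MCCAR optimizer is a fully specified
  implementation of the stated objective, not a port of any particular
  fusion toolbox; published toolboxes may differ in optimizer details
  and in their (undocumented) λ conventions.
* Under a permuted reference with several equally strong shared sources
  the per-component objective is near-flat and the convergence flag can
  trip; results remain deterministic and the permutation test accounts
  for this by construction.
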