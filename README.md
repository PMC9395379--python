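# prsfusion

Polygenic-risk-guided multimodal brain feature fusion: a tested pipeline
for discovering, replicating and validating a genetic-risk-associated
brain pattern from two imaging modalities.

## The problem

Schizophrenia polygenic risk scores (PRS) correlate only weakly with any
single imaging feature at population scale, yet the *multimodal pattern*
associated with genetic risk — a covarying set of functional (fALFF-like)
and structural (GMV-like) brain regions — can be a robust, transferable
biomarker. This package implements the full analysis chain:

1. **PRS construction** — quality control (missingness ≤ 0.05, MAF ≥ 0.01,
   Hardy-Weinberg p ≥ 1e-6), greedy clump-based LD pruning (r² < 0.1
   within a 200-kb window), GWAS p-value thresholding (5e-8 / 1e-4 /
   0.05), and the weighted dosage sum `PRS_i = Σ_j d_ij · ln(OR_j)`.
2. **Supervised fusion (MCCA with reference + joint ICA)** — with `A_k`
   the subjects × M loading matrix of modality k, maximize

   ```
   Σ_{k,j=1..2} { ‖corr(A_k, A_j)‖² + 2λ·‖corr(A_k, PRS)‖² }
   ```

   by per-modality PCA reduction, alternating exact eigenproblem updates
   with deflation, then a single Infomax ICA over the modality-concatenated
   component maps. The component whose loadings are PRS-correlated in
   *both* modalities (after BH-FDR) is selected.
3. **Network features** — the selected component's Z-maps are split by
   sign into positive (Z > 0) and negative (Z < 0) networks per modality;
   each subject gets 4 network-mean features (optionally + 5 PCs per
   network = 24 features).
4. **Replication and validation** — least-squares projection of the
   spatial maps onto new cohorts, Pearson/Dice spatial similarity, a
   permuted-reference null-pattern test, linear-SVM diagnosis with
   stratified CV, and the transferred 4-feature linear prediction model
   `score = β₀ + fALFF⁺β₁ + fALFF⁻β₂ + GMV⁺β₃ + GMV⁻β₄`.

Because the real cohorts behind such analyses are access-restricted, the
package ships a first-class synthetic-data module that emulates their
statistical structure — LD-blocked genotypes, planted GWAS weights, and
modality matrices sharing a joint source whose loadings correlate with
the PRS at a configurable level — with full ground truth, so every stage
is testable end to end.

## Worked example

```python
import prsfusion as pf

cfg = pf.SimConfig(n_subjects=500, n_snps=120, ld_block_size=10,
                   n_voxels_per_modality=(800, 800), n_sources=5,
                   target_ref_correlation=0.3, noise_sd=1.0, seed=2026)
study = pf.simulate_study(cfg)          # genotypes -> PRS -> imaging cohort
x1 = pf.regress_covariates(study["x1"], study["covariates"],
                           ["age", "sex", "site", "mean_fd"])
x2 = pf.regress_covariates(study["x2"], study["covariates"],
                           ["age", "sex", "site", "mean_fd"])
fc = pf.FusionConfig(n_components=5, lambda_ref=0.5, seed=2026)
d = pf.select_component(pf.fuse_with_reference(x1, x2, study["prs"], fc))
print(d.selected, d.ref_correlations[d.ref_correlations.component == d.selected])
```

Running the numbered drivers reproduces the whole study
(`python analysis/01_simulate_study.py` … `06_validate.py`); on the
default seed they print:

```
planted loading-PRS correlation: 0.3000 (target 0.3)
fALFF_loading_prs_r: 0.3026   fALFF_map_vs_truth_r: 0.9975
GMV_loading_prs_r:   0.3029   GMV_map_vs_truth_r:   0.9966
projected loading-reference correlation in replication cohort: r = 0.296
fALFF: cross-cohort pattern similarity r = 0.998, Dice(|Z|>2) = 0.917
null-pattern test: observed reference association r = 0.303, p = 0.020
case/control classification (24 features): ACC = 100.0%, AUC = 1.00
transfer prediction (true R^2 = 0.25): r = 0.605 on the independent cohort
```

i.e. the supervised fusion recovers the planted PRS-associated source
almost exactly (map correlation > 0.99), the pattern transfers to an
independent cohort at the planted association strength, the permutation
test confirms reference specificity (p = 0.02 at 49 permutations), and
the downstream classifier/prediction stages behave as the planted effect
sizes dictate. A small table layer (`results/`) holds the compact
reports; bulky subject × voxel matrices are regenerated under `scratch/`.

There is also a CLI mirroring the stages
(`prsfusion simulate|prs|preprocess|fuse|extract|project|similarity|`
`nulltest|classify|predict-fit|predict-apply|stats|power|run`).

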