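#!/usr/bin/env python
"""Replication: projection, spatial similarity, null-pattern test.

Builds an independent cohort expressing the same planted spatial sources,
projects the discovery component onto it to estimate loadings and their
PRS correlation, compares the discovery Z-maps against the replication
cohort's own supervised decomposition, and runs the permuted-reference
null-pattern test on the discovery cohort.
"""

import json
import warnings
from pathlib import Path

import numpy as np

import prsfusion as pf
from prsfusion import io as pio

BASE = Path(__file__).resolve().parent.parent
STUDY = BASE / "scratch" / "study"
FUSION = BASE / "results" / "fusion"
OUT = BASE / "results" / "replication"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 2026

x1 = pio.read_modality_matrix(STUDY / "fALFF.tsv", modality_tag="fALFF")
x2 = pio.read_modality_matrix(STUDY / "GMV.tsv", modality_tag="GMV")
covs = pio.read_covariates(STUDY / "covariates.tsv")
prs = pio.read_prs(STUDY / "prs.tsv")
covariates = ["age", "sex", "site", "mean_fd"]
x1r = pf.regress_covariates(x1, covs, covariates)
x2r = pf.regress_covariates(x2, covs, covariates)

report = {}

# --- independent cohort with the same planted sources --------------------
disc_cfg = pf.SimConfig(n_subjects=500, n_snps=120, ld_block_size=10,
                        n_voxels_per_modality=(800, 800), n_sources=5,
                        target_ref_correlation=0.3, noise_sd=1.0, seed=SEED)
disc = pf.simulate_study(disc_cfg)  # regenerates the discovery truth
rep_cfg = pf.SimConfig(n_subjects=400, n_snps=120, ld_block_size=10,
                       n_voxels_per_modality=(800, 800), n_sources=5,
                       target_ref_correlation=0.3, noise_sd=1.0, seed=SEED + 1)
rep_ref = np.random.default_rng(SEED + 1).standard_normal(400)
y1, y2, _, _ = pf.generate_fusion_cohort(rep_cfg, rep_ref,
                                         sources=disc["truth"])

zmap_f = pio.read_table(FUSION / "zmap_fALFF.tsv")["z"].to_numpy()
fusion_report = json.loads((FUSION / "fusion_report.json").read_text())
comp = fusion_report["selected_component"]

config = pf.FusionConfig(n_components=5, seed=SEED, n_ica_restarts=10)
decomp = pf.select_component(pf.fuse_with_reference(x1r, x2r, prs, config))
maps_sel = decomp.maps["fALFF"][comp:comp + 1]
_, proj_stats = pf.project_maps(y1, maps_sel, reference=rep_ref)
report["projected_loading_ref_r"] = proj_stats[0][0]
report["projected_loading_ref_p"] = proj_stats[0][1]
print(f"projected loading-reference correlation in replication cohort: "
      f"r = {proj_stats[0][0]:.3f} (planted 0.3)")

# --- spatial similarity with the replication cohort's own fusion ----------
rep_decomp = pf.select_component(
    pf.fuse_with_reference(y1, y2, rep_ref,
                           pf.FusionConfig(n_components=5, seed=SEED + 1,
                                           n_ica_restarts=10)))
if rep_decomp.selected is not None:
    z_disc = pf.zscore_map(decomp, comp)
    z_rep = pf.zscore_map(rep_decomp, rep_decomp.selected)
    for tag in ("fALFF", "GMV"):
        sim = pf.spatial_similarity(z_disc[tag], z_rep[tag], threshold=2.0)
        report[f"{tag}_similarity_pearson_r"] = sim.pearson_r
        report[f"{tag}_similarity_dice"] = sim.dice
        print(f"{tag}: cross-cohort pattern similarity r = {sim.pearson_r:.3f}, "
              f"Dice(|Z|>2) = {sim.dice:.3f}")

# --- null-pattern permutation test ---------------------------------------
with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    null_res = pf.null_pattern_test(
        x1r, x2r, prs, pf.FusionConfig(n_components=5, seed=SEED,
                                       n_ica_restarts=2),
        n_perm=49, seed=SEED)
report["null_pattern_p"] = null_res.p_value
report["null_pattern_observed_r"] = null_res.observed_stat
sims = [abs(m["fALFF"].pearson_r) for m in null_res.null_similarities]
report["null_similarity_mean"] = float(np.mean(sims))
print(f"null-pattern test: observed reference association "
      f"r = {null_res.observed_stat:.3f}, p = {null_res.p_value:.3f} "
      f"(49 permutations); permuted patterns are dissimilar "
      f"(mean |r| = {np.mean(sims):.2f})")

(OUT / "replication_report.json").write_text(json.dumps(report, indent=2))
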