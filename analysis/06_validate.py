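#!/usr/bin/env python
"""Validation: classification, group differences, prediction, power.

Builds a synthetic case/control cohort whose four network means are
lowered in cases, classifies cases vs controls with a linear SVM on the
24-feature set, tests group differences with Welch t-tests under BH-FDR,
trains the four-feature linear prediction model on one cohort and applies
it unchanged to an independent cohort, and tabulates the analytic power
of the population-scale correlation test.
"""

import json
from pathlib import Path

import pandas as pd

import prsfusion as pf
from prsfusion import io as pio
from prsfusion.simulate import generate_prediction_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "validation"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 2026

report = {}

# --- case/control classification -----------------------------------------
cc_cfg = pf.SimConfig(n_subjects=300, n_snps=60,
                      n_voxels_per_modality=(500, 500), n_sources=5,
                      seed=SEED)
effect = {k: 1.0 for k in ("fALFF_positive", "fALFF_negative",
                           "GMV_positive", "GMV_negative")}
x1, x2, labels, masks = pf.generate_case_control(cc_cfg, effect)
feats24 = pf.extract_pc_features(x1, x2, masks, n_pc=5)
clf = pf.classify_svm(feats24, labels, n_folds=10, seed=SEED)
pio.write_table(clf.roc_points, OUT / "roc_points.tsv")
report["classifier"] = {"accuracy_pct": clf.accuracy, "auc": clf.auc,
                        "confusion": clf.confusion}
print(f"case/control classification ({feats24.shape[1]} features): "
      f"{clf.summary()}")

# --- group differences -----------------------------------------------------
means = pf.extract_mean_features(x1, x2, masks)
stats_tab = pf.group_difference(means, labels)
pio.write_table(stats_tab, OUT / "group_differences.tsv")
n_sig = int((stats_tab[stats_tab["test"] == "t"]["p_fdr"] < 0.05).sum())
print(f"group differences: {n_sig}/4 network means significant after FDR; "
      "case means are lower on every network")

# --- cross-cohort prediction ----------------------------------------------
fa, ya = generate_prediction_cohort(100, true_r2=0.25, seed=SEED)
fb, yb = generate_prediction_cohort(150, true_r2=0.25, seed=SEED + 1)
model = pf.fit_prediction_model(fa, ya)
_, res = pf.apply_prediction_model(model, fb, yb)
report["prediction"] = {"train_n": 100, "transfer_n": 150,
                        "transfer_r": res["r"], "transfer_p": res["p"],
                        "coefficients": model.coefficients.to_dict()}
print(f"transfer prediction (true R^2 = 0.25): r = {res['r']:.3f} "
      f"on the independent cohort (analytic expectation 0.50)")

# --- power table -----------------------------------------------------------
rows = []
for r, n in ((0.074, 22_459), (0.074, 500), (0.3, 500), (0.3, 100)):
    rows.append({"r": r, "n": n, "power": pf.power_pearson(r, n, 0.05)})
power_tab = pd.DataFrame(rows)
pio.write_table(power_tab.set_index(["r", "n"]), OUT / "power.tsv")
report["power_r0074_n22459"] = power_tab.iloc[0]["power"]
print(power_tab.to_string(index=False))
print("a correlation of 0.074 is underpowered at desk-scale n but has "
      "power ~1 at population scale")

(OUT / "validation_report.json").write_text(json.dumps(report, indent=2))
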