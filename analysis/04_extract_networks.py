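#!/usr/bin/env python
"""Positive/negative networks and per-subject features.

Splits the selected component's Z-maps by sign into four networks
(fALFF positive/negative, GMV positive/negative), extracts each
subject's network means — the four regressors of the prediction model —
and the extended mean + 5-PC feature set used for classification.
"""

from pathlib import Path

import prsfusion as pf
from prsfusion import io as pio
from prsfusion.containers import ZMap

BASE = Path(__file__).resolve().parent.parent
STUDY = BASE / "scratch" / "study"
FUSION = BASE / "results" / "fusion"
SCRATCH = BASE / "scratch" / "networks"
OUT = BASE / "results" / "networks"

x1 = pio.read_modality_matrix(STUDY / "fALFF.tsv", modality_tag="fALFF")
x2 = pio.read_modality_matrix(STUDY / "GMV.tsv", modality_tag="GMV")

zmaps = {}
for tag in ("fALFF", "GMV"):
    df = pio.read_table(FUSION / f"zmap_{tag}.tsv")
    zmaps[tag] = ZMap(df["z"].to_numpy(), list(df.index), tag)

masks = pf.derive_network_masks(zmaps)
counts = masks.counts()
pio.write_table(counts.set_index("modality"), OUT / "mask_counts.tsv")
print(counts.to_string(index=False))

means = pf.extract_mean_features(x1, x2, masks)
pio.write_table(means, SCRATCH / "mean_features.tsv")

full = pf.extract_pc_features(x1, x2, masks, n_pc=5)
pio.write_table(full, SCRATCH / "mean_plus_pc_features.tsv")

print(f"wrote {means.shape[1]}-column mean features and "
      f"{full.shape[1]}-column extended features for {len(means)} subjects")
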