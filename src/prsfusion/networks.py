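"""Positive/negative network masks and per-subject feature extraction.

The selected joint component's Z-scored spatial map is split by sign into
a positive network (Z > 0) and a negative network (Z < 0) per modality —
four networks in total. Each network yields one mean feature per subject
(the Eq.-style regressors fALFF_positive, fALFF_negative, GMV_positive,
GMV_negative); optionally the first 5 principal-component scores per
network are appended, giving 24 features for classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .containers import ModalityMatrix, ZMap
from .errors import ConfigurationError, DataError, DegenerateMapError

__all__ = [
    "NetworkMasks",
    "derive_network_masks",
    "extract_mean_features",
    "PcFeatureExtractor",
    "extract_pc_features",
    "MEAN_FEATURE_ORDER",
]

MEAN_FEATURE_ORDER = ("fALFF_positive", "fALFF_negative", "GMV_positive", "GMV_negative")


@dataclass
class NetworkMasks:
    """Per-modality positive/negative voxel index sets (0-based column
    indices into the modality matrix, tied to ``voxel_ids`` order)."""

    positive: Dict[str, np.ndarray]
    negative: Dict[str, np.ndarray]
    voxel_ids: Dict[str, list]

    def counts(self) -> pd.DataFrame:
        rows = [
            {"modality": t, "positive": len(self.positive[t]),
             "negative": len(self.negative[t])}
            for t in self.positive
        ]
        return pd.DataFrame(rows)


def derive_network_masks(zmaps: Dict[str, ZMap]) -> NetworkMasks:
    """Strict sign partition of each modality's Z-map.

    Voxels with Z exactly 0 belong to neither network. A map whose
    positive or negative side is empty is degenerate and rejected.
    """
    positive, negative, voxel_ids = {}, {}, {}
    for tag, zmap in zmaps.items():
        z = np.asarray(zmap.values, float)
        pos = np.flatnonzero(z > 0)
        neg = np.flatnonzero(z < 0)
        if len(pos) == 0 or len(neg) == 0:
            raise DegenerateMapError(
                f"modality {tag}: Z-map has no {'positive' if len(pos) == 0 else 'negative'} voxels"
            )
        positive[tag], negative[tag] = pos, neg
        voxel_ids[tag] = list(zmap.voxel_ids)
    return NetworkMasks(positive=positive, negative=negative, voxel_ids=voxel_ids)


def _resolve(x: ModalityMatrix, masks: NetworkMasks, tag: str) -> None:
    if tag not in masks.positive:
        raise DataError(f"masks carry no modality '{tag}'")
    ref_ids = masks.voxel_ids[tag]
    if list(x.voxel_ids) != list(ref_ids):
        # transfer by id where possible
        missing = set(ref_ids) - set(x.voxel_ids)
        if missing:
            raise DataError(
                f"modality {tag}: {len(missing)} mask voxels unresolvable in target matrix"
            )


def _mask_columns(x: ModalityMatrix, masks: NetworkMasks, tag: str, idx: np.ndarray):
    if list(x.voxel_ids) == list(masks.voxel_ids[tag]):
        return x.values[:, idx]
    pos_map = {vid: j for j, vid in enumerate(x.voxel_ids)}
    cols = [pos_map[masks.voxel_ids[tag][i]] for i in idx]
    return x.values[:, cols]


def extract_mean_features(
    x1: ModalityMatrix, x2: ModalityMatrix, masks: NetworkMasks
) -> pd.DataFrame:
    """Per-subject mean within each of the four network masks.

    Masks transfer verbatim to any cohort whose matrices share the
    discovery voxel ids (matched by id, not position).
    """
    if x1.subjects != x2.subjects:
        raise DataError("modality matrices have mismatched subjects")
    out = {}
    for x in (x1, x2):
        _resolve(x, masks, x.modality_tag)
        for sign, idx in (("positive", masks.positive[x.modality_tag]),
                          ("negative", masks.negative[x.modality_tag])):
            col = f"{x.modality_tag}_{sign}"
            out[col] = _mask_columns(x, masks, x.modality_tag, idx).mean(axis=1)
    return pd.DataFrame(out, index=x1.subjects)


class PcFeatureExtractor:
    """Train-once principal-component features per network.

    For each of the four networks the PCA basis (and centering) is fitted
    on the training cohort's masked submatrix only, then applied unchanged
    to any other cohort — no information leaks from test cohorts into the
    basis.
    """

    def __init__(self, masks: NetworkMasks, n_pc: int = 5):
        if n_pc < 1:
            raise ConfigurationError("n_pc must be >= 1")
        self.masks = masks
        self.n_pc = n_pc
        self._bases: Optional[dict] = None

    def fit(self, x1: ModalityMatrix, x2: ModalityMatrix) -> "PcFeatureExtractor":
        self._bases = {}
        for x in (x1, x2):
            _resolve(x, self.masks, x.modality_tag)
            for sign in ("positive", "negative"):
                idx = getattr(self.masks, sign)[x.modality_tag]
                if len(idx) < self.n_pc:
                    raise DataError(
                        f"network {x.modality_tag}_{sign} has {len(idx)} voxels "
                        f"< n_pc = {self.n_pc}"
                    )
                sub = _mask_columns(x, self.masks, x.modality_tag, idx)
                mean = sub.mean(axis=0)
                _, _, vt = np.linalg.svd(sub - mean, full_matrices=False)
                self._bases[f"{x.modality_tag}_{sign}"] = (mean, vt[: self.n_pc])
        return self

    def transform(self, x1: ModalityMatrix, x2: ModalityMatrix) -> pd.DataFrame:
        if self._bases is None:
            raise DataError("PcFeatureExtractor must be fitted before transform")
        cols = {}
        for x in (x1, x2):
            for sign in ("positive", "negative"):
                net = f"{x.modality_tag}_{sign}"
                mean, basis = self._bases[net]
                idx = getattr(self.masks, sign)[x.modality_tag]
                sub = _mask_columns(x, self.masks, x.modality_tag, idx)
                scores = (sub - mean) @ basis.T
                for j in range(self.n_pc):
                    cols[f"{net}_pc{j + 1}"] = scores[:, j]
        return pd.DataFrame(cols, index=x1.subjects)


def extract_pc_features(
    x1: ModalityMatrix,
    x2: ModalityMatrix,
    masks: NetworkMasks,
    n_pc: int = 5,
    extractor: Optional[PcFeatureExtractor] = None,
) -> pd.DataFrame:
    """Mean + first ``n_pc`` PC scores per network (4*(1+n_pc) columns).

    Pass a fitted ``extractor`` to apply a training cohort's PCA bases to
    a new cohort; otherwise the bases are fitted on the given data.
    """
    means = extract_mean_features(x1, x2, masks)
    if extractor is None:
        extractor = PcFeatureExtractor(masks, n_pc=n_pc).fit(x1, x2)
    pcs = extractor.transform(x1, x2)
    return pd.concat([means, pcs], axis=1)
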