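"""Cross-cohort projection, spatial similarity, and the null-pattern test.

A pattern discovered in one cohort is carried to another in two ways: its
spatial maps are linearly projected onto the new cohort's data to estimate
subject loadings (least squares), and its network masks transfer verbatim
for feature extraction. Spatial agreement between two patterns is
quantified both as the Pearson correlation of unthresholded Z-maps and as
the Dice overlap of |Z| > threshold masks (sign-matched first). The
null-pattern permutation test reruns the whole supervised fusion with a
permuted reference to show that the discovered pattern is specific to the
reference rather than generic covariance structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from ._linalg import pearson_fisher
from .containers import ModalityMatrix, PrsVector, ZMap
from .errors import ConfigurationError, DataError
from .fusion import FusionConfig, fuse_with_reference, select_component, zscore_map

__all__ = [
    "project_maps",
    "SimilarityReport",
    "spatial_similarity",
    "NullPatternResult",
    "null_pattern_test",
]

logger = logging.getLogger(__name__)


def project_maps(
    x_new: ModalityMatrix,
    maps: np.ndarray,
    reference=None,
):
    """Least-squares loading estimate for a new cohort: X_new_c @ pinv(maps).

    ``maps`` is the discovery cohort's M x voxels source matrix for this
    modality; voxel spaces must align. Returns ``(loadings, ref_stats)``
    where ``ref_stats`` is a list of (r, p) per component against the
    supplied reference (empty when no reference given).
    """
    maps = np.asarray(maps, float)
    if maps.ndim != 2:
        raise DataError("maps must be M x voxels")
    if maps.shape[1] != x_new.n_voxels:
        raise DataError(
            f"voxel mismatch: maps have {maps.shape[1]}, cohort has {x_new.n_voxels}"
        )
    xc = x_new.values - x_new.values.mean(axis=0)
    loadings = xc @ np.linalg.pinv(maps)
    ref_stats = []
    if reference is not None:
        refv = (
            reference.reindex(x_new.subjects).values()
            if isinstance(reference, PrsVector)
            else np.asarray(reference, float)
        )
        for comp in range(loadings.shape[1]):
            ref_stats.append(pearson_fisher(loadings[:, comp], refv))
    return loadings, ref_stats


@dataclass
class SimilarityReport:
    """Pearson r of Z-maps plus Dice overlap of supra-threshold masks."""

    pearson_r: float
    dice: Optional[float]  # None when a supra-threshold mask is empty
    threshold: float
    sign_flipped: bool

    def as_dict(self):
        return {
            "pearson_r": self.pearson_r,
            "dice": self.dice,
            "threshold": self.threshold,
            "sign_flipped": self.sign_flipped,
        }


def spatial_similarity(map_a, map_b, threshold: float = 2.0) -> SimilarityReport:
    """Compare two spatial maps over the same voxel space.

    Pearson r is computed on the raw (unflipped) values. For Dice, map_b
    is sign-flipped first if r < 0, then Dice = 2|A∩B| / (|A|+|B|) over
    the |Z| > threshold voxel sets with matching signs (a supra-threshold
    voxel counts as shared only if its sign agrees after matching).
    """
    a = np.asarray(map_a.values if isinstance(map_a, ZMap) else map_a, float).ravel()
    b = np.asarray(map_b.values if isinstance(map_b, ZMap) else map_b, float).ravel()
    if a.shape != b.shape:
        raise DataError("maps live in different voxel spaces")
    if a.std() == 0 or b.std() == 0:
        raise DataError("zero-variance map in similarity computation")
    r = float(np.corrcoef(a, b)[0, 1])
    b_m = -b if r < 0 else b
    sup_a = np.abs(a) > threshold
    sup_b = np.abs(b_m) > threshold
    denom = int(sup_a.sum() + sup_b.sum())
    if denom == 0:
        dice = None
    else:
        shared = int(np.sum(sup_a & sup_b & (np.sign(a) == np.sign(b_m))))
        dice = 2.0 * shared / denom
    return SimilarityReport(pearson_r=r, dice=dice, threshold=threshold,
                            sign_flipped=bool(r < 0))


def _top_component(decomp) -> int:
    """Component with the largest worst-modality |loading-reference r|,
    regardless of significance (used for null patterns, which rarely pass
    the FDR gate)."""
    rc = decomp.ref_correlations
    min_abs = rc.groupby("component")["r"].apply(lambda s: s.abs().min())
    return int(min_abs.idxmax())


@dataclass
class NullPatternResult:
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    null_similarities: list  # per permutation: modality tag -> SimilarityReport
    n_failed: int
    observed_zmaps: Dict[str, ZMap]


def null_pattern_test(
    x1: ModalityMatrix,
    x2: ModalityMatrix,
    reference: PrsVector,
    config: FusionConfig = FusionConfig(),
    n_perm: int = 49,
    seed: int = 0,
) -> NullPatternResult:
    """Permutation test of reference specificity.

    The test statistic is the strength of the reference association of
    the decomposition's top component — the smaller across modalities of
    |corr(loading, reference)| — which is exchangeable under permutation
    of the reference. For each of ``n_perm`` permutations the full fusion
    is rerun (same configuration and seed) with a permuted reference and
    the statistic recomputed; the empirical p-value uses the add-one
    convention p = (1 + #{null >= observed}) / (n_perm + 1).

    The spatial similarity of each null pattern to the observed pattern
    is also reported (these are typically low: a permuted reference pulls
    out a different, non-specific component).
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    refv = reference.reindex(x1.subjects) if isinstance(reference, PrsVector) else reference

    observed = select_component(fuse_with_reference(x1, x2, refv, config))
    obs_comp = observed.selected if observed.selected is not None else _top_component(observed)
    rc = observed.ref_correlations
    obs_stat = float(rc[rc["component"] == obs_comp]["r"].abs().min())
    obs_zmaps = zscore_map(observed, obs_comp)

    rng = np.random.default_rng([int(seed) % (2**31), 211])
    ref_arr = refv.values() if isinstance(refv, PrsVector) else np.asarray(refv, float)
    null_stats, null_sims = [], []
    n_failed = 0
    import warnings as _warnings

    for it in range(n_perm):
        perm = rng.permutation(ref_arr)
        try:
            with _warnings.catch_warnings():
                # stalled-convergence warnings are expected under permutation
                _warnings.simplefilter("ignore", UserWarning)
                d = fuse_with_reference(x1, x2, perm, config)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("permutation %d failed: %s", it, exc)
            n_failed += 1
            continue
        comp = _top_component(d)
        rcn = d.ref_correlations
        null_stats.append(float(rcn[rcn["component"] == comp]["r"].abs().min()))
        zn = zscore_map(d, comp)
        null_sims.append(
            {t: spatial_similarity(obs_zmaps[t], zn[t]) for t in d.modalities}
        )
    null_stats = np.asarray(null_stats)
    n_eff = len(null_stats)
    if n_eff == 0:
        raise DataError("all permutations failed")
    p = (1.0 + float(np.sum(null_stats >= obs_stat))) / (n_eff + 1.0)
    return NullPatternResult(
        observed_stat=obs_stat,
        null_stats=null_stats,
        p_value=p,
        null_similarities=null_sims,
        n_failed=n_failed,
        observed_zmaps=obs_zmaps,
    )
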