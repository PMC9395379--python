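"""Shared in-memory containers for the fusion pipeline.

The pipeline passes around three recurring objects: a subjects-by-voxels
feature matrix for one imaging modality (:class:`ModalityMatrix`), a
per-subject polygenic score vector (:class:`PrsVector`), and the result of
the supervised joint decomposition (:class:`JointDecomposition`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class ModalityMatrix:
    """Subjects x voxels feature matrix for one imaging modality.

    Parameters
    ----------
    values
        2-D float array, one row per subject, one column per voxel/feature.
    subjects
        Ordered subject identifiers (row labels).
    voxel_ids
        Ordered voxel identifiers (column labels). For NIfTI-backed data
        these encode flattened in-mask coordinates in mask-scan order.
    modality_tag
        Short label such as ``"fALFF"`` or ``"GMV"``; used as the prefix of
        derived feature names.
    """

    values: np.ndarray
    subjects: list
    voxel_ids: list
    modality_tag: str = "modality"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.subjects = list(self.subjects)
        self.voxel_ids = list(self.voxel_ids)
        if self.values.ndim != 2:
            raise DataError("modality values must be a 2-D matrix")
        if self.values.shape[0] != len(self.subjects):
            raise DataError(
                f"{len(self.subjects)} subjects but {self.values.shape[0]} rows"
            )
        if self.values.shape[1] != len(self.voxel_ids):
            raise DataError(
                f"{len(self.voxel_ids)} voxel ids but {self.values.shape[1]} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("modality matrix contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subjects, columns=self.voxel_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality_tag: str = "modality"):
        return cls(
            values=df.to_numpy(dtype=float),
            subjects=list(df.index),
            voxel_ids=list(df.columns),
            modality_tag=modality_tag,
        )

    def copy(self) -> "ModalityMatrix":
        return ModalityMatrix(
            self.values.copy(), list(self.subjects), list(self.voxel_ids),
            self.modality_tag,
        )


@dataclass
class PrsVector:
    """Per-subject polygenic risk score with its construction parameters."""

    scores: pd.Series  # index: subject_id, values: float
    n_snps_used: int
    config: Optional[object] = None  # PrsConfig; kept loose to avoid cycles

    def __post_init__(self):
        self.scores = pd.Series(self.scores, dtype=float)
        if self.scores.index.has_duplicates:
            raise DataError("duplicate subject ids in PRS vector")

    @property
    def subjects(self) -> list:
        return list(self.scores.index)

    def values(self) -> np.ndarray:
        return self.scores.to_numpy()

    def reindex(self, subjects: Sequence) -> "PrsVector":
        sub = self.scores.reindex(list(subjects))
        if sub.isna().any():
            missing = sub.index[sub.isna()].tolist()
            raise DataError(f"PRS missing for subjects: {missing[:5]}")
        return PrsVector(sub, self.n_snps_used, self.config)


@dataclass
class ZMap:
    """Z-scored spatial map for one modality (zero mean, unit SD in-mask)."""

    values: np.ndarray
    voxel_ids: list
    modality_tag: str
    display_threshold: float = 2.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.voxel_ids):
            raise DataError("Z-map length does not match voxel ids")


@dataclass
class JointDecomposition:
    """Output of the reference-guided two-modality decomposition.

    ``loadings[k]`` is the subjects x M mixing matrix for modality k (the
    A_k whose columns are correlated with the reference), ``maps[k]`` the
    M x voxels spatial sources, ``unmixing`` the M x M ICA unmixing applied
    to the concatenated canonical maps, and ``ref_correlations`` a DataFrame
    with one row per (modality, component) holding r and its p-value.
    """

    modalities: list
    loadings: dict          # tag -> (n_subjects, M)
    maps: dict              # tag -> (M, V_k)
    voxel_ids: dict         # tag -> list
    unmixing: np.ndarray    # (M, M)
    ref_correlations: pd.DataFrame
    subjects: list
    objective_trace: list = field(default_factory=list)
    converged: bool = True
    ica_stability: float = float("nan")
    selected: Optional[int] = None
    selection_stats: Optional[pd.DataFrame] = None

    @property
    def n_components(self) -> int:
        return next(iter(self.loadings.values())).shape[1]
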