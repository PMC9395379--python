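"""Readers and writers for the pipeline's on-disk formats.

Tabular data is tab-delimited UTF-8 with a mandatory header row and '.'
for missing values. Genomic positions are 1-based (VCF convention); voxel
indices are 0-based in flattened mask-scan (C-order) order — NIfTI-backed
matrices record the in-mask linear index of each voxel as its column id.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import ModalityMatrix, PrsVector
from .errors import ConfigurationError, DataError

__all__ = [
    "read_table",
    "write_table",
    "read_modality_matrix",
    "write_modality_matrix",
    "read_nifti_modality",
    "read_covariates",
    "read_weights",
    "read_dosages",
    "read_vcf_dosages",
    "write_prs",
    "read_prs",
    "load_config",
    "file_sha256",
]

_NA = "."


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[_NA], index_col=0)


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep=_NA)
    return path


def read_modality_matrix(
    path,
    modality_tag: str = "modality",
    nifti_paths: Optional[Sequence] = None,
    mask_path=None,
) -> ModalityMatrix:
    """Load a subjects x voxels matrix from TSV, or from NIfTI volumes.

    TSV: first column = subject id, header row = voxel ids. NIfTI: pass
    ``nifti_paths`` (one volume per subject; subject ids are the file
    stems) and a binary ``mask_path``; in-mask voxels are flattened in
    C order and column ids are ``vox<linear_index>``.
    """
    if nifti_paths is not None:
        return read_nifti_modality(nifti_paths, mask_path, modality_tag)
    df = read_table(path)
    if df.isna().any().any():
        raise DataError(f"{path}: modality matrix contains missing values")
    if df.index.has_duplicates:
        raise DataError(f"{path}: duplicate subject ids")
    return ModalityMatrix.from_frame(df, modality_tag=modality_tag)


def write_modality_matrix(x: ModalityMatrix, path) -> Path:
    return write_table(x.to_frame(), path)


def read_nifti_modality(nifti_paths: Sequence, mask_path, modality_tag: str) -> ModalityMatrix:
    import nibabel as nib

    if mask_path is None:
        raise ConfigurationError("NIfTI input requires a mask")
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj)
    uniq = np.unique(mask[np.isfinite(mask)])
    if not set(uniq.tolist()) <= {0.0, 1.0}:
        raise DataError(f"mask is not binary (values {uniq[:5]})")
    flat_idx = np.flatnonzero(mask.ravel(order="C") > 0)
    rows, subjects = [], []
    for p in nifti_paths:
        img = nib.load(str(p))
        vol = np.asarray(img.dataobj, dtype=float)
        if vol.shape != mask.shape:
            raise DataError(f"{p}: volume shape {vol.shape} != mask shape {mask.shape}")
        rows.append(vol.ravel(order="C")[flat_idx])
        subjects.append(Path(p).name.split(".")[0])
    return ModalityMatrix(
        np.vstack(rows), subjects, [f"vox{i}" for i in flat_idx], modality_tag
    )


def read_covariates(path) -> pd.DataFrame:
    df = read_table(path)
    if df.index.has_duplicates:
        raise DataError(f"{path}: duplicate subject ids in covariates")
    return df


def read_weights(path) -> pd.DataFrame:
    from .prs import validate_weights

    df = pd.read_csv(path, sep="\t", na_values=[_NA])
    return validate_weights(df)


def read_dosages(path) -> pd.DataFrame:
    return read_table(path)


def read_vcf_dosages(path, field: str = "DS") -> tuple:
    """Dosages from a VCF: the DS FORMAT field when present, else the
    genotype allele count. Returns ``(dosages, counted_alleles)`` where
    dosages count ALT alleles and counted_alleles maps snp_id -> (ALT, REF).
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF input") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids, counted = [], [], {}
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        try:
            ds = np.asarray(var.format(field), float).ravel()
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(var.genotype.array())[:, :2]
            ds = np.where((gt < 0).any(axis=1), np.nan, (gt > 0).sum(axis=1)).astype(float)
        cols.append(ds)
        ids.append(vid)
        counted[vid] = (var.ALT[0] if var.ALT else ".", var.REF)
    dosages = pd.DataFrame(np.column_stack(cols), index=samples, columns=ids)
    return dosages, counted


def write_prs(prs: PrsVector, path) -> Path:
    df = pd.DataFrame(
        {"score": prs.scores, "n_snps_used": prs.n_snps_used}
    )
    df.index.name = "subject_id"
    return write_table(df, path)


def read_prs(path) -> PrsVector:
    df = read_table(path)
    return PrsVector(scores=df["score"], n_snps_used=int(df["n_snps_used"].iloc[0]))


def load_config(path) -> dict:
    """Parse and minimally validate a pipeline YAML configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError("pipeline config must be a mapping")
    if "seed" not in cfg:
        raise ConfigurationError("config must set a top-level 'seed'")
    if "out_dir" not in cfg:
        raise ConfigurationError("config must set 'out_dir'")
    return cfg


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
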