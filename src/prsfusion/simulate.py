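"""Synthetic imaging-genetics cohorts with planted ground truth.

Every downstream stage of the pipeline (polygenic scoring, covariate
regression, reference-guided fusion, network feature extraction,
classification and prediction) is exercised on data produced here, so the
generator controls all the structure those stages are supposed to recover:

* genotypes are organized in linkage-disequilibrium (LD) blocks via a
  latent Gaussian copula, so clump-based pruning has real work to do;
* GWAS-style weights (ln odds ratios) are planted on a subset of "risk"
  SNPs, with p-values consistent with the weight magnitudes;
* the two modality matrices share a joint spatial source whose subject
  loadings correlate with the polygenic score at an exactly controlled
  target level, on top of super-Gaussian (Laplace) nuisance sources,
  covariate confound effects, and Gaussian noise.

All randomness derives from ``SimConfig.seed``; identical configurations
produce bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import standardize_vector
from .containers import ModalityMatrix, PrsVector
from .errors import ConfigurationError, DataError

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_genotypes",
    "generate_covariates",
    "generate_fusion_cohort",
    "generate_case_control",
    "generate_prediction_cohort",
    "simulate_study",
]

# distinct sub-stream keys so stages never share a bit generator
_STREAM_GENO = 11
_STREAM_COHORT = 23
_STREAM_CASECTRL = 37


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Attributes
    ----------
    n_subjects, n_snps, ld_block_size
        Cohort size, SNP panel size, and the number of consecutive SNPs
        sharing a latent LD block (1 = independent SNPs).
    maf_range
        Minor-allele-frequency range, uniform per SNP, in (0, 0.5].
    n_voxels_per_modality
        (V1, V2) voxel counts for the fALFF-like and GMV-like matrices.
    n_sources
        Number of joint spatial sources mixed into each modality.
    target_ref_correlation
        Planted Pearson correlation between the reference (PRS) and the
        subject loadings of source 0, imposed exactly in-sample.
    noise_sd
        SD of the additive Gaussian voxel noise (each source contributes
        unit variance per voxel, so noise_sd=1 with 5 sources is a 5:1
        signal-to-noise variance ratio).
    confound_effect_sizes
        Covariate name -> effect SD per voxel; effects are linear in the
        (standardized or indicator-coded) covariate so that ordinary
        least-squares regression removes them exactly.
    ld_rho
        Within-block latent correlation of the genotype copula.
    risk_snp_fraction
        Fraction of SNPs given a nonzero ln-odds-ratio weight.
    """

    n_subjects: int = 500
    n_snps: int = 200
    ld_block_size: int = 10
    maf_range: Tuple[float, float] = (0.05, 0.5)
    n_voxels_per_modality: Tuple[int, int] = (1000, 1000)
    n_sources: int = 5
    target_ref_correlation: float = 0.3
    noise_sd: float = 1.0
    confound_effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.1, "sex": 0.1, "site": 0.15, "mean_fd": 0.1}
    )
    seed: int = 0
    ld_rho: float = 0.6
    risk_snp_fraction: float = 0.2
    n_sites: int = 3

    def validate(self) -> None:
        for name in ("n_subjects", "n_snps", "ld_block_size", "n_sources", "n_sites"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}"
            )
        if not (0.0 <= self.target_ref_correlation < 1.0):
            raise ConfigurationError("target_ref_correlation must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigurationError("ld_rho must be in [0, 1)")
        if any(int(v) < 1 for v in self.n_voxels_per_modality):
            raise ConfigurationError("voxel counts must be >= 1")
        if not (0.0 < self.risk_snp_fraction <= 1.0):
            raise ConfigurationError("risk_snp_fraction must be in (0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclass
class GroundTruth:
    """Planted quantities a successful analysis should recover."""

    true_sources: dict            # modality tag -> (n_sources, V_k)
    true_loadings: np.ndarray     # (n_subjects, n_sources)
    planted_ref_index: int
    true_weights: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# genotypes + GWAS weights
# ---------------------------------------------------------------------------

def _haplotypes(rng, n, mafs, block_size, rho):
    """One haplotype per subject: latent Gaussian with block-constant
    correlation rho, thresholded at the per-SNP allele-frequency quantile."""
    p = len(mafs)
    eps = rng.standard_normal((n, p))
    if rho > 0 and block_size > 1:
        n_blocks = int(np.ceil(p / block_size))
        shared = rng.standard_normal((n, n_blocks))
        shared_full = np.repeat(shared, block_size, axis=1)[:, :p]
        latent = np.sqrt(rho) * shared_full + np.sqrt(1.0 - rho) * eps
    else:
        latent = eps
    return (latent < stats.norm.ppf(mafs)[None, :]).astype(np.int8)


def generate_genotypes(config: SimConfig):
    """Simulate LD-blocked dosages and a matching GWAS weights table.

    Returns
    -------
    dosages : pandas.DataFrame
        subjects x SNPs, values in {0, 1, 2} (counts of the effect allele).
    weights : pandas.DataFrame
        columns snp_id, chromosome, position, effect_allele, other_allele,
        weight (ln OR; zero for non-risk SNPs), p_value. Within-block SNP
        spacing is 5 kb and blocks are separated by 1 Mb, so the default
        200-kb clump window spans a block but never two.
    """
    config.validate()
    rng = config.rng(_STREAM_GENO)
    p = config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)

    h1 = _haplotypes(rng, config.n_subjects, mafs, config.ld_block_size, config.ld_rho)
    h2 = _haplotypes(rng, config.n_subjects, mafs, config.ld_block_size, config.ld_rho)
    dos = (h1 + h2).astype(float)

    snp_ids = [f"rs{i + 1:06d}" for i in range(p)]
    block_idx = np.arange(p) // config.ld_block_size
    within_idx = np.arange(p) % config.ld_block_size
    positions = 1 + block_idx * 1_000_000 + within_idx * 5_000

    n_risk = max(1, int(round(config.risk_snp_fraction * p)))
    risk = rng.choice(p, size=n_risk, replace=False)
    beta = np.zeros(p)
    beta[risk] = rng.normal(0.0, 0.15, size=n_risk)
    # association z-scores: beta/SE for risk SNPs, standard normal for nulls
    se = 0.02
    z = rng.standard_normal(p)
    z[risk] = beta[risk] / se
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)

    weights = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": "1",
            "position": positions.astype(int),
            "effect_allele": "A",
            "other_allele": "G",
            "weight": beta,
            "p_value": pvals,
        }
    )
    subjects = [f"subj{i + 1:05d}" for i in range(config.n_subjects)]
    dosages = pd.DataFrame(dos, index=subjects, columns=snp_ids)
    return dosages, weights


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def generate_covariates(config: SimConfig, rng=None) -> pd.DataFrame:
    """Age/sex/site/motion table with one row per subject."""
    if rng is None:
        rng = config.rng(_STREAM_COHORT + 1)
    n = config.n_subjects
    return pd.DataFrame(
        {
            "subject_id": [f"subj{i + 1:05d}" for i in range(n)],
            "age": np.clip(rng.normal(45.0, 15.0, n), 18.0, 85.0),
            "sex": rng.integers(0, 2, n),
            "site": np.array([f"site{s + 1}" for s in rng.integers(0, config.n_sites, n)]),
            "mean_fd": rng.gamma(4.0, 0.05, n),
            "max_translation": rng.gamma(2.0, 0.3, n),
            "max_rotation": rng.gamma(2.0, 0.25, n),
        }
    ).set_index("subject_id")


def _confound_design(covs: pd.DataFrame, effect_sizes: Mapping[str, float], rng):
    """Columns (standardized numeric or site indicators) and their SDs."""
    cols = []
    for name, gamma in effect_sizes.items():
        if gamma == 0:
            continue
        if name == "site":
            levels = sorted(covs["site"].unique())
            for lev in levels[1:]:  # all-but-one indicator coding
                cols.append((f"site[{lev}]", gamma,
                             (covs["site"] == lev).to_numpy(float)))
        else:
            if name not in covs.columns:
                raise DataError(f"confound covariate '{name}' not in table")
            v = covs[name].to_numpy(float)
            if v.std() == 0:
                continue
            cols.append((name, gamma, standardize_vector(v)))
    return cols


# ---------------------------------------------------------------------------
# fusion cohort with planted reference-correlated source
# ---------------------------------------------------------------------------

def _planted_loading(rng, reference: np.ndarray, target_r: float) -> np.ndarray:
    """Unit-variance loading with *exact* in-sample correlation target_r
    to the reference, via Gram-Schmidt mixing with orthogonalized noise."""
    z = standardize_vector(reference)
    e = rng.standard_normal(len(z))
    e = e - (e @ z) / (z @ z) * z
    e = standardize_vector(e)
    return target_r * z + np.sqrt(1.0 - target_r**2) * e


def generate_fusion_cohort(config: SimConfig, prs: PrsVector, sources=None):
    """Two modality matrices sharing a PRS-correlated joint source.

    Each modality is built as ``loadings @ sources + confounds + noise``.
    Source maps are Laplace distributed (super-Gaussian) so the ICA stage
    is identifiable; loading column ``planted_ref_index`` (always 0) has
    exact in-sample correlation ``target_ref_correlation`` with the PRS.

    ``sources`` may carry the spatial maps of another cohort (a
    :class:`GroundTruth` or a ``{"fALFF": ..., "GMV": ...}`` dict) to
    build an independent replication cohort expressing the same sources.

    Returns ``(x1, x2, covariates, ground_truth)``.
    """
    config.validate()
    ref = prs.values() if isinstance(prs, PrsVector) else np.asarray(prs, float)
    if len(ref) != config.n_subjects:
        raise DataError(
            f"PRS length {len(ref)} != n_subjects {config.n_subjects}"
        )
    rng = config.rng(_STREAM_COHORT)
    n, S = config.n_subjects, config.n_sources
    v1, v2 = (int(v) for v in config.n_voxels_per_modality)

    loadings = rng.standard_normal((n, S))
    loadings[:, 0] = _planted_loading(rng, ref, config.target_ref_correlation)

    if sources is not None:
        src_map = sources.true_sources if isinstance(sources, GroundTruth) else sources
        src1 = np.asarray(src_map["fALFF"], float)
        src2 = np.asarray(src_map["GMV"], float)
        if src1.shape != (S, v1) or src2.shape != (S, v2):
            raise DataError("supplied sources do not match the configured dimensions")
    else:
        # unit-variance Laplace sources: scale b = 1/sqrt(2)
        src1 = rng.laplace(0.0, 1.0 / np.sqrt(2.0), (S, v1))
        src2 = rng.laplace(0.0, 1.0 / np.sqrt(2.0), (S, v2))

    x1 = loadings @ src1
    x2 = loadings @ src2

    cov_rng = config.rng(_STREAM_COHORT + 1)
    covs = generate_covariates(config, cov_rng)
    for _, gamma, col in _confound_design(covs, config.confound_effect_sizes, rng):
        x1 += gamma * np.outer(col, rng.standard_normal(v1))
        x2 += gamma * np.outer(col, rng.standard_normal(v2))

    if config.noise_sd > 0:
        x1 += config.noise_sd * rng.standard_normal((n, v1))
        x2 += config.noise_sd * rng.standard_normal((n, v2))

    subjects = list(covs.index)
    m1 = ModalityMatrix(x1, subjects, [f"v{j}" for j in range(v1)], "fALFF")
    m2 = ModalityMatrix(x2, subjects, [f"v{j}" for j in range(v2)], "GMV")
    truth = GroundTruth(
        true_sources={"fALFF": src1, "GMV": src2},
        true_loadings=loadings,
        planted_ref_index=0,
    )
    return m1, m2, covs, truth


# ---------------------------------------------------------------------------
# case/control cohort for classification and group-difference validation
# ---------------------------------------------------------------------------

def generate_case_control(config: SimConfig, effect: Mapping[str, float]):
    """Two-group cohort with network-mean features shifted in cases.

    ``effect`` maps network names (``fALFF_positive``, ``fALFF_negative``,
    ``GMV_positive``, ``GMV_negative``) to shifts expressed in SDs of the
    corresponding network-mean feature; positive shifts *lower* the case
    group (patients show reduced values in the planted networks). Networks
    are the sign partitions of source 0's spatial maps.

    Returns ``(x1, x2, labels, masks)`` where ``labels`` is a 0/1 Series
    (1 = case) and ``masks`` the ground-truth :class:`NetworkMasks`.
    """
    from .networks import NetworkMasks  # local import to avoid a cycle

    config.validate()
    for k, v in effect.items():
        if not np.isfinite(v):
            raise ConfigurationError(f"effect for {k} must be finite")
    rng = config.rng(_STREAM_CASECTRL)
    n, S = config.n_subjects, config.n_sources
    v1, v2 = (int(v) for v in config.n_voxels_per_modality)

    loadings = rng.standard_normal((n, S))
    src1 = rng.laplace(0.0, 1.0 / np.sqrt(2.0), (S, v1))
    src2 = rng.laplace(0.0, 1.0 / np.sqrt(2.0), (S, v2))
    x1 = loadings @ src1 + config.noise_sd * rng.standard_normal((n, v1))
    x2 = loadings @ src2 + config.noise_sd * rng.standard_normal((n, v2))

    subjects = [f"subj{i + 1:05d}" for i in range(n)]
    labels = pd.Series(rng.permutation(np.arange(n) % 2), index=subjects, name="label")

    masks = NetworkMasks(
        positive={"fALFF": np.flatnonzero(src1[0] > 0),
                  "GMV": np.flatnonzero(src2[0] > 0)},
        negative={"fALFF": np.flatnonzero(src1[0] < 0),
                  "GMV": np.flatnonzero(src2[0] < 0)},
        voxel_ids={"fALFF": [f"v{j}" for j in range(v1)],
                   "GMV": [f"v{j}" for j in range(v2)]},
    )

    mats = {"fALFF": x1, "GMV": x2}
    case = labels.to_numpy() == 1
    for net, shift in effect.items():
        if shift == 0:
            continue
        tag, sign = net.rsplit("_", 1)
        idx = masks.positive[tag] if sign == "positive" else masks.negative[tag]
        feat = mats[tag][:, idx].mean(axis=1)
        mats[tag][np.ix_(case, idx)] -= float(shift) * feat.std(ddof=1)

    m1 = ModalityMatrix(mats["fALFF"], subjects, masks.voxel_ids["fALFF"], "fALFF")
    m2 = ModalityMatrix(mats["GMV"], subjects, masks.voxel_ids["GMV"], "GMV")
    return m1, m2, labels, masks


def generate_prediction_cohort(n_subjects: int, true_r2: float, seed: int):
    """Network-mean feature table plus a target with planted linear signal.

    Features are iid standard normal; the target is a fixed linear
    combination carrying exactly ``true_r2`` of the target variance
    (population value), the rest Gaussian noise. The expected
    out-of-sample correlation between predictions of a correctly
    specified linear model and the target is sqrt(true_r2).
    """
    if not (0.0 <= true_r2 < 1.0):
        raise ConfigurationError("true_r2 must be in [0, 1)")
    rng = np.random.default_rng([int(seed) % (2**31), 53])
    cols = ["fALFF_positive", "fALFF_negative", "GMV_positive", "GMV_negative"]
    idx = [f"subj{i + 1:05d}" for i in range(n_subjects)]
    f = pd.DataFrame(rng.standard_normal((n_subjects, 4)), index=idx, columns=cols)
    beta = np.sqrt(true_r2) / 2.0 * np.array([1.0, -1.0, 1.0, -1.0])
    y = f.to_numpy() @ beta + np.sqrt(1.0 - true_r2) * rng.standard_normal(n_subjects)
    return f, pd.Series(y, index=idx, name="score")


# ---------------------------------------------------------------------------
# one-call study: genotypes -> PRS -> imaging cohort
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig, prs_config=None):
    """Full synthetic study: genotypes, weights, PRS, and imaging cohort.

    The PRS is computed from the simulated genotypes with the standard
    QC -> clump -> threshold -> score pipeline, then used as the planted
    reference of the fusion cohort. Returns a dict with keys ``dosages``,
    ``weights``, ``prs``, ``x1``, ``x2``, ``covariates``, ``truth``.
    """
    from .prs import PrsConfig, compute_prs

    dosages, weights = generate_genotypes(config)
    if prs_config is None:
        # the simulated weight scale puts risk-SNP p-values across many
        # orders of magnitude; a mid-range threshold keeps most of them
        prs_config = PrsConfig(p_snp_threshold=1e-4)
    prs = compute_prs(dosages, weights, prs_config)
    x1, x2, covs, truth = generate_fusion_cohort(config, prs.reindex(dosages.index))
    return {
        "dosages": dosages,
        "weights": weights,
        "prs": prs,
        "x1": x1,
        "x2": x2,
        "covariates": covs,
        "truth": truth,
    }
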