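"""Polygenic risk score construction.

The score for subject *i* is the weighted allele-dosage sum

    PRS_i = sum_j d_ij * beta_j

over SNPs that survive quality control, clump-based linkage-disequilibrium
pruning, and a GWAS p-value threshold, with beta_j the natural log of the
per-allele odds ratio. Defaults follow common practice for schizophrenia
scores: P_SNP <= 5e-8, r^2 < 0.1 within a 200-kb clump window, QC at
missing rate 0.05 / MAF 0.01 / Hardy-Weinberg p 1e-6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PrsVector
from .errors import AlleleMismatchError, ConfigurationError, DataError

__all__ = [
    "PrsConfig",
    "qc_filter",
    "SampleLd",
    "clump",
    "score",
    "compute_prs",
    "validate_weights",
]

WEIGHT_COLUMNS = ("snp_id", "chromosome", "position", "effect_allele", "weight", "p_value")
_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass(frozen=True)
class PrsConfig:
    """Thresholds for PRS construction.

    ``p_snp_threshold`` is the GWAS significance cutoff (genome-wide 5e-8
    by default; 1e-4 and 0.05 are the usual relaxed alternates), and
    ``r2_threshold``/``clump_window`` control greedy LD pruning.
    """

    p_snp_threshold: float = 5.0e-8
    r2_threshold: float = 0.1
    clump_window: int = 200_000
    max_missing_rate: float = 0.05
    min_maf: float = 0.01
    hwe_p_floor: float = 1.0e-6
    max_sample_missing_rate: float = 0.05

    def validate(self) -> None:
        if not (0.0 < self.p_snp_threshold <= 1.0):
            raise ConfigurationError("p_snp_threshold must be in (0, 1]")
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ConfigurationError("r2_threshold must be in [0, 1]")
        if self.clump_window < 0:
            raise ConfigurationError("clump_window must be nonnegative")
        for name in ("max_missing_rate", "min_maf", "max_sample_missing_rate"):
            if not (0.0 <= getattr(self, name) <= 0.5):
                raise ConfigurationError(f"{name} out of range")
        if not (0.0 <= self.hwe_p_floor <= 1.0):
            raise ConfigurationError("hwe_p_floor must be in [0, 1]")


def validate_weights(weights: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise DataError(f"weights table missing columns: {missing}")
    if weights["snp_id"].duplicated().any():
        dup = weights.loc[weights["snp_id"].duplicated(), "snp_id"].tolist()
        raise DataError(f"duplicate snp_id in weights: {dup[:5]}")
    p = weights["p_value"].to_numpy(float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DataError("p_value must lie in (0, 1]")
    if (weights["position"] < 0).any():
        raise DataError("positions must be nonnegative")
    return weights


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def _hwe_pvalue(column: np.ndarray) -> float:
    """Chi-square (1 df) Hardy-Weinberg goodness-of-fit on genotype counts."""
    g = np.round(column[~np.isnan(column)]).astype(int)
    n = len(g)
    if n == 0:
        return 1.0
    counts = np.array([(g == 0).sum(), (g == 1).sum(), (g == 2).sum()], float)
    p_hat = (2 * counts[2] + counts[1]) / (2 * n)
    if p_hat in (0.0, 1.0):
        return 1.0
    expected = n * np.array([(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(dosages: pd.DataFrame, config: PrsConfig = PrsConfig()):
    """Remove SNPs and samples failing standard genotype QC.

    SNP filters (applied in order, first failure recorded as the reason):
    missing rate > ``max_missing_rate``; minor allele frequency <
    ``min_maf``; Hardy-Weinberg chi-square p < ``hwe_p_floor``. Samples
    with genotype missing rate > ``max_sample_missing_rate`` are dropped
    first. Returns ``(filtered, report)`` with a tidy exclusion report
    (columns item, kind, reason, value).
    """
    config.validate()
    rows = []

    sample_miss = dosages.isna().mean(axis=1)
    bad_samples = sample_miss[sample_miss > config.max_sample_missing_rate]
    for sid, rate in bad_samples.items():
        rows.append((sid, "sample", "missing_rate", float(rate)))
    kept = dosages.drop(index=bad_samples.index)

    vals = kept.to_numpy(float)
    miss = np.isnan(vals).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(vals, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)

    drop = np.zeros(vals.shape[1], dtype=bool)
    for j, snp in enumerate(kept.columns):
        if miss[j] > config.max_missing_rate:
            rows.append((snp, "snp", "missing_rate", float(miss[j])))
            drop[j] = True
        elif not np.isfinite(maf[j]) or maf[j] < config.min_maf:
            rows.append((snp, "snp", "maf", float(maf[j])))
            drop[j] = True
        else:
            hwe_p = _hwe_pvalue(vals[:, j])
            if hwe_p < config.hwe_p_floor:
                rows.append((snp, "snp", "hwe", hwe_p))
                drop[j] = True

    filtered = kept.loc[:, ~drop]
    if filtered.shape[1] == 0 or filtered.shape[0] == 0:
        raise DataError("QC removed every SNP or every sample")
    report = pd.DataFrame(rows, columns=["item", "kind", "reason", "value"])
    return filtered, report


# ---------------------------------------------------------------------------
# LD and clumping
# ---------------------------------------------------------------------------

class SampleLd:
    """Pairwise r^2 estimated from the sample's own dosages.

    r^2 is the squared Pearson correlation of the two dosage columns over
    subjects with both calls present. No external reference panel is used.
    """

    def __init__(self, dosages: pd.DataFrame):
        self._dosages = dosages

    def r2(self, snp_a: str, snp_b: str) -> float:
        try:
            a = self._dosages[snp_a].to_numpy(float)
            b = self._dosages[snp_b].to_numpy(float)
        except KeyError as exc:
            raise DataError(f"no dosages for SNP {exc} — cannot compute LD") from exc
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
        if len(a) < 2 or a.std() == 0 or b.std() == 0:
            raise DataError(f"LD undefined for pair ({snp_a}, {snp_b})")
        return float(np.corrcoef(a, b)[0, 1] ** 2)


def clump(
    weights: pd.DataFrame,
    ld: "SampleLd | Callable[[str, str], float]",
    config: PrsConfig = PrsConfig(),
) -> list:
    """Greedy clump-based LD pruning; returns retained snp_ids.

    Repeatedly takes the most significant unassigned SNP as a clump index
    and discards SNPs on the same chromosome within ``clump_window`` base
    pairs whose r^2 with the index is >= ``r2_threshold``. Ties in p-value
    break by (chromosome, position) so the retained set is deterministic.
    """
    config.validate()
    validate_weights(weights)
    r2_of = ld.r2 if hasattr(ld, "r2") else ld

    order = weights.sort_values(
        ["p_value", "chromosome", "position"], kind="mergesort"
    )
    assigned: set = set()
    retained: list = []
    by_chrom = {c: g for c, g in order.groupby("chromosome", sort=False)}
    for _, row in order.iterrows():
        snp = row["snp_id"]
        if snp in assigned:
            continue
        retained.append(snp)
        assigned.add(snp)
        near = by_chrom[row["chromosome"]]
        in_window = near[
            (near["position"] - row["position"]).abs() <= config.clump_window
        ]
        for _, other in in_window.iterrows():
            o = other["snp_id"]
            if o in assigned:
                continue
            if r2_of(snp, o) >= config.r2_threshold:
                assigned.add(o)
    return retained


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _align_alleles(dosages, weights, counted_alleles):
    """Flip dosages (2 - d) where the weights' effect allele is the panel's
    other allele; drop strand-ambiguous SNPs with a warning; raise for
    unresolvable mismatches."""
    if counted_alleles is None:
        return dosages, weights
    vals = dosages.copy()
    keep, bad, ambiguous = [], [], []
    for _, row in weights.iterrows():
        snp = row["snp_id"]
        alleles = counted_alleles.get(snp)
        if alleles is None:
            keep.append(snp)
            continue
        counted, other = alleles
        eff = row["effect_allele"]
        if frozenset({counted, other}) in _AMBIGUOUS:
            ambiguous.append(snp)
        elif eff == counted:
            keep.append(snp)
        elif eff == other:
            vals[snp] = 2.0 - vals[snp]
            keep.append(snp)
        else:
            bad.append(snp)
    if bad:
        raise AlleleMismatchError(bad)
    if ambiguous:
        warnings.warn(
            f"dropping {len(ambiguous)} strand-ambiguous (A/T or C/G) SNPs",
            stacklevel=3,
        )
    return vals, weights[weights["snp_id"].isin(keep)]


def score(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    config: PrsConfig = PrsConfig(),
    counted_alleles: Optional[dict] = None,
) -> PrsVector:
    """Weighted dosage sum over the supplied (already pruned) SNP set.

    ``weights`` should contain only SNPs that passed QC, clumping and the
    p-value threshold; every weight SNP must be present in ``dosages``.
    Missing dosages are mean-imputed per SNP before summation.
    ``counted_alleles`` optionally maps snp_id -> (counted, other) allele
    of the dosage coding, enabling effect-allele alignment.
    """
    config.validate()
    validate_weights(weights)
    dosages, weights = _align_alleles(dosages, weights, counted_alleles)
    snps = [s for s in weights["snp_id"] if s in dosages.columns]
    absent = set(weights["snp_id"]) - set(snps)
    if absent:
        raise DataError(f"weights refer to SNPs absent from dosages: {sorted(absent)[:5]}")

    if snps:
        mat = dosages[snps].to_numpy(float)
        col_mean = np.nanmean(np.where(np.isnan(mat), np.nan, mat), axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        idx = np.where(np.isnan(mat))
        mat[idx] = col_mean[idx[1]]
        w = weights.set_index("snp_id").loc[snps, "weight"].to_numpy(float)
        vals = mat @ w
    else:
        vals = np.zeros(len(dosages))
    scores = pd.Series(vals, index=dosages.index, name="prs")
    return PrsVector(scores=scores, n_snps_used=len(snps), config=config)


def compute_prs(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    config: PrsConfig = PrsConfig(),
    counted_alleles: Optional[dict] = None,
) -> PrsVector:
    """Full pipeline: QC -> p-value threshold -> clump -> score."""
    validate_weights(weights)
    filtered, _ = qc_filter(dosages, config)
    avail = weights[weights["snp_id"].isin(filtered.columns)]
    sig = avail[avail["p_value"] <= config.p_snp_threshold]
    if sig.empty:
        return PrsVector(
            scores=pd.Series(0.0, index=filtered.index, name="prs"),
            n_snps_used=0,
            config=config,
        )
    retained = clump(sig, SampleLd(filtered), config)
    final = sig[sig["snp_id"].isin(retained)]
    return score(filtered, final, config, counted_alleles)
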