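"""Reference-guided supervised fusion of two modality matrices (MCCAR + jICA).

The decomposition seeks M joint components whose subject loadings are
correlated across modalities *and* with an external per-subject reference
(here a polygenic risk score). With A_k the subjects x M loading matrix of
modality k, the objective maximized is

    sum_{k,j=1..2} { ||corr(A_k, A_j)||^2 + 2*lambda * ||corr(A_k, ref)||^2 }

where corr(.,.) is taken column-wise. lambda = 0 recovers unsupervised
multiset CCA; larger lambda pulls loading columns toward the reference.
The pipeline is: per-modality PCA reduction -> reference-guided multiset
CCA (alternating exact eigenproblem updates, deflation across components)
-> back-reconstructed component maps -> one joint Infomax ICA over the
modality-concatenated maps -> final loadings A_k = canonical loadings
times the ICA mixing matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from ._linalg import orth_basis, pearson_fisher, standardize_vector
from .containers import JointDecomposition, ModalityMatrix, PrsVector, ZMap
from .errors import ConfigurationError, DataError, DegenerateMapError

__all__ = [
    "FusionConfig",
    "pca_reduce",
    "mccar_fit",
    "joint_ica",
    "fuse_with_reference",
    "select_component",
    "zscore_map",
]


@dataclass(frozen=True)
class FusionConfig:
    """Knobs of the supervised decomposition.

    ``n_components`` (M) joint components are extracted from data reduced
    to ``pca_rank`` principal components per modality (defaults to M).
    ``lambda_ref`` is the supervision weight lambda; 0.5 by default —
    strong enough to steer one component toward the reference without
    overwhelming the cross-modality terms. ICA runs ``n_ica_restarts``
    seeded restarts and keeps the most stable one.
    """

    n_components: int = 5
    lambda_ref: float = 0.5
    max_iter: int = 200
    tol: float = 1e-6
    n_ica_restarts: int = 10
    ica_max_iter: int = 1000
    seed: int = 0
    pca_rank: Optional[int] = None

    def validate(self):
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")
        if self.lambda_ref < 0:
            raise ConfigurationError("lambda_ref must be nonnegative")
        if self.max_iter < 1 or self.ica_max_iter < 1:
            raise ConfigurationError("iteration limits must be >= 1")
        if self.tol <= 0:
            raise ConfigurationError("tol must be positive")
        if self.n_ica_restarts < 1:
            raise ConfigurationError("n_ica_restarts must be >= 1")
        if self.pca_rank is not None and self.pca_rank < self.n_components:
            raise ConfigurationError("pca_rank must be >= n_components")

    @property
    def rank(self) -> int:
        return self.pca_rank if self.pca_rank is not None else self.n_components


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------

def pca_reduce(x, rank: int, seed: int = 0, exact: Optional[bool] = None):
    """Reduce a subjects x voxels matrix to its top principal components.

    Returns ``(scores, basis, mean)`` with ``scores`` subjects x rank,
    ``basis`` rank x voxels orthonormal rows, and the column means, so
    ``scores @ basis + mean`` is the rank-``rank`` reconstruction. The
    squared reconstruction error equals the sum of discarded eigenvalues
    of the scatter matrix (exact solver). Large matrices fall back to a
    seeded randomized SVD.
    """
    vals = x.values if isinstance(x, ModalityMatrix) else np.asarray(x, float)
    n, v = vals.shape
    if rank > min(n, v):
        raise ConfigurationError(f"rank {rank} exceeds min(n, v) = {min(n, v)}")
    mean = vals.mean(axis=0)
    xc = vals - mean
    if exact is None:
        exact = (n * v <= 4_000_000) or rank >= min(n, v) // 2
    if exact:
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
    else:
        from sklearn.utils.extmath import randomized_svd

        u, s, vt = randomized_svd(
            xc, n_components=rank, n_oversamples=10, n_iter=7,
            random_state=int(seed) % (2**31),
        )
    scores = u[:, :rank] * s[:rank]
    basis = vt[:rank]
    return scores, basis, mean


# ---------------------------------------------------------------------------
# reference-guided multiset CCA
# ---------------------------------------------------------------------------

def _component_objective(a_cols: Sequence[np.ndarray], z: np.ndarray, lam: float) -> float:
    """Objective restricted to one component: for unit-norm centered
    columns a_k, sum_{k,j} corr(a_k,a_j)^2 + 2*lam*corr(a_k,z)^2."""
    k = len(a_cols)
    obj = 0.0
    for i in range(k):
        for j in range(k):
            cij = float(a_cols[i] @ a_cols[j]) if i != j else 1.0
            obj += cij**2 + 2.0 * lam * float(a_cols[i] @ z) ** 2
    return obj


def mccar_fit(
    y_list: Sequence[np.ndarray],
    reference,
    config: FusionConfig = FusionConfig(),
):
    """Reference-guided multiset CCA on reduced data.

    Parameters
    ----------
    y_list
        Two subjects x rank reduced matrices (aligned subject order).
    reference
        Per-subject reference vector (PRS); must have nonzero variance.

    Returns
    -------
    a_list : list of (n, M) arrays
        Canonical loading columns, unit norm and centered; within each
        modality successive columns are exactly decorrelated (deflation).
    trace : list of list of float
        Per-component objective values across alternating iterations;
        non-decreasing because each update solves its block subproblem
        exactly (a symmetric eigenproblem).
    converged : bool
    """
    config.validate()
    if len(y_list) != 2:
        raise DataError("exactly two modalities are supported")
    ref = reference.values() if isinstance(reference, PrsVector) else np.asarray(reference, float)
    n = y_list[0].shape[0]
    if any(y.shape[0] != n for y in y_list) or len(ref) != n:
        raise DataError("subject dimension mismatch between modalities and reference")
    if np.std(ref) == 0:
        raise DataError("reference has zero variance")
    z = standardize_vector(ref) / np.sqrt(n)  # unit norm, centered
    m = config.n_components
    lam = config.lambda_ref

    centered = [y - y.mean(axis=0) for y in y_list]
    a_list = [np.zeros((n, m)) for _ in y_list]
    trace: List[List[float]] = []
    stalled: List[int] = []

    for comp in range(m):
        bases = []
        for k, yc in enumerate(centered):
            resid = yc
            if comp > 0:
                prev = a_list[k][:, :comp]
                resid = yc - prev @ (prev.T @ yc)
            u = orth_basis(resid)
            if u.shape[1] == 0:
                raise DataError(
                    f"modality {k} exhausted after {comp} components; "
                    "increase pca_rank or lower n_components"
                )
            bases.append(u)

        # init from the top correlated pair of the two subspaces
        cross = bases[0].T @ bases[1]
        uu, _, vvt = np.linalg.svd(cross)
        a = [bases[0] @ uu[:, 0], bases[1] @ vvt[0, :]]

        comp_trace = [_component_objective(a, z, lam)]
        for _ in range(config.max_iter):
            for k in range(2):
                other = a[1 - k]
                b = np.column_stack([other, z])
                d = np.array([2.0, 4.0 * lam])  # two cross terms; ref term counted per (k,j)
                g = bases[k].T @ b
                msym = (g * d) @ g.T
                evals, evecs = np.linalg.eigh(msym)
                a[k] = bases[k] @ evecs[:, -1]
            comp_trace.append(_component_objective(a, z, lam))
            if comp_trace[-1] - comp_trace[-2] < config.tol:
                break
        else:
            stalled.append(comp)
        # deterministic sign: loading of modality 1 correlates nonnegatively
        # with the reference (or with modality 2 when lambda is 0)
        anchor = z if lam > 0 else a[1]
        if float(a[0] @ anchor) < 0:
            a[0] = -a[0]
        if float(a[1] @ a[0]) < 0:
            a[1] = -a[1]
        a_list[0][:, comp] = a[0]
        a_list[1][:, comp] = a[1]
        trace.append(comp_trace)

    converged = not stalled
    if stalled:
        # near-degenerate optima (e.g. equal-strength competing sources)
        # improve by > tol for many iterations without changing the answer
        warnings.warn(
            f"MCCAR: components {stalled} still improving by > tol after "
            f"{config.max_iter} iterations; result flagged as unconverged"
        )
    return a_list, trace, converged


# ---------------------------------------------------------------------------
# joint Infomax ICA
# ---------------------------------------------------------------------------

def _infomax_core(xw: np.ndarray, rng, lr0: float, max_iter: int, tol: float):
    """Natural-gradient Infomax with a logistic nonlinearity on whitened
    data (components x samples). Learning rate halves on blowup."""
    m, nsamp = xw.shape
    w = orth_basis(rng.standard_normal((m, m))).T
    if w.shape != (m, m):  # extremely unlikely rank deficiency
        w = np.eye(m)
    lr = lr0
    last_good = w.copy()
    for _ in range(max_iter):
        u = w @ xw
        y = -np.tanh(u / 2.0)  # 1 - 2*logistic(u)
        grad = (np.eye(m) + (y @ u.T) / nsamp) @ w
        w_new = w + lr * grad
        if not np.all(np.isfinite(w_new)) or np.abs(w_new).max() > 1e8:
            lr *= 0.5
            w = last_good.copy()
            if lr < 1e-8:
                raise DataError("Infomax ICA diverged despite learning-rate annealing")
            continue
        delta = np.abs(lr * grad).max()
        last_good = w = w_new
        if delta < tol:
            break
    return w


def joint_ica(concatenated_maps: np.ndarray, config: FusionConfig = FusionConfig()):
    """Infomax ICA on the M x (V1+V2) concatenated component maps.

    Runs ``n_ica_restarts`` seeded restarts; each restart's components are
    matched to every other restart by maximal absolute correlation
    (Hungarian assignment) and the restart with the highest mean matched
    |corr| is kept. Returns ``(sources, unmixing, stability)`` with
    sources scaled to unit variance and ``sources = unmixing @ centered
    input``.
    """
    config.validate()
    c = np.asarray(concatenated_maps, float)
    if c.ndim != 2:
        raise DataError("concatenated maps must be 2-D")
    m, v = c.shape
    cc = c - c.mean(axis=1, keepdims=True)
    if m == 1:
        sd = cc.std(axis=1)[0]
        if sd == 0:
            raise DataError("single map has zero variance")
        return cc / sd, np.array([[1.0 / sd]]), 1.0

    # whiten across components
    cov = (cc @ cc.T) / v
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() <= 1e-12 * evals.max():
        raise DataError("concatenated maps are rank deficient; reduce n_components")
    k_white = (evecs / np.sqrt(evals)).T  # (m, m)
    xw = k_white @ cc

    rng = np.random.default_rng([int(config.seed) % (2**31), 101])
    runs = []
    for _ in range(config.n_ica_restarts):
        w = _infomax_core(xw, rng, lr0=0.1 / np.log(m + 2), max_iter=config.ica_max_iter,
                          tol=1e-7)
        runs.append(w @ k_white)  # unmixing acting on centered input

    sources_runs = [w @ cc for w in runs]
    n_runs = len(runs)
    if n_runs == 1:
        stability = [1.0]
    else:
        stability = []
        for i in range(n_runs):
            sims = []
            for j in range(n_runs):
                if i == j:
                    continue
                corr = np.abs(np.corrcoef(sources_runs[i], sources_runs[j])[:m, m:])
                ri, cj = linear_sum_assignment(-corr)
                sims.append(corr[ri, cj].mean())
            stability.append(float(np.mean(sims)))
    best = int(np.argmax(stability))
    unmix = runs[best]
    s = unmix @ cc
    sd = s.std(axis=1)
    if np.any(sd == 0):
        raise DataError("degenerate ICA source with zero variance")
    unmix = unmix / sd[:, None]
    return s / sd[:, None], unmix, float(stability[best])


# ---------------------------------------------------------------------------
# full pipeline and component selection
# ---------------------------------------------------------------------------

def fuse_with_reference(
    x1: ModalityMatrix,
    x2: ModalityMatrix,
    reference: PrsVector,
    config: FusionConfig = FusionConfig(),
) -> JointDecomposition:
    """Run the supervised decomposition end-to-end.

    Stages: PCA-reduce each modality; reference-guided multiset CCA on the
    reduced data; back-reconstruct component maps via the pseudo-inverse
    of the canonical loadings; joint Infomax ICA on the concatenated maps;
    final loadings = canonical loadings @ ICA mixing. Loading-reference
    correlations (with two-sided Fisher-z p-values) are reported per
    modality and component.
    """
    config.validate()
    if x1.subjects != x2.subjects:
        raise DataError("modality matrices have mismatched subject order")
    ref = reference.reindex(x1.subjects) if isinstance(reference, PrsVector) else reference
    refv = ref.values() if isinstance(ref, PrsVector) else np.asarray(ref, float)

    rank = config.rank
    reduced = []
    for x in (x1, x2):
        scores, basis, mean = pca_reduce(x, rank, seed=config.seed)
        reduced.append((scores, basis, mean))

    a_list, trace, converged = mccar_fit(
        [reduced[0][0], reduced[1][0]], refv, config
    )

    maps = []
    for (scores, basis, _mean), a in zip(reduced, a_list):
        xc_red = (scores - scores.mean(axis=0)) @ basis  # centered rank-reduced data
        maps.append(np.linalg.pinv(a) @ xc_red)

    v1 = maps[0].shape[1]
    conc = np.concatenate(maps, axis=1)
    sources, unmix, stability = joint_ica(conc, config)
    mixing = np.linalg.pinv(unmix)

    tags = [x1.modality_tag, x2.modality_tag]
    loadings = {t: a @ mixing for t, a in zip(tags, a_list)}
    split_maps = {tags[0]: sources[:, :v1], tags[1]: sources[:, v1:]}

    rows = []
    m = config.n_components
    for t in tags:
        for comp in range(m):
            r, p = pearson_fisher(loadings[t][:, comp], refv)
            rows.append({"modality": t, "component": comp, "r": r, "p": p})
    ref_corr = pd.DataFrame(rows)

    return JointDecomposition(
        modalities=tags,
        loadings=loadings,
        maps=split_maps,
        voxel_ids={tags[0]: list(x1.voxel_ids), tags[1]: list(x2.voxel_ids)},
        unmixing=unmix,
        ref_correlations=ref_corr,
        subjects=list(x1.subjects),
        objective_trace=trace,
        converged=converged,
        ica_stability=stability,
    )


def select_component(
    decomp: JointDecomposition, alpha: float = 0.05
) -> JointDecomposition:
    """Pick the component significantly tied to the reference in *both*
    modalities after Benjamini-Hochberg correction across all 2M tests,
    maximizing the smaller of the two |r|; flip its sign so the reference
    correlations are positive. Sets ``decomp.selected`` (None if nothing
    survives) and returns the same object.
    """
    from statsmodels.stats.multitest import multipletests

    rc = decomp.ref_correlations.copy()
    rc["p_fdr"] = multipletests(rc["p"].to_numpy(), method="fdr_bh")[1]
    m = decomp.n_components
    stats_rows = []
    best, best_min_r = None, -np.inf
    for comp in range(m):
        sub = rc[rc["component"] == comp]
        min_abs_r = sub["r"].abs().min()
        significant = bool((sub["p_fdr"] <= alpha).all())
        stats_rows.append(
            {"component": comp, "min_abs_r": float(min_abs_r), "significant": significant}
        )
        if significant and min_abs_r > best_min_r:
            best, best_min_r = comp, min_abs_r
    decomp.selection_stats = pd.DataFrame(stats_rows).merge(rc, on="component")
    decomp.selected = best
    if best is not None:
        sub = rc[rc["component"] == best]
        if sub["r"].mean() < 0:  # one sign per joint component
            for t in decomp.modalities:
                decomp.loadings[t][:, best] *= -1.0
                decomp.maps[t][best] *= -1.0
            flip = decomp.ref_correlations["component"] == best
            decomp.ref_correlations.loc[flip, "r"] *= -1.0
    return decomp


def zscore_map(
    decomp: JointDecomposition, component: int, display_threshold: float = 2.0
) -> dict:
    """Z-score the selected component's spatial map in each modality
    (population SD over in-mask voxels). Returns tag -> ZMap."""
    out = {}
    for t in decomp.modalities:
        vals = decomp.maps[t][component]
        sd = vals.std()  # population SD: a map is the full voxel population
        if sd == 0:
            raise DegenerateMapError(f"zero-variance map for modality {t}")
        out[t] = ZMap(
            values=(vals - vals.mean()) / sd,
            voxel_ids=decomp.voxel_ids[t],
            modality_tag=t,
            display_threshold=display_threshold,
        )
    return out
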