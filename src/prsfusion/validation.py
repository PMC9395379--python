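"""Diagnostic classification, cross-cohort prediction, and statistics.

The four network-mean features (optionally extended with per-network PC
scores) are validated three ways: a linear support-vector machine with
stratified cross-validation separates cases from controls; a multiple
linear regression

    predicted score = b0 + fALFF_positive*b1 + fALFF_negative*b2
                         + GMV_positive*b3 + GMV_negative*b4

trained on one cohort predicts symptom/cognition scores in others without
refitting; and two-sample t-tests / ANOVA with Benjamini-Hochberg FDR
quantify group differences. A Fisher-z power calculation covers the
"small r, huge n" regime of population-scale correlation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from ._linalg import pearson_fisher
from .errors import ConfigurationError, DataError

__all__ = [
    "ClassifierReport",
    "classify_svm",
    "PredictionModel",
    "fit_prediction_model",
    "apply_prediction_model",
    "group_difference",
    "fdr_correct",
    "power_pearson",
]

MEAN_FEATURES = ("fALFF_positive", "fALFF_negative", "GMV_positive", "GMV_negative")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class ClassifierReport:
    fold_accuracy: list
    accuracy: float          # pooled, percent
    auc: float
    roc_points: pd.DataFrame  # fpr, tpr, threshold
    confusion: Dict[str, int]
    n_folds: int

    def summary(self) -> str:
        return f"ACC = {self.accuracy:.1f}%, AUC = {self.auc:.2f} ({self.n_folds}-fold CV)"


def classify_svm(
    features: pd.DataFrame,
    labels: pd.Series,
    n_folds: int = 10,
    C: float = 1.0,
    seed: int = 0,
) -> ClassifierReport:
    """Linear-SVM diagnosis with stratified k-fold cross-validation.

    Features are standardized inside each training fold (statistics frozen
    and applied to the fold's test subjects — no leakage); decision values
    are pooled across folds for a single ROC curve and AUC.
    """
    y = pd.Series(labels).reindex(features.index)
    if y.isna().any():
        raise DataError("labels missing for some subjects")
    y = y.to_numpy()
    classes = np.unique(y)
    if len(classes) != 2:
        raise DataError(f"need exactly two classes, got {list(classes)}")
    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    x = features.to_numpy(float)
    y01 = (y == classes[1]).astype(int)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(seed) % (2**31))
    pooled_scores = np.empty(len(y01))
    pooled_pred = np.empty(len(y01), dtype=int)
    fold_acc = []
    for train, test in skf.split(x, y01):
        if set(train) & set(test):
            raise DataError("train/test overlap in CV folds")
        scaler = StandardScaler().fit(x[train])
        clf = SVC(kernel="linear", C=C).fit(scaler.transform(x[train]), y01[train])
        xt = scaler.transform(x[test])
        pred = clf.predict(xt)
        pooled_pred[test] = pred
        pooled_scores[test] = clf.decision_function(xt)
        fold_acc.append(float((pred == y01[test]).mean() * 100.0))

    acc = float((pooled_pred == y01).mean() * 100.0)
    auc = float(roc_auc_score(y01, pooled_scores))
    fpr, tpr, thr = roc_curve(y01, pooled_scores)
    confusion = {
        "tp": int(np.sum((pooled_pred == 1) & (y01 == 1))),
        "tn": int(np.sum((pooled_pred == 0) & (y01 == 0))),
        "fp": int(np.sum((pooled_pred == 1) & (y01 == 0))),
        "fn": int(np.sum((pooled_pred == 0) & (y01 == 1))),
    }
    return ClassifierReport(
        fold_accuracy=fold_acc,
        accuracy=acc,
        auc=auc,
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        confusion=confusion,
        n_folds=n_folds,
    )


# ---------------------------------------------------------------------------
# cross-cohort linear prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictionModel:
    """Four-feature linear model with frozen training standardization.

    ``intercept`` and the four coefficients are stored alongside the
    training means/SDs used to standardize the features; applying the
    model to a new cohort reuses those statistics unchanged.
    """

    intercept: float
    coefficients: pd.Series          # index = MEAN_FEATURES
    feature_means: pd.Series
    feature_sds: pd.Series

    def params(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.coefficients.to_numpy()])


def _check_features(features: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEAN_FEATURES if c not in features.columns]
    if missing:
        raise DataError(f"feature table missing columns: {missing}")
    return features[list(MEAN_FEATURES)]


def fit_prediction_model(features: pd.DataFrame, target) -> PredictionModel:
    """OLS fit of the four-feature linear model on a training cohort.

    Features are standardized (training mean/SD, n-1 denominator) before
    fitting so coefficients are comparable across features.
    """
    f = _check_features(features)
    y = pd.Series(target).reindex(f.index)
    if y.isna().any():
        raise DataError("target missing for some subjects")
    n = len(f)
    if n <= 5:
        raise DataError(f"need more than 5 subjects to fit 5 parameters, got {n}")
    means = f.mean()
    sds = f.std(ddof=1)
    if (sds == 0).any():
        raise DataError(f"zero-variance features: {list(sds.index[sds == 0])}")
    z = (f - means) / sds
    design = np.column_stack([np.ones(n), z.to_numpy(float)])
    beta = np.linalg.lstsq(design, y.to_numpy(float), rcond=None)[0]
    return PredictionModel(
        intercept=float(beta[0]),
        coefficients=pd.Series(beta[1:], index=list(MEAN_FEATURES)),
        feature_means=means,
        feature_sds=sds,
    )


def apply_prediction_model(model: PredictionModel, features: pd.DataFrame, truth=None):
    """Evaluate the linear model on a (possibly new) cohort.

    Standardization uses the model's frozen training statistics. Returns
    ``(predictions, stats)`` where stats holds the Pearson r and p against
    ``truth`` when given (r is None for degenerate constant predictions).
    """
    f = _check_features(features)
    z = (f - model.feature_means) / model.feature_sds
    pred = pd.Series(
        model.intercept + z.to_numpy(float) @ model.coefficients.to_numpy(),
        index=f.index,
        name="predicted",
    )
    result = {"r": None, "p": None}
    if truth is not None:
        y = pd.Series(truth).reindex(f.index)
        if y.isna().any():
            raise DataError("truth missing for some subjects")
        if pred.std() == 0 or y.std() == 0:
            result["note"] = "correlation undefined (constant predictions or truth)"
        else:
            r, p = pearson_fisher(pred.to_numpy(), y.to_numpy())
            result = {"r": r, "p": p}
    return pred, result


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def _regress_out_site(features: pd.DataFrame, site: pd.Series) -> pd.DataFrame:
    dummies = pd.get_dummies(site.reindex(features.index), drop_first=True, dtype=float)
    design = np.column_stack([np.ones(len(features)), dummies.to_numpy()])
    vals = features.to_numpy(float)
    beta = np.linalg.lstsq(design, vals, rcond=None)[0]
    resid = vals - design @ beta + vals.mean(axis=0)
    return pd.DataFrame(resid, index=features.index, columns=features.columns)


def group_difference(
    features: pd.DataFrame,
    group_labels: pd.Series,
    site: Optional[pd.Series] = None,
    equal_var: bool = False,
    fdr: bool = True,
) -> pd.DataFrame:
    """Two-tailed two-sample t-tests per feature (Welch by default),
    pairwise across groups, plus one-way ANOVA when more than two groups.

    When ``site`` is supplied it is regressed out of every feature first.
    ``equal_var=True`` switches to pooled-variance t-tests (under which
    the two-group ANOVA F equals t^2 exactly). BH-FDR-adjusted p-values
    are appended across all tests in the table.
    """
    g = pd.Series(group_labels).reindex(features.index)
    if g.isna().any():
        raise DataError("group labels missing for some subjects")
    levels = sorted(g.unique(), key=str)
    if len(levels) < 2:
        raise DataError("need at least two groups")
    counts = g.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise DataError(f"groups with fewer than 2 subjects: {list(small.index)}")
    if site is not None:
        features = _regress_out_site(features, site)

    rows = []
    for col in features.columns:
        v = features[col]
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                a = v[g == levels[i]].to_numpy(float)
                b = v[g == levels[j]].to_numpy(float)
                t, p = stats.ttest_ind(a, b, equal_var=equal_var)
                rows.append(
                    {"feature": col, "test": "t", "group_a": levels[i],
                     "group_b": levels[j], "statistic": float(t), "p": float(p),
                     "mean_a": float(a.mean()), "mean_b": float(b.mean())}
                )
        if len(levels) > 2 or equal_var:
            groups = [v[g == lev].to_numpy(float) for lev in levels]
            f_stat, p = stats.f_oneway(*groups)
            rows.append(
                {"feature": col, "test": "anova", "group_a": None, "group_b": None,
                 "statistic": float(f_stat), "p": float(p),
                 "mean_a": np.nan, "mean_b": np.nan}
            )
    table = pd.DataFrame(rows)
    if fdr:
        table["p_fdr"] = fdr_correct(table["p"].to_numpy())
    return table


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def power_pearson(r: float, n: int, alpha: float = 0.05) -> float:
    """Two-sided power of the Pearson-correlation test via Fisher's z.

    With z_r = atanh(r), the test statistic is ~N(z_r*sqrt(n-3), 1), so

        power = Phi(z_r*sqrt(n-3) - z_{1-a/2}) + Phi(-z_r*sqrt(n-3) - z_{1-a/2})

    At r = 0 this returns alpha exactly.
    """
    if not (abs(r) < 1):
        raise ConfigurationError("|r| must be < 1")
    if n < 4:
        raise ConfigurationError("n must be >= 4")
    if not (0 < alpha < 1):
        raise ConfigurationError("alpha must be in (0, 1)")
    zr = np.arctanh(r) * np.sqrt(n - 3)
    q = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(zr - q) + stats.norm.cdf(-zr - q))
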