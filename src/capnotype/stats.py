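"""Statistical battery: one-way ANOVA, Newman–Keuls pairwise comparisons,
and canonical discriminant analysis (CDA).

The CDA solves the generalized symmetric eigenproblem
``B v = lambda W v`` with ``W`` the pooled within-class scatter and ``B``
the between-class scatter; the eigenvectors span the canonical space (at
most ``n_classes - 1`` variates), discrimination is summarized by Wilks'
lambda ``prod 1/(1+lambda_i)``, and cycles are classified by the nearest
class centroid in canonical space with equal priors.  The classification
matrix is resubstitution (apparent) error, the protocol matched by a
printed classification matrix without a held-out set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateDataError, InvalidParameterError


# ---------------------------------------------------------------------------
# ANOVA


@dataclass
class AnovaResult:
    feature: str
    f_statistic: float
    p_value: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]


def anova_oneway(groups: dict[str, np.ndarray], feature: str = "") -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across the cycle types."""
    if len(groups) < 2:
        raise DegenerateDataError("ANOVA needs at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise DegenerateDataError(f"group {k!r} has < 2 observations")
    f, p = sps.f_oneway(*arrays.values())
    if not np.isfinite(f):  # identical values in every group
        f, p = 0.0, 1.0
    return AnovaResult(
        feature=feature,
        f_statistic=float(f),
        p_value=float(p),
        group_means={k: float(v.mean()) for k, v in arrays.items()},
        group_sds={k: float(v.std(ddof=1)) for k, v in arrays.items()},
        group_ns={k: int(v.size) for k, v in arrays.items()},
    )


def anova_table(features_df: pd.DataFrame, labels: pd.Series,
                feature_names: list[str]) -> pd.DataFrame:
    """One ANOVA row per feature, mirroring a means ± SD summary table."""
    rows = []
    for name in feature_names:
        groups = {t: features_df.loc[labels == t, name].to_numpy()
                  for t in sorted(labels.unique())}
        res = anova_oneway(groups, feature=name)
        row = {"feature": name, "F": res.f_statistic, "p": res.p_value}
        for t in groups:
            row[f"mean_{t}"] = res.group_means[t]
            row[f"sd_{t}"] = res.group_sds[t]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Newman–Keuls


def snk_pairwise(groups: dict[str, np.ndarray], alpha: float = 0.05
                 ) -> dict[tuple[str, str], bool]:
    """Stepwise Newman–Keuls multiple comparison of group means.

    Uses the studentized range with step-dependent critical values: the
    pair spanning r ordered means is tested against ``q(alpha, r, df)``,
    and a non-significant stretch protects all pairs inside it.  The
    classical balanced formula is used with the harmonic mean of the two
    group sizes when groups are unbalanced.  Returns per-pair significance
    flags keyed by (name_i, name_j) in sorted-name order.
    """
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must be in (0, 1)")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise DegenerateDataError("need at least 2 groups")
    for k, v in arrays.items():
        if v.size < 2:
            raise DegenerateDataError(f"group {k!r} has < 2 observations")

    names = sorted(arrays, key=lambda k: arrays[k].mean())
    means = {k: arrays[k].mean() for k in names}
    ns = {k: arrays[k].size for k in names}
    n_total = sum(ns.values())
    df_error = n_total - len(names)
    ms_within = sum(((arrays[k] - means[k]) ** 2).sum() for k in names) / df_error

    tested_significant: set[tuple[str, str]] = set()
    homogeneous: list[tuple[int, int]] = []  # accepted (protected) stretches

    def key(a: str, b: str) -> tuple[str, str]:
        return tuple(sorted((a, b)))

    def test_stretch(lo: int, hi: int) -> None:
        """Test the extreme pair of the ordered stretch [lo, hi]."""
        if hi - lo < 1:
            return
        if any(l <= lo and hi <= h for l, h in homogeneous):
            return  # protected by an accepted homogeneous stretch
        a, b = names[lo], names[hi]
        r = hi - lo + 1
        n_h = 2.0 / (1.0 / ns[a] + 1.0 / ns[b])
        se = np.sqrt(ms_within / n_h)
        q_obs = abs(means[b] - means[a]) / se if se > 0 else np.inf
        if se == 0 and means[b] == means[a]:
            q_obs = 0.0
        q_crit = sps.studentized_range.ppf(1 - alpha, r, df_error)
        if q_obs > q_crit:
            tested_significant.add(key(a, b))
            test_stretch(lo, hi - 1)
            test_stretch(lo + 1, hi)
        else:
            homogeneous.append((lo, hi))

    test_stretch(0, len(names) - 1)

    significant: dict[tuple[str, str], bool] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            k = key(names[i], names[j])
            protected = any(l <= i and j <= h for l, h in homogeneous)
            significant[k] = (k in tested_significant) and not protected
    return significant


# ---------------------------------------------------------------------------
# Canonical discriminant analysis


class CanonicalDiscriminantAnalysis(ClassifierMixin, TransformerMixin,
                                    BaseEstimator):
    """Canonical discriminant analysis with nearest-centroid classification.

    Projects the feature space onto at most ``n_classes - 1`` canonical
    variates maximizing between- to within-class scatter, scaled so each
    variate has unit pooled within-class variance.  ``predict`` assigns
    the nearest class centroid in canonical space (equal priors).

    Parameters
    ----------
    ridge : float, default 0.0
        Relative ridge added to the within-class scatter diagonal when it
        is numerically singular.  With the default 0, a singular scatter
        raises; set a small value (e.g. 1e-8) to enable the fallback,
        which is then flagged in ``ridge_applied_``.

    Attributes
    ----------
    scalings_ : (n_features, n_variates) canonical coefficients.
    eigenvalues_ : canonical eigenvalues (of W^-1 B).
    wilks_lambda_ : float in (0, 1]; small = good discrimination.
    centroids_ : (n_classes, n_variates) class centroids in canonical space.
    classes_ : class labels.
    ridge_applied_ : whether the ridge fallback was used.
    """

    def __init__(self, ridge: float = 0.0):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise InvalidParameterError("X must be 2-D with one label per row")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, p = X.shape
        g = len(self.classes_)
        if g < 2:
            raise DegenerateDataError("need at least 2 classes")
        if n <= g:
            raise DegenerateDataError("need more observations than classes")

        grand = X.mean(axis=0)
        within = np.zeros((p, p))
        between = np.zeros((p, p))
        class_means = np.empty((g, p))
        for c in range(g):
            xc = X[y_idx == c]
            mc = xc.mean(axis=0)
            class_means[c] = mc
            dev = xc - mc
            within += dev.T @ dev
            dm = (mc - grand)[:, None]
            between += len(xc) * (dm @ dm.T)

        self.ridge_applied_ = False
        w = within
        try:
            evals, evecs = scipy.linalg.eigh(between, w)
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
            if self.ridge <= 0:
                raise DegenerateDataError(
                    "within-class scatter is singular; set ridge > 0 "
                    "to enable the regularized fallback") from None
            scale = np.trace(within) / p
            if scale <= 0:
                scale = 1.0
            w = within + self.ridge * scale * np.eye(p)
            self.ridge_applied_ = True
            try:
                evals, evecs = scipy.linalg.eigh(between, w)
            except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
                raise DegenerateDataError(
                    "within-class scatter remains singular after the ridge "
                    "fallback; increase ridge") from None

        order = np.argsort(evals)[::-1]
        n_variates = min(g - 1, p)
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]

        # eigh normalizes v' W v = 1; rescale to unit pooled within-class
        # *variance* (divide scatter by its degrees of freedom)
        evecs = evecs / np.sqrt(1.0 / (n - g))

        self.eigenvalues_ = evals[:n_variates]
        self.wilks_lambda_ = float(np.prod(1.0 / (1.0 + evals)))
        self.scalings_ = evecs[:, :n_variates]
        self.xbar_ = grand
        self.centroids_ = (class_means - grand) @ self.scalings_
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        return (X - self.xbar_) @ self.scalings_

    def predict(self, X):
        z = self.transform(X)
        d2 = ((z[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]


@dataclass
class CdaResult:
    """Fitted CDA summary plus its resubstitution classification matrix."""

    coefficients: np.ndarray
    eigenvalues: np.ndarray
    wilks_lambda: float
    centroids: np.ndarray
    classes: list
    confusion_matrix: np.ndarray
    percent_correct: dict = field(default_factory=dict)
    ridge_applied: bool = False


def cda_fit(X, y, feature_names: list[str] | None = None,
            ridge: float = 0.0) -> CdaResult:
    """Fit a CDA and classify the same observations (resubstitution)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 3:
        raise DegenerateDataError("CDA requires at least 3 retained features")
    model = CanonicalDiscriminantAnalysis(ridge=ridge).fit(X, y)
    predicted = model.predict(X)
    matrix = _sk_confusion(y, predicted, labels=model.classes_)
    summary = confusion_summary(matrix)
    return CdaResult(
        coefficients=model.scalings_,
        eigenvalues=model.eigenvalues_,
        wilks_lambda=model.wilks_lambda_,
        centroids=model.centroids_,
        classes=list(model.classes_),
        confusion_matrix=matrix,
        percent_correct=summary,
        ridge_applied=model.ridge_applied_,
    )


def confusion_summary(matrix) -> dict:
    """Per-class and overall percent correct of a classification matrix.

    Rows are true classes, columns assigned classes.  Per-class percent is
    ``diagonal / row total * 100`` (two decimals); overall is
    ``trace / total * 100``.  Column sums are included so a printed matrix
    can be checked for internal consistency.
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidParameterError("matrix must be square")
    if (m < 0).any() or not np.issubdtype(m.dtype, np.number):
        raise InvalidParameterError("matrix must be nonnegative counts")
    row_totals = m.sum(axis=1)
    if (row_totals == 0).any():
        raise DegenerateDataError("a class has zero observations")
    per_class = np.round(100.0 * np.diag(m) / row_totals, 2)
    overall = round(100.0 * np.trace(m) / m.sum(), 2)
    return {
        "per_class_percent": per_class.tolist(),
        "overall_percent": float(overall),
        "row_totals": row_totals.tolist(),
        "column_totals": m.sum(axis=0).tolist(),
    }
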