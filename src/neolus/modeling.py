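"""Chi-square feature ranking and pooled-covariance LDA classification.

The selector discretizes each image feature into quantile bins computed
on the training rows and ranks features by the p-value of a chi-square
test of independence between bin and class; the classifier is a
pooled-covariance linear discriminant with equal or empirical class
priors, fitted on standardized features with a small ridge on the
covariance.  Both are scikit-learn estimators and compose in a
``sklearn.pipeline.Pipeline``; the module-level functions
(:func:`chi2_rank`, :func:`select_top_k`, :func:`fit_lda`,
:func:`predict`) are thin wrappers over them.

Clinical covariates are "protected" columns: they are never ranked and
always pass selection, mirroring a design in which the three clinical
features accompany the top-15 image features into the classifier.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .features import CLINICAL_NAMES

META_COLUMNS = ("subject_id", "video_id", "frame_index", "class_label",
                "lung_region")


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Named feature matrix with per-row sample identity."""

    matrix: np.ndarray                  # (n_samples, n_features)
    names: list[str]
    labels: np.ndarray                  # class label per row
    groups: np.ndarray                  # subject id per row
    clinical_mask: np.ndarray           # bool per column

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        self.groups = np.asarray(self.groups)
        self.clinical_mask = np.asarray(self.clinical_mask, dtype=bool)
        n, f = self.matrix.shape
        if not (len(self.names) == f == self.clinical_mask.size):
            raise ValueError("feature names/mask do not match matrix width")
        if not (self.labels.size == n == self.groups.size):
            raise ValueError("labels/groups do not match matrix height")
        if np.isnan(self.matrix).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def subset_rows(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.matrix[idx], self.names, self.labels[idx],
                            self.groups[idx], self.clinical_mask)

    def subset_columns(self, col_idx: np.ndarray) -> "FeatureTable":
        col_idx = np.asarray(col_idx)
        return FeatureTable(self.matrix[:, col_idx],
                            [self.names[i] for i in col_idx],
                            self.labels, self.groups,
                            self.clinical_mask[col_idx])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.names)
        df.insert(0, "subject_id", self.groups)
        df.insert(1, "class_label", self.labels)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        feat_cols = [c for c in df.columns if c not in META_COLUMNS]
        mask = np.array([c in CLINICAL_NAMES for c in feat_cols])
        return cls(df[feat_cols].to_numpy(dtype=float), feat_cols,
                   df["class_label"].to_numpy(),
                   df["subject_id"].to_numpy(), mask)


# ---------------------------------------------------------------------------
# Vectorized chi-square machinery
# ---------------------------------------------------------------------------

def quantile_bin_edges(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Interior quantile edges, shape (n_bins - 1, n_features)."""
    qs = np.arange(1, n_bins) / n_bins
    return np.quantile(x, qs, axis=0)


def assign_bins(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin index per value: number of edges the value reaches (>=)."""
    bins = np.zeros(x.shape, dtype=np.int64)
    for e in edges:
        bins += x >= e
    return bins


def chi2_pvalues(bins: np.ndarray, y_codes: np.ndarray, n_bins: int,
                 n_classes: int) -> np.ndarray:
    """Chi-square independence p-value per feature column.

    ``bins`` is (n_samples, n_features) with values in [0, n_bins);
    empty bins or classes reduce the degrees of freedom; a feature whose
    samples all share one bin gets p = 1.
    """
    n, f = bins.shape
    flat = (np.arange(f)[None, :] * (n_bins * n_classes)
            + bins * n_classes + y_codes[:, None])
    counts = np.bincount(flat.ravel(), minlength=f * n_bins * n_classes)
    counts = counts.reshape(f, n_bins, n_classes).astype(float)
    row = counts.sum(axis=2, keepdims=True)       # per-bin totals
    col = counts.sum(axis=1, keepdims=True)       # per-class totals
    expected = row * col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    stat = terms.sum(axis=(1, 2))
    dof = ((row[:, :, 0] > 0).sum(axis=1) - 1) * ((col[:, 0, :] > 0).sum(axis=1) - 1)
    p = np.ones(f)
    ok = dof > 0
    p[ok] = chi2_dist.sf(stat[ok], dof[ok])
    return p


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class QuantileChi2Selector(TransformerMixin, BaseEstimator):
    """Select the k image features most dependent on the class label.

    Each non-protected column is discretized into ``n_bins`` quantile
    bins computed on the fitted data; a chi-square test of independence
    against the class labels yields its p-value, and the k smallest
    p-values win (ties broken by original column order).  Protected
    columns (the clinical covariates) always pass and never count
    towards k.
    """

    def __init__(self, k: int = 15, n_bins: int = 10,
                 protected: np.ndarray | None = None):
        self.k = k
        self.n_bins = n_bins
        self.protected = protected

    def fit(self, X: np.ndarray, y: np.ndarray) -> "QuantileChi2Selector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        classes, y_codes = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes to rank features")
        prot = (np.zeros(X.shape[1], dtype=bool) if self.protected is None
                else np.asarray(self.protected, dtype=bool))
        img_idx = np.flatnonzero(~prot)
        if self.k > img_idx.size:
            raise ValueError(f"k={self.k} exceeds the "
                             f"{img_idx.size} rankable features")
        xi = X[:, img_idx]
        edges = quantile_bin_edges(xi, self.n_bins)
        p = chi2_pvalues(assign_bins(xi, edges), y_codes, self.n_bins,
                         classes.size)
        order = np.argsort(p, kind="stable")
        self.pvalues_ = np.ones(X.shape[1])
        self.pvalues_[img_idx] = p
        self.ranking_ = img_idx[order]            # best image feature first
        top = np.sort(img_idx[order[: self.k]])
        self.support_ = prot.copy()
        self.support_[top] = True
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X)[:, self.support_]


class PooledCovarianceLDA(ClassifierMixin, BaseEstimator):
    """Linear discriminant with pooled within-class covariance.

    Features are standardized with the training mean/SD, the pooled
    covariance gets a ridge ``ridge * trace(S)/d`` on its diagonal, and
    class priors are either equal or proportional to the training class
    counts.  Prediction is the arg-max of the linear discriminant scores
    including log-priors, ties resolved in class order.
    """

    def __init__(self, priors: str = "equal", ridge: float = 1e-6,
                 standardize: bool = True):
        self.priors = priors
        self.ridge = ridge
        self.standardize = standardize

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PooledCovarianceLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, y_codes = np.unique(y, return_inverse=True)
        counts = np.bincount(y_codes)
        if (counts < 2).any():
            small = classes[counts < 2]
            raise ValueError(f"classes {list(small)} have fewer than "
                             "2 training samples")
        n, d = X.shape
        if d >= n:
            warnings.warn(f"{d} features for only {n} samples; "
                          "LDA estimates will be unstable", stacklevel=2)
        if self.standardize:
            self.center_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
        else:
            self.center_ = np.zeros(d)
            self.scale_ = np.ones(d)
        z = (X - self.center_) / self.scale_

        self.classes_ = classes
        self.means_ = np.vstack([z[y_codes == c].mean(axis=0)
                                 for c in range(classes.size)])
        pooled = np.zeros((d, d))
        for c in range(classes.size):
            r = z[y_codes == c] - self.means_[c]
            pooled += r.T @ r
        pooled /= (n - classes.size)
        pooled[np.diag_indices(d)] += self.ridge * np.trace(pooled) / d
        self.covariance_ = pooled

        if self.priors == "equal":
            self.priors_ = np.full(classes.size, 1.0 / classes.size)
        elif self.priors == "empirical":
            self.priors_ = counts / n
        else:
            raise ValueError(f"unknown priors mode {self.priors!r}")

        try:
            cf = cho_factor(pooled)
        except np.linalg.LinAlgError as err:
            raise ValueError("pooled covariance singular even after "
                             "regularization") from err
        inv_means = cho_solve(cf, self.means_.T).T     # Sigma^-1 mu_c
        self.coef_ = inv_means / self.scale_
        self.intercept_ = (np.log(self.priors_)
                           - 0.5 * np.einsum("cd,cd->c", self.means_, inv_means)
                           - self.coef_ @ self.center_)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.coef_.shape[1]:
            raise ValueError(f"expected {self.coef_.shape[1]} features, "
                             f"got {X.shape[1]}")
        return X @ self.coef_.T + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def save(self, path: str, feature_names: list[str] | None = None) -> None:
        """Serialize the fitted model to one portable JSON file.

        Schema: ``classes``, ``means`` (standardized space), ``covariance``
        (pooled, regularized), ``priors``, ``scaler`` (center/scale),
        ``params`` and optionally the selected ``feature_names``.
        """
        payload = {
            "classes": self.classes_.tolist(),
            "means": self.means_.tolist(),
            "covariance": self.covariance_.tolist(),
            "priors": self.priors_.tolist(),
            "scaler": {"center": self.center_.tolist(),
                       "scale": self.scale_.tolist()},
            "params": self.get_params(),
            "feature_names": feature_names,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> tuple["PooledCovarianceLDA",
                                      list[str] | None]:
        with open(path) as fh:
            payload = json.load(fh)
        model = cls(**payload["params"])
        model.classes_ = np.array(payload["classes"])
        model.center_ = np.array(payload["scaler"]["center"])
        model.scale_ = np.array(payload["scaler"]["scale"])
        model.means_ = np.array(payload["means"])
        model.covariance_ = np.array(payload["covariance"])
        model.priors_ = np.array(payload["priors"])
        cf = cho_factor(model.covariance_)
        inv_means = cho_solve(cf, model.means_.T).T
        model.coef_ = inv_means / model.scale_
        model.intercept_ = (np.log(model.priors_)
                            - 0.5 * np.einsum("cd,cd->c", model.means_,
                                              inv_means)
                            - model.coef_ @ model.center_)
        return model, payload["feature_names"]


# ---------------------------------------------------------------------------
# Thin functional wrappers (the operation surface)
# ---------------------------------------------------------------------------

@dataclass
class RankedFeatures:
    """Image features ordered by ascending chi-square p-value."""

    names: list[str]
    pvalues: np.ndarray
    column_indices: np.ndarray = field(default_factory=lambda: np.array([]))


LdaModel = PooledCovarianceLDA


def chi2_rank(t: FeatureTable, n_bins: int = 10) -> RankedFeatures:
    """Rank the non-clinical features of a table by class dependence."""
    sel = QuantileChi2Selector(k=1, n_bins=n_bins, protected=t.clinical_mask)
    sel.fit(t.matrix, t.labels)
    order = sel.ranking_
    return RankedFeatures([t.names[i] for i in order],
                          sel.pvalues_[order], order)


def select_top_k(r: RankedFeatures, k: int = 15,
                 t: FeatureTable | None = None) -> FeatureTable:
    """Restrict a table to the k best image features plus all clinical."""
    if t is None:
        raise ValueError("a FeatureTable is required")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > r.column_indices.size:
        raise ValueError(f"k={k} exceeds the {r.column_indices.size} "
                         "ranked features")
    keep = np.sort(np.concatenate([r.column_indices[:k],
                                   np.flatnonzero(t.clinical_mask)]))
    return t.subset_columns(keep)


def fit_lda(t: FeatureTable, priors_mode: str = "equal",
            ridge: float = 1e-6) -> PooledCovarianceLDA:
    model = PooledCovarianceLDA(priors=priors_mode, ridge=ridge)
    return model.fit(t.matrix, t.labels)


def predict(m: PooledCovarianceLDA,
            rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and discriminant scores for feature rows."""
    scores = m.decision_function(rows)
    return m.classes_[np.argmax(scores, axis=1)], scores
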