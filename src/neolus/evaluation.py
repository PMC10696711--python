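"""Cross-validation drivers and classification metrics.

Two schemes mirror per-image and per-subject evaluation: leave-one-out
(LOO) holds out a single image per fold; leave-one-subject-out (LOSO)
holds out all images of one subject.  Feature ranking, selection,
standardization and LDA fitting are redone inside every fold on the
training rows only, so no information from the held-out rows leaks into
selection.

LOO over hundreds of images re-ranks thousands of features per fold, so
the driver computes each fold's training quantile edges from a single
pre-sorted copy of the matrix (removing one row from a sorted column is
an index shift, not a re-sort); the result is bit-identical to the naive
per-fold computation and is asserted as such in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modeling import (FeatureTable, PooledCovarianceLDA, assign_bins,
                       chi2_pvalues, quantile_bin_edges)
from .phantom import CLASS_LABELS


@dataclass
class CVReport:
    """Per-fold predictions and summary metrics of one CV run."""

    scheme: str
    classes: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    fold_ids: np.ndarray
    confusion_counts: np.ndarray
    confusion_rowpct: np.ndarray
    overall_accuracy: float            # percent
    weighted_f1: float
    selected_features: list[list[str]] = field(default_factory=list)

    def rowpct_table(self) -> pd.DataFrame:
        """Row-percentage confusion matrix rounded to two decimals."""
        return pd.DataFrame(np.round(self.confusion_rowpct, 2),
                            index=self.classes, columns=self.classes)


def _class_order(labels: np.ndarray) -> list[str]:
    present = set(np.unique(labels).tolist())
    if present <= set(CLASS_LABELS):
        return [c for c in CLASS_LABELS if c in present]
    return sorted(present)


def metrics_from_confusion(counts: np.ndarray) -> tuple[float, float]:
    """Overall accuracy (percent) and weighted F1 from a count matrix.

    Rows are true classes, columns predictions.  Per-class F1 uses
    precision from the column and recall from the row (0 when
    undefined); the weighted F1 averages per-class F1 with each class's
    true-label count as weight.
    """
    m = np.asarray(counts, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (m < 0).any():
        raise ValueError("confusion matrix must be non-negative")
    total = m.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    acc = 100.0 * np.trace(m) / total
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    diag = np.diag(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(col > 0, diag / col, 0.0)
        rec = np.where(row > 0, diag / row, 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    weighted = float((row / total * f1).sum())
    return float(acc), weighted


def counts_from_row_percentages(rowpct: np.ndarray,
                                class_totals: np.ndarray) -> np.ndarray:
    """Reconstruct integer counts from a printed row-percentage matrix.

    Printed cells are rounded, so each cell is rounded to the nearest
    integer and row sums are repaired to the known class totals by
    largest remainder (deterministic column-order tie-break).
    """
    rowpct = np.asarray(rowpct, dtype=float)
    class_totals = np.asarray(class_totals)
    out = np.zeros_like(rowpct, dtype=np.int64)
    for r in range(rowpct.shape[0]):
        raw = rowpct[r] * class_totals[r] / 100.0
        cells = np.rint(raw).astype(np.int64)
        diff = int(class_totals[r] - cells.sum())
        rem = raw - cells
        if diff > 0:
            for idx in np.argsort(-rem, kind="stable")[:diff]:
                cells[idx] += 1
        elif diff < 0:
            for idx in np.argsort(rem, kind="stable")[:-diff]:
                cells[idx] -= 1
        out[r] = cells
    return out


# ---------------------------------------------------------------------------
# Fold machinery
# ---------------------------------------------------------------------------

def _loo_edges(sorted_cols: np.ndarray, ranks_row: np.ndarray,
               n_bins: int) -> np.ndarray:
    """Training-fold quantile edges with one row removed.

    ``sorted_cols`` is the column-sorted full matrix; ``ranks_row`` the
    stable-sort rank of the removed row's value in each column.  Equals
    ``quantile_bin_edges`` of the matrix with that row deleted.
    """
    n, f = sorted_cols.shape
    m = n - 1
    qs = np.arange(1, n_bins) / n_bins
    pos = qs * (m - 1)
    i0 = np.floor(pos).astype(int)
    t = pos - i0
    cols = np.arange(f)
    edges = np.empty((n_bins - 1, f))
    for b in range(n_bins - 1):
        lo_idx = i0[b] + (i0[b] >= ranks_row)
        hi_idx = (i0[b] + 1) + (i0[b] + 1 >= ranks_row)
        lo = sorted_cols[lo_idx, cols]
        hi = sorted_cols[np.minimum(hi_idx, n - 1), cols]
        edges[b] = (1 - t[b]) * lo + t[b] * hi
    return edges


def _fit_predict_fold(t: FeatureTable, train: np.ndarray, test: np.ndarray,
                      p_img: np.ndarray, img_idx: np.ndarray, k: int,
                      priors_mode: str, ridge: float,
                      ) -> tuple[np.ndarray, list[str]]:
    order = np.argsort(p_img, kind="stable")
    cols = np.sort(np.concatenate([img_idx[order[:k]],
                                   np.flatnonzero(t.clinical_mask)]))
    model = PooledCovarianceLDA(priors=priors_mode, ridge=ridge)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(t.matrix[np.ix_(train, cols)], t.labels[train])
    pred = model.predict(t.matrix[np.ix_(test, cols)])
    return pred, [t.names[i] for i in img_idx[order[:k]]]


def _finalize(scheme: str, t: FeatureTable, y_pred: np.ndarray,
              fold_ids: np.ndarray, selected: list[list[str]]) -> CVReport:
    classes = _class_order(t.labels)
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for yt, yp in zip(t.labels, y_pred):
        counts[idx[yt], idx[yp]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        rowpct = np.where(counts.sum(axis=1, keepdims=True) > 0,
                          100.0 * counts / counts.sum(axis=1, keepdims=True),
                          0.0)
    acc, f1 = metrics_from_confusion(counts)
    return CVReport(scheme, classes, t.labels.copy(), y_pred, fold_ids,
                    counts, rowpct, acc, f1, selected)


def _check_training_classes(t: FeatureTable, train: np.ndarray,
                            fold: str) -> None:
    missing = set(np.unique(t.labels)) - set(np.unique(t.labels[train]))
    if missing:
        warnings.warn(f"classes {sorted(missing)} absent from the training "
                      f"rows of fold {fold}", stacklevel=3)


def run_loo_cv(t: FeatureTable, k: int = 15, priors_mode: str = "equal",
               n_bins: int = 10, ridge: float = 1e-6) -> CVReport:
    """Leave-one-image-out CV with per-fold ranking and selection."""
    n = t.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples for LOO")
    img_idx = np.flatnonzero(~t.clinical_mask)
    xi = t.matrix[:, img_idx]
    sorted_cols = np.sort(xi, axis=0)
    order = np.argsort(xi, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n)[:, None], axis=0)
    _, y_codes = np.unique(t.labels, return_inverse=True)
    n_classes = int(y_codes.max()) + 1

    y_pred = np.empty(n, dtype=t.labels.dtype)
    selected: list[list[str]] = []
    all_rows = np.arange(n)
    for r in range(n):
        train = all_rows != r
        _check_training_classes(t, train, str(r))
        edges = _loo_edges(sorted_cols, ranks[r], n_bins)
        bins = assign_bins(xi[train], edges)
        p = chi2_pvalues(bins, y_codes[train], n_bins, n_classes)
        pred, sel = _fit_predict_fold(t, train, ~train, p, img_idx, k,
                                      priors_mode, ridge)
        y_pred[r] = pred[0]
        selected.append(sel)
    return _finalize("LOO", t, y_pred, all_rows, selected)


def run_loso_cv(t: FeatureTable, k: int = 15, priors_mode: str = "equal",
                n_bins: int = 10, ridge: float = 1e-6) -> CVReport:
    """Leave-one-subject-out CV: one fold per subject."""
    subjects = np.unique(t.groups)
    if subjects.size < 2:
        raise ValueError("need at least 2 subjects for LOSO")
    img_idx = np.flatnonzero(~t.clinical_mask)
    xi = t.matrix[:, img_idx]
    _, y_codes = np.unique(t.labels, return_inverse=True)
    n_classes = int(y_codes.max()) + 1

    y_pred = np.empty(t.n_samples, dtype=t.labels.dtype)
    fold_ids = np.empty(t.n_samples, dtype=np.int64)
    selected: list[list[str]] = []
    for fi, subj in enumerate(subjects):
        test = t.groups == subj
        train = ~test
        _check_training_classes(t, train, str(subj))
        edges = quantile_bin_edges(xi[train], n_bins)
        bins = assign_bins(xi[train], edges)
        p = chi2_pvalues(bins, y_codes[train], n_bins, n_classes)
        pred, sel = _fit_predict_fold(t, train, test, p, img_idx, k,
                                      priors_mode, ridge)
        y_pred[test] = pred
        fold_ids[test] = fi
        selected.append(sel)
    return _finalize("LOSO", t, y_pred, fold_ids, selected)


def sweep_feature_count(t: FeatureTable, k_values: list[int],
                        scheme: str = "loso",
                        priors_mode: str = "equal") -> pd.DataFrame:
    """Accuracy/F1 curve over the number of selected image features."""
    if not k_values or list(k_values) != sorted(k_values):
        raise ValueError("k_values must be non-empty and ascending")
    runner = {"loo": run_loo_cv, "loso": run_loso_cv}[scheme.lower()]
    rows = []
    for k in k_values:
        rep = runner(t, k=k, priors_mode=priors_mode)
        rows.append({"k": k, "accuracy_pct": rep.overall_accuracy,
                     "weighted_f1": rep.weighted_f1})
    return pd.DataFrame(rows)
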