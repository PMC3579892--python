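"""Balanced nearest-centroid subtype classification and cross-study transfer.

Training starts from "core" samples — those whose silhouette width under
their subtype label (distance = 1 - Pearson) is positive, i.e. samples more
similar to their own subtype than to any other.  Per class, genes are scored
with a t-like statistic comparing the class mean to the overall mean over a
regularized pooled within-class SD; each gene is assigned to the single
class maximizing its absolute score, which makes the per-class gene lists
disjoint by construction.  The number of genes kept per class is chosen by
stratified cross-validation over a small grid.  Class centroids are
per-gene medians over the core samples, and prediction assigns each sample
to the centroid with the smallest 1 - Pearson distance.

For transfer to external cohorts two harmonization routes are provided:
rescaling the external data to the training per-gene means/SDs (arrays on a
comparable platform), and per-gene median-centering plus unit-scaling of
both centroids and external data (sequencing-based expression).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples
from sklearn.model_selection import StratifiedKFold

from .errors import DataError
from .expression_prep import median_center_genes

__all__ = [
    "SubtypeModel",
    "silhouette_core_samples",
    "train_nearest_centroid_classifier",
    "predict_subtypes",
    "build_subtype_centroids",
    "cross_study_validate",
    "harmonize_external",
    "standardize_and_predict",
]

DEFAULT_GENES_PER_CLASS_GRID = (50, 100, 150, 210, 300)


@dataclass
class SubtypeModel:
    """A trained nearest-centroid subtype classifier."""

    classes: list
    classifier_genes: dict  # class -> disjoint gene list
    centroids: pd.DataFrame  # gene x class median centroids
    train_gene_mean: pd.Series
    train_gene_sd: pd.Series
    genes_per_class: int
    distance_metric: str = "one_minus_pearson"
    cv_error: float = float("nan")

    def __post_init__(self) -> None:
        seen = set()
        for c in self.classes:
            genes = set(self.classifier_genes[c])
            if genes & seen:
                raise DataError("per-class gene lists must be disjoint")
            seen |= genes
        if (self.train_gene_sd.loc[sorted(seen)] <= 0).any():
            raise DataError("train_gene_sd must be positive for classifier genes")

    @property
    def all_genes(self) -> list:
        out = []
        for c in self.classes:
            out.extend(self.classifier_genes[c])
        return out

    def to_json(self, path) -> None:
        payload = {
            "classes": [str(c) for c in self.classes],
            "classifier_genes": {str(c): list(g) for c, g in self.classifier_genes.items()},
            "centroids": {str(c): self.centroids[c].to_dict() for c in self.classes},
            "train_gene_mean": self.train_gene_mean.to_dict(),
            "train_gene_sd": self.train_gene_sd.to_dict(),
            "genes_per_class": self.genes_per_class,
            "distance_metric": self.distance_metric,
            "cv_error": self.cv_error,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SubtypeModel":
        with open(path) as fh:
            payload = json.load(fh)
        centroids = pd.DataFrame({c: pd.Series(v)
                                  for c, v in payload["centroids"].items()})
        return cls(classes=payload["classes"],
                   classifier_genes=payload["classifier_genes"],
                   centroids=centroids,
                   train_gene_mean=pd.Series(payload["train_gene_mean"]),
                   train_gene_sd=pd.Series(payload["train_gene_sd"]),
                   genes_per_class=payload["genes_per_class"],
                   distance_metric=payload["distance_metric"],
                   cv_error=payload["cv_error"])


# ---------------------------------------------------------------------------
# Core-sample selection
# ---------------------------------------------------------------------------

def silhouette_core_samples(matrix: pd.DataFrame, labels: pd.Series):
    """Silhouette widths under 1 - Pearson distance; core = width > 0.

    Returns ``(core_mask, widths)`` indexed by sample.  Every class must
    have at least 2 samples for the intra-class mean distance to exist.
    """
    labels = labels.reindex(matrix.columns)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise DataError("need at least 2 subtypes")
    small = counts[counts < 2]
    if len(small):
        raise DataError(f"class {small.index[0]!r} has fewer than 2 samples")
    corr = np.corrcoef(matrix.to_numpy(), rowvar=False)
    d = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    widths = silhouette_samples(d, labels.to_numpy(), metric="precomputed")
    widths = pd.Series(widths, index=matrix.columns, name="silhouette_width")
    return widths > 0, widths


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _class_gene_scores(matrix: pd.DataFrame, labels: pd.Series):
    """t-like score of each gene for each class vs the overall mean."""
    classes = sorted(labels.unique())
    X = matrix.to_numpy()
    lab = labels.reindex(matrix.columns).to_numpy()
    overall = X.mean(axis=1)
    n = X.shape[1]
    k = len(classes)
    within_ss = np.zeros(X.shape[0])
    class_means = {}
    for c in classes:
        sub = X[:, lab == c]
        mu = sub.mean(axis=1)
        class_means[c] = mu
        within_ss += ((sub - mu[:, None]) ** 2).sum(axis=1)
    pooled_sd = np.sqrt(within_ss / max(n - k, 1))
    s0 = float(np.median(pooled_sd))
    if s0 == 0 and np.all(pooled_sd == 0):
        raise DataError("pooled within-class SD is zero for all genes")
    scores = pd.DataFrame(
        {c: (class_means[c] - overall) / (pooled_sd + s0) for c in classes},
        index=matrix.index)
    return scores


def _select_genes(scores: pd.DataFrame, genes_per_class: int) -> dict:
    """Assign each gene to its |score|-maximizing class; keep the top
    ``genes_per_class`` per class, ties broken by gene id."""
    abs_scores = scores.abs()
    assigned = abs_scores.idxmax(axis=1)
    selection = {}
    for c in scores.columns:
        mine = abs_scores.loc[assigned == c, c]
        order = sorted(mine.index, key=lambda g: (-mine[g], str(g)))
        if len(order) < genes_per_class:
            raise DataError(
                f"class {c!r}: only {len(order)} genes assigned, "
                f"cannot keep {genes_per_class}")
        selection[c] = order[:genes_per_class]
    return selection


def _fit(matrix: pd.DataFrame, labels: pd.Series, genes_per_class: int):
    scores = _class_gene_scores(matrix, labels)
    selection = _select_genes(scores, genes_per_class)
    genes = [g for c in scores.columns for g in selection[c]]
    centroids = build_subtype_centroids(matrix.loc[genes], labels)
    return selection, centroids


def _pearson_dist(x: np.ndarray, y: np.ndarray) -> float:
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        return np.inf
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.inf
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


def train_nearest_centroid_classifier(matrix: pd.DataFrame, labels: pd.Series,
                                      genes_per_class_grid=DEFAULT_GENES_PER_CLASS_GRID,
                                      cv_folds: int = 5, seed=None,
                                      genes_per_class: int = None) -> SubtypeModel:
    """Train the balanced nearest-centroid classifier on core samples.

    When ``genes_per_class`` is given the grid search is skipped.  The CV
    error is the stratified ``cv_folds``-fold misclassification rate with
    gene selection redone inside each fold.
    """
    labels = labels.reindex(matrix.columns)
    counts = labels.value_counts()
    if (counts < cv_folds).any() and genes_per_class is None:
        raise DataError("every class needs at least cv_folds core samples")
    classes = sorted(labels.unique())

    def cv_error_at(q: int) -> float:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                              random_state=_as_int_seed(seed))
        errors = 0
        y = labels.to_numpy()
        for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
            tr_cols = matrix.columns[train_idx]
            te_cols = matrix.columns[test_idx]
            try:
                selection, centroids = _fit(matrix[tr_cols], labels[tr_cols], q)
            except DataError:
                return np.inf
            pred, _ = _predict_frame(matrix[te_cols], centroids)
            errors += int((pred.to_numpy() != y[test_idx]).sum())
        return errors / len(y)

    cv_err = float("nan")
    if genes_per_class is None:
        feasible = [q for q in genes_per_class_grid
                    if q * len(classes) <= matrix.shape[0]]
        if not feasible:
            raise DataError("no feasible genes_per_class in grid")
        errs = {q: cv_error_at(q) for q in feasible}
        genes_per_class = min(feasible, key=lambda q: (errs[q], q))
        cv_err = errs[genes_per_class]
    selection, centroids = _fit(matrix, labels, genes_per_class)
    genes = [g for c in classes for g in selection[c]]
    sub = matrix.loc[genes]
    return SubtypeModel(classes=classes,
                       classifier_genes=selection,
                       centroids=centroids,
                       train_gene_mean=sub.mean(axis=1),
                       train_gene_sd=sub.std(axis=1, ddof=1),
                       genes_per_class=genes_per_class,
                       cv_error=cv_err)


def _as_int_seed(seed):
    if seed is None or isinstance(seed, (int, np.integer)):
        return None if seed is None else int(seed)
    return int(np.random.default_rng(seed).integers(0, 2 ** 31 - 1))


def _predict_frame(matrix: pd.DataFrame, centroids: pd.DataFrame):
    common = centroids.index.intersection(matrix.index)
    sub = matrix.loc[common].to_numpy()
    cen = centroids.loc[common].to_numpy()
    classes = list(centroids.columns)
    labels, dists = [], []
    for i in range(sub.shape[1]):
        row = [_pearson_dist(sub[:, i], cen[:, j]) for j in range(len(classes))]
        labels.append(classes[int(np.argmin(row))])
        dists.append(row)
    return (pd.Series(labels, index=matrix.columns, name="subtype"),
            pd.DataFrame(dists, index=matrix.columns, columns=classes))


def predict_subtypes(model: SubtypeModel, matrix: pd.DataFrame):
    """Assign each sample to its nearest centroid (1 - Pearson).

    Requires at least 50% of the classifier genes to be present; missing
    genes are dropped pairwise and the coverage fraction is reported.
    Returns ``(labels, distances, coverage)``.
    """
    genes = model.all_genes
    common = [g for g in genes if g in matrix.index]
    coverage = len(common) / len(genes)
    if coverage < 0.5:
        raise DataError(
            f"only {len(common)}/{len(genes)} classifier genes present "
            f"(coverage {coverage:.2f} < 0.50)")
    labels, dists = _predict_frame(matrix, model.centroids)
    return labels, dists, coverage


def build_subtype_centroids(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Gene x class matrix of per-class median expression."""
    labels = labels.reindex(matrix.columns)
    classes = sorted(labels.dropna().unique())
    if labels.isna().any():
        raise DataError("labels missing for some samples")
    out = {}
    for c in classes:
        cols = labels.index[labels == c]
        if len(cols) == 0:
            raise DataError(f"class {c!r} is empty")
        out[c] = matrix[cols].median(axis=1)
    return pd.DataFrame(out)


def cross_study_validate(matrix_a: pd.DataFrame, labels_a: pd.Series,
                         matrix_b: pd.DataFrame, labels_b: pd.Series,
                         min_genes: int = 100) -> pd.DataFrame:
    """Centroid distance matrix (1 - Pearson) between two studies' subtypes.

    Both datasets are restricted to their gene intersection and gene
    median-centered separately before the median centroids are compared.
    Rows are study-A subtypes, columns study-B subtypes; entries lie in
    [0, 2] and concordant subtypes show up as small diagonal entries.
    """
    common = matrix_a.index.intersection(matrix_b.index)
    if len(common) < min_genes:
        raise DataError(f"gene intersection {len(common)} below floor {min_genes}")
    cen_a = build_subtype_centroids(median_center_genes(matrix_a.loc[common]), labels_a)
    cen_b = build_subtype_centroids(median_center_genes(matrix_b.loc[common]), labels_b)
    out = pd.DataFrame(index=cen_a.columns, columns=cen_b.columns, dtype=float)
    for a in cen_a.columns:
        for b in cen_b.columns:
            out.loc[a, b] = _pearson_dist(cen_a[a].to_numpy(), cen_b[b].to_numpy())
    return out


def harmonize_external(model: SubtypeModel, external: pd.DataFrame) -> pd.DataFrame:
    """Rescale external data to the training per-gene means and SDs.

    Per overlapping classifier gene the external values are z-scored and
    rescaled so that the harmonized per-gene mean/SD equal the model's
    stored values.  Zero-variance external genes are dropped with a
    warning.
    """
    genes = [g for g in model.all_genes if g in external.index]
    sub = external.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    dropped = list(sd.index[sd == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance external genes: {dropped}")
        sub = sub.drop(index=dropped)
        sd = sd.drop(index=dropped)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return (z.mul(model.train_gene_sd.reindex(z.index), axis=0)
             .add(model.train_gene_mean.reindex(z.index), axis=0))


def standardize_and_predict(model: SubtypeModel, matrix: pd.DataFrame) -> pd.Series:
    """Predict labels after per-gene median-centering and unit-scaling both
    the model centroids and the external data (sequencing-style transfer).

    Constant external genes are dropped with a warning; class centroids are
    standardized across classes the same way.
    """
    genes = [g for g in model.all_genes if g in matrix.index]
    if len(genes) / len(model.all_genes) < 0.5:
        raise DataError("fewer than 50% of classifier genes present")
    sub = matrix.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    constant = list(sd.index[sd == 0])
    if constant:
        warnings.warn(f"dropping constant external genes: {constant}")
        sub = sub.drop(index=constant)
        sd = sd.drop(index=constant)
    ext = sub.sub(sub.median(axis=1), axis=0).div(sd, axis=0)
    cen = model.centroids.loc[ext.index]
    cen_sd = cen.std(axis=1, ddof=1)
    keep = cen_sd > 0
    ext, cen, cen_sd = ext[keep.to_numpy()], cen[keep.to_numpy()], cen_sd[keep]
    cen = cen.sub(cen.median(axis=1), axis=0).div(cen_sd, axis=0)
    labels, _ = _predict_frame(ext, cen)
    return labels
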