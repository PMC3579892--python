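"""Unsupervised subtype discovery and cluster-significance testing.

Two stages:

1. **Consensus clustering** — repeated hierarchical clustering (average
   linkage, distance = 1 - Pearson correlation between samples) on random
   80% subsets of the samples.  The consensus matrix records, for every
   sample pair, the fraction of co-draws in which the pair co-clustered; the
   final labels come from hierarchically clustering ``1 - consensus``.  The
   empirical CDF of consensus values per k, the change in area under that
   CDF between consecutive k (delta-area), and a label-tracking count drive
   model selection.

2. **Cluster-significance testing** — for each pair of discovered subtypes,
   a Monte-Carlo test of the null hypothesis that the pair arose from a
   single multivariate Gaussian.  The test statistic is the 2-cluster index
   (within-cluster sum of squares over total sum of squares).  The null
   Gaussian's covariance eigenvalues are the sample covariance eigenvalues
   floored at a background noise variance estimated from the MAD of all
   matrix entries; each simulated dataset is scored by the minimal cluster
   index over seeded 2-means restarts, so the null accounts for the
   cluster-seeking optimization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .errors import DataError

__all__ = [
    "ConsensusResult",
    "ClusterSignificance",
    "consensus_cluster",
    "select_k",
    "cluster_index",
    "sigclust_pvalue",
    "sigclust_all_pairs",
    "adjusted_rand_index",
]

MAD_TO_SD = 1.4826


def _pearson_distance(columns: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns (samples), over genes."""
    corr = np.corrcoef(columns, rowvar=False)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _check_sample_variance(matrix: pd.DataFrame) -> None:
    sd = matrix.to_numpy().std(axis=0)
    if np.any(sd == 0):
        bad = matrix.columns[np.flatnonzero(sd == 0)[0]]
        raise DataError(f"sample {bad!r} has zero variance; Pearson undefined")


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, labels, and model-selection diagnostics."""

    k_range: list
    sample_ids: list
    consensus: dict  # k -> sample x sample DataFrame in [0, 1]
    labels: dict  # k -> Series of labels in 1..k
    area: dict  # k -> area under the consensus CDF
    delta_area: dict  # k -> change in area vs previous k (first k: area itself)
    tracking: dict = field(default_factory=dict)  # (k, k+1) -> samples changing class


def consensus_cluster(matrix: pd.DataFrame, k_range, n_resamples: int = 1000,
                      item_fraction: float = 0.8, seed=None,
                      linkage_method: str = "average") -> ConsensusResult:
    """Resampled hierarchical consensus clustering over a range of k.

    ``matrix`` is a preprocessed gene x sample frame.  Per resample,
    ``ceil(item_fraction * n)`` samples are drawn without replacement and
    hierarchically clustered with 1 - Pearson distance; consensus(i, j) is
    the co-cluster count divided by the co-draw count.
    """
    k_range = sorted(k_range)
    n = matrix.shape[1]
    if not all(2 <= k <= n - 1 for k in k_range):
        raise DataError("k_range must lie within [2, n_samples - 1]")
    _check_sample_variance(matrix)
    rng = np.random.default_rng(seed)
    X = matrix.to_numpy()
    size = int(np.ceil(item_fraction * n))
    codraw = np.zeros((n, n))
    cocluster = {k: np.zeros((n, n)) for k in k_range}
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        d = _pearson_distance(X[:, idx])
        link = hierarchy.linkage(squareform(d, checks=False), method=linkage_method)
        codraw[np.ix_(idx, idx)] += 1
        for k in k_range:
            labs = hierarchy.fcluster(link, k, criterion="maxclust")
            same = labs[:, None] == labs[None, :]
            cocluster[k][np.ix_(idx, idx)] += same
    if np.any(codraw == 0):
        raise DataError("some sample pairs were never co-drawn; "
                        "increase n_resamples")
    ids = list(matrix.columns)
    consensus, labels, area, delta = {}, {}, {}, {}
    prev_area = None
    for k in k_range:
        cons = cocluster[k] / codraw
        cons = (cons + cons.T) / 2
        np.fill_diagonal(cons, 1.0)
        consensus[k] = pd.DataFrame(cons, index=ids, columns=ids)
        link = hierarchy.linkage(
            squareform(np.clip(1.0 - cons, 0, None), checks=False),
            method=linkage_method)
        labels[k] = pd.Series(
            hierarchy.fcluster(link, k, criterion="maxclust"), index=ids)
        upper = cons[np.triu_indices(n, k=1)]
        # area under the empirical CDF on [0, 1] equals 1 - mean
        area[k] = float(1.0 - upper.mean())
        delta[k] = area[k] if prev_area is None else area[k] - prev_area
        prev_area = area[k]
    tracking = {}
    for k1, k2 in zip(k_range[:-1], k_range[1:]):
        tracking[(k1, k2)] = _label_changes(labels[k1], labels[k2])
    return ConsensusResult(k_range=k_range, sample_ids=ids, consensus=consensus,
                           labels=labels, area=area, delta_area=delta,
                           tracking=tracking)


def _label_changes(a: pd.Series, b: pd.Series) -> int:
    """Samples changing class between two labelings, minimized over renaming."""
    cats_a = sorted(a.unique())
    cats_b = sorted(b.unique())
    cont = np.zeros((len(cats_a), len(cats_b)))
    for i, ca in enumerate(cats_a):
        for j, cb in enumerate(cats_b):
            cont[i, j] = int(((a == ca) & (b == cb)).sum())
    rows, cols = linear_sum_assignment(-cont)
    return int(len(a) - cont[rows, cols].sum())


def select_k(result: ConsensusResult, delta_threshold: float = 0.05,
             pac_bounds=(0.1, 0.9), pac_unstable: float = 0.5) -> dict:
    """Recommend k from the consensus CDF diagnostics.

    The recommendation is the largest k whose delta-area is at least
    ``delta_threshold`` (i.e. the last k that still adds cluster stability).
    The run is flagged unstable when no k clears the threshold, when the
    delta-area never flattens within the examined range (the recommendation
    sits at the top of ``k_range``, as for a single Gaussian blob), or when
    the proportion of ambiguous consensus entries (PAC, entries strictly
    inside ``pac_bounds``) at the recommended k exceeds ``pac_unstable``.
    """
    if len(result.k_range) < 3:
        raise DataError("need at least 3 values of k")
    candidates = [k for k in result.k_range if result.delta_area[k] >= delta_threshold]
    if candidates:
        k_rec = max(candidates)
        cons = result.consensus[k_rec].to_numpy()
        n = cons.shape[0]
        upper = cons[np.triu_indices(n, k=1)]
        pac = float(np.mean((upper > pac_bounds[0]) & (upper < pac_bounds[1])))
        stable = pac <= pac_unstable and k_rec < max(result.k_range)
    else:
        k_rec = result.k_range[0]
        pac = float("nan")
        stable = False
    return {
        "recommended_k": int(k_rec),
        "stable": bool(stable),
        "pac": pac,
        "area": dict(result.area),
        "delta_area": dict(result.delta_area),
        "tracking": {f"{a}->{b}": v for (a, b), v in result.tracking.items()},
    }


# ---------------------------------------------------------------------------
# Cluster-significance testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSignificance:
    pair: tuple
    cluster_index: float
    p_value: float
    p_adjusted: float
    n_sim: int


def cluster_index(matrix: pd.DataFrame, labels: pd.Series) -> float:
    """2-group cluster index: within-cluster SS / total SS over all genes.

    Defined as 0 when the total sum of squares vanishes (all samples at a
    single point).
    """
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise DataError("cluster_index requires exactly 2 label values")
    X = matrix.to_numpy()
    lab = labels.reindex(matrix.columns).to_numpy()
    total = float(((X - X.mean(axis=1, keepdims=True)) ** 2).sum())
    if total == 0:
        return 0.0
    within = 0.0
    for g in groups:
        sub = X[:, lab == g]
        if sub.shape[1] == 0:
            raise DataError(f"group {g!r} is empty")
        within += float(((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum())
    return within / total


def _min_two_means_ci(X: np.ndarray, n_restarts: int, seed) -> float:
    """Minimal 2-cluster index over seeded 2-means restarts.

    ``X`` is samples x features; the cluster index equals the 2-means
    inertia divided by the total sum of squares, so the best restart gives
    the minimum.  Lloyd's iterations run vectorized across all restarts
    (random 2-point initializations), which keeps the Monte-Carlo null loop
    fast at these sizes.
    """
    total = float(((X - X.mean(axis=0)) ** 2).sum())
    if total == 0:
        return 0.0
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    # k-means++-style init: second center drawn with probability
    # proportional to squared distance from the first
    first = rng.integers(0, n, size=n_restarts)
    sq = ((X[None, :, :] - X[first, None, :]) ** 2).sum(-1)  # (restarts, n)
    second = np.array([rng.choice(n, p=row / row.sum()) for row in sq])
    centers = np.stack([X[first], X[second]], axis=1).astype(float)  # (R, 2, d)
    assign = np.full((n_restarts, n), -1)
    for _ in range(100):
        d2 = ((X[None, None, :, :] - centers[:, :, None, :]) ** 2).sum(-1)
        new_assign = d2.argmin(axis=1)  # (restarts, n)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for r in range(n_restarts):
            for c in (0, 1):
                mask = assign[r] == c
                if mask.any():
                    centers[r, c] = X[mask].mean(axis=0)
    inertia = np.take_along_axis(d2, assign[:, None, :], axis=1)[:, 0, :].sum(-1)
    return float(inertia.min()) / total


def _null_eigenvalues(eigvals: np.ndarray, sigma2: float,
                      method: str) -> np.ndarray:
    """Null covariance spectrum from the sample spectrum.

    ``hard`` floors each sample eigenvalue at the background noise variance.
    ``soft`` (default) shrinks all eigenvalues by a common offset before
    flooring, with the offset chosen to preserve the total variance; this
    counteracts the upward bias of the leading sample eigenvalues, which
    otherwise makes the test severely conservative (simulated null data
    would look more clusterable than the data themselves).
    """
    if method == "hard":
        return np.maximum(eigvals, sigma2)
    if method != "soft":
        raise DataError(f"unknown covariance method {method!r}")
    total = float(eigvals.sum())
    d = len(eigvals)
    if total <= d * sigma2:
        return np.full(d, sigma2)
    lo, hi = 0.0, float(eigvals.max())
    for _ in range(100):
        tau = (lo + hi) / 2
        if np.maximum(eigvals - tau, sigma2).sum() > total:
            lo = tau
        else:
            hi = tau
    return np.maximum(eigvals - hi, sigma2)


def sigclust_pvalue(matrix: pd.DataFrame, labels: pd.Series, n_sim: int = 1000,
                    seed=None, n_restarts: int = 10,
                    covariance_method: str = "soft") -> ClusterSignificance:
    """Monte-Carlo p-value for the separation of two sample groups.

    Null model: a single multivariate Gaussian whose covariance eigenvalues
    are estimated from the sample covariance across genes (see
    :func:`_null_eigenvalues`), with the background noise variance sigma^2
    estimated from the MAD of all matrix entries scaled by the Gaussian
    consistency factor.  Each null dataset of the same dimensions is scored
    by the minimal cluster index over 2-means restarts; the p-value uses
    the add-one estimator, so it is bounded below by 1/(1 + n_sim).
    """
    if n_sim < 100:
        raise DataError("n_sim must be >= 100")
    if matrix.shape[1] < 3:
        raise DataError("need at least 3 samples")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise DataError("sigclust_pvalue requires exactly 2 groups")
    obs_ci = cluster_index(matrix, labels)
    X = matrix.to_numpy().T  # samples x genes
    n, d = X.shape
    sigma2 = (MAD_TO_SD * float(np.median(np.abs(X - np.median(X))))) ** 2
    Xc = X - X.mean(axis=0)
    sv = np.linalg.svd(Xc, compute_uv=False)
    eigvals = np.zeros(d)
    eigvals[: len(sv)] = sv ** 2 / max(n - 1, 1)
    if not np.all(np.isfinite(eigvals)):
        raise DataError("non-finite covariance spectrum")
    null_var = _null_eigenvalues(eigvals, sigma2, covariance_method)
    null_sd = np.sqrt(null_var)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    km_seeds = rng.integers(0, 2 ** 31 - 1, size=n_sim)
    hits = 0
    for s in range(n_sim):
        Z = rng.normal(size=(n, d)) * null_sd
        if _min_two_means_ci(Z, n_restarts, int(km_seeds[s])) <= obs_ci:
            hits += 1
    p = (1 + hits) / (1 + n_sim)
    return ClusterSignificance(pair=tuple(groups), cluster_index=obs_ci,
                               p_value=p, p_adjusted=min(1.0, p), n_sim=n_sim)


def sigclust_all_pairs(matrix: pd.DataFrame, labels: pd.Series,
                       n_sim: int = 1000, seed=None, n_restarts: int = 10,
                       covariance_method: str = "soft") -> list:
    """Cluster-significance test for every unordered pair of subtypes,
    Bonferroni-adjusted over the K(K-1)/2 tests."""
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise DataError("need at least 2 subtypes")
    pairs = list(itertools.combinations(groups, 2))
    n_tests = len(pairs)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(n_tests)
    out = []
    for (a, b), child in zip(pairs, seeds):
        cols = labels.index[labels.isin([a, b])]
        res = sigclust_pvalue(matrix[cols], labels[cols], n_sim=n_sim,
                              seed=child, n_restarts=n_restarts,
                              covariance_method=covariance_method)
        out.append(ClusterSignificance(
            pair=(a, b), cluster_index=res.cluster_index,
            p_value=res.p_value,
            p_adjusted=min(1.0, res.p_value * n_tests), n_sim=n_sim))
    return out


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index between two labelings (chance-corrected)."""
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(np.asarray(a), np.asarray(b)))
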