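"""Association and survival statistics for subtype-linked clinical analysis.

Includes an exact two-sided Fisher test for general r x c contingency
tables (full enumeration of margin-fixed tables, with a state budget), a
Monte-Carlo variant for tables too large to enumerate, Kruskal-Wallis,
a permutation-based two-class differential-expression test controlling the
median false discovery rate, and Kaplan-Meier / log-rank survival
comparison (via lifelines).

Two-sided Fisher p-values use the "probability at most that of the observed
table" rule with a 1e-7 relative tolerance, matching the convention of the
standard statistical environments for r x c tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import DataError

__all__ = [
    "fisher_exact_rxc",
    "fisher_monte_carlo",
    "kruskal_wallis",
    "SamResult",
    "sam_two_class",
    "km_logrank",
    "read_clinical_table",
    "crosstab",
]

_REL_TOL = 1e-7


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise DataError("contingency table must be at least 2 x 2")
    if (t < 0).any():
        raise DataError("counts must be non-negative")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise DataError("every row and column needs a positive margin")
    return t


def _log_table_prob(t: np.ndarray, lg_margins: float) -> float:
    """log hypergeometric probability of a margin-fixed table."""
    return lg_margins - gammaln(t + 1).sum()


def fisher_exact_rxc(table, max_tables: int = 10_000_000) -> float:
    """Exact two-sided Fisher test for an r x c table.

    Enumerates every table with the observed margins and sums the
    probability of those whose hypergeometric probability does not exceed
    the observed table's.  Raises when the enumeration would exceed
    ``max_tables`` states (use :func:`fisher_monte_carlo` instead).
    """
    t = _validate_table(table)
    # p is invariant to row order; put the largest row last (it is implied
    # by the margins) to shrink the enumeration
    t = t[np.argsort(t.sum(axis=1)), :]
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    lg_margins = (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
                  - gammaln(n + 1))
    obs_term = -gammaln(t + 1).sum()  # log prob without the margin constant
    cutoff = obs_term + np.log1p(_REL_TOL)
    r, c = t.shape
    lg = gammaln(np.arange(n + 1) + 1)  # log factorials 0..n

    total = 0.0
    states = 0

    def recurse(row: int, remaining_cols: np.ndarray, acc: float):
        nonlocal total, states
        if row == r - 1:
            states += 1
            if states > max_tables:
                raise DataError(
                    "enumeration budget exceeded; use fisher_monte_carlo")
            logp = acc - lg[remaining_cols].sum()
            if logp <= cutoff:
                total += np.exp(lg_margins + logp)
            return
        target = rows[row]

        def fill(col: int, left: int, cell_acc: float, rem: np.ndarray):
            if col == c - 1:
                if left <= rem[col]:
                    nxt = rem.copy()
                    nxt[col] -= left
                    recurse(row + 1, nxt, cell_acc - lg[left])
                return
            lo = max(0, left - rem[col + 1:].sum())
            hi = min(left, rem[col])
            for v in range(lo, hi + 1):
                nxt = rem.copy()
                nxt[col] -= v
                fill(col + 1, left - v, cell_acc - lg[v], nxt)

        fill(0, int(target), acc, remaining_cols)

    recurse(0, cols.copy(), 0.0)
    return float(min(total, 1.0))


def fisher_monte_carlo(table, n_sim: int = 100_000, seed=None) -> dict:
    """Monte-Carlo two-sided Fisher test by permuting category assignments.

    Margin-fixed null tables are generated by permuting the row-category
    labels against fixed column labels.  Returns the add-one p estimate and
    its Monte-Carlo standard error.
    """
    if n_sim < 1000:
        raise DataError("n_sim must be >= 1000")
    t = _validate_table(table)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    lg_margins = (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
                  - gammaln(n + 1))
    obs_logp = _log_table_prob(t, lg_margins)
    cutoff = obs_logp + np.log1p(_REL_TOL)
    rng = np.random.default_rng(seed)
    row_vec = np.repeat(np.arange(t.shape[0]), rows)
    col_vec = np.repeat(np.arange(t.shape[1]), cols)
    hits = 0
    chunk = max(1, min(n_sim, 20_000))
    done = 0
    r, c = t.shape
    while done < n_sim:
        b = min(chunk, n_sim - done)
        perms = rng.permuted(np.tile(row_vec, (b, 1)), axis=1)
        logp = np.full(b, lg_margins)
        for i in range(r):
            for j in range(c):
                cnt = ((perms == i) & (col_vec == j)).sum(axis=1)
                logp -= gammaln(cnt + 1)
        hits += int((logp <= cutoff).sum())
        done += b
    p = (1 + hits) / (1 + n_sim)
    se = float(np.sqrt(p * (1 - p) / n_sim))
    return {"p_value": p, "se": se, "n_sim": n_sim}


def kruskal_wallis(groups) -> tuple:
    """Tie-corrected Kruskal-Wallis H and chi-squared p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise DataError("need >= 2 non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise DataError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


@dataclass
class SamResult:
    """Outcome of the permutation differential-expression test."""

    d: pd.Series  # per-gene moderated t-like statistic
    called: pd.Series  # per-gene flag at the chosen cutoff
    cutoff: float
    median_fdr: float
    n_perm: int


def sam_two_class(matrix: pd.DataFrame, labels: pd.Series, n_perm: int = 1000,
                  fdr_threshold: float = 0.01, seed=None,
                  s0: float = None) -> SamResult:
    """Two-class permutation differential expression with median-FDR control.

    Per gene, ``d = (mean_1 - mean_2) / (pooled SE + s0)`` with ``s0`` the
    median pooled SE by default.  Label permutations give the null
    distribution of d; genes are called at the smallest symmetric |d|
    cutoff whose estimated median FDR — the median over permutations of the
    null exceedance count divided by the number of called genes — does not
    exceed ``fdr_threshold``.
    """
    labels = labels.reindex(matrix.columns)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise DataError("sam_two_class requires exactly 2 classes")
    y = (labels == classes[0]).to_numpy()
    n1, n2 = int(y.sum()), int((~y).sum())
    if n1 < 2 or n2 < 2:
        raise DataError("each class needs at least 2 samples")
    X = matrix.to_numpy()

    def d_stat(mask: np.ndarray) -> np.ndarray:
        a, b = X[:, mask], X[:, ~mask]
        va = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        vb = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        pooled = (va + vb) / (n1 + n2 - 2)
        se = np.sqrt(pooled * (1 / n1 + 1 / n2))
        return a.mean(axis=1) - b.mean(axis=1), se

    diff, se = d_stat(y)
    if s0 is None:
        s0 = float(np.median(se))
    d = diff / (se + s0)
    rng = np.random.default_rng(seed)
    null_sorted = np.empty((n_perm, X.shape[0]))
    for b in range(n_perm):
        perm = rng.permutation(len(y))
        mask = np.zeros(len(y), dtype=bool)
        mask[perm[:n1]] = True
        pdiff, pse = d_stat(mask)
        null_sorted[b] = np.sort(np.abs(pdiff / (pse + s0)))
    abs_d = np.abs(d)
    cutoffs = np.sort(abs_d)[::-1]  # most extreme first; calling i+1 genes
    # per permutation, null exceedance count at every candidate cutoff
    counts = np.empty((n_perm, len(cutoffs)))
    asc = cutoffs[::-1]
    for b in range(n_perm):
        counts[b] = (len(asc) - np.searchsorted(null_sorted[b], asc,
                                                side="left"))[::-1]
    med_counts = np.median(counts, axis=0)
    # permutation-resolution floor: a finite permutation set cannot certify
    # fewer than ~half a false call, so never report an estimated FDR of 0
    n_called = np.arange(1, len(cutoffs) + 1)
    fdr = np.maximum(med_counts, 0.5) / n_called
    passing = np.flatnonzero(fdr <= fdr_threshold)
    if len(passing) == 0:
        called = pd.Series(False, index=matrix.index)
        return SamResult(d=pd.Series(d, index=matrix.index), called=called,
                         cutoff=float("inf"), median_fdr=0.0, n_perm=n_perm)
    best = int(passing[-1])  # smallest passing cutoff = most genes called
    chosen = cutoffs[best]
    called = pd.Series(abs_d >= chosen, index=matrix.index)
    med_fdr = min(1.0, float(fdr[best]))
    return SamResult(d=pd.Series(d, index=matrix.index), called=called,
                     cutoff=float(chosen), median_fdr=med_fdr, n_perm=n_perm)


def km_logrank(clinical: pd.DataFrame, groups: pd.Series) -> dict:
    """Kaplan-Meier curves per group and the multi-group log-rank test.

    ``clinical`` must carry ``rfs_months`` and ``event`` columns; ``groups``
    assigns each sample to a comparison group.  Raises when no events are
    observed.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    groups = groups.reindex(clinical.index).dropna()
    data = clinical.loc[groups.index]
    if groups.nunique() < 2:
        raise DataError("need at least 2 groups")
    if (data["rfs_months"] < 0).any():
        raise DataError("negative survival time")
    if int(data["event"].sum()) == 0:
        raise DataError("no events")
    curves = {}
    for g in sorted(groups.unique()):
        sub = data.loc[groups == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["rfs_months"], event_observed=sub["event"], label=str(g))
        curves[g] = kmf.survival_function_
    res = multivariate_logrank_test(data["rfs_months"], groups, data["event"])
    return {"curves": curves, "statistic": float(res.test_statistic),
            "p_value": float(res.p_value),
            "df": int(groups.nunique() - 1)}


def read_clinical_table(path) -> pd.DataFrame:
    """Read a clinical TSV indexed by sample id and validate outcomes."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "rfs_months" in df and (df["rfs_months"].dropna() < 0).any():
        raise DataError("rfs_months must be non-negative")
    if "event" in df and not df["event"].dropna().isin([0, 1]).all():
        raise DataError("event flag must be 0 or 1")
    return df


def crosstab(clinical: pd.DataFrame, covariate: str,
             by: str = "subtype") -> pd.DataFrame:
    """Covariate x subtype contingency table; missing values are excluded
    row-wise, never imputed."""
    sub = clinical[[covariate, by]].dropna()
    return pd.crosstab(sub[covariate], sub[by])
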