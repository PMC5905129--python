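"""Downstream statistics on labeling indices.

Sample clustering into genotype-like groups, per-metabolite differential
labeling (two-tailed t tests at an uncorrected threshold), and chi-square
over-representation of a metabolite category among the significant hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .mid import LabelingIndexTable

__all__ = [
    "PartitionResult",
    "DifferentialLabelingResult",
    "CategoryEnrichment",
    "cluster_partition",
    "differential_labeling",
    "category_overrepresentation",
]


@dataclass
class PartitionResult:
    assignments: pd.Series  # sample -> cluster id (1..k)
    k: int
    method: str
    ari: float | None = None
    linkage_matrix: np.ndarray | None = None
    medoids: list[str] | None = None
    degenerate: bool = False


@dataclass
class DifferentialLabelingResult:
    table: pd.DataFrame  # metabolite x {mean_a, mean_b, t, p, q, significant}
    alpha: float
    groups: tuple[str, str]

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


@dataclass
class CategoryEnrichment:
    table: np.ndarray  # 2x2: rows significant/not, cols in-category/not
    chi2: float
    p: float
    df: int = 1
    correction: str = "none"
    fisher_p: float | None = None  # reported when an expected cell < 1


def _feature_matrix(table: LabelingIndexTable) -> pd.DataFrame:
    feats = table.drop_invalid()
    if feats.empty:
        raise ValueError("no metabolite has a complete row of valid indices")
    return feats


def _kmedoids(dist: np.ndarray, k: int, seed: int, n_iter: int = 100) -> np.ndarray:
    """Plain PAM-style k-medoids on a precomputed distance matrix."""
    n = dist.shape[0]
    rng = np.random.default_rng(seed)
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(n_iter):
        assign = np.argmin(dist[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue
            costs = dist[np.ix_(members, members)].sum(axis=0)
            new[c] = members[np.argmin(costs)]
        if np.array_equal(np.sort(new), np.sort(medoids)):
            break
        medoids = new
    return np.argmin(dist[:, medoids], axis=1), medoids


def cluster_partition(
    table: LabelingIndexTable,
    k: int = 2,
    method: str = "hierarchical",
    linkage_method: str = "ward",
    seed: int = 0,
    true_labels: pd.Series | Sequence | None = None,
) -> PartitionResult:
    """Cluster samples on Euclidean distance between labeling-index vectors.

    Metabolites with any invalid index are dropped listwise before the
    distance computation.  ARI against ``true_labels`` is attached when
    given.
    """
    feats = _feature_matrix(table)
    X = feats.to_numpy(dtype=float).T  # samples x metabolites
    samples = list(feats.columns)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(samples):
        raise ValueError(f"k={k} exceeds the {len(samples)} samples")
    degenerate = bool(np.allclose(X, X[0]))
    if degenerate:
        warnings.warn("all labeling vectors identical: single effective cluster", stacklevel=2)
    lm = None
    medoids = None
    if method == "hierarchical":
        lm = linkage(X, method=linkage_method, metric="euclidean")
        assign = fcluster(lm, t=k, criterion="maxclust")
    elif method == "kmedoids":
        from scipy.spatial.distance import cdist

        dist = cdist(X, X)
        assign, med_idx = _kmedoids(dist, k, seed)
        assign = assign + 1
        medoids = [samples[i] for i in med_idx]
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    assignments = pd.Series(assign, index=samples, name="cluster")
    ari = None
    if true_labels is not None:
        truth = pd.Series(true_labels)
        if set(truth.index) == set(samples):
            truth = truth.reindex(samples)
        ari = float(adjusted_rand_score(truth.to_numpy(), assignments.to_numpy()))
    return PartitionResult(
        assignments=assignments,
        k=k,
        method=method,
        ari=ari,
        linkage_matrix=lm,
        medoids=medoids,
        degenerate=degenerate,
    )


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / df
    diff = a.mean() - b.mean()
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        sp2 = 0.0
    if sp2 == 0:
        # both groups constant: identical means -> no evidence; different
        # means -> infinitely strong evidence (degenerate)
        return (0.0, 1.0) if diff == 0 else (float(np.sign(diff) * np.inf), 0.0)
    t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def differential_labeling(
    table: LabelingIndexTable,
    labels: pd.Series | Sequence,
    alpha: float = 0.05,
    welch: bool = False,
) -> DifferentialLabelingResult:
    """Two-tailed per-metabolite t tests on labeling indices.

    The significance flag uses the uncorrected p < alpha rule; BH q-values
    are reported alongside.  Metabolites are tested wherever both groups
    have >= 2 valid values.
    """
    labels = pd.Series(labels)
    if set(labels.index) == set(table.values.columns):
        labels = labels.reindex(table.values.columns)
    elif len(labels) == table.values.shape[1]:
        labels.index = table.values.columns
    else:
        raise ValueError("labels do not align with samples")
    groups = list(pd.unique(labels))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    ga, gb = groups
    rows = []
    for met in table.values.index:
        vals = table.values.loc[met]
        ok = table.valid.loc[met]
        a = vals[(labels == ga) & ok].to_numpy(dtype=float)
        b = vals[(labels == gb) & ok].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            rows.append((met, np.nan, np.nan, np.nan, np.nan, False))
            continue
        if welch:
            res = stats.ttest_ind(a, b, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
            if np.isnan(t):  # zero variance in both groups
                t, p = _pooled_t(a, b)
        else:
            t, p = _pooled_t(a, b)
        rows.append((met, a.mean(), b.mean(), t, p, bool(p < alpha)))
    out = pd.DataFrame(
        rows, columns=["metabolite", "mean_a", "mean_b", "t", "p", "significant"]
    ).set_index("metabolite")
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out = out[["mean_a", "mean_b", "t", "p", "q", "significant"]]
    return DifferentialLabelingResult(table=out, alpha=alpha, groups=(ga, gb))


def chi2_2x2(table: np.ndarray, correction: str = "none") -> tuple[float, float]:
    """Pearson chi-square (df=1) on a 2x2 table; optional Yates correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    n = t.sum()
    a, b, c, d = t.ravel()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if correction == "yates":
        diff = max(diff - n / 2, 0.0)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    chi2 = n * diff**2 / margins
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def category_overrepresentation(
    significant: Iterable[str],
    category: Iterable[str],
    universe: Iterable[str],
    correction: str = "none",
) -> CategoryEnrichment:
    """Chi-square over-representation of a category among significant hits.

    The 2x2 table is built over the universe.  If any expected cell falls
    below 1, a Fisher exact p is additionally reported with a warning.
    """
    universe = set(universe)
    significant = set(significant)
    category = set(category)
    if not significant <= universe or not category <= universe:
        raise ValueError("significant and category sets must be subsets of the universe")
    if len(universe) < 4:
        raise ValueError("universe too small")
    a = len(significant & category)
    b = len(significant - category)
    c = len(category - significant)
    d = len(universe - significant - category)
    table = np.array([[a, b], [c, d]], dtype=float)
    chi2, p = chi2_2x2(table, correction=correction)
    fisher_p = None
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 1).any():
        warnings.warn("expected cell < 1: chi-square unreliable, reporting Fisher exact too",
                      stacklevel=2)
        fisher_p = float(stats.fisher_exact(table.astype(int))[1])
    return CategoryEnrichment(table=table, chi2=chi2, p=p, correction=correction,
                              fisher_p=fisher_p)
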