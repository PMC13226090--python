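"""Compartment-frequency harmonization and cross-cohort mapping.

Pooled z-scoring of compartment frequencies across cohorts, group
aggregation, cosine similarity between group profiles (the archetype
mapping step), within-group relative variance, and Pearson/BH correlation
matrices between cell-density features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureZScores",
    "SimilarityMatrix",
    "CorrelationMatrix",
    "combined_zscore",
    "aggregate_by_group",
    "cosine_similarity_matrix",
    "relative_variance",
    "pairwise_pearson_bh",
    "hierarchical_order",
    "umap_embedding",
]


@dataclass
class FeatureZScores:
    """Frequencies z-scored with pooled per-feature moments."""

    zscores: pd.DataFrame
    feature_means: pd.Series
    feature_sds: pd.Series


@dataclass
class SimilarityMatrix:
    """Cosine similarity (and distance = 1 - similarity) between group rows."""

    similarity: pd.DataFrame
    distance: pd.DataFrame


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r with raw and BH-adjusted two-sided p-values."""

    pearson_r: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    n_used: pd.DataFrame


def combined_zscore(frequencies: pd.DataFrame | list[pd.DataFrame]) -> FeatureZScores:
    """Z-score features over the pooled samples of one or more cohorts.

    The mean and (population) standard deviation of each feature are computed
    jointly over all samples of all cohorts — not per cohort — so cohorts end
    up on a common scale.  Zero-variance features map to all-zero columns.
    """
    tables = [frequencies] if isinstance(frequencies, pd.DataFrame) else list(frequencies)
    cols = set(tables[0].columns)
    for t in tables[1:]:
        if set(t.columns) != cols:
            only_a = sorted(cols - set(t.columns))
            only_b = sorted(set(t.columns) - cols)
            raise ValueError(
                f"cohort feature mismatch: only in first {only_a}, only in other {only_b}"
            )
    pooled = pd.concat([t[tables[0].columns] for t in tables])
    means = pooled.mean()
    sds = pooled.std(ddof=0)
    z = pooled.sub(means).div(sds.replace(0.0, np.nan))
    constant = sds.index[sds == 0.0]
    if len(constant):
        warnings.warn(f"constant features mapped to zeros: {list(constant)}", stacklevel=2)
        z[constant] = 0.0
    return FeatureZScores(zscores=z, feature_means=means, feature_sds=sds)


def aggregate_by_group(
    table: pd.DataFrame, group_labels: pd.Series, statistic: str = "median"
) -> pd.DataFrame:
    """Collapse samples to one row per group by the median or mean."""
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    labels = group_labels.reindex(table.index)
    if labels.isna().any():
        missing = list(table.index[labels.isna()])[:5]
        raise ValueError(f"samples without a group label, e.g. {missing}")
    grouped = table.groupby(labels, observed=True)
    return grouped.median() if statistic == "median" else grouped.mean()


def cosine_similarity_matrix(
    rows_table: pd.DataFrame, cols_table: pd.DataFrame | None = None
) -> SimilarityMatrix:
    """Cosine similarity between the rows of two group-profile tables.

    Each row vector is normalized to unit length; the similarity matrix is
    the product of the normalized row table with the normalized column
    table's transpose.  Distance is 1 - similarity.
    """
    if cols_table is None:
        cols_table = rows_table
    if list(rows_table.columns) != list(cols_table.columns):
        raise ValueError("tables must share identical feature columns (same order)")
    for tab, side in ((rows_table, "rows"), (cols_table, "cols")):
        norms = np.linalg.norm(tab.values, axis=1)
        if np.any(norms == 0):
            bad = tab.index[norms == 0][0]
            raise ValueError(f"all-zero {side} profile for group {bad!r}")
    U = rows_table.values / np.linalg.norm(rows_table.values, axis=1, keepdims=True)
    V = cols_table.values / np.linalg.norm(cols_table.values, axis=1, keepdims=True)
    sim = pd.DataFrame(U @ V.T, index=rows_table.index, columns=cols_table.index)
    return SimilarityMatrix(similarity=sim, distance=1.0 - sim)


def relative_variance(table: pd.DataFrame, group_labels: pd.Series) -> pd.DataFrame:
    """Within-group relative variance (CV^2) per feature.

    Population variance divided by the squared group mean: a scale-free
    dispersion measure comparable across features of different magnitudes.
    Features with a zero group mean are reported as missing.
    """
    labels = group_labels.reindex(table.index)
    if labels.isna().any():
        raise ValueError("every sample needs a group label")
    counts = table.groupby(labels, observed=True).size()
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    g = table.groupby(labels, observed=True)
    var = g.var(ddof=0)
    mean = g.mean()
    return var / mean.pow(2).replace(0.0, np.nan)


def pairwise_pearson_bh(
    table: pd.DataFrame,
    feature_pairs: list[tuple[str, str]] | None = None,
) -> CorrelationMatrix:
    """Pearson correlation matrix with BH-adjusted two-sided p-values.

    Uses pairwise-complete observations (recording n per pair); p-values come
    from the t-distribution transform of r.  The BH family is all tested
    off-diagonal pairs jointly; pairs involving a constant feature are
    reported as missing and excluded from the family.
    """
    feats = list(table.columns)
    if feature_pairs is None:
        feature_pairs = [(a, b) for i, a in enumerate(feats) for b in feats[i + 1 :]]
    r = pd.DataFrame(np.eye(len(feats)), index=feats, columns=feats)
    p_raw = pd.DataFrame(np.nan, index=feats, columns=feats)
    n_used = pd.DataFrame(0, index=feats, columns=feats)
    np.fill_diagonal(p_raw.values, 0.0)
    np.fill_diagonal(n_used.values, table.notna().sum().reindex(feats).values)

    tested, pvals = [], []
    for a, b in feature_pairs:
        sub = table[[a, b]].dropna()
        n = len(sub)
        n_used.loc[a, b] = n_used.loc[b, a] = n
        if n < 3:
            raise ValueError(f"pair ({a}, {b}) has {n} complete observations; need >= 3")
        if sub[a].nunique() < 2 or sub[b].nunique() < 2:
            r.loc[a, b] = r.loc[b, a] = np.nan
            continue
        res = stats.pearsonr(sub[a], sub[b])
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p_raw.loc[a, b] = p_raw.loc[b, a] = res.pvalue
        tested.append((a, b))
        pvals.append(res.pvalue)

    p_adj = p_raw.copy()
    if pvals:
        adj = multipletests(pvals, method="fdr_bh")[1]
        for (a, b), q in zip(tested, adj):
            p_adj.loc[a, b] = p_adj.loc[b, a] = q
    return CorrelationMatrix(pearson_r=r, p_raw=p_raw, p_adjusted=p_adj, n_used=n_used)


def umap_embedding(zscores: pd.DataFrame, seed: int = 0, **kwargs) -> pd.DataFrame:
    """2-D UMAP embedding of z-scored profiles (display plumbing only).

    A seeded pass-through to umap-learn for joint visualization of cohorts on
    a shared feature scale; carries no numeric guarantees.
    """
    from umap import UMAP

    emb = UMAP(n_components=2, random_state=seed, **kwargs).fit_transform(zscores.values)
    return pd.DataFrame(emb, index=zscores.index, columns=["umap1", "umap2"])


def hierarchical_order(table: pd.DataFrame) -> list:
    """Row order from average-linkage clustering on Euclidean distances.

    Convenience for heatmap display of z-scored group profiles.
    """
    if len(table) < 3:
        return list(table.index)
    Z = average(pdist(table.values))
    return [table.index[i] for i in leaves_list(Z)]
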