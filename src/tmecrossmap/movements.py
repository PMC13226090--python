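"""Program "movements": coordinated GEP usage and survival stratification.

Percentile-based gene scores per program, Pearson/BH correlation between
T-cell and myeloid program scores across samples, quantile binning of
subjects into high/low program groups, and Kaplan-Meier / log-rank survival
comparison of the resulting strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tmecrossmap.composition import CorrelationMatrix
from tmecrossmap.matching import GeneSignature
from tmecrossmap.synthetic import SurvivalCohort

__all__ = [
    "BinnedCohort",
    "SurvivalCurves",
    "gene_score",
    "movement_correlation",
    "bin_by_quantile",
    "kaplan_meier",
    "logrank_test",
]


@dataclass
class BinnedCohort:
    """Per-subject high/low/excluded labels per program, with joint labels."""

    bins: pd.DataFrame  # subjects x programs, values in {high, low, excluded}
    joint: pd.Series  # crossed label, e.g. "T3^Hi My2^Hi"; NaN if any excluded
    thresholds: pd.DataFrame  # programs x {low, high} quantile cut values


@dataclass
class SurvivalCurves:
    """Kaplan-Meier step functions per group plus a log-rank comparison."""

    curves: dict[str, pd.DataFrame]  # group -> columns [time, survival, at_risk]
    median_survival: pd.Series
    logrank_statistic: float
    logrank_p: float


def gene_score(expression: pd.DataFrame, signature: GeneSignature | list[str]) -> pd.Series:
    """Percentile-normalized mean expression of a program's top genes.

    Each signature gene's expression is replaced by its fractional rank
    across samples (rank / n, ties averaged); the score is the mean of these
    normalized values per sample.  Rank-based, so invariant under monotone
    per-gene transformations.
    """
    genes = signature.genes if isinstance(signature, GeneSignature) else list(signature)
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 samples to rank")
    present = [g for g in genes if g in expression.index]
    if not present:
        raise ValueError("no signature genes present in the expression table")
    if len(present) < len(genes):
        warnings.warn(
            f"{len(genes) - len(present)} signature genes missing from expression; dropped",
            stacklevel=2,
        )
    ranks = expression.loc[present].rank(axis=1, method="average") / expression.shape[1]
    name = signature.program if isinstance(signature, GeneSignature) else None
    return pd.Series(ranks.mean(axis=0), name=name)


def movement_correlation(t_scores: pd.DataFrame, my_scores: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlation of every T program against every myeloid program.

    Scores are inner-joined on sample ids; two-sided p-values are BH-adjusted
    over all pairs of the matrix jointly.
    """
    shared = t_scores.index.intersection(my_scores.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    T = t_scores.loc[shared]
    M = my_scores.loc[shared]
    r = pd.DataFrame(np.nan, index=T.columns, columns=M.columns)
    p = r.copy()
    n = pd.DataFrame(len(shared), index=T.columns, columns=M.columns)
    tested, pvals = [], []
    for a in T.columns:
        for b in M.columns:
            if T[a].nunique() < 2 or M[b].nunique() < 2:
                continue
            res = stats.pearsonr(T[a], M[b])
            r.loc[a, b] = res.statistic
            p.loc[a, b] = res.pvalue
            tested.append((a, b))
            pvals.append(res.pvalue)
    p_adj = p.copy()
    if pvals:
        adj = multipletests(pvals, method="fdr_bh")[1]
        for (a, b), q in zip(tested, adj):
            p_adj.loc[a, b] = q
    return CorrelationMatrix(pearson_r=r, p_raw=p, p_adjusted=p_adj, n_used=n)


def bin_by_quantile(
    scores: pd.DataFrame,
    programs: list[str] | None = None,
    q_low: float = 0.5,
    q_high: float = 0.5,
) -> BinnedCohort:
    """Label subjects high/low per program by score quantiles.

    Scores strictly above the ``q_high`` quantile are "high", strictly below
    the ``q_low`` quantile are "low", the rest "excluded"; subjects tied with
    a threshold fall toward the lower bin, deterministically.  With
    ``q_low = q_high = 0.5`` the cohort splits into top/bottom halves; with
    0.3/0.7 the middle 40% is excluded.  Joint labels cross the per-program
    bins for subjects high or low in every requested program.
    """
    if not (0 < q_low <= q_high < 1) or q_low + (1 - q_high) > 1:
        raise ValueError("need 0 < q_low <= q_high < 1")
    progs = list(scores.columns) if programs is None else list(programs)
    bins = pd.DataFrame("excluded", index=scores.index, columns=progs)
    thr = pd.DataFrame(index=progs, columns=["low", "high"], dtype=float)
    for prog in progs:
        s = scores[prog]
        lo = s.quantile(q_low)
        hi = s.quantile(q_high)
        thr.loc[prog] = [lo, hi]
        bins.loc[s > hi, prog] = "high"
        bins.loc[s <= lo, prog] = "low"
        if (bins[prog] == "high").sum() == 0 or (bins[prog] == "low").sum() == 0:
            raise ValueError(f"program {prog}: empty high or low bin at q=({q_low}, {q_high})")
    tag = {"high": "Hi", "low": "Lo"}
    included = (bins != "excluded").all(axis=1)
    joint = pd.Series(np.nan, index=scores.index, dtype=object)
    joint[included] = bins[included].apply(
        lambda row: " ".join(f"{p}^{tag[row[p]]}" for p in progs), axis=1
    )
    return BinnedCohort(bins=bins, joint=joint, thresholds=thr)


def kaplan_meier(cohort: SurvivalCohort, groups: pd.Series) -> SurvivalCurves:
    """Product-limit survival curves per group with a log-rank comparison.

    Right-censored product-limit estimator (deaths precede censorings at tied
    times); group membership comes from ``groups`` (subjects with missing
    labels are dropped).
    """
    g = groups.reindex(cohort.time.index).dropna()
    if g.empty:
        raise ValueError("no labeled subjects")
    if cohort.event[g.index].sum() == 0:
        warnings.warn("no events among labeled subjects; curves stay at 1", stacklevel=2)
    curves: dict[str, pd.DataFrame] = {}
    medians = {}
    for label in sorted(g.unique()):
        idx = g.index[g == label]
        if len(idx) == 0:
            raise ValueError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(cohort.time[idx], cohort.event[idx], label=str(label))
        ev = kmf.event_table
        curves[str(label)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index,
                "survival": kmf.survival_function_.iloc[:, 0].values,
                "at_risk": ev["at_risk"].reindex(kmf.survival_function_.index).values,
            }
        ).reset_index(drop=True)
        medians[str(label)] = float(kmf.median_survival_time_)
    if g.nunique() >= 2:
        stat, p = logrank_test(cohort, g)
    else:
        stat, p = float("nan"), float("nan")
    return SurvivalCurves(
        curves=curves,
        median_survival=pd.Series(medians, name="median_survival"),
        logrank_statistic=stat,
        logrank_p=p,
    )


def _logrank_chi2_2group(times: np.ndarray, events: np.ndarray, in_b: np.ndarray) -> float:
    """Two-group log-rank chi-square with the hypergeometric tie correction."""
    ome = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_b = (at_risk & in_b).sum()
        d = ((times == t) & (events == 1)).sum()
        d_b = ((times == t) & (events == 1) & in_b).sum()
        ome += d_b - d * n_b / n
        if n > 1:
            var += d * (n_b / n) * (1 - n_b / n) * (n - d) / (n - 1)
    return float(ome**2 / var) if var > 0 else 0.0


def logrank_test(
    cohort: SurvivalCohort, groups: pd.Series, *, method: str = "auto", max_enumeration: int = 10000
) -> tuple[float, float]:
    """Unweighted k-group log-rank test.

    The statistic is the standard chi-square form (df = k - 1).  For two
    small groups (``method="auto"`` and at most ``max_enumeration`` distinct
    group assignments) the p-value is computed exactly by enumerating the
    permutation distribution of the statistic — the chi-square asymptotic is
    visibly miscalibrated at such sizes.  Larger cohorts (or ``k > 2``) use
    the chi-square asymptotic p.
    """
    if method not in ("auto", "asymptotic", "exact"):
        raise ValueError("method must be 'auto', 'asymptotic' or 'exact'")
    g = groups.reindex(cohort.time.index).dropna()
    if g.nunique() < 2:
        raise ValueError("need >= 2 nonempty groups")
    idx = g.index
    if cohort.event[idx].sum() == 0:
        warnings.warn("no events in any group; log-rank statistic is 0", stacklevel=2)
        return 0.0, 1.0
    res = multivariate_logrank_test(cohort.time[idx], g, cohort.event[idx])
    stat = float(res.test_statistic)

    from math import comb

    n = len(idx)
    labels = g.unique()
    n_b = int((g == labels[1]).sum()) if len(labels) == 2 else 0
    enumerable = len(labels) == 2 and comb(n, n_b) <= max_enumeration
    if method == "exact" and not enumerable:
        raise ValueError("exact p requested but the assignment space is too large or k > 2")
    if method == "asymptotic" or not enumerable:
        return stat, float(res.p_value)

    from itertools import combinations

    times = cohort.time[idx].to_numpy()
    events = cohort.event[idx].to_numpy()
    hits = total = 0
    for chosen in combinations(range(n), n_b):
        b = np.zeros(n, dtype=bool)
        b[list(chosen)] = True
        total += 1
        if _logrank_chi2_2group(times, events, b) >= stat - 1e-12:
            hits += 1
    return stat, hits / total
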