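"""Consensus NMF discovery of gene expression programs (GEPs).

The pipeline: log2 preprocessing with MAD-based gene selection; repeated
seeded NMF runs per rank; connectivity/consensus matrices; cophenetic
correlation (CCC) rank stability sweep with candidate ranks at local maxima
of the median CCC; and an outlier-pruned consensus factorization (k-means
clustering of concatenated factors, local-outlier-factor pruning, element
wise medians) yielding W_Con / H_Con.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.neighbors import LocalOutlierFactor

from tmecrossmap.nmf import NMFRun, nmf_run

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessedMatrix",
    "RankStabilityProfile",
    "GEPResult",
    "preprocess",
    "connectivity_matrix",
    "consensus_and_ccc",
    "rank_stability_sweep",
    "consensus_factorization",
    "consensus_from_runs",
]


@dataclass
class PreprocessedMatrix:
    """log2-scaled expression restricted to the most variable genes."""

    values: pd.DataFrame  # genes x samples, log2 scale, nonnegative
    selected_genes: list[str]  # ordered by MAD descending
    provenance: dict = field(default_factory=dict)


@dataclass
class RankStabilityProfile:
    """Median cophenetic correlation per rank and candidate stable ranks."""

    ranks: list[int]
    median_ccc: list[float]
    ccc_per_repeat: dict[int, list[float]]
    repeats: int
    candidate_ranks: list[int]


@dataclass
class GEPResult:
    """Consensus factorization: unit-L2 gene weights and sample usages."""

    W_con: pd.DataFrame  # genes x k, columns unit L2 norm
    H_con: pd.DataFrame  # k x samples
    k: int
    cluster_sizes: list[int]
    retained_counts: list[int]


def preprocess(expression: pd.DataFrame, n_top_genes: int = 5000) -> PreprocessedMatrix:
    """log2(x+1)-transform and keep the ``n_top_genes`` most variable genes.

    Variability is the median absolute deviation (MAD) of the log2 values
    across samples; ties are broken by gene id so the selection is
    deterministic.
    """
    if (expression.values < 0).any():
        raise ValueError("expression must be nonnegative")
    logx = np.log2(expression.astype(float) + 1.0)
    med = logx.median(axis=1)
    mad = (logx.sub(med, axis=0)).abs().median(axis=1)
    if (mad > 0).sum() < 2:
        raise ValueError("fewer than 2 genes with nonzero MAD; nothing to factorize")
    if n_top_genes > len(mad):
        warnings.warn(
            f"n_top_genes={n_top_genes} exceeds available genes ({len(mad)}); keeping all",
            stacklevel=2,
        )
    order = pd.DataFrame({"mad": mad, "gene": mad.index}).sort_values(
        ["mad", "gene"], ascending=[False, True]
    )
    keep = order["gene"].head(n_top_genes).tolist()
    return PreprocessedMatrix(
        values=logx.loc[keep],
        selected_genes=keep,
        provenance={"n_top_genes": n_top_genes, "transform": "log2(x+1)", "criterion": "MAD"},
    )


def connectivity_matrix(run: NMFRun) -> np.ndarray:
    """Binary sample x sample co-assignment matrix for one NMF run.

    A sample's factor is the argmax of its usage column (ties resolved to the
    lowest factor index); entry (i, j) is 1 iff samples i and j share a
    factor.
    """
    H = run.H
    zero = ~np.any(H > 0, axis=0)
    if zero.any():
        raise ValueError(f"all-zero usage column for sample index {int(np.flatnonzero(zero)[0])}")
    assign = np.argmax(H, axis=0)  # argmax returns the lowest index on ties
    return (assign[:, None] == assign[None, :]).astype(float)


def consensus_and_ccc(runs: list[NMFRun]) -> tuple[np.ndarray, float]:
    """Average connectivity matrices and score their cophenetic stability.

    The consensus matrix is the mean of the runs' connectivity matrices.  The
    cophenetic correlation coefficient (CCC) is the Pearson correlation
    between the condensed distances D = 1 - consensus and the cophenetic
    distances induced by average-linkage hierarchical clustering of D.  A
    perfectly reproducible partition gives a 0/1 block consensus, which is
    ultrametric, hence CCC = 1.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for a consensus matrix")
    n = runs[0].H.shape[1]
    if any(r.H.shape[1] != n for r in runs):
        raise ValueError("runs disagree on sample count")
    consensus = np.mean([connectivity_matrix(r) for r in runs], axis=0)
    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    if np.allclose(condensed, condensed[0]):
        warnings.warn("degenerate consensus (all pairwise distances equal); CCC undefined", stacklevel=2)
        return consensus, float("nan")
    Z = average(condensed)
    ccc, _ = cophenet(Z, condensed)
    return consensus, float(ccc)


def _run_seed(global_seed: int, rank: int, repeat: int, run_index: int) -> int:
    """Deterministic per-run seed below 2**31."""
    ss = np.random.SeedSequence([int(global_seed), int(rank), int(repeat), int(run_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _local_maxima(ranks: list[int], values: list[float]) -> list[int]:
    """Strict interior local maxima; a plateau contributes its leftmost rank."""
    out = []
    v = np.asarray(values, dtype=float)
    for i in range(1, len(v) - 1):
        left = v[i] > v[i - 1]
        j = i
        while j + 1 < len(v) and v[j + 1] == v[i]:  # walk over a plateau
            j += 1
        if j == len(v) - 1:
            continue  # plateau runs into the endpoint
        right = v[i] > v[j + 1]
        if left and right:
            out.append(ranks[i])
    return out


def rank_stability_sweep(
    matrix: pd.DataFrame | np.ndarray,
    ranks: range | list[int] = range(3, 31),
    runs_per_rank: int = 50,
    repeats: int = 5,
    seed: int = 0,
    *,
    max_iter: int = 200,
) -> RankStabilityProfile:
    """Sweep ranks, scoring each by the median CCC over independent repeats.

    Each repeat factorizes the matrix ``runs_per_rank`` times with distinct
    seeds, builds a consensus matrix and computes its CCC; the median over
    repeats is the rank's stability score.  Candidate ranks are the strict
    interior local maxima of the median-CCC curve (plateaus count their
    leftmost rank; endpoints are excluded).  Sweep-stage factorizations run a
    capped number of multiplicative-update iterations: factor assignments
    (argmax usages) stabilize long before the factors themselves converge.
    """
    X = np.asarray(matrix, dtype=float)
    n, m = X.shape
    usable, med, per_repeat = [], [], {}
    for k in ranks:
        if k >= min(n, m):
            warnings.warn(f"rank {k} >= min(genes, samples); skipped", stacklevel=2)
            continue
        cccs = []
        for rep in range(repeats):
            runs = [
                nmf_run(X, k, _run_seed(seed, k, rep, r), max_iter=max_iter)
                for r in range(runs_per_rank)
            ]
            _, ccc = consensus_and_ccc(runs)
            cccs.append(ccc)
        usable.append(int(k))
        per_repeat[int(k)] = cccs
        med.append(float(np.nanmedian(cccs)))
    candidates = _local_maxima(usable, med)
    if not candidates:
        warnings.warn(
            "no interior local maximum in median CCC; review endpoint ranks", stacklevel=2
        )
    return RankStabilityProfile(
        ranks=usable, median_ccc=med, ccc_per_repeat=per_repeat, repeats=repeats,
        candidate_ranks=candidates,
    )


def consensus_factorization(
    matrix: pd.DataFrame,
    k: int,
    n_runs: int = 10,
    lof_contamination: float = 0.40,
    seed: int = 0,
    *,
    cluster_on: str = "H",
    max_iter: int = 500,
) -> GEPResult:
    """Outlier-pruned consensus factorization at a chosen rank.

    Runs ``n_runs`` seeded factorizations, L2-normalizes every factor's gene
    weight vector (moving the scale into the usages), concatenates all
    ``n_runs * k`` factors, clusters them into ``k`` groups by k-means on the
    usage vectors (``cluster_on="W"`` clusters on gene weights instead),
    prunes a ``lof_contamination`` fraction of each cluster by local outlier
    factor, and takes element-wise medians of the retained members.  The
    consensus gene-weight columns are re-normalized to unit L2 norm with the
    usages rescaled accordingly.
    """
    if n_runs < 3:
        raise ValueError("n_runs must be >= 3")
    X = np.asarray(matrix, dtype=float)
    runs = [nmf_run(X, k, _run_seed(seed, k, 0, r), max_iter=max_iter) for r in range(n_runs)]
    genes = list(matrix.index) if isinstance(matrix, pd.DataFrame) else None
    samples = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else None
    return consensus_from_runs(
        runs,
        k,
        lof_contamination=lof_contamination,
        seed=seed,
        cluster_on=cluster_on,
        genes=genes,
        samples=samples,
    )


def consensus_from_runs(
    runs: list[NMFRun],
    k: int,
    lof_contamination: float = 0.40,
    seed: int = 0,
    *,
    cluster_on: str = "H",
    genes: list | None = None,
    samples: list | None = None,
) -> GEPResult:
    """Aggregate precomputed NMF runs into a consensus factorization.

    The aggregation half of :func:`consensus_factorization`: factor
    normalization, k-means clustering of the concatenated factors, local
    outlier-factor pruning (``lof_contamination=0`` disables pruning) and
    element-wise medians.  Taking the runs as input lets robustness
    experiments inject corrupted runs.
    """
    if cluster_on not in ("H", "W"):
        raise ValueError("cluster_on must be 'H' or 'W'")
    if not 0 <= lof_contamination <= 0.5:
        raise ValueError("lof_contamination must be in [0, 0.5]")
    W_parts, H_parts = [], []
    for run in runs:
        norms = np.linalg.norm(run.W, axis=0)
        norms[norms == 0] = 1.0
        W_parts.append(run.W / norms)  # unit-L2 columns
        H_parts.append(run.H * norms[:, None])  # scale moved into usages
    W_cat = np.concatenate(W_parts, axis=1)  # genes x (n_runs*k)
    H_cat = np.concatenate(H_parts, axis=0)  # (n_runs*k) x samples

    feats = H_cat if cluster_on == "H" else W_cat.T
    km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**31))
    labels = km.fit_predict(feats)

    W_cols, H_rows, sizes, retained = [], [], [], []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            raise ValueError(
                f"consensus cluster {c} is empty; try lower lof_contamination or fewer clusters"
            )
        sizes.append(int(members.size))
        keep = members
        if lof_contamination > 0 and members.size >= 2:
            n_neighbors = min(5, members.size - 1)
            lof = LocalOutlierFactor(n_neighbors=n_neighbors, contamination=lof_contamination)
            flags = lof.fit_predict(feats[members])
            kept = members[flags == 1]
            if kept.size == 0:
                raise ValueError(
                    f"cluster {c} lost all members to outlier pruning; lower lof_contamination"
                )
            keep = kept
        elif lof_contamination > 0:
            warnings.warn(f"cluster {c} has a single member; outlier pruning skipped", stacklevel=2)
        retained.append(int(keep.size))
        W_cols.append(np.median(W_cat[:, keep], axis=1))
        H_rows.append(np.median(H_cat[keep], axis=0))

    W_con = np.column_stack(W_cols)
    H_con = np.vstack(H_rows)
    norms = np.linalg.norm(W_con, axis=0)
    norms[norms == 0] = 1.0
    W_con /= norms
    H_con *= norms[:, None]

    prog = [f"GEP{j + 1}" for j in range(k)]
    return GEPResult(
        W_con=pd.DataFrame(W_con, index=genes, columns=prog),
        H_con=pd.DataFrame(H_con, index=prog, columns=samples),
        k=k,
        cluster_sizes=sizes,
        retained_counts=retained,
    )
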