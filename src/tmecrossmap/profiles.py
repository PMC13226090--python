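"""Cross-compartment expression scaling for ligand/receptor panels.

Between-sample normalization (TMM factors + counts per million,
upper-quartile), pseudobulk aggregation of single-cell expression,
per-species z-scoring across compartments, and one-to-one ortholog mapping
that puts two species' profiles on a shared gene axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompartmentProfile",
    "OrthologMap",
    "OrthologReport",
    "tmm_normalize",
    "upper_quartile_normalize",
    "pseudobulk_mean",
    "zscore_across_compartments",
    "map_orthologs",
]


@dataclass
class CompartmentProfile:
    """Gene x compartment expression table with its normalization state."""

    values: pd.DataFrame
    normalization_state: str  # raw | tmm-cpm | upper-quartile | log | zscored
    species: str = ""


@dataclass
class OrthologMap:
    """Cross-species gene correspondence with a one-to-one filtering policy."""

    pairs: list[tuple[str, str]]
    one_to_one: bool = True

    def filtered(self) -> list[tuple[str, str]]:
        """Pairs after dropping many-to-many genes (if the policy is on)."""
        if not self.one_to_one:
            return list(self.pairs)
        a_counts = pd.Series([a for a, _ in self.pairs]).value_counts()
        b_counts = pd.Series([b for _, b in self.pairs]).value_counts()
        return [
            (a, b)
            for a, b in self.pairs
            if a_counts[a] == 1 and b_counts[b] == 1
        ]

    @classmethod
    def from_tsv(cls, path, one_to_one: bool = True) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        return cls(pairs=list(df.iloc[:, :2].itertuples(index=False, name=None)), one_to_one=one_to_one)


@dataclass
class OrthologReport:
    """Bookkeeping for genes dropped during ortholog harmonization."""

    retained: int
    dropped_unmapped: int
    dropped_multi: int
    total: int


def tmm_normalize(
    counts: pd.DataFrame,
    *,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> tuple[pd.Series, pd.DataFrame]:
    """Trimmed-mean-of-M-values scaling factors and the resulting CPM table.

    The reference sample is the one whose upper-quartile (of nonzero counts)
    is closest to the mean upper-quartile.  For each sample, genes expressed
    in both sample and reference are scored by log-ratio M and average
    log-abundance A; the top/bottom ``trim_m`` of M and ``trim_a`` of A are
    trimmed and the factor is the inverse-variance-weighted mean M
    (asymptotic binomial weights), exponentiated.  Factors are rescaled to
    geometric mean 1; CPM uses factor-adjusted library sizes.
    """
    X = counts.astype(float)
    lib = X.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"all-zero samples: {bad}")

    def _uq(col: pd.Series) -> float:
        nz = col[col > 0]
        return float(np.quantile(nz, 0.75)) if len(nz) else 0.0

    uq = X.apply(_uq) / lib
    ref_name = (uq - uq.mean()).abs().idxmin()
    ref = X[ref_name].values
    ref_lib = lib[ref_name]

    log2_factors = {}
    for s in X.columns:
        obs = X[s].values
        obs_lib = lib[s]
        if s == ref_name:
            log2_factors[s] = 0.0
            continue
        ok = (obs > 0) & (ref > 0)
        o, r = obs[ok], ref[ok]
        M = np.log2((o / obs_lib) / (r / ref_lib))
        A = 0.5 * np.log2((o / obs_lib) * (r / ref_lib))
        # asymptotic binomial variance of M
        w = (obs_lib - o) / (obs_lib * o) + (ref_lib - r) / (ref_lib * r)
        finite = np.isfinite(M) & np.isfinite(A) & (w > 0)
        M, A, w = M[finite], A[finite], w[finite]
        if M.size == 0:
            log2_factors[s] = 0.0
            continue
        m_lo, m_hi = np.quantile(M, [trim_m, 1.0 - trim_m])
        a_lo, a_hi = np.quantile(A, [trim_a, 1.0 - trim_a])
        keep = (M >= m_lo) & (M <= m_hi) & (A >= a_lo) & (A <= a_hi)
        if not keep.any():
            log2_factors[s] = 0.0
            continue
        log2_factors[s] = float(np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))

    f = pd.Series({s: 2.0 ** v for s, v in log2_factors.items()})[X.columns]
    f /= np.exp(np.log(f).mean())  # geometric mean 1
    cpm = X.div(lib * f, axis=1) * 1e6
    return f, cpm


def upper_quartile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample by its 75th-percentile gene count, then log2(x+1)."""
    X = counts.astype(float)
    q75 = X.quantile(0.75, axis=0)
    if (q75 <= 0).any():
        bad = list(q75.index[q75 <= 0])
        raise ValueError(f"samples with zero 75th-percentile count: {bad}")
    return np.log2(X.div(q75, axis=1) + 1.0)


def pseudobulk_mean(
    cells: pd.DataFrame,
    compartment: pd.Series,
    sample: pd.Series | None = None,
    species: str = "",
) -> CompartmentProfile:
    """Average per-cell expression within each (compartment, sample) group.

    ``cells`` is cell x gene; the result is gene x group, where a group is a
    compartment or a (compartment, sample) pair.
    """
    comp = compartment.reindex(cells.index)
    if comp.isna().any():
        raise ValueError("every cell needs a compartment label")
    keys = [comp]
    if sample is not None:
        samp = sample.reindex(cells.index)
        if samp.isna().any():
            raise ValueError("every cell needs a sample label")
        keys.append(samp)
    means = cells.groupby(keys, observed=True).mean()
    return CompartmentProfile(values=means.T, normalization_state="raw", species=species)


def zscore_across_compartments(profile: CompartmentProfile) -> CompartmentProfile:
    """Z-score each gene over its compartment-level values (one species).

    Expects log-scale input; population standard deviation; zero-variance
    genes become all-zero rows.  This is the per-species scaling step: the
    cross-species comparison happens only after each species is scaled
    against its own compartments.
    """
    vals = profile.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0)
    z = vals.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return CompartmentProfile(values=z, normalization_state="zscored", species=profile.species)


def map_orthologs(
    profile_a: CompartmentProfile,
    profile_b: CompartmentProfile,
    ortholog_map: OrthologMap,
) -> tuple[pd.DataFrame, pd.DataFrame, OrthologReport]:
    """Restrict two species' profiles to one-to-one ortholog pairs.

    Returns the two tables re-indexed to a shared gene axis (species A gene
    ids) plus a report counting retained, unmapped and many-to-many genes of
    species A.  ``retained + dropped_unmapped + dropped_multi == total``.
    """
    if not ortholog_map.pairs:
        raise ValueError("ortholog map is empty")
    genes_a = set(profile_a.values.index)
    genes_b = set(profile_b.values.index)
    one2one = ortholog_map.filtered()
    multi_a = {a for a, _ in ortholog_map.pairs} - {a for a, _ in one2one}
    usable = [(a, b) for a, b in one2one if a in genes_a and b in genes_b]
    retained_a = {a for a, _ in usable}
    dropped_multi = len(genes_a & multi_a)
    dropped_unmapped = len(genes_a) - len(retained_a) - dropped_multi
    report = OrthologReport(
        retained=len(retained_a),
        dropped_unmapped=dropped_unmapped,
        dropped_multi=dropped_multi,
        total=len(genes_a),
    )
    if not usable:
        raise ValueError("no genes survive ortholog harmonization")
    a_idx = [a for a, _ in usable]
    b_idx = [b for _, b in usable]
    tab_a = profile_a.values.loc[a_idx]
    tab_b = profile_b.values.loc[b_idx]
    tab_b.index = a_idx  # shared gene axis named by species A
    return tab_a, tab_b, report
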