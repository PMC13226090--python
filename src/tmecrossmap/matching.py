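"""Cross-species matching of gene expression programs.

Top-gene signatures from consensus weights, Jaccard overlap between two GEP
sets after ortholog translation, and Fisher's exact significance of each
overlap over a stated gene universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tmecrossmap.gep import GEPResult
from tmecrossmap.profiles import OrthologMap

__all__ = [
    "GeneSignature",
    "MatchTable",
    "top_genes",
    "jaccard_matrix",
    "fisher_overlap_test",
]


@dataclass
class GeneSignature:
    """Top-n genes of one program, ordered by descending consensus weight."""

    program: str
    genes: list[str]
    n: int
    universe_size: int


@dataclass
class MatchTable:
    """Pairwise Jaccard indices and Fisher p-values between two GEP sets."""

    jaccard: pd.DataFrame  # rows = set A programs, cols = set B programs
    overlap: pd.DataFrame
    fisher_p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    universe_size: int


def top_genes(gep: GEPResult, n: int) -> list[GeneSignature]:
    """Per program, the ``n`` genes with highest consensus weight.

    Ties are broken by gene id; zero-weight genes never enter a signature
    (a short signature triggers a warning).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sigs = []
    universe = gep.W_con.shape[0]
    for prog in gep.W_con.columns:
        w = gep.W_con[prog]
        nz = w[w > 0]
        ordered = (
            pd.DataFrame({"w": nz, "gene": nz.index})
            .sort_values(["w", "gene"], ascending=[False, True])["gene"]
            .tolist()
        )
        if len(ordered) < n:
            warnings.warn(
                f"program {prog}: only {len(ordered)} nonzero-weight genes for n={n}",
                stacklevel=2,
            )
        sigs.append(GeneSignature(program=prog, genes=ordered[:n], n=n, universe_size=universe))
    return sigs


def fisher_overlap_test(
    sig_a: set | GeneSignature,
    sig_b: set | GeneSignature,
    universe_size: int,
    *,
    alternative: str = "two-sided",
) -> float:
    """Fisher's exact test for the overlap of two gene sets.

    The 2x2 table counts genes in both sets, in one only, and in neither,
    over a universe of ``universe_size`` eligible genes.  Two-sided p by
    summing hypergeometric outcomes no more probable than the observed one.
    """
    a = set(sig_a.genes) if isinstance(sig_a, GeneSignature) else set(sig_a)
    b = set(sig_b.genes) if isinstance(sig_b, GeneSignature) else set(sig_b)
    union = len(a | b)
    if universe_size < union:
        raise ValueError(f"universe_size={universe_size} smaller than |A ∪ B|={union}")
    n11 = len(a & b)
    n12 = len(a) - n11
    n21 = len(b) - n11
    n22 = universe_size - union
    _, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative=alternative)
    return float(p)


def jaccard_matrix(
    signatures_a: list[GeneSignature],
    signatures_b: list[GeneSignature],
    ortholog_map: OrthologMap | None = None,
    *,
    universe_size: int | None = None,
    alpha: float = 0.05,
    alternative: str = "two-sided",
    bh_correct: bool = False,
) -> MatchTable:
    """Jaccard indices and Fisher p-values between two sets of signatures.

    Set B's genes are translated through the one-to-one ortholog map (B-side
    id -> A-side id) before intersection; genes without a one-to-one ortholog
    drop out of B's signatures.  The Fisher universe defaults to the number
    of one-to-one mapped genes (or the A universe when no map is needed) —
    only genes observable in both analyses can overlap.
    """
    if not signatures_a or not signatures_b:
        raise ValueError("signatures must be nonempty")
    if ortholog_map is not None:
        translate = {b: a for a, b in ortholog_map.filtered()}
        default_universe = len(translate)
    else:
        translate = None
        default_universe = signatures_a[0].universe_size
    universe = universe_size if universe_size is not None else default_universe

    rows = [s.program for s in signatures_a]
    cols = [s.program for s in signatures_b]
    J = pd.DataFrame(np.nan, index=rows, columns=cols)
    O = pd.DataFrame(0, index=rows, columns=cols)
    P = pd.DataFrame(np.nan, index=rows, columns=cols)
    for sb in signatures_b:
        genes_b = set(sb.genes) if translate is None else {
            translate[g] for g in sb.genes if g in translate
        }
        if not genes_b:
            warnings.warn(f"program {sb.program}: empty signature after ortholog mapping", stacklevel=2)
            continue
        for sa in signatures_a:
            genes_a = set(sa.genes)
            inter = len(genes_a & genes_b)
            J.loc[sa.program, sb.program] = inter / len(genes_a | genes_b)
            O.loc[sa.program, sb.program] = inter
            P.loc[sa.program, sb.program] = fisher_overlap_test(
                genes_a, genes_b, universe, alternative=alternative
            )
    P_eff = P.copy()
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        flat = P.values.ravel()
        ok = np.isfinite(flat)
        adj = flat.copy()
        adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        P_eff = pd.DataFrame(adj.reshape(P.shape), index=rows, columns=cols)
    return MatchTable(
        jaccard=J,
        overlap=O,
        fisher_p=P_eff,
        significant=P_eff < alpha,
        alpha=alpha,
        universe_size=universe,
    )
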