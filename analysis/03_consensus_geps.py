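"""Extract consensus gene expression programs for both species at k = 6.

Runs the outlier-pruned consensus factorization (10 seeded NMF runs, k-means
clustering of concatenated factors, 40% LOF pruning, element-wise medians)
on each species and scores recovery of the planted gene-weight vectors by
Hungarian-matched cosine similarity.  Writes the top-20 gene signatures used
downstream for cross-species matching.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from tmecrossmap import io
from tmecrossmap.gep import consensus_factorization, preprocess
from tmecrossmap.matching import top_genes
from tmecrossmap.synthetic import SyntheticCohortConfig, generate_planted_gep_dataset

SEED = 2026
RESULTS = Path(__file__).resolve().parents[1] / "results"


def matched_cosine(W_true, W_est):
    A = W_true / np.linalg.norm(W_true, axis=0, keepdims=True)
    B = W_est / np.linalg.norm(W_est, axis=0, keepdims=True)
    C = A.T @ B
    ri, ci = linear_sum_assignment(-C)
    return float(C[ri, ci].mean())


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    ds = generate_planted_gep_dataset(SyntheticCohortConfig(seed=SEED))
    for species, expr, W_true in (
        ("a", ds.expression_a, ds.true_W_a),
        ("b", ds.expression_b, ds.true_W_b),
    ):
        pm = preprocess(expr, n_top_genes=1000)
        res = consensus_factorization(pm.values, k=6, seed=SEED)
        cos = matched_cosine(W_true.loc[pm.values.index].values, res.W_con.values)
        io.write_signatures(top_genes(res, 20), RESULTS / f"signatures_top20_species_{species}.tsv")
        res.H_con.T.to_csv(RESULTS / f"usages_species_{species}.tsv", sep="\t")
        print(
            f"species {species.upper()}: k=6 consensus factors, cluster sizes "
            f"{res.cluster_sizes}, retained after LOF {res.retained_counts}, "
            f"matched cosine to planted weights {cos:.3f}"
        )


if __name__ == "__main__":
    main()
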