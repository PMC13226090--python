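"""Consensus NMF: preprocessing, stability sweep and consensus factors."""

import numpy as np
import pandas as pd
import pytest

from tests.conftest import matched_cosine
from tmecrossmap.gep import (
    _local_maxima,
    connectivity_matrix,
    consensus_and_ccc,
    consensus_factorization,
    consensus_from_runs,
    preprocess,
    rank_stability_sweep,
)
from tmecrossmap.nmf import NMFRun, nmf_run


def _fake_run(H, W=None):
    H = np.asarray(H, dtype=float)
    k = H.shape[0]
    W = np.ones((3, k)) if W is None else np.asarray(W, dtype=float)
    return NMFRun(W=W, H=H, k=k, seed=0, objective=0.0)


class TestPreprocess:
    def test_log_and_mad_selection(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(
            rng.uniform(0, 100, size=(20, 10)),
            index=[f"g{i:02d}" for i in range(20)],
        )
        tab.loc["g00"] = 5.0  # constant gene: MAD 0, ranked last
        pm = preprocess(tab, n_top_genes=10)
        assert "g00" not in pm.selected_genes
        assert (pm.values.values >= 0).all()
        np.testing.assert_allclose(
            pm.values.values, np.log2(tab.loc[pm.selected_genes].values + 1)
        )

    def test_mad_hand_value_and_tie_break(self):
        # values {1,1,5} give MAD = median(|x - 1|) = 0: such genes tie at
        # zero and the tie is broken lexicographically by gene id
        tab = pd.DataFrame(
            {"s1": [1.0, 1.0, 3.0, 2.0], "s2": [1.0, 1.0, 9.0, 5.0], "s3": [5.0, 5.0, 27.0, 40.0]},
            index=["g_b", "g_c", "g_a", "g_d"],
        )
        pm = preprocess(tab, n_top_genes=3)
        assert pm.selected_genes[:2] == ["g_d", "g_a"] or pm.selected_genes[:2] == ["g_a", "g_d"]
        assert pm.selected_genes[2] == "g_b"  # zero-MAD tie: smaller id wins

    def test_requesting_too_many_genes_warns(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame(rng.uniform(0, 10, size=(5, 6)))
        with pytest.warns(UserWarning, match="keeping all"):
            pm = preprocess(tab, n_top_genes=50)
        assert len(pm.selected_genes) == 5

    def test_all_constant_raises(self):
        tab = pd.DataFrame(np.ones((4, 5)))
        with pytest.raises(ValueError, match="nonzero MAD"):
            preprocess(tab)


class TestNMFRun:
    def test_exact_rank2_recovery(self):
        rng = np.random.default_rng(2)
        W = rng.uniform(0, 1, size=(30, 2))
        H = rng.uniform(0, 1, size=(2, 20))
        X = W @ H
        # a noiseless rank-2 instance is exactly recoverable given a deep
        # enough multiplicative-update budget
        run = nmf_run(X, 2, seed=0, max_iter=5000, tol=1e-12)
        assert run.objective < 1e-6 * np.linalg.norm(X)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, size=(15, 10))
        r1 = nmf_run(X, 3, seed=5)
        r2 = nmf_run(X, 3, seed=5)
        np.testing.assert_array_equal(r1.W, r2.W)
        np.testing.assert_array_equal(r1.H, r2.H)

    def test_objective_monotone(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, size=(25, 12))
        run = nmf_run(X, 4, seed=1)
        assert (np.diff(run.objective_trace) <= 1e-9).all()

    def test_rank_out_of_range(self):
        X = np.ones((4, 5))
        with pytest.raises(ValueError, match="out of range"):
            nmf_run(X, 4, seed=0)
        with pytest.raises(ValueError, match="out of range"):
            nmf_run(X, 1, seed=0)

    def test_nonnegative_factors(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, size=(20, 10))
        run = nmf_run(X, 3, seed=2)
        assert (run.W >= 0).all() and (run.H >= 0).all()


class TestConnectivity:
    def test_same_factor_all_ones(self):
        H = [[5.0, 4.0, 3.0], [1.0, 1.0, 1.0]]
        np.testing.assert_array_equal(connectivity_matrix(_fake_run(H)), np.ones((3, 3)))

    def test_different_factors_zero(self):
        H = [[5.0, 1.0], [1.0, 5.0]]
        C = connectivity_matrix(_fake_run(H))
        assert C[0, 1] == 0 and C[0, 0] == 1 and C[1, 1] == 1

    def test_tie_goes_to_lowest_factor(self):
        H = [[2.0, 2.0], [2.0, 1.0]]
        C = connectivity_matrix(_fake_run(H))
        assert C[0, 1] == 1  # both assigned to factor 0

    def test_zero_usage_column_raises(self):
        H = [[1.0, 0.0], [1.0, 0.0]]
        with pytest.raises(ValueError, match="sample index 1"):
            connectivity_matrix(_fake_run(H))


class TestConsensusAndCCC:
    def test_average_of_connectivities(self):
        same = _fake_run([[5.0, 5.0], [1.0, 1.0]])
        diff = _fake_run([[5.0, 1.0], [1.0, 5.0]])
        consensus, _ = consensus_and_ccc([same, same, same, diff, diff])
        assert consensus[0, 1] == pytest.approx(0.6)

    def test_stable_partition_gives_ccc_one(self):
        runs = [_fake_run([[5, 5, 1, 1], [1, 1, 5, 5]]) for _ in range(4)]
        consensus, ccc = consensus_and_ccc(runs)
        assert set(np.unique(consensus)) <= {0.0, 1.0}
        assert ccc == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_consensus_returns_nan(self):
        runs = [
            _fake_run([[5, 5, 1], [1, 1, 5]]),
            _fake_run([[5, 1, 5], [1, 5, 1]]),
            _fake_run([[1, 5, 5], [5, 1, 1]]),
        ]
        # every pair co-clusters in exactly 1 of 3 runs -> all distances equal
        with pytest.warns(UserWarning, match="degenerate"):
            consensus, ccc = consensus_and_ccc(runs)
        off = consensus[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0])
        assert np.isnan(ccc)

    def test_consensus_matrix_invariants(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, size=(40, 25))
        runs = [nmf_run(X, 3, seed=s, max_iter=50) for s in range(5)]
        consensus, _ = consensus_and_ccc(runs)
        np.testing.assert_allclose(consensus, consensus.T)
        np.testing.assert_allclose(np.diag(consensus), 1.0)
        assert (consensus >= 0).all() and (consensus <= 1).all()


class TestLocalMaxima:
    def test_interior_maxima(self):
        assert _local_maxima([3, 4, 5, 6, 7], [0.80, 0.95, 0.85, 0.90, 0.70]) == [4, 6]

    def test_strictly_decreasing_none(self):
        assert _local_maxima([3, 4, 5], [0.9, 0.8, 0.7]) == []

    def test_plateau_leftmost(self):
        assert _local_maxima([3, 4, 5, 6], [0.8, 0.9, 0.9, 0.7]) == [4]

    def test_plateau_into_endpoint_excluded(self):
        assert _local_maxima([3, 4, 5, 6], [0.8, 0.9, 0.9, 0.9]) == []


class TestRankSweep:
    def test_sweep_contract_on_small_data(self, small_dataset):
        X = preprocess(small_dataset.expression_a, n_top_genes=300).values
        prof = rank_stability_sweep(
            X, ranks=range(3, 7), runs_per_rank=5, repeats=2, seed=0, max_iter=60
        )
        assert prof.ranks == [3, 4, 5, 6]
        assert len(prof.median_ccc) == 4
        assert all(len(v) == 2 for v in prof.ccc_per_repeat.values())
        assert all(-1 <= c <= 1 for c in prof.median_ccc)
        assert set(prof.candidate_ranks) <= set(prof.ranks)

    def test_oversized_rank_skipped(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, size=(30, 8))
        with pytest.warns(UserWarning, match="skipped"):
            prof = rank_stability_sweep(
                X, ranks=[3, 9], runs_per_rank=3, repeats=2, seed=0, max_iter=30
            )
        assert prof.ranks == [3]


class TestConsensusFactorization:
    def test_identical_runs_equal_single_run(self):
        rng = np.random.default_rng(8)
        W = rng.uniform(0, 1, size=(30, 3))
        H = rng.uniform(0, 1, size=(3, 20))
        run = nmf_run(W @ H, 3, seed=1)
        norms = np.linalg.norm(run.W, axis=0)
        res = consensus_from_runs([run] * 5, 3, lof_contamination=0.0)
        got = res.W_con.values
        expect = run.W / norms
        assert matched_cosine(expect, got) == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_planted_recovery(self):
        rng = np.random.default_rng(9)
        W = np.zeros((60, 3))
        for j in range(3):
            W[j * 20 : (j + 1) * 20, j] = rng.uniform(1, 3, size=20)
        H = rng.gamma(2.0, 1.0, size=(3, 40))
        X = pd.DataFrame(W @ H)
        res = consensus_factorization(X, k=3, seed=0)
        assert matched_cosine(W, res.W_con.values) >= 0.99

    def test_unit_l2_columns_and_nonnegativity(self, small_dataset):
        X = preprocess(small_dataset.expression_a, n_top_genes=300).values
        res = consensus_factorization(X, k=4, seed=1, max_iter=200)
        np.testing.assert_allclose(np.linalg.norm(res.W_con.values, axis=0), 1.0, atol=1e-9)
        assert (res.W_con.values >= 0).all() and (res.H_con.values >= 0).all()
        assert res.k == 4
        assert len(res.cluster_sizes) == 4
        assert all(r <= s for r, s in zip(res.retained_counts, res.cluster_sizes))

    def test_input_scale_invariance(self, small_dataset):
        """Scaling the matrix leaves W_con unchanged and scales H_con."""
        X = preprocess(small_dataset.expression_a, n_top_genes=300).values
        r1 = consensus_factorization(X, k=4, seed=2, max_iter=200)
        r2 = consensus_factorization(X * 3.0, k=4, seed=2, max_iter=200)
        # same seed stream, scaled input: multiplicative updates commute with
        # positive scaling up to the (scale-free) initialization magnitude
        assert matched_cosine(r1.W_con.values, r2.W_con.values) == pytest.approx(1.0, abs=1e-6)
        ratio = r2.H_con.values.sum() / r1.H_con.values.sum()
        assert ratio == pytest.approx(3.0, rel=1e-3)

    def test_lof_pruning_recovers_from_corrupted_run(self, small_dataset):
        """A sample-permuted run degrades the consensus less with pruning."""
        X = preprocess(small_dataset.expression_a, n_top_genes=300).values
        Wt = small_dataset.true_W_a.loc[X.index].values
        gains = []
        for seed in range(3):
            runs = [nmf_run(X.values, 4, seed=100 * seed + r, max_iter=200) for r in range(10)]
            rng = np.random.default_rng(seed)
            perm = rng.permutation(X.shape[1])
            bad = runs[0]
            runs[0] = NMFRun(W=bad.W, H=bad.H[:, perm], k=4, seed=bad.seed, objective=bad.objective)
            with_prune = consensus_from_runs(runs, 4, lof_contamination=0.4, seed=seed)
            no_prune = consensus_from_runs(runs, 4, lof_contamination=0.0, seed=seed)
            gains.append(
                matched_cosine(Wt, with_prune.W_con.values)
                - matched_cosine(Wt, no_prune.W_con.values)
            )
        assert np.mean(gains) >= 0

    def test_too_few_runs_rejected(self, small_dataset):
        X = preprocess(small_dataset.expression_a, n_top_genes=100).values
        with pytest.raises(ValueError, match="n_runs"):
            consensus_factorization(X, k=3, n_runs=2)
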