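"""Nonnegative matrix factorization by multiplicative updates.

Minimal Frobenius-loss NMF solver used as the inner engine of the consensus
pipeline.  Multiplicative updates (Lee & Seung) with seeded uniform random
nonnegative initialization: deterministic in the seed, objective monotone
non-increasing, and the solver is swappable behind :func:`nmf_run`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NMFRun", "nmf_run"]

_EPS = 1e-12


@dataclass
class NMFRun:
    """One NMF factorization X ~ W @ H.

    Attributes
    ----------
    W : (n_genes, k) nonnegative gene weights.
    H : (k, n_samples) nonnegative sample usages.
    k : factorization rank.
    seed : seed used for initialization.
    objective : final Frobenius reconstruction error ||X - WH||_F.
    objective_trace : error at each monitoring step (monotone non-increasing).
    n_iter : iterations actually run.
    """

    W: np.ndarray
    H: np.ndarray
    k: int
    seed: int
    objective: float
    objective_trace: list[float] = field(default_factory=list, repr=False)
    n_iter: int = 0


def nmf_run(
    matrix: np.ndarray,
    k: int,
    seed: int,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    check_every: int = 10,
) -> NMFRun:
    """Factorize a nonnegative matrix at rank ``k``.

    Parameters
    ----------
    matrix : (n_genes, n_samples) nonnegative array.
    k : rank; must satisfy ``2 <= k < min(matrix.shape)``.
    seed : seed for the random nonnegative initialization.
    max_iter : iteration cap.
    tol : relative decrease of the objective between monitoring steps below
        which the run stops.
    check_every : iterations between objective evaluations.

    Returns
    -------
    NMFRun with W, H >= 0 and the objective trace.
    """
    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if np.any(X < 0):
        raise ValueError("NMF input must be nonnegative")
    n, m = X.shape
    if not (2 <= k < min(n, m)):
        raise ValueError(f"rank k={k} out of range [2, {min(n, m) - 1}] for shape {X.shape}")

    rng = np.random.default_rng(seed)
    # uniform init scaled to the data magnitude so W@H starts near X in scale
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    W = rng.uniform(_EPS, 1.0, size=(n, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, m)) * scale

    norm_X = np.linalg.norm(X)
    trace: list[float] = []
    prev = np.inf
    n_iter = 0
    for it in range(1, max_iter + 1):
        # H <- H * (W^T X) / (W^T W H)
        WtX = W.T @ X
        WtWH = (W.T @ W) @ H
        H *= WtX / np.maximum(WtWH, _EPS)
        # W <- W * (X H^T) / (W H H^T)
        XHt = X @ H.T
        WHHt = W @ (H @ H.T)
        W *= XHt / np.maximum(WHHt, _EPS)
        n_iter = it
        if it % check_every == 0 or it == max_iter:
            err = np.linalg.norm(X - W @ H)
            trace.append(err)
            if prev - err <= tol * max(norm_X, _EPS):
                break
            prev = err

    objective = trace[-1] if trace else float(np.linalg.norm(X - W @ H))
    return NMFRun(W=W, H=H, k=k, seed=seed, objective=float(objective), objective_trace=trace, n_iter=n_iter)
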