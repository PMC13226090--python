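"""Synthetic cohorts with planted ground truth.

Generators for every input the cross-species pipeline consumes:

* two-species expression matrices with shared and species-specific planted
  gene expression programs (GEPs) under nonnegative noise;
* archetype-structured compartment-frequency cohorts (immune-rich /
  immune-desert bimodality with a macrophage-biased "mouse-like" group);
* survival cohorts whose hazard depends on planted program scores.

All generators are deterministic in their seed: the same seed reproduces the
dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticCohortConfig",
    "PlantedGEPDataset",
    "FrequencyCohort",
    "SurvivalCohort",
    "generate_planted_gep_dataset",
    "generate_frequency_cohort",
    "generate_survival_cohort",
    "default_archetype_centroids",
    "mouse_like_centroids",
    "COMPARTMENT_FEATURES",
]

#: The ten cellular-compartment frequency features the composition analyses use.
COMPARTMENT_FEATURES = [
    "cd8_t",
    "cd4_conv_t",
    "treg",
    "b_cell",
    "nk_cell",
    "macrophage",
    "monocyte",
    "cdc1",
    "cdc2",
    "stroma_tumor",
]


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Configuration for a two-species planted-GEP expression dataset.

    ``k_shared`` of the ``k_true`` programs are planted in both species with
    ortholog-corresponding marker genes; the rest are species-specific with
    disjoint marker sets.  ``noise_scale`` is the noise magnitude relative to
    the mean signal (gaussian-clipped) or the overdispersion scale (poisson).
    """

    n_genes: int = 1000
    n_samples_a: int = 200
    n_samples_b: int = 200
    k_true: int = 6
    k_shared: int = 3
    noise_model: str = "gaussian-clipped"
    noise_scale: float = 0.5
    markers_per_program: int = 30
    unmapped_fraction: float = 0.05
    multi_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_shared > self.k_true:
            raise ValueError(f"k_shared={self.k_shared} exceeds k_true={self.k_true}")
        if min(self.n_genes, self.n_samples_a, self.n_samples_b, self.k_true) <= 0:
            raise ValueError("counts must be positive")
        if self.noise_model not in ("gaussian-clipped", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        needed = (2 * self.k_true - self.k_shared) * self.markers_per_program
        if needed > self.n_genes:
            raise ValueError(
                f"need {needed} marker genes for disjoint programs but only {self.n_genes} genes"
            )


@dataclass
class PlantedGEPDataset:
    """Two-species expression matrices with known factorization ground truth."""

    expression_a: pd.DataFrame  # genes x samples, species A
    expression_b: pd.DataFrame
    true_W_a: pd.DataFrame  # genes x k_true
    true_W_b: pd.DataFrame
    true_H_a: pd.DataFrame  # k_true x samples
    true_H_b: pd.DataFrame
    shared_program_ids: list[int]
    ortholog_map: list[tuple[str, str]]
    config: SyntheticCohortConfig
    seed: int


@dataclass
class FrequencyCohort:
    """Sample x feature compartment fractions drawn around group centroids."""

    frequencies: pd.DataFrame  # samples x features, rows sum to 1
    group_labels: pd.Series
    centroids: pd.DataFrame  # groups x features


@dataclass
class SurvivalCohort:
    """Right-censored survival outcomes with per-subject program scores."""

    time: pd.Series
    event: pd.Series
    scores: pd.DataFrame
    true_log_hazard_coefficients: pd.Series


def _program_weights(
    rng: np.random.Generator,
    n_genes: int,
    marker_blocks: list[np.ndarray],
    marker_weights: list[np.ndarray],
) -> np.ndarray:
    """Assemble a gene x k weight matrix: low background + exclusive markers."""
    k = len(marker_blocks)
    W = rng.uniform(0.0, 0.05, size=(n_genes, k))
    for j, (idx, wts) in enumerate(zip(marker_blocks, marker_weights)):
        W[idx, j] = wts
    return W


def _sparse_usages(rng: np.random.Generator, k: int, n_samples: int) -> np.ndarray:
    """Gamma usages with a per-sample mask: 1-3 active programs each.

    One primary program dominates each sample (cycled so every program is
    represented), with up to two secondary programs at lower usage; the rest
    is low background.  Program dominance is what makes the planted rank a
    stable consensus partition.
    """
    H = rng.gamma(shape=2.0, scale=0.02, size=(k, n_samples))
    for s in range(n_samples):
        primary = s % k
        H[primary, s] = rng.gamma(shape=3.0, scale=1.0) + 1.0
        n_secondary = rng.integers(0, 3)
        if n_secondary:
            others = [j for j in range(k) if j != primary]
            secondary = rng.choice(others, size=n_secondary, replace=False)
            H[secondary, s] = rng.gamma(shape=2.0, scale=0.15, size=n_secondary)
    return H


def _add_noise(rng: np.random.Generator, X: np.ndarray, model: str, scale: float) -> np.ndarray:
    if scale == 0:
        return X.copy()
    if model == "gaussian-clipped":
        noise = rng.normal(0.0, scale * X.mean(), size=X.shape)
        return np.clip(X + noise, 0.0, None)
    # poisson: counts at mean X/scale, rescaled, so variance grows with scale
    return scale * rng.poisson(np.clip(X / scale, 0, None)).astype(np.float64)


def generate_planted_gep_dataset(config: SyntheticCohortConfig) -> PlantedGEPDataset:
    """Generate a two-species expression dataset with planted programs.

    The first ``k_shared`` programs are planted in both species: their marker
    genes occupy the same gene indices with identical weights, so after
    ortholog mapping their top-gene sets coincide exactly (ground-truth
    Jaccard 1).  Species-specific programs use disjoint marker blocks, also
    disjoint between species.  A configurable fraction of non-marker genes is
    left out of the ortholog map or mapped many-to-many to exercise the
    one-to-one filtering policy downstream.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    m = cfg.markers_per_program

    genes_a = [f"g{i + 1:04d}_a" for i in range(cfg.n_genes)]
    genes_b = [f"g{i + 1:04d}_b" for i in range(cfg.n_genes)]
    samples_a = [f"sA{j + 1:03d}" for j in range(cfg.n_samples_a)]
    samples_b = [f"sB{j + 1:03d}" for j in range(cfg.n_samples_b)]
    programs = [f"P{j + 1}" for j in range(cfg.k_true)]

    # disjoint marker blocks: shared programs first, then A-specific, then
    # B-specific, laid out over non-overlapping gene index ranges
    blocks = [np.arange(j * m, (j + 1) * m) for j in range(2 * cfg.k_true - cfg.k_shared)]
    shared_blocks = blocks[: cfg.k_shared]
    a_specific = blocks[cfg.k_shared : cfg.k_true]
    b_specific = blocks[cfg.k_true :]

    # identical marker weights in both species for shared programs, so the
    # within-program gene ranking corresponds under the ortholog map
    shared_wts = [np.sort(rng.uniform(2.0, 6.0, size=m))[::-1] for _ in range(cfg.k_shared)]
    a_wts = shared_wts + [rng.uniform(2.0, 6.0, size=m) for _ in a_specific]
    b_wts = [w.copy() for w in shared_wts] + [rng.uniform(2.0, 6.0, size=m) for _ in b_specific]

    W_a = _program_weights(rng, cfg.n_genes, shared_blocks + a_specific, a_wts)
    W_b = _program_weights(rng, cfg.n_genes, shared_blocks + b_specific, b_wts)
    H_a = _sparse_usages(rng, cfg.k_true, cfg.n_samples_a)
    H_b = _sparse_usages(rng, cfg.k_true, cfg.n_samples_b)

    X_a = _add_noise(rng, W_a @ H_a, cfg.noise_model, cfg.noise_scale)
    X_b = _add_noise(rng, W_b @ H_b, cfg.noise_model, cfg.noise_scale)

    # ortholog map: (g_i_a, g_i_b) for every gene, minus an unmapped fraction,
    # plus many-to-many pairs; shared-program markers are always kept clean
    protected = set(np.concatenate(shared_blocks).tolist()) if cfg.k_shared else set()
    free = np.array([i for i in range(cfg.n_genes) if i not in protected])
    rng.shuffle(free)
    n_unmapped = int(round(cfg.unmapped_fraction * cfg.n_genes))
    n_multi = int(round(cfg.multi_fraction * cfg.n_genes))
    unmapped = set(free[:n_unmapped].tolist())
    multi = free[n_unmapped : n_unmapped + n_multi]
    pairs = [(genes_a[i], genes_b[i]) for i in range(cfg.n_genes) if i not in unmapped]
    for i, j in zip(multi, np.roll(multi, 1)):
        if i != j:
            pairs.append((genes_a[i], genes_b[j]))  # makes gene_a i many-to-many

    return PlantedGEPDataset(
        expression_a=pd.DataFrame(X_a, index=genes_a, columns=samples_a),
        expression_b=pd.DataFrame(X_b, index=genes_b, columns=samples_b),
        true_W_a=pd.DataFrame(W_a, index=genes_a, columns=programs),
        true_W_b=pd.DataFrame(W_b, index=genes_b, columns=programs),
        true_H_a=pd.DataFrame(H_a, index=programs, columns=samples_a),
        true_H_b=pd.DataFrame(H_b, index=programs, columns=samples_b),
        shared_program_ids=list(range(cfg.k_shared)),
        ortholog_map=pairs,
        config=cfg,
        seed=cfg.seed,
    )


def default_archetype_centroids() -> pd.DataFrame:
    """Compartment-frequency centroids for five recurrent human TME archetypes.

    Immune-rich archetypes carry high lymphocyte fractions; immune-desert
    archetypes are dominated by macrophages or by the stroma/tumor bulk,
    reproducing the rich/poor bimodality of total immune infiltration.
    """
    rows = {
        "immune_rich_cd8": [0.22, 0.12, 0.05, 0.08, 0.05, 0.08, 0.05, 0.03, 0.04, 0.28],
        "immune_rich_cd4": [0.08, 0.22, 0.10, 0.08, 0.04, 0.08, 0.05, 0.03, 0.06, 0.26],
        "immune_stromal": [0.06, 0.07, 0.04, 0.04, 0.03, 0.07, 0.05, 0.02, 0.04, 0.58],
        "immune_desert_mac": [0.02, 0.02, 0.01, 0.01, 0.01, 0.30, 0.09, 0.02, 0.04, 0.48],
        "immune_desert_low": [0.01, 0.02, 0.01, 0.01, 0.01, 0.05, 0.04, 0.01, 0.02, 0.82],
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=COMPARTMENT_FEATURES)


def mouse_like_centroids() -> pd.DataFrame:
    """Centroids for synthetic mouse tumor-model groups.

    Most models are macrophage-biased and poorly infiltrated (near the
    immune-desert macrophage-rich archetype); one outlier model is highly
    infiltrated and CD4/myeloid-biased.
    """
    rows = {
        "model_mc38": [0.03, 0.02, 0.01, 0.01, 0.02, 0.32, 0.08, 0.02, 0.03, 0.46],
        "model_b16": [0.02, 0.01, 0.01, 0.01, 0.01, 0.27, 0.10, 0.02, 0.04, 0.51],
        "model_ct26": [0.04, 0.03, 0.02, 0.01, 0.02, 0.29, 0.07, 0.02, 0.04, 0.46],
        "model_renca": [0.06, 0.16, 0.12, 0.03, 0.03, 0.14, 0.08, 0.04, 0.08, 0.26],
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=COMPARTMENT_FEATURES)


def generate_frequency_cohort(
    centroids: pd.DataFrame,
    n_per_group: int,
    concentration: float = 100.0,
    seed: int = 0,
) -> FrequencyCohort:
    """Draw compositional samples around each group centroid.

    Per-sample frequencies are Dirichlet draws with parameter
    ``concentration * centroid``; larger concentration gives tighter groups.
    Rows sum to 1 exactly (compositional draws).
    """
    cents = centroids.astype(float)
    if (cents.values < 0).any():
        bad = cents.index[(cents.values < 0).any(axis=1)][0]
        raise ValueError(f"centroid row {bad!r} has a negative entry")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    cents = cents.div(cents.sum(axis=1), axis=0)  # ensure valid compositions

    rng = np.random.default_rng(seed)
    frames, labels = [], []
    for group, row in cents.iterrows():
        alpha = np.clip(row.values * concentration, 1e-6, None)
        draws = rng.dirichlet(alpha, size=n_per_group)
        idx = [f"{group}_s{i + 1:03d}" for i in range(n_per_group)]
        frames.append(pd.DataFrame(draws, index=idx, columns=cents.columns))
        labels.extend([group] * n_per_group)
    frequencies = pd.concat(frames)
    return FrequencyCohort(
        frequencies=frequencies,
        group_labels=pd.Series(labels, index=frequencies.index, name="group"),
        centroids=cents,
    )


def generate_survival_cohort(
    scores: pd.DataFrame,
    coefficients: dict[str, float] | pd.Series,
    baseline_hazard: float = 0.1,
    censor_rate: float = 0.0,
    seed: int = 0,
) -> SurvivalCohort:
    """Simulate right-censored survival under a proportional-hazards model.

    Event times are exponential with per-subject rate
    ``baseline_hazard * exp(sum(coef * score))``.  Censoring times are
    exponential with a per-subject rate chosen so each subject is censored
    with probability ``censor_rate``, independent of its event time.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    coefs = pd.Series(coefficients, dtype=float)
    missing = coefs.index.difference(scores.columns)
    if len(missing):
        raise ValueError(f"coefficients refer to unknown score columns: {list(missing)}")

    rng = np.random.default_rng(seed)
    lin = scores[coefs.index].values @ coefs.values
    rate = baseline_hazard * np.exp(lin)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        # Exp censoring at rate c with c/(c+rate) = censor_rate per subject
        c = rate * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(len(t_event), dtype=int)
        time = t_event
    return SurvivalCohort(
        time=pd.Series(time, index=scores.index, name="time"),
        event=pd.Series(event, index=scores.index, name="event"),
        scores=scores.copy(),
        true_log_hazard_coefficients=coefs,
    )
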