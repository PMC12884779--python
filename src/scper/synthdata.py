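"""Synthetic single-cell count data with known structure and confounders.

Emulates a multi-study reference setting: several cell types distinguished by
marker genes, overlaid with a batch effect (a multiplicative fold on a fixed
gene subset) strong enough that the batch is decodable from raw expression.
Counts are negative binomial with a shared dispersion and log-normal per-cell
library-size factors. Every draw is reproducible from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import GeneByCellCounts


@dataclass
class SyntheticSpec:
    """Generative settings for a synthetic reference.

    Defaults describe a two-batch, four-type dataset of ~3,000 cells and
    2,000 genes: 50 markers per type at 4-fold elevation, 300 batch-affected
    genes at 4-fold between batches (enough that a linear classifier reads the
    batch off raw data), negative-binomial dispersion 0.2 and library-size
    factors log-normal with sigma 0.35.
    """

    n_genes: int = 2000
    cell_types: dict[str, int] = field(
        default_factory=lambda: {"typeA": 750, "typeB": 750, "typeC": 750, "typeD": 750}
    )
    n_marker_genes_per_type: int = 50
    marker_fold_change: float = 4.0
    batches: dict[str, float] = field(default_factory=lambda: {"batch1": 0.5, "batch2": 0.5})
    batch_effect_genes: int = 300
    batch_effect_fold: float = 4.0
    nb_dispersion: float = 0.2
    base_mean_range: tuple[float, float] = (0.05, 3.0)
    library_size_lognormal: tuple[float, float] = (0.0, 0.35)
    n_patients: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or any(n < 1 for n in self.cell_types.values()):
            raise ValueError("gene and cell counts must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        lo, hi = self.base_mean_range
        if not (0 < lo <= hi):
            raise ValueError("base_mean_range must be positive and ordered")
        if abs(sum(self.batches.values()) - 1.0) > 1e-9:
            raise ValueError("batch assignment fractions must sum to 1")
        if self.n_marker_genes_per_type * len(self.cell_types) > self.n_genes:
            raise ValueError("not enough genes for disjoint marker sets")


def generate_sc(spec: SyntheticSpec) -> GeneByCellCounts:
    """Draw a gene-by-cell negative-binomial count matrix per ``spec``.

    Per gene g and cell j the mean is
    ``base_g * marker_fold(type_j, g) * batch_fold(batch_j, g) * s_j`` with
    s_j a log-normal library-size factor; counts are NB(mean, dispersion)
    with variance mean + dispersion * mean^2.
    """
    rng = np.random.default_rng(spec.seed)
    types = list(spec.cell_types)
    n_cells = sum(spec.cell_types.values())

    lo, hi = spec.base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_genes))

    # disjoint marker blocks, one per type, then a batch-effect block drawn
    # from the remaining genes (may be empty)
    perm = rng.permutation(spec.n_genes)
    markers = {
        t: perm[i * spec.n_marker_genes_per_type : (i + 1) * spec.n_marker_genes_per_type]
        for i, t in enumerate(types)
    }
    rest = perm[len(types) * spec.n_marker_genes_per_type :]
    batch_genes = rest[: min(spec.batch_effect_genes, len(rest))]

    cell_type = np.concatenate([[t] * n for t, n in spec.cell_types.items()]).astype(object)
    batch_labels = list(spec.batches)
    batch = rng.choice(
        batch_labels, size=n_cells, p=np.array(list(spec.batches.values()))
    ).astype(object)
    patient = np.array(
        [f"P{rng.integers(spec.n_patients)}" for _ in range(n_cells)], dtype=object
    )
    size_factor = rng.lognormal(*spec.library_size_lognormal, size=n_cells)

    mean = np.tile(base[:, None], (1, n_cells))
    for t in types:
        mean[np.ix_(markers[t], cell_type == t)] *= spec.marker_fold_change
    # fold applied to the second..kth batches relative to the first
    for b in batch_labels[1:]:
        mean[np.ix_(batch_genes, batch == b)] *= spec.batch_effect_fold
    mean *= size_factor[None, :]

    # NB(mean mu, dispersion a): gamma-Poisson with shape 1/a, scale a*mu
    shape = 1.0 / spec.nb_dispersion
    lam = rng.gamma(shape, mean / shape)
    counts = rng.poisson(lam).astype(float)

    return GeneByCellCounts(
        gene_ids=np.array([f"gene{i:05d}" for i in range(spec.n_genes)], dtype=object),
        cell_ids=np.array([f"cell{j:05d}" for j in range(n_cells)], dtype=object),
        counts=counts,
        cell_type=cell_type,
        batch=batch,
        patient=patient,
    )


def make_mixture_latents(
    reference: np.ndarray,
    proportions: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Convex combination of reference rows plus Gaussian noise.

    Oracle input for proportion-estimation tests: with ``noise_sd = 0`` the
    result is exactly ``proportions @ reference``.
    """
    R = np.asarray(reference, dtype=float)
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or len(p) != R.shape[0]:
        raise ValueError(f"proportions length {p.shape} does not match {R.shape[0]} types")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("proportions must be non-negative and sum to 1")
    out = p @ R
    if noise_sd > 0:
        out = out + np.random.default_rng(seed).normal(0.0, noise_sd, size=R.shape[1])
    return out
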