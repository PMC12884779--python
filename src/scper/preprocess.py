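"""Single-cell reference and bulk preprocessing.

Quality control, library-size normalization (counts-per-10k + log1p),
highly-variable-gene selection by standardized dispersion, gene-panel
intersection with the bulk cohort, stratified subsampling of cells, and
graph-diffusion (MAGIC-style) imputation.

All expression matrices are genes-as-rows, cells/samples-as-columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess


class PreprocessError(ValueError):
    """Raised when a preprocessing step produces an empty or invalid result."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GeneByCellCounts:
    """Raw single-cell count matrix with per-cell annotations.

    Parameters
    ----------
    gene_ids : array of str
        Unique gene identifiers, one per matrix row.
    cell_ids : array of str
        Unique cell identifiers, one per matrix column.
    counts : ndarray, shape (n_genes, n_cells)
        Non-negative counts.
    cell_type, batch, tissue : arrays of str, length n_cells
        Per-cell annotations. ``tissue`` defaults to a single dummy label.
    patient : array of str or None
        Optional per-cell donor/patient label.
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    counts: np.ndarray
    cell_type: np.ndarray
    batch: np.ndarray
    tissue: np.ndarray | None = None
    patient: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if sparse.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")
        if self.tissue is None:
            self.tissue = np.array(["tissue0"] * self.n_cells, dtype=object)
        for name in ("cell_type", "batch", "tissue"):
            vec = np.asarray(getattr(self, name), dtype=object)
            if len(vec) != self.n_cells:
                raise ValueError(f"{name} has length {len(vec)}, expected {self.n_cells}")
            setattr(self, name, vec)
        if self.patient is not None:
            self.patient = np.asarray(self.patient, dtype=object)
            if len(self.patient) != self.n_cells:
                raise ValueError("patient annotation length mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_cells(self, idx: np.ndarray) -> "GeneByCellCounts":
        return GeneByCellCounts(
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
            counts=self.counts[:, idx],
            cell_type=self.cell_type[idx],
            batch=self.batch[idx],
            tissue=self.tissue[idx],
            patient=None if self.patient is None else self.patient[idx],
        )

    def subset_genes(self, idx: np.ndarray) -> "GeneByCellCounts":
        return replace(self, gene_ids=self.gene_ids[idx], counts=self.counts[idx, :])

    def reindex_genes(self, gene_ids: np.ndarray) -> "GeneByCellCounts":
        """Reorder/restrict rows to ``gene_ids`` (all must be present)."""
        pos = pd.Index(self.gene_ids).get_indexer(gene_ids)
        if (pos < 0).any():
            missing = np.asarray(gene_ids)[pos < 0][:5]
            raise KeyError(f"genes not in matrix: {list(missing)}")
        return self.subset_genes(pos)


@dataclass
class BulkExpressionMatrix:
    """Bulk expression table, genes x samples, non-negative."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape inconsistent with ids")
        if (self.values < 0).any():
            raise ValueError("bulk expression must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def reindex_genes(self, gene_ids: np.ndarray) -> "BulkExpressionMatrix":
        pos = pd.Index(self.gene_ids).get_indexer(gene_ids)
        if (pos < 0).any():
            missing = np.asarray(gene_ids)[pos < 0][:5]
            raise KeyError(f"genes not in bulk matrix: {list(missing)}")
        return BulkExpressionMatrix(
            gene_ids=self.gene_ids[pos], sample_ids=self.sample_ids, values=self.values[pos, :]
        )


@dataclass
class QCStats:
    """Pre-filter per-cell/per-gene detection statistics."""

    detected_genes_per_cell: np.ndarray  # d_j
    library_size_per_cell: np.ndarray  # L_j
    genes_detected_in_n_cells: np.ndarray
    lower_quantile: float
    upper_quantile: float
    n_cells_removed_min_genes: int = 0
    n_cells_removed_quantile: int = 0
    n_genes_removed: int = 0


@dataclass
class NormalizedMatrix:
    """CP10K (Y) and log1p (Y-tilde) matrices over one gene panel."""

    gene_ids: np.ndarray
    cell_or_sample_ids: np.ndarray
    cp10k: np.ndarray
    log1p: np.ndarray
    zero_library_columns: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def reindex_genes(self, gene_ids: np.ndarray) -> "NormalizedMatrix":
        pos = pd.Index(self.gene_ids).get_indexer(np.asarray(gene_ids, dtype=object))
        if (pos < 0).any():
            missing = np.asarray(gene_ids)[pos < 0][:5]
            raise KeyError(f"genes not in normalized matrix: {list(missing)}")
        return NormalizedMatrix(
            gene_ids=self.gene_ids[pos],
            cell_or_sample_ids=self.cell_or_sample_ids,
            cp10k=self.cp10k[pos, :],
            log1p=self.log1p[pos, :],
            zero_library_columns=self.zero_library_columns,
        )


@dataclass
class HVGStats:
    """Per-gene mean/variance of log-normalized expression and dispersion."""

    gene_ids: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    trend: np.ndarray
    dispersion: np.ndarray
    rank: np.ndarray  # rank[i] = position of gene i in the dispersion ordering


@dataclass
class GenePanel:
    """Ordered gene panel shared by reference and bulk."""

    gene_ids: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class PreprocessConfig:
    """Knobs of the reference-preprocessing chain.

    Defaults follow the published workflow: cells with < 200 detected genes
    and genes seen in < 3 cells are dropped, outlier cells outside the
    [Q0.01, Q0.99] detected-gene quantiles are excluded, 5,000 cells are kept
    by stratified subsampling and the top 5,000 highly variable genes form
    the deconvolution panel.
    """

    min_detected_genes: int = 200
    min_cells_per_gene: int = 3
    outlier_quantiles: tuple[float, float] = (0.01, 0.99)
    n_cells_subsample: int = 5000
    n_hvg: int = 5000
    k_neighbors: int = 15
    diffusion_steps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.outlier_quantiles
        if not (0 <= lo < hi <= 1):
            raise ValueError("outlier_quantiles must satisfy 0 <= lo < hi <= 1")
        for name in ("min_detected_genes", "min_cells_per_gene", "n_cells_subsample", "n_hvg"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def filter_cells_genes(
    raw: GeneByCellCounts, cfg: PreprocessConfig | None = None
) -> tuple[GeneByCellCounts, QCStats]:
    """QC filter: drop low-complexity and outlier cells, then rare genes.

    Cells are kept when their detected-gene count d_j is at least
    ``min_detected_genes`` and falls inside the [Q_lo, Q_hi] quantile band of
    the d_j distribution; genes are then kept when detected in at least
    ``min_cells_per_gene`` of the *retained* cells.
    """
    cfg = cfg or PreprocessConfig()
    if raw.n_cells == 0 or raw.n_genes == 0:
        raise PreprocessError("input matrix is empty")
    detected = raw.counts > 0
    stats = QCStats(
        detected_genes_per_cell=detected.sum(axis=0),
        library_size_per_cell=raw.counts.sum(axis=0),
        genes_detected_in_n_cells=detected.sum(axis=1),
        lower_quantile=cfg.outlier_quantiles[0],
        upper_quantile=cfg.outlier_quantiles[1],
    )
    lo, hi = cfg.outlier_quantiles
    current = raw
    # iterate cell filter (threshold + quantile band) then gene filter to a
    # fixed point, so the result is stable under re-application
    for _ in range(raw.n_cells + raw.n_genes):
        d_j = (current.counts > 0).sum(axis=0)
        q_lo, q_hi = np.quantile(d_j, [lo, hi])
        keep_min = d_j >= cfg.min_detected_genes
        keep_quant = (d_j >= q_lo) & (d_j <= q_hi)
        keep_cells = keep_min & keep_quant
        stats.n_cells_removed_min_genes += int((~keep_min).sum())
        stats.n_cells_removed_quantile += int((keep_min & ~keep_quant).sum())
        if not keep_cells.any():
            raise PreprocessError("cell filter removed every cell")
        filtered = current.subset_cells(np.flatnonzero(keep_cells))

        gene_det = (filtered.counts > 0).sum(axis=1)
        keep_genes = gene_det >= cfg.min_cells_per_gene
        stats.n_genes_removed += int((~keep_genes).sum())
        if not keep_genes.any():
            raise PreprocessError("gene filter removed every gene")
        filtered = filtered.subset_genes(np.flatnonzero(keep_genes))
        unchanged = (
            filtered.n_cells == current.n_cells and filtered.n_genes == current.n_genes
        )
        current = filtered
        if unchanged:
            break
    return current, stats


def library_normalize(
    mat: np.ndarray, ids: np.ndarray | None = None, gene_ids: np.ndarray | None = None
) -> NormalizedMatrix:
    """Counts-per-10k per column, then log1p: Y_gj = 1e4 X_gj / L_j."""
    mat = np.asarray(mat, dtype=float)
    if (mat < 0).any():
        raise ValueError("expression must be non-negative")
    lib = mat.sum(axis=0)
    zero_cols = np.flatnonzero(lib == 0)
    if len(zero_cols) == mat.shape[1]:
        raise ValueError("no column has a nonzero library size")
    safe_lib = np.where(lib == 0, 1.0, lib)
    cp10k = 1e4 * mat / safe_lib
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(mat.shape[0])], dtype=object)
    if ids is None:
        ids = np.array([f"c{j}" for j in range(mat.shape[1])], dtype=object)
    return NormalizedMatrix(
        gene_ids=np.asarray(gene_ids, dtype=object),
        cell_or_sample_ids=np.asarray(ids, dtype=object),
        cp10k=cp10k,
        log1p=np.log1p(cp10k),
        zero_library_columns=zero_cols,
    )


def _lowess_trend(log_mean: np.ndarray, log_var: np.ndarray) -> np.ndarray:
    """Smooth mean-variance trend f(log mean) via local linear regression.

    The span is widened on small gene sets so that at least ~30 genes support
    each local fit.
    """
    n = len(log_mean)
    frac = min(1.0, max(0.3, 30.0 / max(n, 1)))
    fitted = lowess(log_var, log_mean, frac=frac, it=1, return_sorted=False)
    return np.asarray(fitted, dtype=float)


def select_hvgs(
    norm: NormalizedMatrix, n_hvg: int, restrict_to: np.ndarray | None = None
) -> tuple[GenePanel, HVGStats]:
    """Rank genes by standardized dispersion delta_g = log var - f(log mean).

    Mean and variance are taken over the log-normalized expression. Genes with
    zero variance get dispersion -inf (never selected); ties break
    lexicographically by gene identifier for determinism.
    """
    expr = norm.log1p
    gene_ids = norm.gene_ids
    if restrict_to is not None:
        keep = pd.Index(gene_ids).get_indexer(np.asarray(restrict_to, dtype=object))
        keep = keep[keep >= 0]
        expr = expr[keep, :]
        gene_ids = gene_ids[keep]
    mean = expr.mean(axis=1)
    var = expr.var(axis=1, ddof=1) if expr.shape[1] > 1 else np.zeros(len(gene_ids))
    ok = var > 0
    if not ok.any():
        raise ValueError("all genes have zero variance; cannot rank dispersions")

    trend = np.full(len(gene_ids), np.nan)
    disp = np.full(len(gene_ids), -np.inf)
    # log of mean can be -inf only if the gene is all-zero, which implies var 0
    trend[ok] = _lowess_trend(np.log(mean[ok]), np.log(var[ok]))
    disp[ok] = np.log(var[ok]) - trend[ok]

    order = np.lexsort((gene_ids.astype(str), -disp))
    rank = np.empty(len(gene_ids), dtype=int)
    rank[order] = np.arange(len(gene_ids))
    n_avail = int(ok.sum())
    if n_hvg > n_avail:
        warnings.warn(
            f"requested {n_hvg} HVGs but only {n_avail} genes have nonzero "
            "variance; returning all of them",
            stacklevel=2,
        )
        n_hvg = n_avail
    panel = GenePanel(gene_ids[order[:n_hvg]], provenance=f"top-{n_hvg} by standardized dispersion")
    stats = HVGStats(
        gene_ids=gene_ids, mean=mean, variance=var, trend=trend, dispersion=disp, rank=rank
    )
    return panel, stats


def intersect_genes(sc: GeneByCellCounts, bulk: BulkExpressionMatrix) -> GenePanel:
    """Common gene set G* = genes(X) ∩ genes(U), in reference-matrix order."""
    if sc.n_genes == 0 or len(bulk.gene_ids) == 0:
        raise ValueError("cannot intersect empty gene sets")
    bulk_set = set(bulk.gene_ids)
    shared = np.array([g for g in sc.gene_ids if g in bulk_set], dtype=object)
    if len(shared) == 0:
        raise ValueError(
            "no genes shared between reference and bulk; e.g. reference has "
            f"{list(sc.gene_ids[:3])}, bulk has {list(bulk.gene_ids[:3])} — "
            "check identifier namespaces"
        )
    return GenePanel(shared, provenance="intersection(reference, bulk)")


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` over ``fractions`` (sum to 1)."""
    quota = fractions * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    # ties in remainder broken by position order (stable argsort)
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def stratified_subsample(
    sc: GeneByCellCounts, n_cells: int, seed: int = 0
) -> GeneByCellCounts:
    """Subsample ``n_cells`` cells balancing per-type counts.

    Quotas follow largest-remainder apportionment of equal per-type shares;
    when a type has fewer cells than its quota all of them are taken and the
    deficit is redistributed proportionally among the types that still have
    spare cells.
    """
    types, counts = np.unique(sc.cell_type.astype(str), return_counts=True)
    k = len(types)
    if n_cells < k:
        raise ValueError(f"n_cells={n_cells} is below the number of cell types ({k})")
    if n_cells >= sc.n_cells:
        return sc

    avail = dict(zip(types, counts))
    quota = dict(zip(types, _largest_remainder(np.full(k, 1.0 / k), n_cells)))
    take = {t: 0 for t in types}
    remaining = n_cells
    active = list(types)
    while remaining > 0 and active:
        share = _largest_remainder(
            np.array([quota[t] for t in active], dtype=float)
            / sum(quota[t] for t in active),
            remaining,
        )
        next_active = []
        for t, s in zip(active, share):
            grant = min(take[t] + s, avail[t])
            remaining -= grant - take[t]
            take[t] = grant
            if grant < avail[t]:
                next_active.append(t)
        active = next_active
        if all(take[t] == avail[t] for t in types):
            break

    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for t in types:
        idx = np.flatnonzero(sc.cell_type.astype(str) == t)
        chosen.append(np.sort(rng.choice(idx, size=take[t], replace=False)))
    return sc.subset_cells(np.concatenate(chosen))


def impute_diffusion(
    norm: NormalizedMatrix, k_neighbors: int = 15, diffusion_steps: int = 3
) -> NormalizedMatrix:
    """Smooth expression by powering a cell-cell Markov affinity matrix.

    An adaptive Gaussian kernel on k-nearest-neighbor distances (bandwidth =
    distance to the k-th neighbor) in log-normalized space is symmetrized and
    row-normalized into a transition matrix M; expression is replaced by M^t
    diffusions of itself. The diffusion averages profiles in linear (CP10K)
    space so that sums of cells — the quantity bulk samples measure — keep
    the same mean structure after imputation; the log1p view is recomputed
    from the smoothed CP10K. ``diffusion_steps = 0`` is the identity.
    """
    n_cells = norm.log1p.shape[1]
    if k_neighbors >= n_cells:
        raise ValueError(f"k_neighbors={k_neighbors} must be < number of cells ({n_cells})")
    if diffusion_steps == 0:
        return norm

    X = norm.log1p.T  # cells x genes
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    sigma = dist[:, -1]
    sigma = np.where(sigma == 0, 1.0, sigma)
    rows = np.repeat(np.arange(n_cells), k_neighbors + 1)
    vals = np.exp(-((dist / sigma[:, None]) ** 2)).ravel()
    K = sparse.csr_matrix((vals, (rows, idx.ravel())), shape=(n_cells, n_cells))
    K = (K + K.T) * 0.5
    M = sparse.diags(1.0 / np.asarray(K.sum(axis=1)).ravel()) @ K

    smoothed = norm.cp10k.T
    for _ in range(diffusion_steps):
        smoothed = M @ smoothed
    smoothed = np.maximum(np.asarray(smoothed), 0.0).T
    return NormalizedMatrix(
        gene_ids=norm.gene_ids,
        cell_or_sample_ids=norm.cell_or_sample_ids,
        cp10k=smoothed,
        log1p=np.log1p(smoothed),
        zero_library_columns=norm.zero_library_columns,
    )


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------


def preprocess_reference(
    sc: GeneByCellCounts,
    bulk: BulkExpressionMatrix | None,
    cfg: PreprocessConfig,
) -> tuple[GeneByCellCounts, NormalizedMatrix, NormalizedMatrix, GenePanel, QCStats]:
    """Full reference chain: QC -> subsample -> intersect -> HVG -> impute.

    Returns the retained (subsampled) raw cells, their imputed log-normalized
    expression restricted to the panel, the matching unsmoothed normalized
    matrix, the panel itself and QC statistics. Genes are intersected with
    the bulk cohort *before* HVG selection so that every panel gene is
    guaranteed to exist in the bulk data.
    """
    filtered, qc = filter_cells_genes(sc, cfg)
    sub = stratified_subsample(filtered, cfg.n_cells_subsample, seed=cfg.seed)
    norm = library_normalize(sub.counts, ids=sub.cell_ids, gene_ids=sub.gene_ids)
    restrict = intersect_genes(sub, bulk).gene_ids if bulk is not None else None
    panel, _ = select_hvgs(norm, cfg.n_hvg, restrict_to=restrict)
    norm_panel = norm.reindex_genes(panel.gene_ids)
    imputed = impute_diffusion(norm_panel, cfg.k_neighbors, cfg.diffusion_steps)
    return sub, imputed, norm_panel, panel, qc


def preprocess_bulk(bulk: BulkExpressionMatrix, panel: GenePanel) -> NormalizedMatrix:
    """Normalize bulk profiles like the single-cell data and restrict to panel."""
    norm = library_normalize(bulk.values, ids=bulk.sample_ids, gene_ids=bulk.gene_ids)
    return norm.reindex_genes(panel.gene_ids)
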