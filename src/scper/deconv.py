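"""Reference-panel construction and latent-space proportion estimation.

Each cell type's representation is the coordinate-wise median of its cells'
latent vectors (rows of R). For each bulk sample the latent vector T is
regressed on the K panel rows across the latent coordinates, T ~= P R;
negative coefficients are clipped to zero and the remainder renormalized to
a probability vector. The default estimator is a gradient-boosted linear
model (linear base learners, whose fitted weights are the coefficients); a
non-negative-least-squares solver is provided as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.stats import pearsonr


@dataclass
class ReferencePanel:
    """Cell types x latent dims matrix of per-type median embeddings."""

    cell_types: list[str]
    R: np.ndarray

    @property
    def n_types(self) -> int:
        return len(self.cell_types)


@dataclass
class BulkLatent:
    sample_ids: np.ndarray
    T: np.ndarray


@dataclass
class ProportionEstimate:
    """Per-sample non-negative, sum-to-one composition over panel cell types."""

    sample_ids: np.ndarray
    cell_types: list[str]
    P: np.ndarray
    raw_coefficients: np.ndarray | None = None
    degenerate_flag: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


@dataclass
class DeconvMetrics:
    per_type_pearson: dict[str, float]
    overall_pearson: float
    mse: float
    mad: float

    @property
    def mean_per_type_pearson(self) -> float:
        vals = [v for v in self.per_type_pearson.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")


def build_reference_panel(latents: np.ndarray, cell_type: np.ndarray) -> ReferencePanel:
    """Coordinate-wise median latent per cell type (rows in sorted type order)."""
    cell_type = np.asarray(cell_type).astype(str)
    latents = np.asarray(latents, dtype=float)
    if latents.shape[0] != len(cell_type):
        raise ValueError("one cell-type label per latent row is required")
    types = sorted(set(cell_type))
    rows = []
    for t in types:
        mask = cell_type == t
        if not mask.any():
            raise ValueError(f"cell type {t!r} has no cells")
        rows.append(np.median(latents[mask], axis=0))
    return ReferencePanel(cell_types=types, R=np.vstack(rows))


def clip_and_renormalize(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Set negative coefficients to 0 and rescale to sum 1.

    Falls back to the uniform vector (flagged) when everything clips to 0.
    """
    clipped = np.maximum(np.asarray(raw, dtype=float), 0.0)
    total = clipped.sum()
    if total <= 0:
        k = len(clipped)
        return np.full(k, 1.0 / k), True
    return clipped / total, False


def _fit_boosted_linear(A: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    """Coefficients of a gradient-boosted linear regression of y on A's columns."""
    import xgboost as xgb

    model = xgb.XGBRegressor(
        booster="gblinear",
        updater="coord_descent",  # deterministic, unlike the parallel default
        n_estimators=500,
        learning_rate=0.5,
        reg_lambda=1e-3,
        reg_alpha=0.0,
        base_score=0.0,
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    )
    model.fit(A, y)
    return np.asarray(model.coef_, dtype=float)


def estimate_proportions(
    panel: ReferencePanel,
    bulk: BulkLatent | np.ndarray,
    method: str = "boosted_linear",
    seed: int = 0,
) -> ProportionEstimate:
    """Solve T = P R per bulk sample and return clipped, renormalized P.

    For each sample the latent coordinates act as observations and the panel
    rows (transposed to d_latent x K) as predictors; ``boosted_linear`` fits
    a regularized linear model by gradient boosting, ``nnls_oracle`` solves
    the same system by non-negative least squares.
    """
    if method not in ("boosted_linear", "nnls_oracle"):
        raise ValueError(f"unknown method {method!r}")
    if isinstance(bulk, BulkLatent):
        T, sample_ids = np.atleast_2d(bulk.T), bulk.sample_ids
    else:
        T = np.atleast_2d(np.asarray(bulk, dtype=float))
        sample_ids = np.array([f"s{i}" for i in range(T.shape[0])], dtype=object)
    if T.shape[1] != panel.R.shape[1]:
        raise ValueError(
            f"bulk latents have {T.shape[1]} dims, panel has {panel.R.shape[1]}"
        )
    if panel.n_types < 2:
        raise ValueError("need at least 2 cell types in the panel")
    A = panel.R.T  # d_latent x K
    raw = np.empty((T.shape[0], panel.n_types))
    P = np.empty_like(raw)
    degenerate = np.zeros(T.shape[0], dtype=bool)
    for i, t in enumerate(T):
        if method == "nnls_oracle":
            raw[i], _ = nnls(A, t)
        else:
            raw[i] = _fit_boosted_linear(A, t, seed)
        P[i], degenerate[i] = clip_and_renormalize(raw[i])
    return ProportionEstimate(
        sample_ids=sample_ids,
        cell_types=list(panel.cell_types),
        P=P,
        raw_coefficients=raw,
        degenerate_flag=degenerate,
    )


def score_predictions(pred: np.ndarray, truth: np.ndarray, cell_types=None) -> DeconvMetrics:
    """Pearson r (per type and overall), MSE and mAD of predicted proportions.

    Per-type r is computed across samples and reported as NaN when undefined
    (fewer than two samples or zero variance on either side).
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    if cell_types is None:
        cell_types = [f"type{k}" for k in range(pred.shape[1])]
    per_type: dict[str, float] = {}
    for k, name in enumerate(cell_types):
        x, y = truth[:, k], pred[:, k]
        if len(x) < 2 or x.std() == 0 or y.std() == 0:
            per_type[name] = float("nan")
        else:
            per_type[name] = float(pearsonr(x, y)[0])
    xf, yf = truth.ravel(), pred.ravel()
    overall = (
        float(pearsonr(xf, yf)[0])
        if len(xf) >= 2 and xf.std() > 0 and yf.std() > 0
        else float("nan")
    )
    diff = pred - truth
    return DeconvMetrics(
        per_type_pearson=per_type,
        overall_pearson=overall,
        mse=float((diff**2).mean()),
        mad=float(np.abs(diff).mean()),
    )
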