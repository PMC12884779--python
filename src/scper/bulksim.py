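"""Pseudobulk simulation with ground-truth proportions.

Two strategies: (a) random-proportion mixing — per sample, draw one uniform
number per cell type, normalize to fractions, apportion a fixed cell budget
and sum the raw counts of the sampled cells; (b) patient-wise aggregation —
one pseudobulk per patient, summing all of that patient's cells, with the
observed per-type cell fractions as truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import BulkExpressionMatrix, GeneByCellCounts, _largest_remainder


@dataclass
class SimulationDraw:
    """One random-proportion draw: r_c, f_c = r_c / sum r, and cell counts N_c."""

    cell_types: list[str]
    random_draws: np.ndarray
    proportions: np.ndarray
    cells_selected: np.ndarray | None = None
    total_cells: int | None = None
    seed: int | None = None


@dataclass
class SimulatedBulk:
    """A pseudobulk expression vector with its ground-truth composition."""

    sample_id: str
    gene_ids: np.ndarray
    expression: np.ndarray
    cell_types: list[str]
    true_proportions: np.ndarray
    provenance: dict = field(default_factory=dict)
    strategy: str = "random_proportion"


def draw_random_proportions(
    cell_types: list[str], seed: int = 0, draws: np.ndarray | None = None
) -> SimulationDraw:
    """Uniform(0,1) draw per type, normalized to fractions summing to 1.

    ``draws`` forces the raw random numbers (for testing the normalization).
    """
    cell_types = list(cell_types)
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    if draws is None:
        draws = np.random.default_rng(seed).uniform(0.0, 1.0, size=len(cell_types))
    draws = np.asarray(draws, dtype=float)
    return SimulationDraw(
        cell_types=cell_types,
        random_draws=draws,
        proportions=draws / draws.sum(),
        seed=seed,
    )


def apportion_cells(draw: SimulationDraw, n_total: int) -> SimulationDraw:
    """Round N_c = f_c * N_total to integers summing exactly to N_total."""
    if n_total < len(draw.cell_types):
        raise ValueError("n_total below number of cell types")
    draw.cells_selected = _largest_remainder(draw.proportions, n_total)
    draw.total_cells = n_total
    return draw


def simulate_bulk_random(
    sc: GeneByCellCounts,
    n_samples: int = 100,
    n_total: int = 500,
    seed: int = 0,
) -> list[SimulatedBulk]:
    """Random-proportion pseudobulks: sample N_c cells per type, sum raw counts.

    Truth is recorded as the realized fractions N_c / N_total. Sampling is
    without replacement when a type has enough cells, with replacement
    otherwise (flagged in provenance).
    """
    types = sorted(set(sc.cell_type.astype(str)))
    idx_by_type = {t: np.flatnonzero(sc.cell_type.astype(str) == t) for t in types}
    for t, idx in idx_by_type.items():
        if len(idx) == 0:
            raise ValueError(f"cell type {t!r} has no cells")
    rng = np.random.default_rng(seed)
    out: list[SimulatedBulk] = []
    for s in range(n_samples):
        if len(types) == 1:
            draw = SimulationDraw(
                cell_types=types, random_draws=np.ones(1), proportions=np.ones(1)
            )
        else:
            draw = draw_random_proportions(
                types, draws=rng.uniform(0.0, 1.0, size=len(types))
            )
        apportion_cells(draw, n_total)
        expr = np.zeros(sc.n_genes)
        chosen_ids: list[str] = []
        replaced = False
        for t, n_c in zip(types, draw.cells_selected):
            pool = idx_by_type[t]
            rep = n_c > len(pool)
            replaced |= bool(rep)
            pick = rng.choice(pool, size=n_c, replace=bool(rep))
            expr += sc.counts[:, pick].sum(axis=1)
            chosen_ids.extend(sc.cell_ids[pick])
        out.append(
            SimulatedBulk(
                sample_id=f"sim{s:03d}",
                gene_ids=sc.gene_ids,
                expression=expr,
                cell_types=types,
                true_proportions=draw.cells_selected / n_total,
                provenance={"cell_ids": chosen_ids, "with_replacement": replaced},
                strategy="random_proportion",
            )
        )
    return out


def simulate_bulk_patientwise(sc: GeneByCellCounts) -> list[SimulatedBulk]:
    """One pseudobulk per patient: exact sum of all that patient's cells.

    Truth is the patient's observed cell-type count fractions.
    """
    if sc.patient is None:
        raise ValueError("patient labels are required for patient-wise simulation")
    types = sorted(set(sc.cell_type.astype(str)))
    out: list[SimulatedBulk] = []
    for p in sorted(set(sc.patient.astype(str))):
        mask = sc.patient.astype(str) == p
        if not mask.any():
            warnings.warn(f"patient {p!r} has no cells; skipped", stacklevel=2)
            continue
        fracs = np.array(
            [(sc.cell_type[mask].astype(str) == t).sum() for t in types], dtype=float
        )
        out.append(
            SimulatedBulk(
                sample_id=str(p),
                gene_ids=sc.gene_ids,
                expression=sc.counts[:, mask].sum(axis=1),
                cell_types=types,
                true_proportions=fracs / fracs.sum(),
                provenance={"patient": p, "n_cells": int(mask.sum())},
                strategy="patient_sum",
            )
        )
    return out


def gene_coverage(bulks: list[SimulatedBulk]) -> np.ndarray:
    """Detected-gene count (expression > 0) per pseudobulk."""
    if not bulks:
        raise ValueError("no pseudobulks given")
    return np.array([(b.expression > 0).sum() for b in bulks])


def bulks_to_matrix(bulks: list[SimulatedBulk]) -> tuple[BulkExpressionMatrix, np.ndarray]:
    """Stack pseudobulks into a genes x samples matrix plus truth table."""
    gene_ids = bulks[0].gene_ids
    mat = BulkExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=np.array([b.sample_id for b in bulks], dtype=object),
        values=np.column_stack([b.expression for b in bulks]),
    )
    truth = np.vstack([b.true_proportions for b in bulks])
    return mat, truth
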