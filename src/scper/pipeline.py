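"""End-to-end orchestration: preprocess -> train -> embed -> deconvolve.

`deconvolve_dataset` is the in-memory pipeline used by the tests and the
acceptance checks; `run_pipeline` wraps it with file I/O, logging and
sidecar metadata for the command-line interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import aae, deconv, io, phenotype
from .preprocess import (
    BulkExpressionMatrix,
    GeneByCellCounts,
    GenePanel,
    PreprocessConfig,
    preprocess_bulk,
    preprocess_reference,
)

log = logging.getLogger("scper")


@dataclass
class PipelineResult:
    panel: GenePanel
    params: aae.EncoderDecoderParams
    reference: deconv.ReferencePanel
    cell_latents: np.ndarray
    cell_types: np.ndarray
    confounder_labels: list[aae.ConfounderLabels]
    bulk_latents: deconv.BulkLatent
    proportions: deconv.ProportionEstimate
    history: dict


def deconvolve_dataset(
    sc: GeneByCellCounts,
    bulk: BulkExpressionMatrix,
    pre_cfg: PreprocessConfig | None = None,
    train_cfg: aae.TrainingConfig | None = None,
    confounders: tuple[str, ...] = ("batch",),
    method: str = "boosted_linear",
) -> PipelineResult:
    """Run the full deconvolution chain on in-memory inputs.

    Reference cells are QC-filtered, subsampled, restricted to the
    bulk-intersected HVG panel and diffusion-imputed; the adversarial
    autoencoder is trained with one adversary per requested confounder;
    cells and bulks are embedded; per-type median latents form the reference
    panel; proportions are estimated per bulk sample.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    train_cfg = train_cfg or aae.TrainingConfig()

    sub, imputed, unsmoothed, panel, qc = preprocess_reference(sc, bulk, pre_cfg)
    log.info(
        "preprocess: %d cells retained, %d panel genes", sub.n_cells, len(panel)
    )
    data = imputed.log1p.T  # cells x genes

    label_objs = [
        aae.ConfounderLabels(name=c, labels=getattr(sub, c)) for c in confounders
    ]
    labels_arg = label_objs[0] if len(label_objs) == 1 else label_objs
    params, _, history = aae.train_adversarial_autoencoder(
        data, labels_arg, train_cfg, gene_ids=panel.gene_ids
    )

    cell_latents = aae.encode(params, data, gene_ids=panel.gene_ids)
    reference = deconv.build_reference_panel(cell_latents, sub.cell_type)

    bulk_norm = preprocess_bulk(bulk, panel)
    T = aae.embed_bulk(params, bulk_norm.log1p.T, gene_ids=panel.gene_ids)
    bulk_latents = deconv.BulkLatent(sample_ids=bulk.sample_ids, T=T)
    proportions = deconv.estimate_proportions(
        reference, bulk_latents, method=method, seed=train_cfg.seed
    )
    return PipelineResult(
        panel=panel,
        params=params,
        reference=reference,
        cell_latents=cell_latents,
        cell_types=sub.cell_type,
        confounder_labels=label_objs,
        bulk_latents=bulk_latents,
        proportions=proportions,
        history=history,
    )


def run_pipeline(cfg: io.RunConfig) -> Path:
    """File-based pipeline: read inputs, deconvolve, write artifacts.

    Writes the panel gene list, reference-panel and latent TSVs, the
    proportions table (with sidecar metadata) and, when a phenotype label
    table is configured, the feature ranking and group-comparison tables.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    stage = "read inputs"
    try:
        sc = io.read_sc_dataset(cfg.sc_path)
        bulk = io.read_bulk(cfg.bulk_path)
        stage = "deconvolve"
        result = deconvolve_dataset(
            sc,
            bulk,
            pre_cfg=cfg.preprocess_config(),
            train_cfg=cfg.training_config(),
            confounders=tuple(cfg.confounders),
            method=cfg.method,
        )
        stage = "write outputs"
        meta = {"config": io.hash_config(cfg.__dict__), "master_seed": cfg.master_seed}
        (out / "panel_genes.txt").write_text("\n".join(map(str, result.panel.gene_ids)) + "\n")
        pd.DataFrame(
            result.reference.R, index=result.reference.cell_types
        ).to_csv(out / "reference_panel.tsv", sep="\t")
        pd.DataFrame(
            result.bulk_latents.T, index=result.bulk_latents.sample_ids
        ).to_csv(out / "bulk_latents.tsv", sep="\t")
        io.write_proportions(result.proportions, out / "proportions.tsv", meta=meta)

        if cfg.labels_path:
            stage = "phenotype"
            labels = pd.read_csv(cfg.labels_path, sep="\t", index_col=0).iloc[:, 0]
            labels = labels.loc[result.proportions.sample_ids].to_numpy()
            seed = io.derive_seed(cfg.master_seed, "phenotype")
            ranking = phenotype.rank_features_mi(result.proportions, labels, seed=seed)
            pd.DataFrame(
                {"feature": ranking.ranked_features,
                 "mean_mi": ranking.mean_scores[ranking.order]}
            ).to_csv(out / "feature_ranking.tsv", sep="\t", index=False)
            phenotype.compare_proportions(result.proportions, labels).to_csv(
                out / "group_comparison.tsv", sep="\t", index=False
            )
    except Exception:
        log.error("pipeline failed during stage: %s", stage)
        raise
    return out
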