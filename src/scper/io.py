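"""Readers, writers and run configuration.

Single-cell input is a directory holding either a MatrixMarket triplet
(``matrix.mtx`` genes x cells, ``genes.tsv`` one id per line, ``cells.tsv``
annotation table) or a dense table (``expression.tsv`` genes as rows plus
``cells.tsv``). Bulk input is a dense TSV/CSV, genes as rows, samples as
columns. All outputs are TSV; every written file gets a JSON sidecar with
the tool version and config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .aae import TrainingConfig
from .deconv import ProportionEstimate
from .preprocess import BulkExpressionMatrix, GeneByCellCounts, PreprocessConfig

TOOL_VERSION = "0.1.0"

_SEED_OFFSETS = {
    "synth": 11,
    "subsample": 23,
    "train": 37,
    "bulksim": 53,
    "deconv": 67,
    "phenotype": 83,
}


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return int((master_seed * 100003 + _SEED_OFFSETS[stage]) % (2**31 - 1))


# ---------------------------------------------------------------------------
# single-cell dataset I/O
# ---------------------------------------------------------------------------

_REQUIRED_CELL_COLS = ("cell_id", "cell_type", "batch")


def read_sc_dataset(path: str | Path) -> GeneByCellCounts:
    """Load a single-cell dataset directory into a GeneByCellCounts."""
    path = Path(path)
    cells_file = path / "cells.tsv"
    if not cells_file.exists():
        raise FileNotFoundError(f"missing annotation table {cells_file}")
    ann = pd.read_csv(cells_file, sep="\t", dtype=str)
    for col in _REQUIRED_CELL_COLS:
        if col not in ann.columns:
            raise ValueError(f"cells.tsv lacks required column {col!r}")
    if ann["cell_id"].duplicated().any():
        dup = ann.loc[ann["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell id {dup!r} in annotations")

    mtx_file = path / "matrix.mtx"
    if mtx_file.exists():
        counts = spio.mmread(mtx_file)
        if sparse.issparse(counts):
            counts = np.asarray(counts.todense())
        gene_ids = (
            pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
        )
        cell_ids = ann["cell_id"].to_numpy()
        if counts.shape[1] != len(cell_ids):
            raise ValueError(
                f"matrix has {counts.shape[1]} cells but annotations list {len(cell_ids)}"
            )
    else:
        dense_file = path / "expression.tsv"
        if not dense_file.exists():
            raise FileNotFoundError(f"neither matrix.mtx nor expression.tsv found in {path}")
        table = pd.read_csv(dense_file, sep="\t", index_col=0)
        gene_ids = table.index.astype(str).to_numpy()
        cell_ids = table.columns.astype(str).to_numpy()
        counts = table.to_numpy(dtype=float)
        missing = set(cell_ids) - set(ann["cell_id"])
        if missing:
            raise ValueError(f"annotation missing for cell {sorted(missing)[0]!r}")
        ann = ann.set_index("cell_id").loc[cell_ids].reset_index()

    def _col(name: str):
        return ann[name].to_numpy() if name in ann.columns else None

    return GeneByCellCounts(
        gene_ids=gene_ids.astype(object),
        cell_ids=ann["cell_id"].to_numpy(dtype=object),
        counts=counts,
        cell_type=ann["cell_type"].to_numpy(dtype=object),
        batch=ann["batch"].to_numpy(dtype=object),
        tissue=_col("tissue"),
        patient=_col("patient"),
    )


def write_sc_dataset(sc: GeneByCellCounts, path: str | Path) -> None:
    """Write a dataset directory (MatrixMarket + annotation TSVs)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(path / "matrix.mtx"), sparse.coo_matrix(sc.counts))
    pd.Series(sc.gene_ids).to_csv(path / "genes.tsv", sep="\t", index=False, header=False)
    ann = pd.DataFrame(
        {
            "cell_id": sc.cell_ids,
            "cell_type": sc.cell_type,
            "batch": sc.batch,
            "tissue": sc.tissue,
        }
    )
    if sc.patient is not None:
        ann["patient"] = sc.patient
    ann.to_csv(path / "cells.tsv", sep="\t", index=False)


def read_bulk(path: str | Path) -> BulkExpressionMatrix:
    """Dense genes-as-rows expression table (TSV, or CSV by extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, index_col=0)
    return BulkExpressionMatrix(
        gene_ids=table.index.astype(str).to_numpy(dtype=object),
        sample_ids=table.columns.astype(str).to_numpy(dtype=object),
        values=table.to_numpy(dtype=float),
    )


def write_bulk(bulk: BulkExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(bulk.values, index=bulk.gene_ids, columns=bulk.sample_ids).to_csv(
        path, sep="\t"
    )


# ---------------------------------------------------------------------------
# proportions and metadata
# ---------------------------------------------------------------------------


def write_proportions(P: ProportionEstimate, path: str | Path, meta: dict | None = None) -> None:
    """TSV with sample rows, cell-type columns (panel order), 6-decimal values."""
    table = pd.DataFrame(P.P, index=P.sample_ids, columns=P.cell_types)
    flags = P.degenerate_flag
    if len(flags) != len(P.sample_ids):
        flags = np.zeros(len(P.sample_ids), dtype=bool)
    table["degenerate_flag"] = flags.astype(int)
    table.index.name = "sample_id"
    table.to_csv(path, sep="\t", float_format="%.6f")
    write_sidecar(path, meta or {})


def read_proportions(path: str | Path) -> ProportionEstimate:
    table = pd.read_csv(path, sep="\t", index_col=0)
    flag = table.pop("degenerate_flag").to_numpy(dtype=bool) if "degenerate_flag" in table else None
    return ProportionEstimate(
        sample_ids=table.index.astype(str).to_numpy(dtype=object),
        cell_types=list(table.columns),
        P=table.to_numpy(dtype=float),
        degenerate_flag=flag if flag is not None else np.zeros(len(table), dtype=bool),
    )


def write_sidecar(path: str | Path, meta: dict) -> None:
    record = {"tool_version": TOOL_VERSION, **meta}
    record.setdefault("config_hash", hash_config(meta.get("config", {})))
    Path(str(path) + ".meta.json").write_text(json.dumps(record, indent=2, default=str))


def hash_config(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Whole-pipeline configuration; round-trips losslessly through YAML.

    Every stochastic stage draws its seed deterministically from
    ``master_seed`` (see :func:`derive_seed`).
    """

    sc_path: str = ""
    bulk_path: str = ""
    labels_path: str = ""
    out_dir: str = "scper_out"
    confounders: list[str] = field(default_factory=lambda: ["batch"])
    method: str = "boosted_linear"
    master_seed: int = 0
    log_level: str = "INFO"
    preprocess: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)

    _KNOWN = {
        "sc_path", "bulk_path", "labels_path", "out_dir", "confounders",
        "method", "master_seed", "log_level", "preprocess", "training",
    }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        # validate stage sections eagerly so errors precede any computation
        cfg.preprocess_config()
        cfg.training_config()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def preprocess_config(self) -> PreprocessConfig:
        kw = dict(self.preprocess)
        if "outlier_quantiles" in kw:
            kw["outlier_quantiles"] = tuple(kw["outlier_quantiles"])
        kw.setdefault("seed", derive_seed(self.master_seed, "subsample"))
        return PreprocessConfig(**kw)

    def training_config(self) -> TrainingConfig:
        kw = dict(self.training)
        for key in ("hidden", "adv_hidden"):
            if key in kw:
                kw[key] = tuple(kw[key])
        kw.setdefault("seed", derive_seed(self.master_seed, "train"))
        return TrainingConfig(**kw)
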