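"""Readers, writers and validated containers for every on-disk format the
pipeline touches.

Single-cell data live in :class:`anndata.AnnData` with UMI counts in ``X``,
cell metadata (``cell_id``, ``sample_id``, ``patient_id``, ``cohort_id``,
``tissue`` and optional ground-truth columns) in ``obs`` and the gene
annotation (``chromosome``, ``arm``, ``start_bp``, ``is_mito``) in ``var``.
Directional gene signatures and bulk expression matrices get small dedicated
containers because they carry their own invariants (disjoint Up/Down sets,
label joins by sample id).

All tabular formats are UTF-8 TSV with a header row; count matrices are
MatrixMarket (1-based on disk, 0-based in memory).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

CELL_COLUMNS = ("cell_id", "sample_id", "patient_id", "cohort_id", "tissue")
TISSUES = ("tumor", "normal", "lymph_node")
GENE_COLUMNS = ("gene_id", "symbol", "chromosome", "arm", "start_bp", "is_mito")
MSI_LEVELS = ("MSI-H", "MSS", "unknown")
CMS_LEVELS = ("CMS1", "CMS2", "CMS3", "CMS4", "unknown")


class DataError(ValueError):
    """Raised when an input file violates a format contract."""


# ---------------------------------------------------------------------------
# single-cell dataset
# ---------------------------------------------------------------------------

def validate_counts(adata: ad.AnnData) -> None:
    """Check the UMI count-matrix invariants; raise :class:`DataError` if violated."""
    X = adata.X
    data = X.data if sp.issparse(X) else np.asarray(X)
    if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
        raise DataError("count matrix entries must be nonnegative integers")
    if adata.obs.index.duplicated().any():
        raise DataError("duplicate cell_ids")
    if adata.var.index.duplicated().any():
        raise DataError("duplicate gene_ids")
    for col in ("sample_id", "patient_id", "cohort_id"):
        if col not in adata.obs.columns:
            raise DataError(f"cell metadata misses required column {col!r}")
    # sample -> patient -> cohort must be functions
    for child, parent in (("sample_id", "patient_id"), ("patient_id", "cohort_id")):
        n = adata.obs.groupby(child, observed=True)[parent].nunique()
        if (n > 1).any():
            bad = n[n > 1].index[0]
            raise DataError(f"{child} {bad!r} maps to multiple {parent} values")


def read_sc_dataset(mtx_path, cells_tsv, genes_tsv) -> ad.AnnData:
    """Read a cells x genes MatrixMarket matrix plus cell/gene TSVs.

    Order is preserved exactly as on disk; any dimension mismatch between the
    matrix and either metadata table is an error, never silently fixed.
    """
    X = scipy.io.mmread(str(mtx_path))
    X = sp.csr_matrix(X)
    cells = pd.read_csv(cells_tsv, sep="\t", dtype={"cell_id": str})
    genes = pd.read_csv(genes_tsv, sep="\t", dtype={"gene_id": str})
    if "cell_id" not in cells.columns:
        raise DataError("cells TSV requires a cell_id column")
    if "gene_id" not in genes.columns:
        raise DataError("genes TSV requires a gene_id column")
    if X.shape != (len(cells), len(genes)):
        raise DataError(
            f"matrix shape {X.shape} does not match metadata "
            f"({len(cells)} cells, {len(genes)} genes)"
        )
    if not np.all(X.data == np.round(X.data)):
        raise DataError("count matrix entries must be integers")
    X = X.astype(np.int64)
    obs = cells.set_index("cell_id", drop=False)
    obs.index.name = None
    var = genes.set_index("gene_id", drop=False)
    var.index.name = None
    adata = ad.AnnData(X=X, obs=obs, var=var)
    validate_counts(adata)
    return adata


def write_sc_dataset(adata: ad.AnnData, out_dir) -> dict[str, Path]:
    """Write counts + metadata as matrix.mtx / cells.tsv / genes.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out / "matrix.mtx",
        "cells": out / "cells.tsv",
        "genes": out / "genes.tsv",
    }
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(paths["mtx"]), X.astype(np.int64))
    obs = adata.obs.copy()
    if "cell_id" not in obs.columns:
        obs.insert(0, "cell_id", obs.index)
    obs.to_csv(paths["cells"], sep="\t", index=False)
    var = adata.var.copy()
    if "gene_id" not in var.columns:
        var.insert(0, "gene_id", var.index)
    var.to_csv(paths["genes"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(tsv_path) -> pd.DataFrame:
    """Read a BED-like gene annotation TSV (chrom, start_bp, gene_id, arm, is_mito)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    required = {"gene_id", "chromosome", "start_bp", "arm"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"gene annotation misses columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise DataError("duplicate gene_ids in annotation")
    bad_arm = ~df["arm"].isin(["p", "q"])
    if bad_arm.any():
        raise DataError(f"invalid arm values: {df.loc[bad_arm, 'arm'].unique()[:5]}")
    if (df["start_bp"] < 0).any():
        raise DataError("start_bp must be >= 0")
    if "is_mito" not in df.columns:
        df["is_mito"] = False
    df["is_mito"] = df["is_mito"].astype(bool)
    return df.set_index("gene_id", drop=False).rename_axis(None)


# ---------------------------------------------------------------------------
# directional signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureSet:
    """Directional gene sets: class label -> {"Up": genes, "Down": genes}.

    The shape of the two-stage intrinsic-subtype marker signatures (848 genes
    over {i2, i3, normal} at stage 1; 715 genes over i2_Up/i2_Down/i3_Up/
    i3_Down at stage 2).
    """

    classes: Mapping[str, Mapping[str, frozenset]]
    provenance: str = ""

    def __post_init__(self):
        norm = {}
        for cls, dirs in self.classes.items():
            up = frozenset(dirs.get("Up", ()))
            down = frozenset(dirs.get("Down", ()))
            if up & down:
                raise DataError(
                    f"class {cls!r}: genes in both Up and Down: {sorted(up & down)[:5]}"
                )
            norm[cls] = {"Up": up, "Down": down}
        object.__setattr__(self, "classes", norm)

    def up(self, cls: str) -> frozenset:
        return self.classes[cls]["Up"]

    def down(self, cls: str) -> frozenset:
        return self.classes[cls]["Down"]

    @property
    def class_labels(self) -> tuple:
        return tuple(self.classes)

    def all_genes(self) -> frozenset:
        out = frozenset()
        for dirs in self.classes.values():
            out |= dirs["Up"] | dirs["Down"]
        return out

    def n_genes(self) -> int:
        return len(self.all_genes())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, cls, direction)
            for cls, dirs in self.classes.items()
            for direction in ("Up", "Down")
            for g in sorted(dirs[direction])
        ]
        return pd.DataFrame(rows, columns=["gene", "class", "direction"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "SignatureSet":
        required = {"gene", "class", "direction"}
        if not required <= set(df.columns):
            raise DataError(f"signature table requires columns {sorted(required)}")
        bad = ~df["direction"].isin(["Up", "Down"])
        if bad.any():
            raise DataError(
                f"invalid direction values: {df.loc[bad, 'direction'].unique()[:5]}"
            )
        df = df.drop_duplicates(subset=["gene", "class", "direction"])
        classes: dict[str, dict[str, set]] = {}
        for (label, direction), grp in df.groupby(["class", "direction"], sort=True):
            classes.setdefault(str(label), {"Up": set(), "Down": set()})[direction] = set(
                grp["gene"]
            )
        return cls(classes, provenance=provenance)


def read_signature(tsv_path) -> SignatureSet:
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    return SignatureSet.from_frame(df, provenance=str(tsv_path))


def write_signature(sig: SignatureSet, tsv_path) -> None:
    sig.to_frame().to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bulk matrices
# ---------------------------------------------------------------------------

@dataclass
class BulkMatrix:
    """Log-scale genes x samples bulk expression with per-sample labels.

    ``labels`` is indexed by sample id with columns ``msi`` (MSI-H/MSS/unknown),
    ``cms`` (CMS1..CMS4/unknown) and ``cohort_id``.
    """

    expr: pd.DataFrame
    labels: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.expr.index.duplicated().any():
            raise DataError("duplicate gene ids in bulk matrix")
        if self.expr.columns.duplicated().any():
            raise DataError("duplicate sample ids in bulk matrix")
        vals = self.expr.to_numpy()
        if not np.isfinite(vals).all():
            raise DataError("bulk matrix contains non-finite values")
        if self.labels is None:
            self.labels = pd.DataFrame(index=self.expr.columns)
        self.labels = self.labels.reindex(self.expr.columns)
        for col, default in (("msi", "unknown"), ("cms", "unknown"), ("cohort_id", "cohort")):
            if col not in self.labels.columns:
                self.labels[col] = default
            self.labels[col] = self.labels[col].fillna(default)
        bad_msi = ~self.labels["msi"].isin(MSI_LEVELS)
        if bad_msi.any():
            raise DataError(f"invalid MSI labels: {self.labels.loc[bad_msi, 'msi'].unique()[:5]}")
        bad_cms = ~self.labels["cms"].isin(CMS_LEVELS)
        if bad_cms.any():
            raise DataError(f"invalid CMS labels: {self.labels.loc[bad_cms, 'cms'].unique()[:5]}")

    @property
    def samples(self) -> pd.Index:
        return self.expr.columns

    @property
    def genes(self) -> pd.Index:
        return self.expr.index


def read_bulk_matrix(tsv_path, labels_tsv=None) -> BulkMatrix:
    """Read a genes x samples TSV (gene ids in the first column) plus optional labels.

    Samples absent from the label table get msi/cms = "unknown".
    """
    expr = pd.read_csv(tsv_path, sep="\t", index_col=0)
    expr.index.name = None
    if expr.columns.duplicated().any():
        raise DataError("duplicate sample ids in bulk matrix header")
    try:
        expr = expr.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-numeric value in bulk matrix: {exc}") from exc
    labels = None
    if labels_tsv is not None:
        lab = pd.read_csv(labels_tsv, sep="\t", dtype=str)
        if "sample_id" not in lab.columns:
            raise DataError("labels TSV requires a sample_id column")
        labels = lab.set_index("sample_id")
    return BulkMatrix(expr=expr, labels=labels)


def write_bulk_matrix(bulk: BulkMatrix, tsv_path, labels_tsv=None) -> None:
    expr = bulk.expr.copy()
    expr.index.name = "gene_id"
    expr.to_csv(tsv_path, sep="\t")
    if labels_tsv is not None:
        lab = bulk.labels.copy()
        lab.index.name = "sample_id"
        lab.to_csv(labels_tsv, sep="\t")
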