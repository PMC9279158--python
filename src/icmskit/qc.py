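"""Three-round single-cell quality control.

Round 1 discards empty droplets (NODG < 300), depth-normalizes to 10,000 UMIs
per cell with a log1p transform, assigns major cell types by Pearson
correlation projection onto reference transcriptomes with per-cluster calling,
and discards whole samples whose per-cell-type median NODG deviates from the
across-sample reference (median of per-sample medians) by more than a factor
of 2 in more than half of the cell types.  Round 2 removes doublets with the
proportion-of-artificial-nearest-neighbors (pANN) statistic at the linear 10x
rate of 0.8% per 1,000 recovered cells.  Round 3 applies cell-type-specific
NODG / mitochondrial-fraction cutoffs.

Every stage only removes cells; counts are never edited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

DEFAULT_CUTOFFS = {"epithelial": (1000, 20.0), "default": (500, 25.0)}


@dataclass
class QCThresholds:
    min_nodg_empty: int = 300
    sample_deviation_factor: float = 2.0
    celltype_cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    doublet_rate_per_1000: float = 0.8
    pann_k: int | None = None  # default: round(0.025 * n_cells incl. artificial)
    pann_artificial_frac: float = 0.25

    def cutoff_for(self, cell_type: str):
        if cell_type in self.celltype_cutoffs:
            return self.celltype_cutoffs[cell_type]
        if "default" not in self.celltype_cutoffs:
            raise KeyError(f"no QC cutoff for cell type {cell_type!r} and no default row")
        return self.celltype_cutoffs["default"]


def nodg(adata: ad.AnnData) -> np.ndarray:
    """Number of detected genes per cell."""
    X = adata.X
    if sp.issparse(X):
        return np.asarray((X > 0).sum(axis=1)).ravel()
    return (np.asarray(X) > 0).sum(axis=1)


def mito_fraction(adata: ad.AnnData) -> np.ndarray:
    if "is_mito" not in adata.var.columns:
        raise ValueError("gene annotation lacks is_mito; cannot compute mito fraction")
    mito = adata.var["is_mito"].to_numpy(dtype=bool)
    X = adata.X
    tot = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mt = np.asarray(X[:, mito].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, mt / tot, 0.0)


def filter_empty_droplets(adata: ad.AnnData, min_nodg: int = 300) -> ad.AnnData:
    """Retain cells with NODG >= min_nodg (strictly fewer detected genes are dropped)."""
    keep = nodg(adata) >= min_nodg
    return adata[keep].copy()


def lognormalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """log(1 + count * scale_factor / cell_total) per entry.

    Raises on cells with zero total counts (run droplet filtering first).
    """
    X = sp.csr_matrix(adata.X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts; filter empty droplets first")
    X = sp.diags(scale_factor / totals) @ X
    X.data = np.log1p(X.data)
    out = ad.AnnData(X=X.tocsr(), obs=adata.obs.copy(), var=adata.var.copy())
    out.uns.update(adata.uns)
    out.uns["lognorm"] = {"scale_factor": float(scale_factor), "pseudocount": 1.0}
    return out


@dataclass
class CellTypeCallResult:
    """Per-cell major-type calls from reference-correlation projection."""

    assignments: pd.DataFrame  # cell_id-indexed: assigned_type, max_correlation, cluster
    cluster_labels: pd.Series  # cluster -> called type
    cluster_median_corr: pd.DataFrame  # cluster x reference type

    @property
    def cell_types(self) -> pd.Series:
        return self.assignments["assigned_type"]


def assign_major_cell_types(
    lognorm: ad.AnnData,
    reference_profiles: pd.DataFrame,
    resolution: float = 1.0,
    seed: int = 0,
) -> CellTypeCallResult:
    """Project cells onto reference transcriptomes and call types per cluster.

    Each cell's Pearson correlation vector to the reference columns is the
    projection; cells are Leiden-clustered in that projection space and each
    cluster is labeled with the reference type of highest median correlation.
    Cells with zero variance across shared genes are 'unassigned'.
    """
    if reference_profiles.shape[1] < 2:
        raise ValueError("need at least 2 reference cell types")
    shared = lognorm.var_names.intersection(reference_profiles.index)
    if len(shared) < 50:
        raise ValueError(f"only {len(shared)} genes shared with the reference (< 50)")
    X = lognorm[:, shared].X
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    R = reference_profiles.loc[shared].to_numpy(dtype=float)

    Xc = X - X.mean(axis=1, keepdims=True)
    Rc = R - R.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    rn = np.linalg.norm(Rc, axis=0)
    degenerate = xn <= 1e-12
    xn_safe = np.where(degenerate, 1.0, xn)
    corr = (Xc @ Rc) / xn_safe[:, None] / rn[None, :]
    corr[degenerate] = np.nan

    proj = ad.AnnData(
        X=np.nan_to_num(corr, nan=0.0),
        obs=lognorm.obs.copy(),
    )
    import scanpy as sc

    n_comp = min(corr.shape[1] - 1, 10)
    sc.pp.neighbors(proj, use_rep="X", n_neighbors=15, random_state=seed)
    sc.tl.leiden(
        proj, resolution=resolution, key_added="cluster", random_state=seed,
        flavor="igraph", n_iterations=2, directed=False,
    )
    clusters = proj.obs["cluster"].astype(str)

    ref_types = list(reference_profiles.columns)
    med = (
        pd.DataFrame(corr, index=lognorm.obs_names, columns=ref_types)
        .groupby(clusters, observed=True)
        .median()
    )
    cluster_label = med.idxmax(axis=1)

    assigned = clusters.map(cluster_label).astype(object)
    assigned[degenerate] = "unassigned"
    max_corr = np.nanmax(np.where(degenerate[:, None], -np.inf, corr), axis=1)
    max_corr[degenerate] = np.nan
    assignments = pd.DataFrame(
        {
            "assigned_type": assigned,
            "max_correlation": max_corr,
            "cluster": clusters,
        },
        index=lognorm.obs_names,
    )
    return CellTypeCallResult(
        assignments=assignments, cluster_labels=cluster_label, cluster_median_corr=med
    )


def flag_low_quality_samples(
    adata: ad.AnnData,
    cell_types: pd.Series,
    thresholds: QCThresholds | None = None,
) -> set:
    """Median-of-medians sample QC.

    The reference NODG of a cell type is the median over samples of the
    per-sample median NODG.  A sample deviates for a cell type when its median
    differs from the reference by a factor strictly greater than
    ``sample_deviation_factor`` in either direction; samples deviating in more
    than half of their assessable cell types are discarded.
    """
    thresholds = thresholds or QCThresholds()
    if adata.obs["sample_id"].nunique() < 2:
        raise ValueError("sample QC requires at least 2 samples")
    df = pd.DataFrame(
        {
            "sample_id": adata.obs["sample_id"].to_numpy(),
            "cell_type": cell_types.reindex(adata.obs_names).to_numpy(),
            "nodg": nodg(adata),
        }
    )
    df = df[df["cell_type"].notna() & (df["cell_type"] != "unassigned")]
    med = df.groupby(["sample_id", "cell_type"], observed=True)["nodg"].median().unstack()
    reference = med.median(axis=0)  # per cell type, across samples

    factor = thresholds.sample_deviation_factor
    ratio = med.divide(reference, axis=1)
    deviates = (ratio > factor) | (ratio < 1.0 / factor)
    assessable = med.notna() & reference.notna()
    n_dev = (deviates & assessable).sum(axis=1)
    n_types = assessable.sum(axis=1)
    flagged = med.index[(n_dev > n_types / 2.0) & (n_types > 0)]
    return set(flagged)


def detect_doublets(
    lognorm: ad.AnnData,
    thresholds: QCThresholds | None = None,
    seed: int = 0,
    n_pcs: int = 20,
) -> set:
    """pANN doublet detection, run independently per sample.

    Artificial doublets (a fraction ``pann_artificial_frac`` of the sample
    size) are averages of random real-cell pairs; real and artificial cells
    are embedded by PCA and each real cell's proportion of artificial
    k-nearest neighbors is thresholded at the expected doublet count
    N = round(n_cells * rate_per_1000/100 * n_cells/1000).
    """
    thresholds = thresholds or QCThresholds()
    rate = thresholds.doublet_rate_per_1000
    if rate <= 0:
        return set()
    doublets: set = set()
    rng = np.random.default_rng(seed)
    for sid, idx in lognorm.obs.groupby("sample_id", observed=True).groups.items():
        n = len(idx)
        if n < 100:
            warnings.warn(f"sample {sid}: only {n} cells, skipping doublet detection")
            continue
        X = lognorm[idx].X
        X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
        n_art = max(int(round(thresholds.pann_artificial_frac * n)), 1)
        pa = rng.integers(0, n, size=n_art)
        pb = rng.integers(0, n, size=n_art)
        art = 0.5 * (X[pa] + X[pb])
        merged = np.vstack([X, art])
        k = thresholds.pann_k or max(int(round(0.025 * (n + n_art))), 5)
        n_comp = min(n_pcs, merged.shape[0] - 1, merged.shape[1] - 1)
        emb = PCA(n_components=n_comp, random_state=seed).fit_transform(merged)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
        _, nbrs = nn.kneighbors(emb[:n])
        nbrs = nbrs[:, 1:]  # drop self
        pann = (nbrs >= n).mean(axis=1)
        expected = int(round(n * (rate * n / 1000.0) / 100.0))
        if expected <= 0:
            continue
        order = np.argsort(pann)[::-1][:expected]
        doublets.update(np.asarray(idx, dtype=object)[order])
    return doublets


def apply_celltype_cutoffs(
    adata: ad.AnnData,
    cell_types: pd.Series,
    thresholds: QCThresholds | None = None,
) -> ad.AnnData:
    """Retain cells meeting their type's NODG minimum and mito-percentage cap.

    Boundary behavior: NODG >= min retained, mito% <= max retained.
    """
    thresholds = thresholds or QCThresholds()
    types = cell_types.reindex(adata.obs_names)
    ng = nodg(adata)
    mito_pct = 100.0 * mito_fraction(adata)
    keep = np.ones(adata.n_obs, dtype=bool)
    for i, ct in enumerate(types):
        min_nodg, max_mito = thresholds.cutoff_for(str(ct))
        keep[i] = (ng[i] >= min_nodg) and (mito_pct[i] <= max_mito)
    return adata[keep].copy()
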