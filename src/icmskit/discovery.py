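"""Discovery of the two intrinsic epithelial subtypes.

The recipe: select informative features, graph-cluster the epithelial cells,
refine the feature space with pairwise differentially expressed genes (DEGs)
between initial clusters and re-cluster, identify the normal-like epithelial
cluster by its normal-tissue composition, split patients into two groups by
PCA + 2-means on patient pseudo-bulk profiles, and derive the first-stage
directional marker signature with the both-other-subtypes consistency rule.

Fold-changes follow the natural-log convention ln(mean(expm1(x)) + eps) with
the DEG threshold 0.4055 = ln(1.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io import SignatureSet

_EPS = 1e-9


@dataclass
class DEGParams:
    logfc_threshold: float = 0.4055  # ln(1.5)
    min_pct: float = 0.25
    adj_p_max: float = 0.05
    min_up_group_mean: float = 0.1
    top_n_per_direction: int = 30


@dataclass
class ClusterAssignment:
    labels: pd.Series  # cell -> cluster id (str)
    resolution: float
    features: tuple


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def select_features(
    lognorm: ad.AnnData,
    method: str = "correlation_range",
    n_features: int = 500,
    min_cells_frac: float = 0.01,
) -> list[str]:
    """Deterministic informative-gene selection.

    ``correlation_range`` scores each gene by the spread of its strongest
    gene-gene correlations (co-regulated genes score high, noise genes low);
    ``hvg`` is mean-binned dispersion (Seurat-style highly variable genes).
    Genes expressed in fewer than ``min_cells_frac`` of cells are excluded
    up front.
    """
    if lognorm.n_obs < 2:
        raise ValueError("need at least 2 cells")
    X = _dense(lognorm.X)
    frac = (X > 0).mean(axis=0)
    keep = np.flatnonzero(frac >= min_cells_frac)
    Xk = X[:, keep]
    names = np.asarray(lognorm.var_names)[keep]

    if method == "correlation_range":
        Z = Xk - Xk.mean(axis=0)
        sd = Z.std(axis=0)
        sd[sd == 0] = 1.0
        Z = Z / sd
        C = (Z.T @ Z) / max(Xk.shape[0] - 1, 1)
        np.fill_diagonal(C, 0.0)
        A = np.abs(C)
        A.sort(axis=1)
        # mean of the 10 strongest correlations minus the median background
        score = A[:, -10:].mean(axis=1) - np.median(A, axis=1)
    elif method == "hvg":
        mean = np.expm1(Xk).mean(axis=0)
        disp = np.expm1(Xk).var(axis=0) / np.maximum(mean, _EPS)
        bins = pd.qcut(mean, q=min(20, max(len(mean) // 20, 2)), duplicates="drop")
        df = pd.DataFrame({"disp": disp, "bin": bins})
        grp = df.groupby("bin", observed=True)["disp"]
        score = ((df["disp"] - grp.transform("mean")) / grp.transform("std").replace(0, 1.0)).to_numpy()
        score = np.nan_to_num(score, nan=-np.inf)
    else:
        raise ValueError(f"unknown feature selection method {method!r}")

    order = np.lexsort((names, -score))
    selected = list(names[order][:n_features])
    if len(selected) < 10:
        raise ValueError(f"only {len(selected)} features selected (< 10)")
    return selected


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_cells(
    lognorm: ad.AnnData,
    features,
    resolution: float = 0.2,
    seed: int = 0,
    n_pcs: int = 15,
    scale_by_cohort: bool = False,
) -> ClusterAssignment:
    """Leiden community detection on an SNN graph in PCA space of the features."""
    features = [f for f in features if f in set(lognorm.var_names)]
    if not features:
        raise ValueError("no feature genes present in the matrix")
    if lognorm.n_obs < 2:
        raise ValueError("cannot cluster a singleton dataset")
    import scanpy as sc

    sub = lognorm[:, features].copy()
    sub.X = _dense(sub.X)
    if scale_by_cohort:
        from .scoring import zscore_within_cohort

        sub.X = zscore_within_cohort(
            pd.DataFrame(sub.X, index=sub.obs_names, columns=features),
            sub.obs["cohort_id"],
        )[0].to_numpy()
    else:
        sc.pp.scale(sub, max_value=10)
    n_comp = min(n_pcs, sub.n_obs - 1, sub.n_vars - 1)
    sc.tl.pca(sub, n_comps=n_comp, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(sub, n_neighbors=15, n_pcs=n_comp, random_state=seed)
    sc.tl.leiden(
        sub, resolution=resolution, key_added="cluster", random_state=seed,
        flavor="igraph", n_iterations=2, directed=False,
    )
    return ClusterAssignment(
        labels=sub.obs["cluster"].astype(str),
        resolution=resolution,
        features=tuple(features),
    )


# ---------------------------------------------------------------------------
# pairwise DEG
# ---------------------------------------------------------------------------

def _deg_table(Xa: np.ndarray, Xb: np.ndarray, genes, params: DEGParams) -> pd.DataFrame:
    """Wilcoxon rank-sum DEG table for group a vs group b (vectorized over genes)."""
    mean_a = np.expm1(Xa).mean(axis=0)
    mean_b = np.expm1(Xb).mean(axis=0)
    lnfc = np.log(mean_a + _EPS) - np.log(mean_b + _EPS)
    pct_a = (Xa > 0).mean(axis=0)
    pct_b = (Xb > 0).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = mannwhitneyu(Xa, Xb, axis=0, alternative="two-sided")
    p = np.nan_to_num(p, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    df = pd.DataFrame(
        {
            "gene": genes,
            "lnfc": lnfc,
            "p": p,
            "adj_p": q,
            "pct_a": pct_a,
            "pct_b": pct_b,
            "mean_a": Xa.mean(axis=0),
            "mean_b": Xb.mean(axis=0),
        }
    )
    up_mean = np.where(df["lnfc"] >= 0, df["mean_a"], df["mean_b"])
    df["is_deg"] = (
        (df["adj_p"] < params.adj_p_max)
        & (df["lnfc"].abs() >= params.logfc_threshold)
        & (np.maximum(df["pct_a"], df["pct_b"]) >= params.min_pct)
        & (up_mean >= params.min_up_group_mean)
    )
    return df


def _top_slots(df: pd.DataFrame, direction: str, n: int) -> list[str]:
    sub = df[df["is_deg"] & ((df["lnfc"] > 0) if direction == "up" else (df["lnfc"] < 0))]
    sub = sub.sort_values(
        by=["adj_p", "lnfc", "gene"],
        ascending=[True, direction != "up", True],
        key=lambda s: s.abs() if s.name == "lnfc" else s,
    )
    return list(sub["gene"].head(n))


def pairwise_deg(
    lognorm: ad.AnnData,
    clusters: pd.Series,
    params: DEGParams | None = None,
):
    """DEG tables for all cluster pairs plus the refined feature set.

    The refined set is the union, over pairs, of the 30 most significant
    up- and 30 most significant downregulated DEGs (ties broken by larger
    absolute fold-change, then gene id).
    """
    params = params or DEGParams()
    clusters = clusters.reindex(lognorm.obs_names)
    labels = sorted(clusters.dropna().unique())
    if len(labels) < 2:
        raise ValueError("pairwise DEG requires at least 2 clusters")
    X = _dense(lognorm.X)
    genes = np.asarray(lognorm.var_names)
    idx = {c: np.flatnonzero((clusters == c).to_numpy()) for c in labels}
    for c, ii in idx.items():
        if len(ii) == 0:
            raise ValueError(f"cluster {c!r} is empty")
    tables = {}
    refined: set[str] = set()
    for a, b in combinations(labels, 2):
        df = _deg_table(X[idx[a]], X[idx[b]], genes, params)
        tables[(a, b)] = df
        refined.update(_top_slots(df, "up", params.top_n_per_direction))
        refined.update(_top_slots(df, "down", params.top_n_per_direction))
    return tables, sorted(refined)


# ---------------------------------------------------------------------------
# normal-like identification
# ---------------------------------------------------------------------------

def identify_normal_like(
    clusters: pd.Series,
    obs: pd.DataFrame,
    frac_threshold: float = 0.5,
    enrichment: float = 3.0,
) -> set:
    """Clusters dominated by normal-tissue epithelium.

    A cluster is normal-like when it holds more than ``frac_threshold`` of all
    normal-tissue cells, or when its internal normal-cell fraction exceeds the
    dataset-wide normal fraction by at least ``enrichment``-fold.
    """
    tissue = obs["tissue"].reindex(clusters.index)
    is_normal = (tissue == "normal").to_numpy()
    if is_normal.sum() == 0:
        warnings.warn("no normal-tissue cells; cannot identify normal-like clusters")
        return set()
    total_norm = is_normal.sum()
    overall_frac = is_normal.mean()
    out = set()
    for c, grp_idx in clusters.groupby(clusters, observed=True).groups.items():
        in_c = clusters.index.isin(grp_idx)
        share_of_normals = (is_normal & in_c).sum() / total_norm
        frac_in_cluster = (is_normal & in_c).sum() / in_c.sum()
        if share_of_normals > frac_threshold or (
            overall_frac > 0 and frac_in_cluster >= enrichment * overall_frac
        ):
            out.add(str(c))
    return out


# ---------------------------------------------------------------------------
# patient pseudo-bulk split
# ---------------------------------------------------------------------------

def patient_pseudobulk_split(
    lognorm: ad.AnnData,
    malignant_mask,
    features,
    seed: int = 0,
    min_cells: int = 20,
):
    """Two-group split of patients from malignant-cell pseudo-bulk PCA.

    Pseudo-bulk = per-patient mean of log-normalized malignant cells over the
    feature genes, z-scored per gene; 2-means on the first two principal
    components (seeded).  Returns ``(groups, pca_coords, pseudobulk)`` with
    groups a patient -> {"A", "B"} Series (labels sorted so "A" is the larger
    group, ties by patient id).
    """
    malignant_mask = np.asarray(malignant_mask, dtype=bool)
    features = [f for f in features if f in set(lognorm.var_names)]
    sub = lognorm[malignant_mask, features]
    X = _dense(sub.X)
    patients = sub.obs["patient_id"]
    counts = patients.value_counts()
    usable = sorted(counts[counts >= min_cells].index)
    dropped = sorted(counts[counts < min_cells].index)
    if dropped:
        warnings.warn(f"excluding patients with < {min_cells} malignant cells: {dropped}")
    if len(usable) < 4:
        raise ValueError("patient split requires at least 4 usable patients")
    pb = np.vstack([X[(patients == p).to_numpy()].mean(axis=0) for p in usable])
    mu, sd = pb.mean(axis=0), pb.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (pb - mu) / sd
    pca = PCA(n_components=2, random_state=seed)
    coords = pca.fit_transform(Z)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(coords)
    lab = km.labels_
    # canonical naming independent of kmeans label order / patient order
    sizes = np.bincount(lab, minlength=2)
    first = int(np.argmax(sizes)) if sizes[0] != sizes[1] else int(lab[0])
    groups = pd.Series(
        np.where(lab == first, "A", "B"), index=usable, name="group"
    )
    pca_coords = pd.DataFrame(coords, index=usable, columns=["PC1", "PC2"])
    pseudobulk = pd.DataFrame(pb, index=usable, columns=features)
    return groups, pca_coords, pseudobulk


# ---------------------------------------------------------------------------
# first-stage markers
# ---------------------------------------------------------------------------

def derive_stage1_markers(
    lognorm: ad.AnnData,
    cell_groups: pd.Series,
    params: DEGParams | None = None,
    class_names: tuple = ("i2", "i3", "normal"),
) -> SignatureSet:
    """First-stage subtype markers from pairwise cell-level DEG analysis.

    ``cell_groups`` maps each epithelial cell to one of the three class names
    (patients grouped by the pseudo-bulk PCA split; normal-like cells as the
    third group).  A gene is a marker of a class only if it is a significant
    upregulated DEG against BOTH other classes.
    """
    params = params or DEGParams()
    cell_groups = cell_groups.reindex(lognorm.obs_names)
    present = [c for c in class_names if (cell_groups == c).sum() >= 2]
    if len(present) < 3:
        missing = set(class_names) - set(present)
        raise ValueError(f"groups with < 2 cells: {sorted(missing)}")
    X = _dense(lognorm.X)
    genes = np.asarray(lognorm.var_names)
    group_labels = cell_groups
    up_vs: dict[tuple, set] = {}
    for a, b in combinations(class_names, 2):
        df = _deg_table(
            X[(group_labels == a).to_numpy()],
            X[(group_labels == b).to_numpy()],
            genes,
            params,
        )
        deg = df[df["is_deg"]]
        up_vs[(a, b)] = set(deg.loc[deg["lnfc"] > 0, "gene"])
        up_vs[(b, a)] = set(deg.loc[deg["lnfc"] < 0, "gene"])
    classes = {}
    for cls in class_names:
        others = [c for c in class_names if c != cls]
        markers = up_vs[(cls, others[0])] & up_vs[(cls, others[1])]
        classes[cls] = {"Up": markers, "Down": set()}
    return SignatureSet(classes, provenance="stage1 pairwise pseudo-bulk DEG")
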