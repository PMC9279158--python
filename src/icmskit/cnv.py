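"""Reference-relative copy-number inference from single-cell transcriptomes.

A deliberately simplified smoothing scheme: genes expressed above a minimum
in the reference (normal-like) cells are ordered along the genome, each
query cell's log-ratio to the reference mean is clipped at +/- 3 reference
standard deviations, averaged in a moving window (default 101 genes) within
each chromosome, and median-centered per cell.  Downstream: Ward clustering
of patient pseudo-bulk profiles into two groups with concordance to the
transcriptome-derived subtypes, arm-level gain/loss calls, marker-arm
enrichment (hypergeometric), and marker-CNV direction concordance.

No HMM, no subclone segmentation, no integer copy calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster import hierarchy
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class CNVProfile:
    scores: pd.DataFrame  # entities x windows (window named by central gene)
    windows: pd.DataFrame  # per window: chromosome, arm, gene_id, position
    reference_ids: tuple

    @property
    def n_windows(self) -> int:
        return self.scores.shape[1]


def _dense(X):
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def _moving_average_1d(values: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges (axis=1)."""
    n = values.shape[1]
    if n == 0:
        return values
    half = w // 2
    cs = np.cumsum(values, axis=1)
    cs = np.concatenate([np.zeros((values.shape[0], 1)), cs], axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[:, hi] - cs[:, lo]) / (hi - lo)


def infer_cnv_profile(
    lognorm,
    reference_mask,
    window: int = 101,
    ref_min_mean: float = 0.1,
    clip_sd: float = 3.0,
) -> CNVProfile:
    """Smoothed relative-expression profile per cell.

    Genes whose mean normalized count among reference cells is below
    ``ref_min_mean`` are excluded before smoothing.  Chromosomes with fewer
    genes than the window simply use all their genes (the window shrinks).
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.sum() == 0:
        raise ValueError("reference cell set is empty")
    var = lognorm.var
    for col in ("chromosome", "arm", "start_bp"):
        if col not in var.columns:
            raise ValueError(f"gene annotation lacks {col!r}")

    X = _dense(lognorm.X)
    ref = X[reference_mask]
    ref_mean_counts = np.expm1(ref).mean(axis=0)
    keep = ref_mean_counts >= ref_min_mean
    # genomic ordering within chromosome, mitochondria excluded
    if "is_mito" in var.columns:
        keep &= ~var["is_mito"].to_numpy(dtype=bool)

    order = var.assign(_keep=keep).reset_index(drop=True)
    order = order[order["_keep"].to_numpy()]
    order = order.sort_values(["chromosome", "arm", "start_bp"], kind="mergesort")
    gidx = order.index.to_numpy()

    rel = X[:, gidx] - ref[:, gidx].mean(axis=0)
    sd = ref[:, gidx].std(axis=0)
    lim = clip_sd * np.where(sd > 0, sd, np.median(sd[sd > 0]) if (sd > 0).any() else 1.0)
    rel = np.clip(rel, -lim, lim)

    smooth = np.empty_like(rel)
    chroms = order["chromosome"].to_numpy()
    for c in pd.unique(chroms):
        cols = np.flatnonzero(chroms == c)
        smooth[:, cols] = _moving_average_1d(rel[:, cols], window)
    smooth = smooth - np.median(smooth, axis=1, keepdims=True)

    windows = pd.DataFrame(
        {
            "gene_id": order["gene_id"].to_numpy(),
            "chromosome": order["chromosome"].to_numpy(),
            "arm": order["arm"].to_numpy(),
            "start_bp": order["start_bp"].to_numpy(),
        }
    )
    scores = pd.DataFrame(smooth, index=lognorm.obs_names, columns=windows["gene_id"])
    return CNVProfile(
        scores=scores,
        windows=windows,
        reference_ids=tuple(lognorm.obs_names[reference_mask]),
    )


def patient_mean_profiles(profile: CNVProfile, patient_ids: pd.Series) -> pd.DataFrame:
    patient_ids = patient_ids.reindex(profile.scores.index)
    return profile.scores.groupby(patient_ids, observed=True).mean()


def cluster_cnv_pseudobulk(
    profile: CNVProfile,
    patient_ids: pd.Series,
    transcriptome_labels: pd.Series,
):
    """Ward k=2 clustering of patient-mean CNV profiles + concordance.

    Concordance is the best label-matching agreement between the CNV split
    and the transcriptome-derived subtype labels, so it is invariant to
    swapping group names.  Returns ``(cnv_groups, concordance)``.
    """
    pb = patient_mean_profiles(profile, patient_ids)
    if len(pb) < 4:
        raise ValueError("CNV patient clustering requires >= 4 patients")
    if float(np.ptp(pb.to_numpy())) < 1e-12:
        raise ValueError("all patient CNV profiles identical; no 2-group structure")
    Z = hierarchy.linkage(pb.to_numpy(), method="ward")
    lab = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    cnv_groups = pd.Series(lab, index=pb.index, name="cnv_group")
    t = transcriptome_labels.reindex(pb.index)
    ok = t.notna()
    agree = 0.0
    if ok.any():
        tl = t[ok].astype(str)
        cl = cnv_groups[ok]
        classes = sorted(tl.unique())
        if len(classes) == 2:
            m1 = ((cl == 1) == (tl == classes[0])).mean()
            agree = float(max(m1, 1.0 - m1))
        else:
            agree = float((cl == cl.mode()[0]).mean())
    return cnv_groups, agree


@dataclass
class ArmSummary:
    scores: pd.DataFrame  # entity/group x arm mean scores
    calls: pd.DataFrame  # entity/group x arm in {gain, loss, neutral}
    threshold: float


def arm_level_summary(
    profile: CNVProfile,
    group_by: pd.Series | None = None,
    threshold: float = 0.05,
    all_arms: list | None = None,
) -> ArmSummary:
    """Mean window score per chromosome arm with gain/loss calls.

    ``group_by`` (entity -> group) averages entities first; arms with no
    profiled genes are reported neutral (score NaN).
    """
    scores = profile.scores
    if group_by is not None:
        scores = scores.groupby(group_by.reindex(scores.index), observed=True).mean()
    arm_key = profile.windows["chromosome"].astype(str) + profile.windows["arm"].astype(str)
    arm_scores = scores.T.groupby(arm_key.to_numpy()).mean().T
    if all_arms:
        arm_scores = arm_scores.reindex(columns=sorted(set(all_arms) | set(arm_scores.columns)))
    calls = pd.DataFrame("neutral", index=arm_scores.index, columns=arm_scores.columns)
    calls = calls.mask(arm_scores > threshold, "gain").mask(arm_scores < -threshold, "loss")
    calls = calls.mask(arm_scores.isna(), "neutral")
    return ArmSummary(scores=arm_scores, calls=calls, threshold=threshold)


def marker_arm_enrichment(
    signature,
    lognorm,
    classes: tuple = ("i2", "i3"),
    expressed_frac: float = 0.05,
) -> pd.DataFrame:
    """Per-arm marker density and hypergeometric enrichment.

    Expressed genes are those with nonzero counts in at least
    ``expressed_frac`` of cells; density = markers on arm / expressed genes on
    arm; p from the hypergeometric tail, BH-corrected across arms per class.
    """
    X = _dense(lognorm.X)
    frac = (X > 0).mean(axis=0)
    var = lognorm.var
    expressed = frac >= expressed_frac
    arm_key = (var["chromosome"].astype(str) + var["arm"].astype(str)).to_numpy()
    if "is_mito" in var.columns:
        expressed = expressed & ~var["is_mito"].to_numpy(dtype=bool)
    expr_genes = set(np.asarray(lognorm.var_names)[expressed])

    rows = []
    for cls in classes:
        markers = (set(signature.up(cls)) | set(signature.down(cls))) & expr_genes
        n_total, k_total = len(expr_genes), len(markers)
        for arm in pd.unique(arm_key[expressed]):
            on_arm = set(np.asarray(lognorm.var_names)[expressed & (arm_key == arm)])
            n_arm = len(on_arm)
            k_arm = len(markers & on_arm)
            density = k_arm / n_arm if n_arm else np.nan
            p = hypergeom.sf(k_arm - 1, n_total, k_total, n_arm) if n_arm else np.nan
            rows.append((cls, arm, n_arm, k_arm, density, p))
    df = pd.DataFrame(
        rows, columns=["class", "arm", "n_expressed", "n_markers", "density", "p"]
    )
    df["q"] = np.nan
    for cls in classes:
        m = df["class"] == cls
        ok = m & df["p"].notna()
        if ok.any():
            df.loc[ok, "q"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    return df


def marker_cnv_concordance(
    signature,
    arm_calls: pd.Series,
    gene_annotation: pd.DataFrame,
    cls: str = "i2",
):
    """Fraction of markers on called arms whose direction matches the call.

    ``arm_calls`` maps arm (e.g. "8q") -> {gain, loss, neutral} for the class
    of interest; a marker is concordant iff it is Up on a gained arm or Down
    on a lost arm.  Returns ``(fraction, per_gene_table)``.
    """
    arm_of = (
        gene_annotation["chromosome"].astype(str) + gene_annotation["arm"].astype(str)
    )
    rows = []
    for direction in ("Up", "Down"):
        genes = signature.up(cls) if direction == "Up" else signature.down(cls)
        for g in genes:
            if g not in arm_of.index:
                continue
            arm = arm_of.loc[g]
            call = arm_calls.get(arm, "neutral")
            if call == "neutral":
                continue
            concordant = (direction == "Up" and call == "gain") or (
                direction == "Down" and call == "loss"
            )
            rows.append((g, arm, direction, call, concordant))
    table = pd.DataFrame(
        rows, columns=["gene", "arm", "direction", "arm_call", "concordant"]
    )
    if table.empty:
        warnings.warn("no markers on gained/lost arms")
        return float("nan"), table
    return float(table["concordant"].mean()), table
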