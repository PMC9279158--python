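"""Metagene scoring and score-based cell classification.

All scores operate on per-cohort z-scaled expression (each gene zero-centered
and scaled to unit variance within its cohort, which removes additive batch
shifts), and a metagene score is simply the mean of the scaled values over the
genes of a set.  Cells are called preferentially i2 or i3 when the difference
of the two subtype metagene scores exceeds a margin (default 0.1 z-units);
tumors in which no single subtype reaches 80% of cells are flagged hybrid,
and bimodality of the score difference is assessed with a 1- vs 2-component
Gaussian mixture BIC comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .io import SignatureSet


def zscore_within_cohort(matrix: pd.DataFrame, cohorts: pd.Series):
    """Zero-center and unit-scale each gene within each cohort.

    ``matrix`` is entities x genes.  Returns ``(scaled, zero_variance)`` where
    ``zero_variance`` is a boolean cohort x gene frame marking genes that were
    constant within a cohort (set to 0 there).
    """
    cohorts = pd.Series(cohorts).reindex(matrix.index)
    if cohorts.isna().any():
        raise ValueError("every entity needs a cohort label")
    scaled = np.empty_like(matrix.to_numpy(), dtype=float)
    flags = {}
    for c, idx in matrix.groupby(cohorts, observed=True).groups.items():
        pos = matrix.index.get_indexer(idx)
        if len(pos) < 2:
            raise ValueError(f"cohort {c!r} has a single entity; cannot scale")
        block = matrix.to_numpy()[pos]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        zero = sd == 0
        sd_safe = np.where(zero, 1.0, sd)
        scaled[pos] = (block - mu) / sd_safe
        scaled[np.ix_(pos, np.flatnonzero(zero))] = 0.0
        flags[c] = zero
    zero_variance = pd.DataFrame(flags, index=matrix.columns).T
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns), zero_variance


@dataclass
class MetageneScore:
    scores: pd.Series  # entity -> score
    coverage: float  # fraction of set genes present in the matrix
    genes_used: tuple


def metagene_score(scaled: pd.DataFrame, gene_set) -> MetageneScore:
    """Mean of scaled values over the present genes of the set."""
    gene_set = list(gene_set)
    present = [g for g in gene_set if g in scaled.columns]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    coverage = len(present) / len(gene_set)
    scores = scaled[present].mean(axis=1)
    return MetageneScore(scores=scores, coverage=coverage, genes_used=tuple(present))


def signature_scores(
    scaled: pd.DataFrame, signature: SignatureSet, mode: str = "up"
) -> pd.DataFrame:
    """Per-entity metagene score for every signature class.

    ``mode='up'`` averages the Up genes only; ``mode='signed'`` uses
    mean(Up) - mean(Down).
    """
    out = {}
    for cls in signature.class_labels:
        up = signature.up(cls)
        score = metagene_score(scaled, up).scores if up else pd.Series(0.0, index=scaled.index)
        if mode == "signed" and signature.down(cls):
            score = score - metagene_score(scaled, signature.down(cls)).scores
        elif mode not in ("up", "signed"):
            raise ValueError(f"unknown scoring mode {mode!r}")
        out[cls] = score
    return pd.DataFrame(out)


@dataclass
class CellSubtypeCall:
    calls: pd.Series  # cell -> preferential_i2 / preferential_i3 / ambiguous
    tumor_fractions: pd.DataFrame  # tumor x three fractions
    hybrid_tumors: pd.Series  # tumor -> bool
    bimodality: dict  # BIC for 1 and 2 components + preferred


def classify_cells_by_score(
    i2_score: pd.Series,
    i3_score: pd.Series,
    tumor_ids: pd.Series | None = None,
    delta: float = 0.1,
    majority: float = 0.8,
    seed: int = 0,
) -> CellSubtypeCall:
    """Score-difference cell classification with a hybrid-tumor flag.

    A cell is preferential for a subtype when that subtype's score exceeds the
    other by strictly more than ``delta``; otherwise ambiguous.  A tumor is
    hybrid when fewer than ``majority`` of its cells are preferential for one
    single subtype.  Bimodality of the i2-i3 score difference is reported as
    the BIC-preferred number (1 or 2) of Gaussian mixture components.
    """
    if not i2_score.index.equals(i3_score.index):
        raise ValueError("scores must be computed on the same cells")
    diff = i2_score - i3_score
    calls = pd.Series("ambiguous", index=diff.index, dtype=object)
    calls[diff > delta] = "preferential_i2"
    calls[-diff > delta] = "preferential_i3"

    d = diff.to_numpy().reshape(-1, 1)
    bic = {}
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, n_init=3, random_state=seed).fit(d)
        bic[k] = float(gm.bic(d))
    bimodality = {"bic_1": bic[1], "bic_2": bic[2], "n_components": 2 if bic[2] < bic[1] else 1}

    if tumor_ids is None:
        tumor_ids = pd.Series("all", index=diff.index)
    tumor_ids = tumor_ids.reindex(diff.index)
    frac = (
        pd.crosstab(tumor_ids, calls, normalize="index")
        .reindex(columns=["preferential_i2", "preferential_i3", "ambiguous"], fill_value=0.0)
    )
    hybrid = frac[["preferential_i2", "preferential_i3"]].max(axis=1) < majority
    return CellSubtypeCall(
        calls=calls, tumor_fractions=frac, hybrid_tumors=hybrid, bimodality=bimodality
    )


# ---------------------------------------------------------------------------
# marker -> cell-type assignment (the eCMS construction)
# ---------------------------------------------------------------------------

def celltype_pseudobulk(
    lognorm, cell_types: pd.Series, patient_ids: pd.Series | None = None
) -> pd.DataFrame:
    """Cell-type x gene pseudo-bulk: mean over patients of per-patient means."""
    import scipy.sparse as sp

    X = lognorm.X
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    cell_types = cell_types.reindex(lognorm.obs_names)
    if patient_ids is None:
        patient_ids = lognorm.obs["patient_id"]
    patient_ids = patient_ids.reindex(lognorm.obs_names)
    df = pd.DataFrame(X, index=lognorm.obs_names, columns=lognorm.var_names)
    per_patient = df.groupby([cell_types, patient_ids], observed=True).mean()
    return per_patient.groupby(level=0, observed=True).mean()


def assign_markers_to_celltypes(
    celltype_pb: pd.DataFrame,
    marker_sets: dict,
    epithelial_label: str = "epithelial",
):
    """Assign each marker gene to the cell type of its highest pseudo-bulk
    expression; extract the epithelial-specific subset per class.

    ``marker_sets`` maps class label -> iterable of genes.  Ties at the argmax
    are broken by the fixed row order of ``celltype_pb`` and flagged.
    Returns ``(assignment_frame, epithelial_subsets)``.
    """
    rows = []
    epi_subsets: dict[str, list] = {cls: [] for cls in marker_sets}
    types = list(celltype_pb.index)
    for cls, genes in marker_sets.items():
        for g in genes:
            if g not in celltype_pb.columns:
                continue
            vals = celltype_pb[g]
            best = vals.idxmax()  # first occurrence wins on ties
            tie = (vals == vals.max()).sum() > 1
            rows.append((g, cls, best, bool(tie)))
            if best == epithelial_label:
                epi_subsets[cls].append(g)
    frame = pd.DataFrame(rows, columns=["gene", "class", "cell_type", "tie"])
    return frame, {cls: sorted(v) for cls, v in epi_subsets.items()}


def bulk_celltype_metagenes(
    bulk_scaled: pd.DataFrame, celltype_markers: dict, min_coverage: float = 0.2
) -> pd.DataFrame:
    """One metagene score per (sample, cell type) on z-scored bulk data.

    ``bulk_scaled`` is samples x genes; ``celltype_markers`` maps cell type ->
    marker genes.
    """
    out = {}
    for ct, genes in celltype_markers.items():
        ms = metagene_score(bulk_scaled, genes)
        if ms.coverage < min_coverage:
            warnings.warn(f"cell type {ct!r}: marker coverage {ms.coverage:.0%} < 20%")
        out[ct] = ms.scores
    return pd.DataFrame(out)
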