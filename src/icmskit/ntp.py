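"""Nearest-template classification of bulk transcriptomes and the layered
IMF (Intrinsic subtype / MSI / Fibrosis) call.

Each class template is +1 on its Up genes and -1 on its Down genes over the
union of signature genes present in the matrix.  A sample is assigned the
class of the nearest template by cosine (default) or correlation distance;
significance comes from a gene-resampling null: random templates of identical
size and sign structure drawn from all genes, p = (1 + #null <= observed) /
(1 + n_perm), BH-corrected across samples, with q >= q_threshold reported as
indeterminate.  The IMF call layers the intrinsic class with the MSI label
and a fibrosis flag (CMS4 label, or a fibroblast metagene above a dataset
quantile when CMS labels are absent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import SignatureSet

IMF_CLASSES = (
    "iCMS2_MSS_NF",
    "iCMS2_MSS_F",
    "iCMS3_MSS_NF",
    "iCMS3_MSS_F",
    "iCMS3_MSI",
    "non_canonical",
    "unclassified",
)


@dataclass
class NTPResult:
    table: pd.DataFrame  # sample-indexed: predicted, distance_<cls>..., p, q, call
    n_permutations: int
    seed: int
    q_threshold: float


def _distance(V: np.ndarray, T: np.ndarray, metric: str) -> np.ndarray:
    """1 - cosine (or Pearson) similarity between sample rows and template cols."""
    if metric == "correlation":
        V = V - V.mean(axis=1, keepdims=True)
        T = T - T.mean(axis=0, keepdims=True)
    vn = np.linalg.norm(V, axis=1)
    tn = np.linalg.norm(T, axis=0)
    vn[vn == 0] = 1.0
    sim = (V @ T) / vn[:, None] / tn[None, :]
    return 1.0 - sim


def ntp_classify(
    bulk_scaled: pd.DataFrame,
    signature: SignatureSet,
    n_perm: int = 1000,
    q_threshold: float = 0.05,
    seed: int = 0,
    metric: str = "cosine",
    class_names: tuple = ("iCMS2", "iCMS3"),
    signature_classes: tuple = ("i2", "i3"),
) -> NTPResult:
    """Classify z-scored bulk samples (samples x genes) by nearest template."""
    genes = bulk_scaled.columns
    present = {}
    for sc in signature_classes:
        up = [g for g in signature.up(sc) if g in genes]
        down = [g for g in signature.down(sc) if g in genes]
        n_sig = len(signature.up(sc)) + len(signature.down(sc))
        if len(up) + len(down) < 10:
            raise ValueError(f"class {sc!r}: fewer than 10 signature genes present")
        if n_sig and (len(up) + len(down)) / n_sig < 0.5:
            warnings.warn(f"class {sc!r}: signature coverage below 50%")
        present[sc] = (up, down)

    union = sorted({g for up, down in present.values() for g in up + down})
    gpos = {g: i for i, g in enumerate(union)}
    V = bulk_scaled[union].to_numpy(dtype=float)
    n_samples = V.shape[0]

    templates = np.zeros((len(union), len(signature_classes)))
    for k, sc in enumerate(signature_classes):
        up, down = present[sc]
        templates[[gpos[g] for g in up], k] = 1.0
        templates[[gpos[g] for g in down], k] = -1.0

    D = _distance(V, templates, metric)
    pred_ix = np.argmin(D, axis=1)
    obs_dist = D[np.arange(n_samples), pred_ix]

    # Permutation null: each draw resamples, for EVERY class, a random gene
    # set of identical size and sign structure, and recomputes the full
    # statistic — distances on the drawn gene union, then the min over
    # classes.  Both the min-selection and the dimensionality of the
    # signature restriction must be replicated or the p-values are
    # anti-conservative.
    rng = np.random.default_rng(seed)
    all_vals = bulk_scaled.to_numpy(dtype=float)
    n_genes_all = all_vals.shape[1]
    sizes = {sc: (len(present[sc][0]), len(present[sc][1])) for sc in signature_classes}
    n_union = sum(u + d for u, d in sizes.values())
    null_min = np.empty((n_samples, n_perm))
    for j in range(n_perm):
        pick = rng.choice(n_genes_all, size=n_union, replace=False)
        sub = all_vals[:, pick]
        T = np.zeros((n_union, len(signature_classes)))
        pos = 0
        for k, sc in enumerate(signature_classes):
            n_up, n_down = sizes[sc]
            T[pos : pos + n_up, k] = 1.0
            T[pos + n_up : pos + n_up + n_down, k] = -1.0
            pos += n_up + n_down
        null_min[:, j] = _distance(sub, T, metric).min(axis=1)
    pvals = (1.0 + (null_min <= obs_dist[:, None]).sum(axis=1)) / (1.0 + n_perm)

    qvals = multipletests(pvals, method="fdr_bh")[1]
    predicted = np.asarray(class_names, dtype=object)[pred_ix]
    call = np.where(qvals < q_threshold, predicted, "indeterminate")
    table = pd.DataFrame(
        {
            "predicted": predicted,
            "call": call,
            "p": pvals,
            "q": qvals,
        },
        index=bulk_scaled.index,
    )
    for k, cn in enumerate(class_names):
        table[f"distance_{cn}"] = D[:, k]
    return NTPResult(table=table, n_permutations=n_perm, seed=seed, q_threshold=q_threshold)


def fibrosis_flag(
    labels: pd.DataFrame | None = None,
    bulk_scaled: pd.DataFrame | None = None,
    fibroblast_markers=None,
    threshold_quantile: float = 0.75,
) -> pd.Series:
    """Per-sample F/NF call.

    When CMS labels are available, F iff CMS4.  Otherwise the fibroblast
    metagene on the z-scored matrix is thresholded at the dataset quantile.
    The provenance of each call is recorded in the Series name attrs.
    """
    if labels is not None and "cms" in labels.columns and (labels["cms"] != "unknown").any():
        known = labels["cms"] != "unknown"
        flags = pd.Series("NF", index=labels.index, dtype=object)
        flags[labels["cms"] == "CMS4"] = "F"
        if (~known).any() and bulk_scaled is not None and fibroblast_markers is not None:
            meta = _fibro_metagene(bulk_scaled, fibroblast_markers)
            cut = meta.quantile(threshold_quantile)
            flags[(~known).to_numpy()] = np.where(
                meta[(~known).to_numpy()] > cut, "F", "NF"
            )
        flags.attrs["source"] = "cms_label"
        return flags
    if bulk_scaled is None or fibroblast_markers is None:
        raise ValueError("need CMS labels or a fibroblast marker set")
    meta = _fibro_metagene(bulk_scaled, fibroblast_markers)
    cut = meta.quantile(threshold_quantile)
    flags = pd.Series(np.where(meta > cut, "F", "NF"), index=bulk_scaled.index, dtype=object)
    flags.attrs["source"] = "fibroblast_metagene"
    return flags


def _fibro_metagene(bulk_scaled: pd.DataFrame, markers) -> pd.Series:
    from .scoring import metagene_score

    return metagene_score(bulk_scaled, list(markers)).scores


def imf_classify(
    ntp: NTPResult,
    msi_labels: pd.Series,
    fibrosis_flags: pd.Series,
) -> pd.DataFrame:
    """Layered IMF class per sample.

    Rule table: (iCMS2, MSS) -> iCMS2_MSS_NF/F; (iCMS3, MSS) -> iCMS3_MSS_NF/F;
    (iCMS3, MSI-H) -> iCMS3_MSI regardless of fibrosis; (iCMS2, MSI-H) ->
    non_canonical; indeterminate or missing layers -> unclassified.
    """
    idx = ntp.table.index
    msi = msi_labels.reindex(idx)
    fib = fibrosis_flags.reindex(idx)
    out = []
    for s in idx:
        i_call = ntp.table.loc[s, "call"]
        m, f = msi.loc[s], fib.loc[s]
        if i_call == "indeterminate" or pd.isna(m) or m == "unknown" or pd.isna(f):
            out.append("unclassified")
        elif i_call == "iCMS3" and m == "MSI-H":
            out.append("iCMS3_MSI")
        elif i_call == "iCMS2" and m == "MSI-H":
            out.append("non_canonical")
        else:
            out.append(f"{i_call}_MSS_{f}")
    return pd.DataFrame(
        {"intrinsic": ntp.table["call"], "msi": msi, "fibrosis": fib, "imf_class": out},
        index=idx,
    )
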