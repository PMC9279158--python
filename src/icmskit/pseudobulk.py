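"""Pseudo-bulk negative-binomial differential expression and the final
directional subtype signature.

Per-patient pseudo-bulk profiles are exact sums of UMI counts over cells.
Testing follows the standard bulk RNA-seq NB GLM recipe: median-of-ratios
size factors, a log-link NB GLM per gene with design ``group + cohort``,
gene-wise dispersion by Cox-Reid-adjusted profile maximum likelihood (with a
method-of-moments fallback), and a Wald test on the group coefficient with
Benjamini-Hochberg correction across tested genes.  Fold-change shrinkage is
deliberately not applied; thresholds act on the maximum-likelihood log2
fold-change estimates.

A gene enters the directional signature (i2_Up / i2_Down / i3_Up / i3_Down)
only when it passes the effect-size, significance and abundance thresholds
consistently against BOTH other groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm as _normal
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .io import SignatureSet

_MIN_ALPHA, _MAX_ALPHA = 1e-8, 10.0


@dataclass
class PseudoBulkMatrix:
    counts: pd.DataFrame  # patients x genes, integer sums
    meta: pd.DataFrame  # patient-indexed: group, cohort_id

    def __post_init__(self):
        self.meta = self.meta.reindex(self.counts.index)
        if self.meta["group"].isna().any():
            raise ValueError("every pseudo-bulk unit needs a group label")


def sum_pseudobulk(
    counts_adata,
    patient_labels: pd.Series,
    groups: pd.Series,
    min_detect_frac: float = 0.05,
) -> PseudoBulkMatrix:
    """Sum UMI counts per patient and drop rarely-detected genes.

    Genes detected (nonzero pseudo-bulk count) in fewer than
    ``min_detect_frac`` of patients are discarded; the filter is idempotent.
    """
    X = counts_adata.X
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    patient_labels = patient_labels.reindex(counts_adata.obs_names)
    if patient_labels.isna().any():
        raise ValueError("every cell needs a patient label")
    df = pd.DataFrame(X, index=counts_adata.obs_names, columns=counts_adata.var_names)
    pb = df.groupby(patient_labels, observed=True).sum()
    if (pb.sum(axis=1) == 0).any():
        raise ValueError("patient with zero total counts")
    detect = (pb > 0).mean(axis=0)
    pb = pb.loc[:, detect >= min_detect_frac]
    cohort = (
        counts_adata.obs.groupby(patient_labels, observed=True)["cohort_id"].first()
        if "cohort_id" in counts_adata.obs
        else pd.Series("cohort", index=pb.index)
    )
    meta = pd.DataFrame({"group": groups.reindex(pb.index), "cohort_id": cohort.reindex(pb.index)})
    return PseudoBulkMatrix(counts=pb.astype(np.int64), meta=meta)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization over positive-geometric-mean genes."""
    with np.errstate(divide="ignore"):
        logc = np.log(counts.to_numpy(dtype=float))
        log_geo = np.mean(np.where(np.isfinite(logc), logc, -np.inf), axis=0)
    usable = np.isfinite(log_geo)
    if usable.sum() < 10:
        raise ValueError("too few all-positive genes for median-of-ratios size factors")
    ratios = logc[:, usable] - log_geo[usable]
    sf = np.exp(np.median(ratios, axis=1))
    return pd.Series(sf, index=counts.index, name="size_factor")


def _nb_loglik(y, mu, alpha):
    size = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + size) - gammaln(size) - gammaln(y + 1)
            + size * np.log(size / (size + mu))
            + y * np.log(mu / (size + mu))
        )
    )


def _cr_adjustment(X, mu, alpha):
    # Cox-Reid term: -0.5 * log det(X' W X) with W the GLM working weights
    w = mu / (1.0 + alpha * mu)
    xtwx = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(xtwx)
    return -0.5 * logdet if sign > 0 else -np.inf


def _estimate_dispersion(y, X, mu, moment_alpha):
    """Cox-Reid adjusted profile ML dispersion given fitted means."""

    def neg_apl(log_a):
        a = float(np.exp(log_a))
        return -(_nb_loglik(y, mu, a) + _cr_adjustment(X, mu, a))

    res = minimize_scalar(
        neg_apl, bounds=(np.log(_MIN_ALPHA), np.log(_MAX_ALPHA)), method="bounded",
        options={"xatol": 1e-3},
    )
    if res.success and np.isfinite(res.fun):
        return float(np.exp(res.x))
    return moment_alpha


@dataclass
class DEGResult:
    table: pd.DataFrame  # per gene: log2fc, se, p, q, base_mean, converged
    contrast: tuple  # (group_a, group_b): log2fc > 0 means higher in group_a
    design_columns: tuple


def nb_deg_test(
    pb: PseudoBulkMatrix,
    contrast: tuple,
    cohort_covariate: bool = True,
) -> DEGResult:
    """Wald test of ``contrast = (a, b)`` on the group coefficient of a
    per-gene NB GLM with log link and design ``~ group + cohort``.

    Requires >= 2 patients per group; the cohort covariate is dropped when
    only one cohort is present.  Non-convergent fits are flagged and excluded
    from the BH correction.
    """
    a, b = contrast
    mask = pb.meta["group"].isin([a, b]).to_numpy()
    counts = pb.counts.loc[mask]
    meta = pb.meta.loc[mask]
    if (meta["group"] == a).sum() < 2 or (meta["group"] == b).sum() < 2:
        raise ValueError(f"need >= 2 patients per group for contrast {contrast}")
    sf = size_factors(counts)
    offset = np.log(sf.to_numpy())

    design = pd.DataFrame({"intercept": 1.0}, index=counts.index)
    design["group"] = (meta["group"] == a).astype(float)
    if cohort_covariate and meta["cohort_id"].nunique() > 1:
        dummies = pd.get_dummies(meta["cohort_id"], prefix="cohort", drop_first=True)
        design = pd.concat([design, dummies.astype(float)], axis=1)
    X = design.to_numpy()
    norm_counts = counts.to_numpy(dtype=float) / sf.to_numpy()[:, None]
    base_mean = norm_counts.mean(axis=0)

    n_genes = counts.shape[1]
    log2fc = np.zeros(n_genes)
    se = np.full(n_genes, np.nan)
    pvals = np.full(n_genes, np.nan)
    alphas = np.full(n_genes, np.nan)
    converged = np.zeros(n_genes, dtype=bool)
    ln2 = np.log(2.0)
    group_ix = list(design.columns).index("group")

    for j in range(n_genes):
        y = counts.to_numpy()[:, j].astype(float)
        if np.all(y == 0):
            continue
        m = norm_counts[:, j].mean()
        v = norm_counts[:, j].var(ddof=1)
        moment_alpha = min(max((v - m) / max(m**2, 1e-12), _MIN_ALPHA), _MAX_ALPHA)
        alpha = moment_alpha
        params = None
        try:
            for _ in range(3):
                model = sm.GLM(
                    y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = model.fit(start_params=params, maxiter=50)
                params = fit.params
                mu = fit.mu
                new_alpha = _estimate_dispersion(y, X, mu, moment_alpha)
                if abs(np.log(new_alpha) - np.log(alpha)) < 1e-2:
                    alpha = new_alpha
                    break
                alpha = new_alpha
            model = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(start_params=params, maxiter=50)
            coef, bse = fit.params[group_ix], fit.bse[group_ix]
            if not (np.isfinite(coef) and np.isfinite(bse) and bse > 0):
                continue
            log2fc[j] = coef / ln2
            se[j] = bse / ln2
            z = coef / bse
            pvals[j] = 2.0 * _normal.sf(abs(z))
            alphas[j] = alpha
            converged[j] = True
        except (np.linalg.LinAlgError, ValueError):
            continue

    qvals = np.full(n_genes, np.nan)
    ok = converged & np.isfinite(pvals)
    if ok.any():
        qvals[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": counts.columns,
            "log2fc": log2fc,
            "se": se,
            "p": pvals,
            "q": qvals,
            "base_mean": base_mean,
            "dispersion": alphas,
            "converged": converged,
        }
    ).set_index("gene", drop=False).rename_axis(None)
    return DEGResult(table=table, contrast=(a, b), design_columns=tuple(design.columns))


# ---------------------------------------------------------------------------
# final signature
# ---------------------------------------------------------------------------

@dataclass
class SignatureParams:
    min_abs_log2fc: float = float(np.log2(1.5))
    max_q: float = 0.05
    abundance_mode: str = "absolute"  # or "percentile"
    abundance_threshold: float = 0.75  # counts if absolute; quantile if percentile


def _passing(table: pd.DataFrame, params: SignatureParams, sign: int) -> set:
    """Genes significant with the given fold-change sign and abundance."""
    if params.abundance_mode == "absolute":
        abundant = table["base_mean"] >= params.abundance_threshold
    elif params.abundance_mode == "percentile":
        cut = table.loc[table["converged"], "base_mean"].quantile(params.abundance_threshold)
        abundant = table["base_mean"] >= cut
    else:
        raise ValueError(f"unknown abundance mode {params.abundance_mode!r}")
    ok = (
        table["converged"]
        & (table["q"] <= params.max_q)
        & (sign * table["log2fc"] >= params.min_abs_log2fc)
        & abundant
    )
    return set(table.index[ok])


def derive_icms_signature(
    results: dict,
    params: SignatureParams | None = None,
    groups: tuple = ("i2", "i3", "normal"),
) -> SignatureSet:
    """Directional subtype signature from the three pairwise contrasts.

    ``results`` maps a frozenset-able pair (a, b) -> DEGResult with log2fc > 0
    meaning higher in ``a``.  A gene is <s>_Up only if up (passing every
    threshold) versus BOTH other groups, <s>_Down only if down versus both.
    """
    params = params or SignatureParams()
    items = results.values() if isinstance(results, dict) else results
    lookup = {res.contrast: res for res in items}

    def up_set(x, y):
        if (x, y) in lookup:
            return _passing(lookup[(x, y)].table, params, +1)
        if (y, x) in lookup:
            return _passing(lookup[(y, x)].table, params, -1)
        raise ValueError(f"missing contrast between {x!r} and {y!r}")

    def down_set(x, y):
        if (x, y) in lookup:
            return _passing(lookup[(x, y)].table, params, -1)
        if (y, x) in lookup:
            return _passing(lookup[(y, x)].table, params, +1)
        raise ValueError(f"missing contrast between {x!r} and {y!r}")

    i2, i3, norm = groups
    classes = {
        i2: {
            "Up": up_set(i2, i3) & up_set(i2, norm),
            "Down": down_set(i2, i3) & down_set(i2, norm),
        },
        i3: {
            "Up": up_set(i3, i2) & up_set(i3, norm),
            "Down": down_set(i3, i2) & down_set(i3, norm),
        },
    }
    return SignatureSet(classes, provenance="pseudo-bulk NB DEG consistency rule")


# ---------------------------------------------------------------------------
# DEG-count distances
# ---------------------------------------------------------------------------

def _tree_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _tree_to_newick(node.get_left(), labels)
    right = _tree_to_newick(node.get_right(), labels)
    return f"({left}:{node.dist / 2:.4g},{right}:{node.dist / 2:.4g})"


def deg_count_distance(
    pb: PseudoBulkMatrix,
    sig_params: SignatureParams | None = None,
    cohort_covariate: bool = True,
):
    """Pairwise number-of-DEGs distance between patient groups + dendrogram.

    d(a, b) = number of genes passing the NB-test thresholds between groups a
    and b; symmetric with zero diagonal.  The tree uses average linkage.
    Returns ``(distance_frame, linkage_matrix, newick)``.
    """
    sig_params = sig_params or SignatureParams()
    labels = sorted(pb.meta["group"].dropna().unique())
    if len(labels) < 3:
        raise ValueError("DEG-count dendrogram requires >= 3 groups")
    for g in labels:
        if (pb.meta["group"] == g).sum() < 2:
            raise ValueError(f"group {g!r} has < 2 patients")
    D = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        res = nb_deg_test(pb, (a, b), cohort_covariate=cohort_covariate)
        n_deg = len(_passing(res.table, sig_params, +1) | _passing(res.table, sig_params, -1))
        D.loc[a, b] = D.loc[b, a] = float(n_deg)
    condensed = hierarchy.distance.squareform(D.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    tree = hierarchy.to_tree(Z)
    newick = _tree_to_newick(tree, labels) + ";"
    return D, Z, newick
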