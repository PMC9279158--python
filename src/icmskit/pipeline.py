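"""End-to-end orchestration: qc -> discovery -> markers -> scoring -> cnv ->
bulk classification -> IMF, with a machine-readable run report.

The driver runs on any conforming dataset (counts + cell metadata + gene
annotation + reference profiles + bulk matrix); when given a simulation
config instead it generates the inputs itself and additionally reports
truth-based recovery metrics.  All randomness is routed through one base
seed; stage results are cached on disk so partial reruns resume without
changing results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import discovery, qc
from . import ntp as ntp_mod
from . import pseudobulk as pb_mod
from . import scoring
from .io import SignatureSet
from .simulate import (
    SimConfig,
    build_gene_universe,
    celltype_reference_profiles,
    simulate_bulk_cohort,
    simulate_sc_cohorts,
)

log = logging.getLogger("icmskit")


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    deg_params: discovery.DEGParams = field(default_factory=discovery.DEGParams)
    sig_params: pb_mod.SignatureParams = field(default_factory=pb_mod.SignatureParams)
    cluster_resolution: float = 0.2
    recluster_resolution: float = 0.5
    n_features: int = 500
    feature_method: str = "correlation_range"
    cnv_window: int = 51
    cnv_arm_threshold: float = 0.05
    score_delta: float = 0.1
    ntp_n_perm: int = 1000
    ntp_q_threshold: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _seed_for(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


class _StageCache:
    def __init__(self, out_dir, digest):
        self.dir = Path(out_dir) / "cache" if out_dir else None
        self.digest = digest
        if self.dir:
            self.dir.mkdir(parents=True, exist_ok=True)

    def load(self, stage):
        if not self.dir:
            return None
        f = self.dir / f"{stage}.{self.digest}.pkl"
        if f.exists():
            log.info("stage %s: using cached result", stage)
            with open(f, "rb") as fh:
                return pickle.load(fh)
        return None

    def save(self, stage, obj):
        if self.dir:
            with open(self.dir / f"{stage}.{self.digest}.pkl", "wb") as fh:
                pickle.dump(obj, fh)
        return obj


def _best_match_accuracy(pred: pd.Series, truth: pd.Series) -> float:
    """Label-permutation-invariant agreement for two-group assignments."""
    pred, truth = pred.align(truth, join="inner")
    pl, tl = sorted(pred.unique()), sorted(truth.unique())
    if len(pl) != 2:
        return float((pred == truth).mean())
    a = ((pred == pl[0]) == (truth == tl[0])).mean()
    return float(max(a, 1.0 - a))


def run_end_to_end(config: PipelineConfig, out_dir=None) -> dict:
    """Run the full pipeline on a seeded simulation; return the run report."""
    cache = _StageCache(out_dir, config.digest())
    report: dict = {"config_digest": config.digest(), "seed": config.seed}
    seed = config.seed

    # ---- simulate ----------------------------------------------------
    sim = cache.load("simulate")
    if sim is None:
        adata, truth = simulate_sc_cohorts(config.sim, seed)
        universe = build_gene_universe(config.sim, seed)
        bulk, bulk_truth = simulate_bulk_cohort(config.sim, seed, universe=universe)
        sim = cache.save("simulate", (adata, truth, universe, bulk, bulk_truth))
    adata, truth, universe, bulk, bulk_truth = sim
    report["simulate"] = {
        "n_cells": int(adata.n_obs),
        "n_genes": int(adata.n_vars),
        "n_samples": int(adata.obs["sample_id"].nunique()),
        "n_patients": int(adata.obs["patient_id"].nunique()),
    }

    # ---- QC ----------------------------------------------------------
    st = cache.load("qc")
    if st is None:
        filtered = qc.filter_empty_droplets(adata, config.qc_thresholds.min_nodg_empty)
        lognorm = qc.lognormalize(filtered)
        ref = celltype_reference_profiles(universe)
        calls = qc.assign_major_cell_types(
            lognorm, ref, seed=_seed_for(seed, "celltype")
        )
        bad_samples = qc.flag_low_quality_samples(
            filtered, calls.cell_types, config.qc_thresholds
        )
        keep = ~filtered.obs["sample_id"].isin(bad_samples)
        filtered = filtered[keep].copy()
        lognorm = lognorm[keep.to_numpy()].copy()
        doublets = qc.detect_doublets(
            lognorm, config.qc_thresholds, seed=_seed_for(seed, "doublets")
        )
        keep = ~filtered.obs_names.isin(doublets)
        filtered = filtered[keep].copy()
        lognorm = lognorm[keep].copy()
        cell_types = calls.cell_types.reindex(filtered.obs_names)
        filtered = qc.apply_celltype_cutoffs(filtered, cell_types, config.qc_thresholds)
        lognorm = lognorm[lognorm.obs_names.isin(filtered.obs_names)].copy()
        cell_types = cell_types.reindex(filtered.obs_names)
        st = cache.save("qc", (filtered, lognorm, cell_types, sorted(bad_samples), len(doublets)))
    filtered, lognorm, cell_types, bad_samples, n_doublets = st
    report["qc"] = {
        "cells_retained": int(filtered.n_obs),
        "samples_discarded": list(bad_samples),
        "doublets_removed": int(n_doublets),
    }

    # ---- discovery ---------------------------------------------------
    st = cache.load("discovery")
    if st is None:
        epi_mask = (cell_types == "epithelial").to_numpy()
        epi_counts = filtered[epi_mask].copy()
        epi = lognorm[epi_mask].copy()
        feats = discovery.select_features(
            epi, config.feature_method, n_features=config.n_features
        )
        resolution = config.cluster_resolution
        for _ in range(4):  # escalate if the graph collapses to one community
            ca = discovery.cluster_cells(
                epi, feats, resolution=resolution,
                seed=_seed_for(seed, "cluster"), scale_by_cohort=True,
            )
            if ca.labels.nunique() >= 2:
                break
            resolution *= 2
        if ca.labels.nunique() >= 2:
            _, refined = discovery.pairwise_deg(epi, ca.labels, config.deg_params)
            if len(refined) < 10:
                refined = feats
        else:
            log.warning("initial clustering found one community; keeping features")
            refined = feats
        ca2 = discovery.cluster_cells(
            epi, refined, resolution=config.recluster_resolution,
            seed=_seed_for(seed, "recluster"), scale_by_cohort=True,
        )
        normal_like = discovery.identify_normal_like(ca2.labels, epi.obs)
        is_normal_like = ca2.labels.isin(normal_like)
        malignant = (~is_normal_like) & epi.obs["tissue"].isin(["tumor", "lymph_node"])
        groups, coords, _ = discovery.patient_pseudobulk_split(
            epi, malignant.to_numpy(), refined, seed=_seed_for(seed, "split")
        )
        cg = pd.Series("", index=epi.obs_names, dtype=object)
        cg[is_normal_like.to_numpy()] = "normal"
        cg[malignant.to_numpy()] = (
            epi.obs["patient_id"][malignant.to_numpy()].map(groups).fillna("").to_numpy()
        )
        in_groups = cg.isin(["A", "B", "normal"]).to_numpy()
        stage1 = discovery.derive_stage1_markers(
            epi[in_groups], cg[in_groups], config.deg_params,
            class_names=("A", "B", "normal"),
        )
        st = cache.save(
            "discovery",
            (epi_counts, epi, refined, ca2.labels, is_normal_like, malignant, groups,
             coords, stage1),
        )
    (epi_counts, epi, refined, clusters, is_normal_like, malignant, groups, coords,
     stage1) = st
    report["discovery"] = {
        "n_epithelial": int(epi.n_obs),
        "n_refined_features": len(refined),
        "n_clusters": int(clusters.nunique()),
        "n_normal_like_cells": int(is_normal_like.sum()),
        "group_sizes": groups.value_counts().to_dict(),
        "stage1_marker_sizes": {
            cls: len(stage1.up(cls)) for cls in stage1.class_labels
        },
    }

    # ---- CNV (also orients the two groups: i2 is the CNV-gain group) -
    st = cache.load("cnv")
    if st is None:
        profile = cnv_mod.infer_cnv_profile(
            epi, is_normal_like.to_numpy(), window=config.cnv_window
        )
        mal_profile = cnv_mod.CNVProfile(
            profile.scores[malignant.to_numpy()], profile.windows, profile.reference_ids
        )
        patient_groups = groups  # A/B from the transcriptome split
        cnv_groups, concordance = cnv_mod.cluster_cnv_pseudobulk(
            mal_profile, epi.obs["patient_id"][malignant.to_numpy()], patient_groups
        )
        # orientation: the split group with larger mean |arm score| burden is i2
        pat_mean = cnv_mod.patient_mean_profiles(
            mal_profile, epi.obs["patient_id"][malignant.to_numpy()]
        )
        burden = pat_mean.abs().mean(axis=1)
        burden_a = burden[groups[groups == "A"].index.intersection(burden.index)].mean()
        burden_b = burden[groups[groups == "B"].index.intersection(burden.index)].mean()
        name_map = {"A": "i2", "B": "i3"} if burden_a >= burden_b else {"A": "i3", "B": "i2"}
        icms_groups = groups.map(name_map)
        arm_summary = cnv_mod.arm_level_summary(
            mal_profile,
            group_by=epi.obs["patient_id"][malignant.to_numpy()].map(icms_groups),
            threshold=config.cnv_arm_threshold,
        )
        st = cache.save("cnv", (profile, icms_groups, concordance, arm_summary))
    profile, icms_groups, cnv_concordance, arm_summary = st
    report["cnv"] = {
        "transcriptome_concordance": float(cnv_concordance),
        "i2_arm_calls": arm_summary.calls.loc["i2"].to_dict()
        if "i2" in arm_summary.calls.index
        else {},
    }

    # ---- final signature (pseudo-bulk NB DEG) ------------------------
    st = cache.load("markers")
    if st is None:
        cell_group = pd.Series("", index=epi.obs_names, dtype=object)
        cell_group[is_normal_like.to_numpy()] = "normal"
        mal_idx = malignant.to_numpy()
        cell_group[mal_idx] = (
            epi.obs["patient_id"][mal_idx].map(icms_groups).fillna("").to_numpy()
        )
        keep_cells = cell_group.isin(["i2", "i3", "normal"]).to_numpy()
        pseudo_patient = epi.obs["patient_id"].astype(str).where(
            ~cell_group.eq("normal"), epi.obs["patient_id"].astype(str) + "_norm"
        )
        sub = epi_counts[keep_cells].copy()
        pb = pb_mod.sum_pseudobulk(
            sub,
            pseudo_patient[keep_cells],
            groups=pd.Series(cell_group[keep_cells].to_numpy(), index=pseudo_patient[keep_cells]).groupby(level=0).first(),
        )
        results = {}
        for a, b in (("i2", "i3"), ("i3", "normal"), ("normal", "i2")):
            results[(a, b)] = pb_mod.nb_deg_test(pb, (a, b))
        signature = pb_mod.derive_icms_signature(results, config.sig_params)
        st = cache.save("markers", (pb, signature))
    pb, signature = st
    report["markers"] = {
        "signature_sizes": {
            f"{cls}_{d}": len(signature.classes[cls][d])
            for cls in signature.class_labels
            for d in ("Up", "Down")
        },
        "n_signature_genes": signature.n_genes(),
    }

    # ---- scoring -----------------------------------------------------
    st = cache.load("scoring")
    if st is None:
        X = epi.X
        import scipy.sparse as sp

        Xd = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
        frame = pd.DataFrame(Xd, index=epi.obs_names, columns=epi.var_names)
        scaled, _flags = scoring.zscore_within_cohort(frame, epi.obs["cohort_id"])
        scores = scoring.signature_scores(scaled, signature, mode="up")
        mal_mask = malignant.to_numpy()
        call = scoring.classify_cells_by_score(
            scores["i2"][mal_mask],
            scores["i3"][mal_mask],
            tumor_ids=epi.obs["patient_id"][mal_mask],
            delta=config.score_delta,
            seed=_seed_for(seed, "gmm"),
        )
        st = cache.save("scoring", (scores, call))
    scores, cell_call = st
    report["scoring"] = {
        "bimodality_components": cell_call.bimodality["n_components"],
        "n_hybrid_tumors": int(cell_call.hybrid_tumors.sum()),
        "mean_preferential_frac": float(
            cell_call.tumor_fractions[["preferential_i2", "preferential_i3"]].max(axis=1).mean()
        ),
    }

    # ---- truth-based recovery metrics --------------------------------
    mal_mask = malignant.to_numpy()
    truth_sub = epi.obs["true_subtype"][mal_mask]
    pred_sub = epi.obs["patient_id"][mal_mask].map(icms_groups)
    valid = truth_sub.isin(["i2", "i3"]).to_numpy()
    subtype_acc = _best_match_accuracy(pred_sub[valid], truth_sub[valid])
    oriented_acc = float((pred_sub[valid] == truth_sub[valid]).mean())
    gt = truth.genes
    recovery = {}
    for cls, direction in (("i2", "Up"), ("i2", "Down"), ("i3", "Up"), ("i3", "Down")):
        planted = set(gt.index[gt["marker_class"] == f"{cls}_{direction}"])
        derived = set(signature.classes.get(cls, {"Up": set(), "Down": set()})[direction])
        if planted:
            recovery[f"{cls}_{direction}"] = len(planted & derived) / len(planted)
    report["truth"] = {
        "malignant_subtype_accuracy": subtype_acc,
        "oriented_subtype_accuracy": oriented_acc,
        "marker_recovery": recovery,
    }

    # ---- bulk classification ------------------------------------------
    st = cache.load("bulk")
    if st is None:
        bulk_scaled, _ = scoring.zscore_within_cohort(
            bulk.expr.T, bulk.labels["cohort_id"]
        )
        ntp_res = ntp_mod.ntp_classify(
            bulk_scaled,
            signature,
            n_perm=config.ntp_n_perm,
            q_threshold=config.ntp_q_threshold,
            seed=_seed_for(seed, "ntp"),
        )
        fib = ntp_mod.fibrosis_flag(bulk.labels)
        imf = ntp_mod.imf_classify(ntp_res, bulk.labels["msi"], fib)
        st = cache.save("bulk", (ntp_res, imf))
    ntp_res, imf = st
    pred_bulk = ntp_res.table["predicted"].map({"iCMS2": "i2", "iCMS3": "i3"})
    bulk_acc = _best_match_accuracy(pred_bulk, bulk_truth["subtype"])
    report["bulk"] = {
        "class_fractions": ntp_res.table["call"].value_counts(normalize=True).to_dict(),
        "imf_fractions": imf["imf_class"].value_counts(normalize=True).to_dict(),
        "bulk_subtype_accuracy": float(bulk_acc),
    }

    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        with open(out / "config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2, default=str)
        from .io import write_signature

        write_signature(signature, out / "signature.tsv")
        ntp_res.table.to_csv(out / "ntp_calls.tsv", sep="\t")
        imf.to_csv(out / "imf_calls.tsv", sep="\t")
    return report
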