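"""Multi-cohort single-cell and bulk transcriptome simulator with ground truth.

The generator emulates the statistical structure the subtyping analysis
assumes: ~11 major cell types with distinctive expression programs, malignant
epithelial cells that belong to one of two planted intrinsic subtypes (i2/i3)
separated by directional marker shifts and arm-level copy-number dosage,
normal-like epithelium admixed into tumor samples, per-patient expression
random effects (patient-specific malignant clusters), per-cohort batch shifts,
heterotypic doublets, degraded samples and low-quality cells.  Bulk samples
are purity/fibroblast mixtures of the cell-type mean profiles with MSI-H
labels confined to i3 tumors.

Counts are negative binomial, parameterized by mean and dispersion alpha with
Var = mu + alpha * mu^2, sampled as a gamma-Poisson mixture.  The generator is
a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq

from .io import BulkMatrix, write_sc_dataset

CELL_TYPES = (
    "epithelial",
    "fibroblast",
    "endothelial",
    "T_NK",
    "B",
    "plasma_B",
    "McDC",
    "mast",
    "neutrophil",
    "pDC",
    "entericglial",
)

#: baseline composition of the non-epithelial compartment of a tumor sample
_STROMA_WEIGHTS = {
    "fibroblast": 0.18,
    "endothelial": 0.08,
    "T_NK": 0.30,
    "B": 0.10,
    "plasma_B": 0.10,
    "McDC": 0.10,
    "mast": 0.04,
    "neutrophil": 0.06,
    "pDC": 0.04,
    "entericglial": 0.10,
}

DEFAULT_ARMS = tuple(
    f"{c}{a}" for c in (1, 2, 3, 4, 5, 6, 7, 8, 13, 17, 18, 20) for a in ("p", "q")
)

MARKER_CLASSES = ("i2_Up", "i2_Down", "i3_Up", "i3_Down")


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_cohorts: int = 5
    patients_per_cohort: int = 4
    cells_per_sample: int = 700
    n_genes: int = 2000
    n_cell_types: int = 11
    # fraction of patients whose tumor is i2 (the remainder are i3)
    i2_fraction: float = 0.55
    # patients contributing a matched adjacent-normal sample
    normal_sample_frac: float = 0.5
    epithelial_frac_tumor: float = 0.7
    epithelial_frac_normal: float = 0.5
    marker_counts: dict = field(
        default_factory=lambda: {"i2_Up": 60, "i2_Down": 50, "i3_Up": 40, "i3_Down": 30}
    )
    marker_lnfc: float = float(np.log(2.0))
    # optional preferential placement of i2 markers on dosage arms:
    # fraction of i2 markers resident on gained/lost arms, and the fraction of
    # those whose direction is concordant with the arm dosage
    marker_arm_frac: float = 0.0
    marker_arm_concordance: float = 0.9
    cnv_arms: dict = field(
        default_factory=lambda: {
            "i2": {"8q": 1.5, "13q": 1.5, "20q": 1.5, "17p": 0.5, "18q": 0.5},
            "i3": {},
        }
    )
    arms: tuple = DEFAULT_ARMS
    nb_dispersion: float = 0.4
    library_size_meanlog: float = float(np.log(8000.0))
    library_size_sdlog: float = 0.3
    doublet_rate_per_1000: float = 0.8
    homotypic_doublet_frac: float = 0.3
    low_quality_sample_frac: float = 0.0
    degraded_nodg_factor: float = 3.0
    low_quality_cell_frac: float = 0.02
    normal_like_frac_in_tumor: float = 0.234
    patient_effect_sd: float = 0.12
    cohort_effect_sd: float = 0.25
    hybrid_tumor_frac: float = 0.0
    msi_frac_in_i3: float = 0.45
    msi_marker_count: int = 30
    msi_lnfc: float = float(np.log(1.5))
    fibrotic_frac: float = 0.25
    n_mito_genes: int = 10
    mito_frac: float = 0.05
    n_celltype_markers: int = 40
    celltype_marker_fold: float = 8.0
    # bulk cohort
    n_bulk_samples: int = 200
    n_bulk_cohorts: int = 3
    bulk_purity_range: tuple = (0.3, 0.9)
    bulk_noise_sd: float = 0.1
    bulk_fibroblast_boost: float = 8.0

    def validate(self) -> None:
        if not 0.0 <= self.i2_fraction <= 1.0:
            raise ValueError("i2_fraction must be in [0, 1]")
        for frac in (
            self.normal_sample_frac,
            self.low_quality_sample_frac,
            self.low_quality_cell_frac,
            self.normal_like_frac_in_tumor,
            self.hybrid_tumor_frac,
            self.msi_frac_in_i3,
            self.fibrotic_frac,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        for sub, arms in self.cnv_arms.items():
            for arm, mult in arms.items():
                if mult <= 0:
                    raise ValueError(f"dosage multiplier for {sub}/{arm} must be > 0")
                if arm not in self.arms:
                    raise ValueError(f"cnv arm {arm!r} not in configured arm list")
        total_markers = sum(self.marker_counts.values()) + self.msi_marker_count
        reserved = self.n_cell_types * self.n_celltype_markers
        pool = int(0.7 * (self.n_genes - self.n_mito_genes))
        if total_markers + reserved > pool:
            raise ValueError("marker sets over-allocate the gene universe")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


@dataclass
class TruthTable:
    """Planted ground truth for one simulated dataset."""

    cells: pd.DataFrame
    samples: pd.DataFrame
    patients: pd.DataFrame
    genes: pd.DataFrame


@dataclass
class GeneUniverse:
    """Gene annotation plus every per-gene effect the generator plants."""

    genes: pd.DataFrame
    base_weights: np.ndarray  # baseline linear-scale expression weight per gene
    celltype_mult: dict  # cell type -> per-gene multiplier
    marker_mult: dict  # subtype ("i2"/"i3") -> per-gene multiplier
    arm_mult: dict  # subtype -> per-gene dosage multiplier
    msi_mult: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def celltype_profile(self, cell_type: str) -> np.ndarray:
        """Linear-scale mean profile (normalized to sum 1) of a non-malignant type."""
        w = self.base_weights * self.celltype_mult[cell_type]
        return w / w.sum()

    def malignant_profile(
        self, subtype: str, patient_effect: np.ndarray | None = None, msi: bool = False
    ) -> np.ndarray:
        w = (
            self.base_weights
            * self.celltype_mult["epithelial"]
            * self.marker_mult[subtype]
            * self.arm_mult[subtype]
        )
        if msi:
            w = w * self.msi_mult
        if patient_effect is not None:
            w = w * patient_effect
        return w / w.sum()


def build_gene_universe(config: SimConfig, seed) -> GeneUniverse:
    """Partition genes across chromosome arms and plant every per-gene effect.

    Marker sets are pairwise disjoint, drawn from well-expressed (above-median
    baseline) non-mitochondrial genes, and assigned to arms uniformly.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    n = config.n_genes
    n_mito = config.n_mito_genes
    n_nuclear = n - n_mito

    arms = list(config.arms)
    arm_of = np.array(arms)[np.sort(rng.integers(0, len(arms), size=n_nuclear))]
    # positions sorted within chromosome
    start = np.zeros(n_nuclear, dtype=np.int64)
    for arm in arms:
        idx = np.flatnonzero(arm_of == arm)
        start[idx] = np.sort(rng.integers(0, 120_000_000, size=len(idx)))
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n)],
            "symbol": [f"G{i:05d}" for i in range(n)],
            "chromosome": list(arm_of.astype(str)) + ["MT"] * n_mito,
            "arm": [a[-1] for a in arm_of] + ["q"] * n_mito,
            "start_bp": list(start) + list(range(100, 100 + 200 * n_mito, 200)),
            "is_mito": [False] * n_nuclear + [True] * n_mito,
        }
    )
    genes["chromosome"] = [
        c[:-1] if c != "MT" else c for c in genes["chromosome"]
    ]
    genes = genes.set_index("gene_id", drop=False).rename_axis(None)

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    # mitochondrial weight tuned so the expected mito fraction matches config
    nonmito_sum = base[:n_nuclear].sum()
    base[n_nuclear:] = (
        config.mito_frac / (1.0 - config.mito_frac) * nonmito_sum / max(n_mito, 1)
    )

    # eligible genes for planted effects: nuclear, clearly expressed
    cut = np.quantile(base[:n_nuclear], 0.3)
    eligible = np.flatnonzero(base[:n_nuclear] >= cut)
    eligible = rng.permutation(eligible)
    used = np.zeros(n, dtype=bool)

    def take_from(mask, k):
        cand = eligible[~used[eligible] & mask[eligible]]
        if len(cand) < k:
            raise ValueError("marker sets over-allocate the gene universe")
        out = cand[:k]
        used[out] = True
        return np.sort(out)

    def take(k):
        return take_from(np.ones(n, dtype=bool), k)

    celltype_marker = np.array([""] * n, dtype=object)
    celltype_mult = {}
    for ct in CELL_TYPES[: config.n_cell_types]:
        idx = take(config.n_celltype_markers)
        mult = np.ones(n)
        if ct == "epithelial":
            # epithelial identity genes are up in all epithelium (incl. malignant)
            mult[idx] = config.celltype_marker_fold
        else:
            mult[idx] = config.celltype_marker_fold
        celltype_marker[idx] = ct
        celltype_mult[ct] = mult
    # each type's markers are near-silent in the other types
    for ct, mult in celltype_mult.items():
        other = (celltype_marker != "") & (celltype_marker != ct)
        mult[other] = 0.1

    # dosage-arm masks (for optional concordant placement of i2 markers)
    arm_key = np.array(
        [f"{c}{a}" for c, a in zip(genes["chromosome"], genes["arm"])], dtype=object
    )
    i2_arms = config.cnv_arms.get("i2", {})
    gained = np.isin(arm_key, [a for a, d in i2_arms.items() if d > 1])
    lost = np.isin(arm_key, [a for a, d in i2_arms.items() if d < 1])
    off_arm = ~(gained | lost)

    marker_class = np.array([""] * n, dtype=object)
    marker_mult = {"i2": np.ones(n), "i3": np.ones(n), "normal": np.ones(n)}
    fold = float(np.exp(config.marker_lnfc))
    for cls in MARKER_CLASSES:
        count = config.marker_counts.get(cls, 0)
        sub, direction = cls.split("_")
        if sub == "i2" and config.marker_arm_frac > 0 and (gained.any() or lost.any()):
            n_arm = int(round(config.marker_arm_frac * count))
            n_conc = int(round(config.marker_arm_concordance * n_arm))
            conc_mask, disc_mask = (gained, lost) if direction == "Up" else (lost, gained)
            idx = np.concatenate(
                [
                    take_from(conc_mask, n_conc),
                    take_from(disc_mask, n_arm - n_conc),
                    take_from(off_arm, count - n_arm),
                ]
            )
        else:
            idx = take_from(off_arm, count) if config.marker_arm_frac > 0 else take(count)
        marker_class[idx] = cls
        marker_mult[sub][idx] = fold if direction == "Up" else 1.0 / fold

    msi_idx = take(config.msi_marker_count)
    msi_mult = np.ones(n)
    msi_mult[msi_idx] = float(np.exp(config.msi_lnfc))

    arm_mult = {}
    for sub in ("i2", "i3"):
        mult = np.ones(n)
        for arm, dosage in config.cnv_arms.get(sub, {}).items():
            on_arm = (
                (genes["chromosome"] == arm[:-1]) & (genes["arm"] == arm[-1])
            ).to_numpy()
            mult[on_arm] *= dosage
        arm_mult[sub] = mult
    arm_mult["normal"] = np.ones(n)

    gtruth = genes.copy()
    gtruth["marker_class"] = marker_class
    gtruth["celltype_marker"] = celltype_marker
    gtruth["is_msi_marker"] = np.isin(np.arange(n), msi_idx)
    gtruth["cnv_mult_i2"] = arm_mult["i2"]
    gtruth["cnv_mult_i3"] = arm_mult["i3"]

    return GeneUniverse(
        genes=gtruth,
        base_weights=base,
        celltype_mult=celltype_mult,
        marker_mult=marker_mult,
        arm_mult=arm_mult,
        msi_mult=msi_mult,
    )


def celltype_reference_profiles(universe: GeneUniverse, scale: float = 1e4) -> pd.DataFrame:
    """Gene x cell-type reference transcriptomes (log1p of depth-scaled means).

    The reference panel the correlation-projection cell typing is given, in
    the role of a curated reference atlas.
    """
    cols = {}
    for ct in universe.celltype_mult:
        p = universe.celltype_profile(ct)
        cols[ct] = np.log1p(scale * p)
    return pd.DataFrame(cols, index=universe.genes.index)


# ---------------------------------------------------------------------------
# single-cell simulation
# ---------------------------------------------------------------------------

def _nb_counts(rng, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson sample with Var = mu + alpha mu^2."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mu)
    return rng.poisson(lam)


def _expected_nodg(profile: np.ndarray, lib: float, alpha: float) -> float:
    mu = lib * profile
    p0 = np.power(1.0 + alpha * mu, -1.0 / alpha)
    return float(np.sum(1.0 - p0))


def _degraded_depth_factor(profile, lib, alpha, nodg_factor) -> float:
    """Depth scaling that reduces the expected NODG by ``nodg_factor``."""
    target = _expected_nodg(profile, lib, alpha) / nodg_factor

    def f(s):
        return _expected_nodg(profile, s * lib, alpha) - target

    return float(brentq(f, 1e-4, 1.0, xtol=1e-6))


def _patient_table(config: SimConfig, rng) -> pd.DataFrame:
    n_pat = config.n_cohorts * config.patients_per_cohort
    subtype = np.array(["i3"] * n_pat, dtype=object)
    n_i2 = int(round(config.i2_fraction * n_pat))
    order = rng.permutation(n_pat)
    subtype[order[:n_i2]] = "i2"
    i3_idx = np.flatnonzero(subtype == "i3")
    msi = np.array([False] * n_pat)
    n_msi = int(round(config.msi_frac_in_i3 * len(i3_idx)))
    msi[rng.permutation(i3_idx)[:n_msi]] = True
    hybrid = np.zeros(n_pat, dtype=bool)
    n_hyb = int(round(config.hybrid_tumor_frac * n_pat))
    hybrid[rng.permutation(n_pat)[:n_hyb]] = True
    fibrotic = np.zeros(n_pat, dtype=bool)
    n_fib = int(round(config.fibrotic_frac * n_pat))
    fibrotic[rng.permutation(n_pat)[:n_fib]] = True
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n_pat)],
            "cohort_id": [f"cohort{i // config.patients_per_cohort}" for i in range(n_pat)],
            "subtype": subtype,
            "msi": np.where(msi, "MSI-H", "MSS"),
            "hybrid": hybrid,
            "fibrotic": fibrotic,
        }
    ).set_index("patient_id", drop=False).rename_axis(None)


def _boost_mito(profile: np.ndarray, is_mito: np.ndarray, target_frac: float) -> np.ndarray:
    p = profile.copy()
    nonmito = p[~is_mito].sum()
    p[is_mito] = p[is_mito] / max(p[is_mito].sum(), 1e-12) * (
        target_frac / (1 - target_frac) * nonmito
    )
    return p / p.sum()


def simulate_sc_cohorts(config: SimConfig, seed: int):
    """Simulate the multi-cohort single-cell dataset.

    Returns ``(AnnData, TruthTable)``; obs carries the truth columns
    (true_cell_type, true_subtype, is_doublet, is_low_quality) alongside the
    regular cell metadata.
    """
    config.validate()
    universe = build_gene_universe(config, seed)
    ss = np.random.SeedSequence([int(seed), 23])
    rng = np.random.default_rng(ss)
    patients = _patient_table(config, rng)
    alpha = config.nb_dispersion
    n_genes = universe.n_genes
    is_mito = universe.genes["is_mito"].to_numpy()

    # per-cohort batch effect and per-patient malignant random effect
    cohorts = sorted(patients["cohort_id"].unique())
    cohort_shift = {
        c: np.exp(rng.normal(0.0, config.cohort_effect_sd, size=n_genes)) for c in cohorts
    }
    patient_effect = {
        p: np.exp(rng.normal(0.0, config.patient_effect_sd, size=n_genes))
        for p in patients.index
    }

    # samples: one tumor per patient + matched normals for a deterministic subset
    sample_rows = []
    for i, (pid, row) in enumerate(patients.iterrows()):
        sample_rows.append((f"{pid}_T", pid, row["cohort_id"], "tumor"))
        if (i % max(int(round(1 / config.normal_sample_frac)), 1) == 0
                if config.normal_sample_frac > 0 else False):
            sample_rows.append((f"{pid}_N", pid, row["cohort_id"], "normal"))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "patient_id", "cohort_id", "tissue"]
    ).set_index("sample_id", drop=False).rename_axis(None)
    n_degraded = int(round(config.low_quality_sample_frac * len(samples)))
    degraded_ids = rng.permutation(samples.index.to_numpy())[:n_degraded]
    samples["is_degraded"] = samples.index.isin(degraded_ids)

    stroma_types = list(_STROMA_WEIGHTS)
    stroma_w = np.array([_STROMA_WEIGHTS[t] for t in stroma_types])
    stroma_w = stroma_w / stroma_w.sum()

    mean_lib = float(np.exp(config.library_size_meanlog + config.library_size_sdlog**2 / 2))
    epi_profile = universe.celltype_profile("epithelial")
    blocks, obs_rows = [], []

    for sid, srow in samples.iterrows():
        pid = srow["patient_id"]
        prow = patients.loc[pid]
        n_cells = config.cells_per_sample
        frac_doub = config.doublet_rate_per_1000 / 100.0 * n_cells / 1000.0
        n_doub = int(round(n_cells * frac_doub))
        n_sing = n_cells - n_doub

        if srow["tissue"] == "tumor":
            n_epi = int(round(config.epithelial_frac_tumor * n_sing))
        else:
            n_epi = int(round(config.epithelial_frac_normal * n_sing))
        n_stroma = n_sing - n_epi
        types = list(rng.choice(stroma_types, size=n_stroma, p=stroma_w))
        subtypes = [""] * n_stroma
        if srow["tissue"] == "tumor":
            n_norm_like = int(round(config.normal_like_frac_in_tumor * n_epi))
            n_mal = n_epi - n_norm_like
            mal_subs = []
            if prow["hybrid"]:
                half = n_mal // 2
                mal_subs = ["i2"] * half + ["i3"] * (n_mal - half)
            else:
                mal_subs = [prow["subtype"]] * n_mal
            types += ["epithelial"] * n_epi
            subtypes += mal_subs + ["normal"] * n_norm_like
        else:
            types += ["epithelial"] * n_epi
            subtypes += ["normal"] * n_epi

        # per-cell mean profiles
        profiles = np.empty((n_sing, n_genes))
        msi_flag = prow["msi"] == "MSI-H"
        cache = {}
        for j, (ct, sub) in enumerate(zip(types, subtypes)):
            key = (ct, sub)
            if key not in cache:
                if ct == "epithelial" and sub in ("i2", "i3"):
                    cache[key] = universe.malignant_profile(
                        sub, patient_effect[pid], msi=msi_flag
                    )
                else:
                    cache[key] = universe.celltype_profile(ct)
            profiles[j] = cache[key]

        libs = rng.lognormal(config.library_size_meanlog, config.library_size_sdlog, n_sing)

        low_q = rng.random(n_sing) < config.low_quality_cell_frac
        for j in np.flatnonzero(low_q):
            profiles[j] = _boost_mito(profiles[j], is_mito, 0.35)
            libs[j] *= 0.12

        if srow["is_degraded"]:
            s = _degraded_depth_factor(
                epi_profile, mean_lib, alpha, config.degraded_nodg_factor
            )
            libs = libs * s
            for j in range(n_sing):
                cur = profiles[j][is_mito].sum()
                profiles[j] = _boost_mito(profiles[j], is_mito, min(2 * cur, 0.6))

        shift = cohort_shift[srow["cohort_id"]]
        mu = profiles * shift
        mu = mu / mu.sum(axis=1, keepdims=True) * libs[:, None]
        counts = _nb_counts(rng, mu, alpha)

        # doublets: averaged-then-resampled pairs, preferentially heterotypic
        d_counts = np.zeros((n_doub, n_genes), dtype=np.int64)
        d_types = []
        type_arr = np.array(types, dtype=object)
        for j in range(n_doub):
            a = int(rng.integers(n_sing))
            if rng.random() < config.homotypic_doublet_frac:
                pool = np.flatnonzero(type_arr == type_arr[a])
            else:
                pool = np.flatnonzero(type_arr != type_arr[a])
            b = int(pool[rng.integers(len(pool))]) if len(pool) else a
            mu_d = 0.5 * (mu[a] + mu[b]) * 2.0  # two cells' worth of RNA
            d_counts[j] = _nb_counts(rng, mu_d, alpha)
            d_types.append(type_arr[a])

        blocks.append(sp.csr_matrix(np.vstack([counts, d_counts]) if n_doub else counts))
        for j in range(n_sing):
            obs_rows.append(
                (f"{sid}_c{j:04d}", sid, pid, srow["cohort_id"], srow["tissue"],
                 types[j], subtypes[j], False, bool(low_q[j]))
            )
        for j in range(n_doub):
            obs_rows.append(
                (f"{sid}_d{j:04d}", sid, pid, srow["cohort_id"], srow["tissue"],
                 d_types[j], "", True, False)
            )

    obs = pd.DataFrame(
        obs_rows,
        columns=[
            "cell_id", "sample_id", "patient_id", "cohort_id", "tissue",
            "true_cell_type", "true_subtype", "is_doublet", "is_low_quality",
        ],
    ).set_index("cell_id", drop=False).rename_axis(None)
    X = sp.vstack(blocks).astype(np.int64)
    adata = ad.AnnData(X=X.tocsr(), obs=obs, var=universe.genes.copy())
    truth = TruthTable(
        cells=obs[["true_cell_type", "true_subtype", "is_doublet", "is_low_quality"]].copy(),
        samples=samples,
        patients=patients,
        genes=universe.genes.copy(),
    )
    adata.uns["sim_seed"] = int(seed)
    return adata, truth


# ---------------------------------------------------------------------------
# bulk simulation
# ---------------------------------------------------------------------------

def simulate_bulk_cohort(
    config: SimConfig,
    seed: int,
    universe: GeneUniverse | None = None,
    patients: pd.DataFrame | None = None,
):
    """Simulate bulk tumors as convex cell-type mixtures.

    Each sample is ``log1p(1e4 * mix)`` plus Gaussian noise, where ``mix`` is a
    purity-weighted combination of the epithelial profile of the sample's
    (planted) subtype and the non-epithelial cell-type profiles.  Fibrotic
    samples get an elevated fibroblast weight; MSI-H occurs only in i3.
    Returns ``(BulkMatrix, truth_frame)``.
    """
    config.validate()
    if universe is None:
        universe = build_gene_universe(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 37]))
    n = config.n_bulk_samples
    subtype = np.where(rng.random(n) < config.i2_fraction, "i2", "i3")
    msi = np.array(
        ["MSI-H" if (s == "i3" and rng.random() < config.msi_frac_in_i3) else "MSS"
         for s in subtype]
    )
    fibrotic = rng.random(n) < config.fibrotic_frac
    purity = rng.uniform(*config.bulk_purity_range, size=n)
    cohort = np.array([f"bulk{j % config.n_bulk_cohorts}" for j in range(n)])

    stroma_types = list(_STROMA_WEIGHTS)
    stroma_profiles = np.stack([universe.celltype_profile(t) for t in stroma_types])
    cols, weights_fb = {}, []
    sample_ids = [f"B{j:04d}" for j in range(n)]
    for j in range(n):
        pe = np.exp(rng.normal(0.0, config.patient_effect_sd, size=universe.n_genes))
        epi = universe.malignant_profile(subtype[j], pe, msi=msi[j] == "MSI-H")
        alphas = np.ones(len(stroma_types))
        if fibrotic[j]:
            alphas[stroma_types.index("fibroblast")] *= config.bulk_fibroblast_boost
        w = rng.dirichlet(alphas) * (1.0 - purity[j])
        mix = purity[j] * epi + w @ stroma_profiles
        expr = np.log1p(1e4 * mix) + rng.normal(0.0, config.bulk_noise_sd, universe.n_genes)
        cols[sample_ids[j]] = expr
        weights_fb.append(w[stroma_types.index("fibroblast")])

    expr = pd.DataFrame(cols, index=universe.genes.index)
    labels = pd.DataFrame(
        {
            "msi": msi,
            "cms": np.where(
                fibrotic, "CMS4", np.where(subtype == "i2", "CMS2", "CMS3")
            ),
            "cohort_id": cohort,
        },
        index=sample_ids,
    )
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subtype": subtype,
            "msi": msi,
            "fibrotic": fibrotic,
            "purity": purity,
            "fibroblast_weight": weights_fb,
            "cohort_id": cohort,
        }
    ).set_index("sample_id", drop=False).rename_axis(None)
    return BulkMatrix(expr=expr, labels=labels), truth


# ---------------------------------------------------------------------------
# on-disk emission (CLI `simulate`)
# ---------------------------------------------------------------------------

def write_simulation(config: SimConfig, seed: int, out_dir) -> dict:
    """Simulate and write MTX/TSV files plus truth tables and references."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    adata, truth = simulate_sc_cohorts(config, seed)
    paths = write_sc_dataset(adata, out)
    universe = build_gene_universe(config, seed)
    ref = celltype_reference_profiles(universe)
    ref_path = out / "reference_profiles.tsv"
    ref.rename_axis("gene_id").to_csv(ref_path, sep="\t")
    bulk, btruth = simulate_bulk_cohort(config, seed, universe=universe)
    from .io import write_bulk_matrix

    write_bulk_matrix(bulk, out / "bulk_expr.tsv", out / "bulk_labels.tsv")
    truth.samples.to_csv(out / "truth_samples.tsv", sep="\t", index=False)
    truth.patients.to_csv(out / "truth_patients.tsv", sep="\t", index=False)
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    btruth.to_csv(out / "truth_bulk.tsv", sep="\t", index=False)
    paths.update(
        reference=ref_path,
        bulk=out / "bulk_expr.tsv",
        bulk_labels=out / "bulk_labels.tsv",
    )
    return paths
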