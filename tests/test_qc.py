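"""QC rules: droplet filtering, normalization identities, correlation-based
cell typing, median-of-medians sample QC, pANN doublets, type cutoffs."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from icmskit import qc
from icmskit.simulate import (
    SimConfig,
    build_gene_universe,
    celltype_reference_profiles,
    simulate_sc_cohorts,
)


def _adata_from_counts(X, sample_ids=None):
    n, g = X.shape
    obs = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "sample_id": sample_ids if sample_ids is not None else "s0",
            "patient_id": "p0",
            "cohort_id": "k0",
            "tissue": "tumor",
        }
    ).set_index("cell_id", drop=False).rename_axis(None)
    var = pd.DataFrame(
        {"gene_id": [f"g{j}" for j in range(g)], "is_mito": [False] * g}
    ).set_index("gene_id", drop=False).rename_axis(None)
    return ad.AnnData(X=sp.csr_matrix(X), obs=obs, var=var)


class TestEmptyDroplets:
    def test_boundary_is_strict(self):
        # cells with NODG 299 and 300 across 400 genes
        X = np.zeros((2, 400), dtype=int)
        X[0, :299] = 1
        X[1, :300] = 1
        out = qc.filter_empty_droplets(_adata_from_counts(X), 300)
        assert list(out.obs_names) == ["c1"]

    def test_brute_force_count(self):
        # NODG 100..1000 step 100; threshold 300 keeps 8 of 10
        X = np.zeros((10, 1000), dtype=int)
        for i in range(10):
            X[i, : (i + 1) * 100] = 1
        out = qc.filter_empty_droplets(_adata_from_counts(X), 300)
        assert out.n_obs == 8


class TestLognormalize:
    def test_closed_form_value(self):
        X = np.zeros((1, 2000), dtype=int)
        X[0, 0] = 20
        X[0, 1:] = 10  # total 20 + 19990 = 20010 -> adjust to exact 20000
        X[0, 1] = 0
        assert X.sum() == 20_000
        out = qc.lognormalize(_adata_from_counts(X), 1e4)
        val = out.X[0, 0]
        assert val == pytest.approx(np.log(11), rel=1e-12)

    def test_all_zero_gene_stays_zero_and_sums_recover_scale(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2, size=(50, 100))
        X[:, 7] = 0
        X[X.sum(axis=1) == 0, 0] = 1
        out = qc.lognormalize(_adata_from_counts(X), 1e4)
        dense = np.asarray(out.X.todense())
        assert np.all(dense[:, 7] == 0)
        assert np.allclose(np.expm1(dense).sum(axis=1), 1e4, rtol=1e-10)

    def test_zero_total_cell_raises(self):
        X = np.zeros((2, 10), dtype=int)
        X[0, 0] = 5
        with pytest.raises(ValueError, match="zero total"):
            qc.lognormalize(_adata_from_counts(X))


class TestCellTyping:
    @pytest.fixture(scope="class")
    def typed(self, small_cfg, small_sim):
        adata, _ = small_sim
        filtered = qc.filter_empty_droplets(adata)
        lognorm = qc.lognormalize(filtered)
        ref = celltype_reference_profiles(build_gene_universe(small_cfg, 11))
        calls = qc.assign_major_cell_types(lognorm, ref, seed=0)
        return filtered, calls

    def test_accuracy_against_truth(self, typed):
        filtered, calls = typed
        mask = ~filtered.obs["is_doublet"] & ~filtered.obs["is_low_quality"]
        acc = (
            calls.cell_types[mask.to_numpy()]
            == filtered.obs["true_cell_type"][mask.to_numpy()]
        ).mean()
        assert acc >= 0.95

    def test_cell_identical_to_reference_has_correlation_one(self, small_cfg):
        uni = build_gene_universe(small_cfg, 11)
        ref = celltype_reference_profiles(uni)
        X = np.vstack([ref["epithelial"].to_numpy()] * 60 + [ref["T_NK"].to_numpy()] * 60)
        obs = pd.DataFrame(
            {
                "sample_id": "s0", "patient_id": "p0", "cohort_id": "k0",
                "tissue": "tumor",
            },
            index=[f"c{i}" for i in range(120)],
        )
        adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=ref.index))
        calls = qc.assign_major_cell_types(adata, ref, seed=0)
        assert calls.assignments["max_correlation"].iloc[0] == pytest.approx(1.0)
        assert calls.cell_types.iloc[0] == "epithelial"
        assert calls.cell_types.iloc[-1] == "T_NK"

    def test_constant_cell_is_unassigned(self, small_cfg):
        uni = build_gene_universe(small_cfg, 11)
        ref = celltype_reference_profiles(uni)
        rng = np.random.default_rng(0)
        X = rng.normal(1, 0.3, size=(100, len(ref)))
        X[0] = 1.0  # zero-variance cell
        obs = pd.DataFrame(
            {"sample_id": "s0", "patient_id": "p0", "cohort_id": "k0", "tissue": "tumor"},
            index=[f"c{i}" for i in range(100)],
        )
        adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=ref.index))
        calls = qc.assign_major_cell_types(adata, ref, seed=0)
        assert calls.cell_types.iloc[0] == "unassigned"


class TestSampleQC:
    def _toy(self, medians):
        """Build a dataset realizing the given per-(sample, type) median NODG."""
        rows, Xs = [], []
        n_genes = 4000
        for sid, per_type in medians.items():
            for ct, med in per_type.items():
                for k in range(3):
                    x = np.zeros(n_genes, dtype=int)
                    x[:med] = 1
                    Xs.append(x)
                    rows.append((f"{sid}_{ct}_{k}", sid, ct))
        obs = pd.DataFrame(rows, columns=["cell_id", "sample_id", "cell_type"])
        sample_ids = obs["sample_id"].to_numpy()
        adata = _adata_from_counts(np.vstack(Xs), sample_ids=sample_ids)
        adata.obs.index = obs["cell_id"].to_numpy()
        types = pd.Series(obs["cell_type"].to_numpy(), index=obs["cell_id"])
        return adata, types

    def test_six_of_eleven_deviations_discards(self):
        types = [f"t{i}" for i in range(11)]
        normal = {t: 1000 for t in types}
        bad = dict(normal)
        for t in types[:6]:
            bad[t] = 450  # ratio 2.22 > 2 in six of eleven types
        medians = {f"s{i}": dict(normal) for i in range(5)}
        medians["s_bad"] = bad
        adata, calls = self._toy(medians)
        assert qc.flag_low_quality_samples(adata, calls) == {"s_bad"}

    def test_ratio_exactly_two_is_not_a_deviation(self):
        types = [f"t{i}" for i in range(11)]
        normal = {t: 1000 for t in types}
        boundary = {t: 500 for t in types}  # ratio exactly 2.0 everywhere
        medians = {f"s{i}": dict(normal) for i in range(5)}
        medians["s_edge"] = boundary
        adata, calls = self._toy(medians)
        assert qc.flag_low_quality_samples(adata, calls) == set()

    def test_planted_degraded_samples_flagged_exactly(self, small_sim):
        adata, truth = small_sim
        filtered = qc.filter_empty_droplets(adata)
        calls = filtered.obs["true_cell_type"]
        flagged = qc.flag_low_quality_samples(filtered, calls)
        degraded = set(truth.samples.index[truth.samples["is_degraded"]])
        assert flagged == degraded


class TestDoublets:
    def test_zero_rate_removes_nothing(self, epi_lognorm):
        th = qc.QCThresholds(doublet_rate_per_1000=0.0)
        assert qc.detect_doublets(epi_lognorm, th, seed=0) == set()

    def test_expected_count_formula(self):
        # 5,000 recovered cells -> expected rate 4%, N = 200
        n = 5000
        rate = 0.8
        assert round(n * (rate * n / 1000.0) / 100.0) == 200

    def test_planted_heterotypic_doublets_recall(self):
        cfg = SimConfig(
            n_cohorts=1,
            patients_per_cohort=1,
            cells_per_sample=1000,
            n_genes=1500,
            doublet_rate_per_1000=5.0,  # 5% at 1,000 cells
            normal_sample_frac=0.0,
            homotypic_doublet_frac=0.0,
        )
        adata, _ = simulate_sc_cohorts(cfg, 13)
        lognorm = qc.lognormalize(qc.filter_empty_droplets(adata))
        th = qc.QCThresholds(doublet_rate_per_1000=5.0)
        found = qc.detect_doublets(lognorm, th, seed=0)
        truth_doub = set(lognorm.obs_names[lognorm.obs["is_doublet"]])
        recall = len(found & truth_doub) / len(truth_doub)
        assert recall >= 0.5


class TestCelltypeCutoffs:
    def test_rule_application_and_boundaries(self):
        th = qc.QCThresholds()
        n_genes = 2000
        # epithelial cell with NODG 900 < 1000 -> discarded;
        # cell at exactly the mito cap -> retained
        X = np.zeros((2, n_genes), dtype=int)
        X[0, :900] = 1
        X[1, :1200] = 4  # 4800 counts
        adata = _adata_from_counts(X)
        adata.var["is_mito"] = [False] * (n_genes - 1) + [True]
        X2 = np.asarray(adata.X.todense())
        X2[1, -1] = 1200  # mito = 1200 / 6000 = exactly 20%
        adata.X = sp.csr_matrix(X2)
        types = pd.Series(["epithelial", "epithelial"], index=adata.obs_names)
        out = qc.apply_celltype_cutoffs(adata, types, th)
        assert list(out.obs_names) == ["c1"]

    def test_planted_low_quality_cells_removed(self, small_sim):
        adata, _ = small_sim
        filtered = qc.filter_empty_droplets(adata)
        lowq = filtered.obs["is_low_quality"].to_numpy()
        assert lowq.sum() > 10
        out = qc.apply_celltype_cutoffs(filtered, filtered.obs["true_cell_type"])
        removed = ~filtered.obs_names.isin(out.obs_names)
        assert (removed & lowq).sum() / lowq.sum() >= 0.9


def test_stages_only_remove_rows(small_sim):
    adata, _ = small_sim
    f1 = qc.filter_empty_droplets(adata)
    f2 = qc.apply_celltype_cutoffs(f1, f1.obs["true_cell_type"])
    assert set(f2.obs_names) <= set(f1.obs_names) <= set(adata.obs_names)
    # counts never edited
    keep = adata.obs_names.isin(f2.obs_names)
    assert (adata[keep].X != f2.X).nnz == 0
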