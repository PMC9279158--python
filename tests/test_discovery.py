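"""Subtype discovery: feature selection, clustering, pairwise DEG refinement,
normal-like identification, patient split, stage-1 markers."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from icmskit import discovery
from icmskit.discovery import DEGParams


@pytest.fixture(scope="module")
def chain(epi_lognorm):
    """Feature selection -> clustering -> refinement -> re-clustering."""
    feats = discovery.select_features(epi_lognorm, "correlation_range", n_features=400)
    ca = discovery.cluster_cells(
        epi_lognorm, feats, resolution=0.2, seed=0, scale_by_cohort=True
    )
    _, refined = discovery.pairwise_deg(epi_lognorm, ca.labels)
    ca2 = discovery.cluster_cells(
        epi_lognorm, refined, resolution=0.5, seed=0, scale_by_cohort=True
    )
    return feats, ca, refined, ca2


class TestFeatureSelection:
    def test_unexpressed_gene_never_selected(self, epi_lognorm):
        sub = epi_lognorm.copy()
        import scipy.sparse as sp

        X = np.asarray(sub.X.todense()) if sp.issparse(sub.X) else np.asarray(sub.X)
        X[:, :5] = 0.0  # force five silent genes
        sub.X = X
        silent = set(sub.var_names[:5])
        feats = discovery.select_features(sub, "correlation_range", 400)
        assert not silent & set(feats)

    def test_planted_markers_enriched(self, chain, small_universe):
        feats, *_ = chain
        markers = set(
            small_universe.genes.index[small_universe.genes["marker_class"] != ""]
        )
        # planted subtype markers should dominate the selected features
        assert len(markers & set(feats)) >= 0.7 * len(markers)

    def test_deterministic(self, epi_lognorm):
        f1 = discovery.select_features(epi_lognorm, "hvg", 200)
        f2 = discovery.select_features(epi_lognorm, "hvg", 200)
        assert f1 == f2


class TestClustering:
    def test_two_blobs_two_clusters(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.3, (150, 40)), rng.normal(2, 0.3, (150, 40))]
        )
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame(index=[f"c{i}" for i in range(300)]),
            var=pd.DataFrame(index=[f"g{j}" for j in range(40)]),
        )
        ca = discovery.cluster_cells(adata, list(adata.var_names), resolution=0.2, seed=0)
        assert ca.labels.nunique() == 2
        truth = np.repeat([0, 1], 150)
        assert adjusted_rand_score(truth, ca.labels) == 1.0

    def test_cell_order_invariance(self, epi_lognorm, chain):
        feats, ca, *_ = chain
        rng = np.random.default_rng(1)
        perm = rng.permutation(epi_lognorm.n_obs)
        shuffled = epi_lognorm[perm].copy()
        ca_s = discovery.cluster_cells(
            shuffled, feats, resolution=0.2, seed=0, scale_by_cohort=True
        )
        joined = pd.concat([ca.labels, ca_s.labels.reindex(ca.labels.index)], axis=1)
        assert adjusted_rand_score(joined.iloc[:, 0], joined.iloc[:, 1]) > 0.95

    def test_recovers_planted_structure(self, chain, epi_lognorm):
        *_, ca2 = chain
        truth = epi_lognorm.obs["true_subtype"].replace({"": "na"})
        assert ca2.labels.nunique() >= 3
        assert adjusted_rand_score(truth, ca2.labels) >= 0.8


class TestPairwiseDEG:
    def test_identical_clusters_give_no_degs(self, epi_lognorm):
        # random split of a homogeneous population
        norm = epi_lognorm[(epi_lognorm.obs["true_subtype"] == "normal").to_numpy()]
        rng = np.random.default_rng(0)
        fake = pd.Series(
            rng.integers(0, 2, norm.n_obs).astype(str), index=norm.obs_names
        )
        tables, refined = discovery.pairwise_deg(norm, fake)
        assert refined == []
        assert not tables[("0", "1")]["is_deg"].any()

    def test_refined_set_bounded_by_union(self, chain):
        _, ca, refined, _ = chain
        k = ca.labels.nunique()
        n_pairs = k * (k - 1) // 2
        assert len(refined) <= n_pairs * 60

    def test_planted_markers_fill_top_slots(self, noarm_epi, noarm_universe):
        # i2 vs i3 malignant cells: top-30 slots should be planted markers
        # (arm-free generator: the markers are the only malignant DEGs)
        sub = noarm_epi[noarm_epi.obs["true_subtype"].isin(["i2", "i3"]).to_numpy()]
        labels = sub.obs["true_subtype"].astype(str)
        tables, refined = discovery.pairwise_deg(sub, labels)
        df = tables[("i2", "i3")]
        planted = set(noarm_universe.genes.index[noarm_universe.genes["marker_class"] != ""])
        top_up = discovery._top_slots(df, "up", 30)
        top_down = discovery._top_slots(df, "down", 30)
        hits = len((set(top_up) | set(top_down)) & planted)
        assert hits >= 0.9 * (len(top_up) + len(top_down))


class TestNormalLike:
    def test_cluster_without_normal_cells_not_flagged(self):
        clusters = pd.Series(["a"] * 50 + ["b"] * 50, index=[f"c{i}" for i in range(100)])
        obs = pd.DataFrame(
            {"tissue": ["normal"] * 50 + ["tumor"] * 50}, index=clusters.index
        )
        assert discovery.identify_normal_like(clusters, obs) == {"a"}

    def test_no_normal_cells_returns_empty_with_warning(self):
        clusters = pd.Series(["a"] * 10, index=[f"c{i}" for i in range(10)])
        obs = pd.DataFrame({"tissue": ["tumor"] * 10}, index=clusters.index)
        with pytest.warns(UserWarning, match="no normal"):
            assert discovery.identify_normal_like(clusters, obs) == set()

    def test_planted_normal_like_recall(self, chain, epi_lognorm):
        *_, ca2 = chain
        nl = discovery.identify_normal_like(ca2.labels, epi_lognorm.obs)
        in_nl = ca2.labels.isin(nl)
        truth = epi_lognorm.obs["true_subtype"] == "normal"
        recall = (in_nl & truth).sum() / truth.sum()
        assert recall >= 0.95


class TestPatientSplit:
    def test_split_matches_truth(self, chain, epi_lognorm, small_sim):
        _, _, refined, ca2 = chain
        nl = discovery.identify_normal_like(ca2.labels, epi_lognorm.obs)
        mal = (~ca2.labels.isin(nl)) & epi_lognorm.obs["tissue"].eq("tumor")
        groups, coords, pb = discovery.patient_pseudobulk_split(
            epi_lognorm, mal.to_numpy(), refined, seed=0
        )
        truth = small_sim[1].patients["subtype"].reindex(groups.index)
        agree = (groups.map({"A": "i2", "B": "i3"}) == truth).mean()
        assert max(agree, 1 - agree) == 1.0

    def test_patient_order_invariance(self, chain, epi_lognorm):
        _, _, refined, ca2 = chain
        nl = discovery.identify_normal_like(ca2.labels, epi_lognorm.obs)
        mal = ((~ca2.labels.isin(nl)) & epi_lognorm.obs["tissue"].eq("tumor")).to_numpy()
        g1, *_ = discovery.patient_pseudobulk_split(epi_lognorm, mal, refined, seed=0)
        rng = np.random.default_rng(3)
        perm = rng.permutation(epi_lognorm.n_obs)
        g2, *_ = discovery.patient_pseudobulk_split(
            epi_lognorm[perm].copy(), mal[perm], refined, seed=0
        )
        assert g1.sort_index().equals(g2.sort_index())

    def test_identical_patients_have_zero_pca_distance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(40, 30))
        X = np.vstack([base, base])  # two patients with identical cells
        obs = pd.DataFrame(
            {
                "patient_id": ["p0"] * 40 + ["p1"] * 40,
                "cohort_id": "k0",
            },
            index=[f"c{i}" for i in range(80)],
        )
        extra = np.vstack([rng.normal(size=(40, 30)) + 3, rng.normal(size=(40, 30)) - 3])
        obs2 = pd.DataFrame(
            {"patient_id": ["p2"] * 40 + ["p3"] * 40, "cohort_id": "k0"},
            index=[f"c{i}" for i in range(80, 160)],
        )
        adata = ad.AnnData(
            X=np.vstack([X, extra]),
            obs=pd.concat([obs, obs2]),
            var=pd.DataFrame(index=[f"g{j}" for j in range(30)]),
        )
        groups, coords, _ = discovery.patient_pseudobulk_split(
            adata, np.ones(160, bool), list(adata.var_names), seed=0
        )
        assert np.linalg.norm(coords.loc["p0"] - coords.loc["p1"]) < 1e-8


class TestStage1Markers:
    @pytest.fixture(scope="class")
    def stage1(self, noarm_epi):
        truth_sub = noarm_epi.obs["true_subtype"]
        groups = truth_sub.where(truth_sub.isin(["i2", "i3", "normal"]))
        sig = discovery.derive_stage1_markers(noarm_epi, groups)
        return sig

    def test_marker_sets_pairwise_disjoint(self, stage1):
        assert not stage1.up("i2") & stage1.up("i3")
        assert not stage1.up("i2") & stage1.up("normal")

    def test_planted_recovery_and_precision(self, stage1, noarm_universe):
        gt = noarm_universe.genes
        for cls in ("i2", "i3"):
            planted = set(gt.index[gt["marker_class"] == f"{cls}_Up"])
            derived = stage1.up(cls)
            assert len(planted & derived) / len(planted) >= 0.9
            # markers not planted as <cls>_Up must stay a small minority
            false = derived - planted
            assert len(false) <= 0.2 * max(len(derived), 1)

    def test_group_with_too_few_cells_raises(self, epi_lognorm):
        groups = pd.Series("i2", index=epi_lognorm.obs_names)
        groups.iloc[0] = "i3"
        with pytest.raises(ValueError, match="< 2 cells"):
            discovery.derive_stage1_markers(epi_lognorm, groups)
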