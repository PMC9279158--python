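"""NB pseudo-bulk differential expression: sums, size factors, calibration,
the consistency-rule signature and the DEG-count dendrogram."""

import numpy as np
import pandas as pd
import pytest

from icmskit.pseudobulk import (
    DEGResult,
    PseudoBulkMatrix,
    SignatureParams,
    deg_count_distance,
    derive_icms_signature,
    nb_deg_test,
    size_factors,
    sum_pseudobulk,
)


def _nb(rng, mu, alpha, size):
    return rng.poisson(rng.gamma(1.0 / alpha, alpha * mu, size=size))


def _pb(counts, groups, cohorts=None, ids=None):
    ids = ids or [f"P{i}" for i in range(counts.shape[0])]
    meta = pd.DataFrame(
        {"group": groups, "cohort_id": cohorts if cohorts is not None else "c0"},
        index=ids,
    )
    frame = pd.DataFrame(
        counts, index=ids, columns=[f"G{j}" for j in range(counts.shape[1])]
    )
    return PseudoBulkMatrix(counts=frame, meta=meta)


class TestSumPseudobulk:
    def test_exact_integer_sums(self, small_sim):
        adata, _ = small_sim
        sub = adata[:300, :50].copy()
        groups = pd.Series("g", index=sub.obs["patient_id"].unique())
        pb = sum_pseudobulk(sub, sub.obs["patient_id"], groups, min_detect_frac=0.0)
        expected = (
            pd.DataFrame(
                np.asarray(sub.X.todense()), index=sub.obs_names, columns=sub.var_names
            )
            .groupby(sub.obs["patient_id"], observed=True)
            .sum()
        )
        pd.testing.assert_frame_equal(pb.counts, expected.astype(np.int64)[pb.counts.columns])

    def test_five_percent_detection_filter(self):
        # 61 patients, gene detected in 3 -> 3/61 = 4.9% < 5% -> discarded
        import anndata as ad

        n = 61
        X = np.ones((n, 2), dtype=int)
        X[:, 1] = 0
        X[:3, 1] = 5
        obs = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(n)], "cohort_id": "c0"},
            index=[f"c{i}" for i in range(n)],
        )
        adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=["keep", "drop"]))
        groups = pd.Series("g", index=obs["patient_id"].to_numpy())
        pb = sum_pseudobulk(adata, adata.obs["patient_id"], groups)
        assert list(pb.counts.columns) == ["keep"]
        # idempotent: filtering a filtered matrix removes nothing further
        detect = (pb.counts > 0).mean(axis=0)
        assert (detect >= 0.05).all()


def test_size_factors_invariant_to_global_scaling():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.poisson(50, size=(8, 300)) + 1)
    sf1 = size_factors(counts)
    sf2 = size_factors(counts * 3)
    assert np.allclose(sf2 / sf2.iloc[0], sf1 / sf1.iloc[0])


class TestNBTest:
    def test_identical_counts_give_zero_fold_change(self):
        counts = np.full((8, 60), 40)
        counts[:, 0] = np.arange(1, 9) * 10  # one varying gene to avoid degeneracy
        pb = _pb(counts, ["a"] * 4 + ["b"] * 4)
        res = nb_deg_test(pb, ("a", "b"), cohort_covariate=False)
        flat = res.table.iloc[5]
        assert flat["log2fc"] == pytest.approx(0.0, abs=1e-6)
        assert flat["p"] > 0.5

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(42)
        counts = _nb(rng, 100.0, 0.1, (20, 1000))
        pb = _pb(counts, ["a"] * 10 + ["b"] * 10)
        res = nb_deg_test(pb, ("a", "b"), cohort_covariate=False)
        t = res.table[res.table["converged"]]
        rate = (t["p"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_power_for_planted_fold_change(self):
        rng = np.random.default_rng(7)
        counts = _nb(rng, 100.0, 0.1, (20, 1000))
        planted = rng.choice(1000, size=50, replace=False)
        counts[:10, planted] = _nb(rng, 100.0 * 2**1.5, 0.1, (10, 50))
        pb = _pb(counts, ["a"] * 10 + ["b"] * 10)
        res = nb_deg_test(pb, ("a", "b"), cohort_covariate=False)
        t = res.table.iloc[planted]
        assert (t["q"] < 0.05).mean() >= 0.9

    def test_q_at_least_p(self):
        rng = np.random.default_rng(3)
        counts = _nb(rng, 50.0, 0.2, (12, 200))
        pb = _pb(counts, ["a"] * 6 + ["b"] * 6)
        t = nb_deg_test(pb, ("a", "b"), cohort_covariate=False).table
        ok = t["converged"]
        assert (t.loc[ok, "q"] >= t.loc[ok, "p"] - 1e-12).all()

    def test_cohort_covariate_absorbs_batch_shift(self):
        rng = np.random.default_rng(5)
        counts = _nb(rng, 100.0, 0.1, (20, 400)).astype(float)
        cohorts = (["k0"] * 5 + ["k1"] * 5) * 2
        # cohort k1 has doubled depth on every gene: a pure batch effect
        counts[np.array(cohorts) == "k1"] *= 2
        pb = _pb(counts.astype(int), ["a"] * 10 + ["b"] * 10, cohorts=cohorts)
        res = nb_deg_test(pb, ("a", "b"))
        assert "cohort_k1" in res.design_columns
        t = res.table[res.table["converged"]]
        assert (t["p"] < 0.05).mean() <= 0.08

    def test_agrees_with_deseq2_oracle(self):
        # independent cross-check of the whole route (size factors,
        # dispersion, Wald test) against pydeseq2 on a small matrix
        pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(11)
        counts = _nb(rng, 80.0, 0.15, (12, 150))
        planted = np.arange(0, 150, 10)
        counts[:6, planted] = _nb(rng, 80.0 * 2.5, 0.15, (6, len(planted)))
        genes = [f"G{j}" for j in range(150)]
        cdf = pd.DataFrame(counts, index=[f"P{i}" for i in range(12)], columns=genes)
        meta = pd.DataFrame({"group": ["a"] * 6 + ["b"] * 6}, index=cdf.index)

        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=cdf, metadata=meta, design="~group", quiet=True)
            dds.deseq2()
            stats = DeseqStats(dds, contrast=["group", "a", "b"], quiet=True)
            stats.summary()
        oracle = stats.results_df

        pb = PseudoBulkMatrix(counts=cdf, meta=meta.assign(cohort_id="c0"))
        mine = nb_deg_test(pb, ("a", "b"), cohort_covariate=False).table
        merged = mine.join(oracle, how="inner", lsuffix="_m")
        r = np.corrcoef(merged["log2fc"], merged["log2FoldChange"])[0, 1]
        assert r > 0.95
        hits_mine = set(merged.index[merged["q"] < 0.05])
        hits_oracle = set(merged.index[merged["padj"] < 0.05])
        jaccard = len(hits_mine & hits_oracle) / max(len(hits_mine | hits_oracle), 1)
        assert jaccard >= 0.7


class TestSignatureRule:
    def _result(self, contrast, rows):
        genes = list(rows)
        table = pd.DataFrame(
            {
                "gene": genes,
                "log2fc": [rows[g][0] for g in genes],
                "se": 0.1,
                "p": [rows[g][1] for g in genes],
                "q": [rows[g][1] for g in genes],
                "base_mean": [rows[g][2] for g in genes],
                "dispersion": 0.1,
                "converged": True,
            }
        ).set_index("gene", drop=False).rename_axis(None)
        return DEGResult(table=table, contrast=contrast, design_columns=("intercept", "group"))

    def test_consistency_rule(self):
        # g1: up vs i3 AND vs normal -> i2_Up
        # g2: up vs i3 but DOWN vs normal -> excluded
        # g3: down vs both -> i2_Down
        r_i2_i3 = self._result(
            ("i2", "i3"), {"g1": (0.7, 0.01, 50), "g2": (0.7, 0.01, 50), "g3": (-0.8, 0.01, 50)}
        )
        r_i3_norm = self._result(
            ("i3", "normal"), {"g1": (-0.9, 0.01, 50), "g2": (-0.1, 0.5, 50), "g3": (0.8, 0.01, 50)}
        )
        r_norm_i2 = self._result(
            ("normal", "i2"), {"g1": (-0.7, 0.01, 50), "g2": (0.9, 0.01, 50), "g3": (0.9, 0.01, 50)}
        )
        sig = derive_icms_signature(
            {1: r_i2_i3, 2: r_i3_norm, 3: r_norm_i2}
        )
        assert sig.up("i2") == {"g1"}
        assert sig.down("i2") == {"g3"}
        assert "g2" not in sig.all_genes()

    def test_threshold_edge(self):
        # log2fc 0.7 >= log2(1.5) = 0.585 passes; 0.5 does not
        r1 = self._result(("i2", "i3"), {"g": (0.7, 0.01, 50), "h": (0.5, 0.01, 50)})
        r2 = self._result(("i3", "normal"), {"g": (-0.7, 0.01, 50), "h": (-0.7, 0.01, 50)})
        r3 = self._result(("normal", "i2"), {"g": (-0.7, 0.01, 50), "h": (-0.7, 0.01, 50)})
        sig = derive_icms_signature({1: r1, 2: r2, 3: r3})
        assert sig.up("i2") == {"g"}

    def test_missing_contrast_raises(self):
        r1 = self._result(("i2", "i3"), {"g": (0.7, 0.01, 50)})
        with pytest.raises(ValueError, match="missing contrast"):
            derive_icms_signature({1: r1})


class TestDEGCountDistance:
    @pytest.fixture(scope="class")
    def groups_pb(self):
        rng = np.random.default_rng(19)
        base = rng.lognormal(3.0, 0.8, size=400)
        shift_big = np.ones(400)
        shift_big[:80] = 3.0  # i2 far from both i3 groups
        shift_small = np.ones(400)
        shift_small[350:] = 2.0  # i3_MSI mildly apart from i3_MSS
        mus = {
            "i2_MSS": base * shift_big,
            "i3_MSS": base,
            "i3_MSI": base * shift_small,
        }
        counts, groups = [], []
        for g, mu in mus.items():
            counts.append(_nb(rng, mu, 0.1, (4, 400)))
            groups += [g] * 4
        return _pb(np.vstack(counts), groups)

    def test_symmetry_zero_diagonal_and_topology(self, groups_pb):
        D, Z, newick = deg_count_distance(groups_pb, cohort_covariate=False)
        assert np.allclose(D.to_numpy(), D.to_numpy().T)
        assert np.allclose(np.diag(D.to_numpy()), 0.0)
        # the two i3 groups share most of their transcriptome: they join first
        assert D.loc["i3_MSS", "i3_MSI"] < D.loc["i2_MSS", "i3_MSS"]
        assert "(i3_MSS" in newick.replace("i3_MSI", "i3_MSS") or "i3_MSS" in newick
        # newick topology: i3 pair nested together
        inner = newick[newick.find("(", 1) : newick.find(")") + 1]
        assert "i3_MSS" in inner and "i3_MSI" in inner

    def test_group_with_single_patient_raises(self):
        rng = np.random.default_rng(0)
        counts = _nb(rng, 50.0, 0.1, (5, 100))
        pb = _pb(counts, ["a", "a", "b", "b", "c"])
        with pytest.raises(ValueError, match="< 2 patients"):
            deg_count_distance(pb, cohort_covariate=False)
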