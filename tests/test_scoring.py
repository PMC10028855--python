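import numpy as np
import pandas as pd
import pytest

from sigcompass import ExpressionDataset
from sigcompass.catalog import Catalog, SignatureGene
from sigcompass.errors import (
    CoverageError,
    EmptySelectionError,
    GenesUnavailableError,
    SigcompassError,
)
from sigcompass.scoring import (
    compute_many,
    compute_signature,
    score_consensus_subtypes,
    score_ips,
    score_ssgsea,
    score_up_down,
    score_weighted_sum,
    score_zscore_mean,
)
from tests import oracles
from tests.conftest import make_sig


def frame(data, genes, obs):
    return pd.DataFrame(np.asarray(data, dtype=float), index=genes, columns=obs)


class TestWeightedSum:
    def test_all_zero_weights(self):
        expr = frame([[1, 2], [3, 4]], ["A", "B"], ["o1", "o2"])
        w = pd.Series({"A": 0.0, "B": 0.0})
        assert (score_weighted_sum(expr, w) == 0).all()

    def test_single_gene_identity(self):
        expr = frame([[5.0, 7.0]], ["A"], ["o1", "o2"])
        out = score_weighted_sum(expr, pd.Series({"A": 1.0}))
        np.testing.assert_allclose(out, [5.0, 7.0])

    def test_matches_dot_product_oracle(self):
        expr = frame([[2, 1], [0, 3], [4, 2]], ["A", "B", "C"], ["o1", "o2"])
        weights = {"A": 1.0, "B": -2.0, "C": 0.5}
        expected = oracles.dot_scores(
            {"A": [2, 1], "B": [0, 3], "C": [4, 2]}, weights
        )
        out = score_weighted_sum(expr, pd.Series(weights))
        np.testing.assert_allclose(out, expected)  # [4.0, -4.0]
        np.testing.assert_allclose(out, [4.0, -4.0])

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(0)
        expr = frame(rng.normal(size=(4, 6)), list("ABCD"), [f"o{i}" for i in range(6)])
        w = pd.Series(rng.normal(size=4), index=list("ABCD"))
        a = score_weighted_sum(expr, w)
        b = score_weighted_sum(expr, 3.0 * w)
        np.testing.assert_allclose(3.0 * a, b)


class TestZscoreMean:
    def test_constant_matrix_scores_zero(self):
        expr = frame(np.full((3, 4), 2.5), list("ABC"), list("wxyz"))
        d = pd.Series("up", index=list("ABC"))
        assert (score_zscore_mean(expr, d) == 0).all()

    def test_two_obs_symmetry(self):
        expr = frame([[1.0, 3.0]], ["A"], ["o1", "o2"])
        d = pd.Series({"A": "up"})
        out = score_zscore_mean(expr, d)
        assert out.iloc[0] == pytest.approx(-out.iloc[1])

    def test_matches_bruteforce_oracle(self):
        data = {"A": [1, 4, 2], "B": [0, 0, 9], "C": [5, 5, 5], "D": [2, 8, 3]}
        directions = {"A": "up", "B": "down", "C": "up", "D": "up"}
        expected = oracles.zscore_mean_scores(data, directions)
        expr = frame(list(data.values()), list(data), ["o1", "o2", "o3"])
        out = score_zscore_mean(expr, pd.Series(directions))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_single_observation_errors(self):
        expr = frame([[1.0]], ["A"], ["o1"])
        with pytest.raises(SigcompassError, match="2 observations"):
            score_zscore_mean(expr, pd.Series({"A": "up"}))

    def test_mean_zero_for_up_only_signature(self):
        rng = np.random.default_rng(3)
        expr = frame(rng.normal(size=(5, 8)), list("ABCDE"), [f"o{i}" for i in range(8)])
        out = score_zscore_mean(expr, pd.Series("up", index=list("ABCDE")))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)


class TestUpDown:
    def test_up_equals_down_scores_zero(self):
        expr = frame([[1, 2], [1, 2]], ["A", "B"], ["o1", "o2"])
        # same genes listed up and down via two rows with equal values
        d = pd.Series({"A": "up", "B": "down"})
        np.testing.assert_allclose(score_up_down(expr, d), [0.0, 0.0])

    def test_empty_down_set_is_up_mean(self):
        expr = frame([[1, 3], [3, 5]], ["A", "B"], ["o1", "o2"])
        d = pd.Series({"A": "up", "B": "up"})
        np.testing.assert_allclose(score_up_down(expr, d), [2.0, 4.0])

    def test_matches_arithmetic_oracle(self):
        data = {"A": [4, 0], "B": [2, 6], "C": [1, 1], "D": [3, 7]}
        directions = {"A": "up", "B": "up", "C": "down", "D": "down"}
        expected = oracles.up_down_scores(data, directions)
        expr = frame(list(data.values()), list(data), ["o1", "o2"])
        out = score_up_down(expr, pd.Series(directions))
        np.testing.assert_allclose(out, expected)
        np.testing.assert_allclose(out, [1.0, -1.0])

    def test_no_up_genes_refused(self):
        expr = frame([[1, 2]], ["A"], ["o1", "o2"])
        with pytest.raises(CoverageError):
            score_up_down(expr, pd.Series({"A": "down"}))


class TestSsgsea:
    def _toy(self, seed=0, n_genes=10, n_obs=3):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(n_genes)]
        return frame(rng.uniform(0, 50, (n_genes, n_obs)), genes,
                     [f"o{i}" for i in range(n_obs)])

    def test_rank_invariance_under_scaling(self):
        expr = self._toy()
        a = score_ssgsea(expr, ["g01", "g03", "g07"])
        b = score_ssgsea(expr * 2.0, ["g01", "g03", "g07"])
        np.testing.assert_allclose(a, b)

    def test_monotone_transform_invariance(self):
        expr = self._toy(seed=5)
        gene_set = ["g00", "g04", "g08"]
        a = score_ssgsea(expr, gene_set)
        b = score_ssgsea(np.exp(expr / 10.0), gene_set)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_whole_genome_set_is_error(self):
        expr = self._toy()
        with pytest.raises(SigcompassError, match="whole background"):
            score_ssgsea(expr, list(expr.index))

    def test_matches_walk_oracle(self):
        expr = self._toy(seed=11)
        gene_set = ["g02", "g05", "g09"]
        out = score_ssgsea(expr, gene_set, alpha=0.25)
        for j, obs in enumerate(expr.columns):
            expected = oracles.ssgsea_score(
                list(expr.index), list(expr[obs]), set(gene_set), alpha=0.25
            )
            assert out[obs] == pytest.approx(expected, abs=1e-9), f"obs {j}"

    def test_tied_values_use_midranks(self):
        expr = frame([[5], [5], [1], [0], [2]], [f"g{i}" for i in range(5)], ["o"])
        out = score_ssgsea(expr, ["g0", "g1"])
        expected = oracles.ssgsea_score(list(expr.index), [5, 5, 1, 0, 2], {"g0", "g1"}, 0.25)
        assert out["o"] == pytest.approx(expected, abs=1e-12)

    def test_too_small_intersection_errors(self):
        expr = self._toy()
        with pytest.raises(CoverageError):
            score_ssgsea(expr, ["g01"])


class TestIps:
    def _inputs(self):
        genes = [f"g{i}" for i in range(8)]
        class_labels = pd.Series(
            ["EC", "EC", "SC", "SC", "MHC", "MHC", "CP", "CP"], index=genes
        )
        sub_classes = pd.Series(genes, index=genes)  # each gene its own sub-class
        weights = pd.Series([1.0] * 8, index=genes)
        return genes, class_labels, sub_classes, weights

    def test_constant_matrix_all_zero_ips_zero(self):
        genes, cl, sc, w = self._inputs()
        expr = frame(np.full((8, 4), 3.0), genes, list("wxyz"))
        out = score_ips(expr, cl, sc, w, "IPS")
        for cat in ("EC", "SC", "MHC", "CP"):
            assert (out[f"IPS_{cat}"] == 0).all()
        assert (out["IPS"] == 0).all()

    def test_az_of_three_maps_to_ten(self):
        genes, cl, sc, w = self._inputs()
        expr = frame(np.full((8, 4), 3.0), genes, list("wxyz"))
        out = score_ips(expr, cl, sc, w, "IPS")
        # direct check of the composite formula at the endpoints
        assert np.minimum(10.0, 10.0 * 3.0 / 3.0) == 10.0
        assert (out["IPS"][out["IPS_AZ"] <= 0] == 0).all()

    def test_matches_hand_computed_oracle(self):
        genes, cl, sc, w = self._inputs()
        rng = np.random.default_rng(2)
        data = {g: list(rng.normal(size=5)) for g in genes}
        expr = frame(list(data.values()), genes, [f"o{i}" for i in range(5)])
        out = score_ips(expr, cl, sc, w, "IPS")
        # oracle: category score = mean of per-gene z over its two genes
        for cat, pair in [("EC", genes[0:2]), ("SC", genes[2:4]),
                          ("MHC", genes[4:6]), ("CP", genes[6:8])]:
            z = oracles.zscore_mean_scores(
                {g: data[g] for g in pair}, {g: "up" for g in pair}
            )
            np.testing.assert_allclose(out[f"IPS_{cat}"], z, atol=1e-12)
        az = out[[f"IPS_{c}" for c in ("EC", "SC", "MHC", "CP")]].mean(axis=1)
        np.testing.assert_allclose(out["IPS_AZ"], az, atol=1e-12)
        expected_ips = np.where(az <= 0, 0.0, np.minimum(10.0, 10.0 * az / 3.0))
        np.testing.assert_allclose(out["IPS"], expected_ips, atol=1e-12)

    def test_missing_category_refused(self):
        genes, cl, sc, w = self._inputs()
        expr = frame(np.ones((6, 3)), genes[:6], list("xyz"))  # no CP genes present
        with pytest.raises(CoverageError, match="CP"):
            score_ips(expr, cl, sc, w)

    def test_negative_sub_class_weight_flips_sign(self):
        genes, cl, sc, _ = self._inputs()
        w = pd.Series([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, 1.0, 1.0], index=genes)
        rng = np.random.default_rng(6)
        expr = frame(rng.normal(size=(8, 5)), genes, [f"o{i}" for i in range(5)])
        pos = score_ips(expr, cl, sc, pd.Series(1.0, index=genes), "IPS")
        mix = score_ips(expr, cl, sc, w, "IPS")
        np.testing.assert_allclose(mix["IPS_SC"], -pos["IPS_SC"], atol=1e-12)
        np.testing.assert_allclose(mix["IPS_EC"], pos["IPS_EC"], atol=1e-12)


class TestConsensus:
    def _centroids(self):
        genes = [f"g{i}" for i in range(6)]
        rng = np.random.default_rng(4)
        return pd.DataFrame(
            rng.normal(size=(6, 4)), index=genes, columns=["DIF", "IMR", "MES", "PRO"]
        )

    def test_observation_equal_to_centroid_scores_one(self):
        cent = self._centroids()
        expr = pd.DataFrame({"obs1": cent["PRO"]})
        out = score_consensus_subtypes(expr, cent, "C")
        assert out.loc["obs1", "C_PRO"] == pytest.approx(1.0)
        assert out.loc["obs1", "C_label"] == "PRO"

    def test_negated_centroid_scores_minus_one(self):
        cent = self._centroids()[["DIF", "IMR"]]
        expr = pd.DataFrame({"obs1": -cent["DIF"]})
        out = score_consensus_subtypes(expr, cent, "C")
        assert out.loc["obs1", "C_DIF"] == pytest.approx(-1.0)

    def test_matches_pearson_oracle(self):
        cent = self._centroids()
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.normal(size=(6, 3)), index=cent.index,
                            columns=["o1", "o2", "o3"])
        out = score_consensus_subtypes(expr, cent, "C")
        for obs in expr.columns:
            for sub in cent.columns:
                expected = oracles.pearson(list(expr[obs]), list(cent[sub]))
                assert out.loc[obs, f"C_{sub}"] == pytest.approx(expected, abs=1e-12)
        assert ((out[[f"C_{s}" for s in cent.columns]] <= 1).all().all()
                and (out[[f"C_{s}" for s in cent.columns]] >= -1).all().all())

    def test_zero_variance_observation_missing(self):
        cent = self._centroids()
        expr = pd.DataFrame({"flat": np.ones(6)}, index=cent.index)
        out = score_consensus_subtypes(expr, cent, "C")
        assert out.loc["flat", [f"C_{s}" for s in cent.columns]].isna().all()
        assert out.loc["flat", "C_label"] is None

    def test_too_few_shared_genes(self):
        cent = self._centroids()
        expr = pd.DataFrame({"o": [1.0, 2.0]}, index=["g0", "g1"])
        with pytest.raises(CoverageError):
            score_consensus_subtypes(expr, cent)


class TestComputeSignature:
    def test_full_coverage(self, toy_dataset):
        sig = make_sig("Full_Sig", genes=[SignatureGene(g, "up") for g in
                                          ["GA", "GB", "GC", "GD", "GE"]])
        res = compute_signature(toy_dataset, sig)
        assert res.genes_used == res.genes_requested == 5

    def test_boundary_coverage_computed_with_warning(self, toy_dataset):
        genes = [SignatureGene("GA", "up"), SignatureGene("GB", "up")] + [
            SignatureGene(f"ZZ{i}", "up") for i in range(38)
        ]
        sig = make_sig("Partial_Sig", genes=genes)
        with pytest.warns(UserWarning, match="absent"):
            res = compute_signature(toy_dataset, sig)
        assert res.genes_used == 2 and res.genes_requested == 40

    def test_below_coverage_refused(self, toy_dataset):
        genes = [SignatureGene("GA", "up")] + [SignatureGene(f"ZZ{i}", "up") for i in range(39)]
        sig = make_sig("Sparse_Sig", genes=genes)
        with pytest.raises(CoverageError, match="1/40"):
            compute_signature(toy_dataset, sig)

    def test_case_insensitive_intersection(self, toy_dataset):
        ds = toy_dataset.copy()
        ds.matrix.index = [g.lower() for g in ds.matrix.index]
        sig = make_sig("Case_Sig", genes=[SignatureGene("GA", "up"), SignatureGene("GB", "up")])
        res = compute_signature(ds, sig)
        assert res.genes_used == 2

    def test_metric_conversion_applied_on_copy(self, counts_dataset):
        sig = make_sig("Conv_Sig", genes=[SignatureGene("G0", "up"), SignatureGene("G1", "up")])
        res = compute_signature(counts_dataset, sig)
        assert counts_dataset.metric == "counts"  # untouched
        assert len(res.values) == counts_dataset.n_obs

    def test_metadata_only_signature_refused(self, toy_dataset, default_catalog):
        with pytest.raises(GenesUnavailableError, match="metadata-only"):
            compute_signature(toy_dataset, "EMT_Mak", catalog=default_catalog)

    def test_deterministic_and_gene_order_invariant(self, toy_dataset):
        genes = [SignatureGene(g, "up") for g in ["GA", "GB", "GC"]]
        sig1 = make_sig("Order_Sig", genes=genes)
        sig2 = make_sig("Order_Sig", genes=list(reversed(genes)))
        a = compute_signature(toy_dataset, sig1)
        b = compute_signature(toy_dataset, sig2)
        np.testing.assert_array_equal(a.values.to_numpy(), b.values.to_numpy())
        assert a.options_fingerprint == b.options_fingerprint

    def test_permutation_of_data_rows_invariant(self, toy_dataset):
        sig = make_sig("Perm_Sig", genes=[SignatureGene(g, "up") for g in ["GA", "GC", "GE"]])
        shuffled = toy_dataset.copy()
        shuffled.matrix = shuffled.matrix.iloc[[4, 2, 0, 3, 1]]
        a = compute_signature(toy_dataset, sig)
        b = compute_signature(shuffled, sig)
        np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy())


class TestComputeMany:
    def _catalog_and_ds(self):
        from sigcompass.synthetic import SimulationDesign, make_synthetic_catalog, simulate_bulk

        design = SimulationDesign(n_genes=120, n_obs=30, seed=5)
        ds, _ = simulate_bulk(design)
        cat = make_synthetic_catalog(6, gene_universe=ds.gene_ids, seed=5)
        return cat, ds

    def test_all_families_attach_columns(self):
        cat, ds = self._catalog_and_ds()
        out, summary, results = compute_many(ds, cat)
        assert (summary["status"] == "ok").all()
        assert len(results) == 6
        assert out.scores.shape[1] >= 6

    def test_failures_logged_not_fatal(self, default_catalog, toy_dataset):
        from sigcompass.catalog import CatalogFilter

        # real catalog genes largely absent from the toy matrix: failures expected
        with pytest.raises(EmptySelectionError):
            compute_many(toy_dataset, default_catalog, CatalogFilter(topic="Hypoxia activity"))

    def test_filter_matching_none_errors(self, toy_dataset):
        cat, ds = self._catalog_and_ds()
        from sigcompass.catalog import CatalogFilter

        with pytest.warns(UserWarning):
            with pytest.raises(EmptySelectionError):
                compute_many(ds, cat, CatalogFilter(topic="No Such Topic"))
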