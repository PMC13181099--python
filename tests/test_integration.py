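"""Standardization, PCA, Ward clustering, correlation screen, ISI, and
soil-matched recommendations."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from lupinest import integration as integ


def summary_frame(rows):
    return pd.DataFrame(rows, columns=["accession_id", "ph_level", "establishment", "total_mm"])


class TestZscore:
    def test_columns_standardized_to_unit_population_sd(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"a": rng.normal(3, 5, 20), "b": rng.uniform(0, 1, 20)})
        z = integ.zscore_matrix(table)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=0), 1.0, atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            z = integ.zscore_matrix(table)
        assert list(z.columns) == ["a"]

    def test_known_two_column_table(self):
        table = pd.DataFrame({"a": [1.0, 3.0], "b": [10.0, 20.0]})
        z = integ.zscore_matrix(table)
        np.testing.assert_allclose(z.to_numpy(), [[-1, -1], [1, 1]], atol=1e-12)


class TestPca:
    def test_rank_one_data_loads_on_single_component(self):
        t = np.linspace(-1, 1, 6)
        z = pd.DataFrame({"a": t, "b": 2 * t, "c": -t})
        res = integ.pca(z)
        assert res.var_explained[0] == pytest.approx(100.0)

    def test_variance_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(1)
        z = integ.zscore_matrix(pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd")))
        res = integ.pca(z)
        assert res.var_explained.sum() == pytest.approx(100.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        z = integ.zscore_matrix(pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc")))
        res = integ.pca(z)
        x = z.to_numpy()
        evals, evecs = np.linalg.eigh(x.T @ x)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(100 * evals / evals.sum(), res.var_explained, atol=1e-10)
        for j in range(3):
            v = evecs[:, j]
            got = res.loadings.iloc[:, j].to_numpy()
            sign = np.sign(v @ got)
            np.testing.assert_allclose(got, sign * v, atol=1e-8)
        # loadings orthonormal
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(3), atol=1e-10)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(3)
        z = integ.zscore_matrix(pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd")))
        res = integ.pca(z)
        for col in res.loadings.columns:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0


def brute_force_ward(x):
    """Ward.D2 agglomeration by exhaustive merge-cost search.

    Cost of merging clusters A, B: sqrt(2|A||B|/(|A|+|B|)) * ||cA - cB||,
    the same update scipy's 'ward' linkage minimizes.
    """
    clusters = {i: [i] for i in range(len(x))}
    merges = []
    next_id = len(x)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                ca = x[clusters[a]].mean(axis=0)
                cb = x[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                cost = np.sqrt(2 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
                if best is None or cost < best[0]:
                    best = (cost, a, b)
        cost, a, b = best
        merges.append((frozenset(clusters[a] + clusters[b]), cost))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestWardClustering:
    def test_merge_order_and_heights_match_brute_force(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 3))
        z = pd.DataFrame(x, index=[f"A{i}" for i in range(6)], columns=list("abc"))
        res = integ.ward_cluster(z, k=2, bootstrap_reps=0)
        oracle = brute_force_ward(x)
        got_sets = []
        members = {i: frozenset([i]) for i in range(6)}
        for i, row in enumerate(res.linkage):
            merged = members[int(row[0])] | members[int(row[1])]
            members[6 + i] = merged
            got_sets.append((merged, row[2]))
        for (s_got, h_got), (s_exp, h_exp) in zip(got_sets, oracle):
            assert s_got == s_exp
            assert h_got == pytest.approx(h_exp, abs=1e-10)

    def test_separated_blobs_recovered_with_high_silhouette(self):
        rng = np.random.default_rng(5)
        blob1 = rng.normal(0, 0.3, size=(10, 2))
        blob2 = rng.normal(8, 0.3, size=(10, 2))
        z = pd.DataFrame(np.vstack([blob1, blob2]), index=[f"A{i}" for i in range(20)])
        res = integ.ward_cluster(z, k=2, bootstrap_reps=50, rng_seed=1)
        labels = res.labels.to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]
        assert res.mean_silhouette > 0.7
        # the two-blob split is the root's children: support should be high
        top = res.node_support.iloc[-3:]
        assert (top["support"].dropna() > 0.8).all()

    def test_duplicated_points_merge_at_zero_height(self):
        z = pd.DataFrame(np.zeros((4, 2)), index=list("wxyz"))
        res = integ.ward_cluster(z, k=2, bootstrap_reps=0)
        np.testing.assert_allclose(res.linkage[:, 2], 0.0, atol=1e-12)

    def test_k_out_of_range_rejected(self):
        z = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="k must be"):
            integ.ward_cluster(z, k=5)


def brute_force_bh(pvals):
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, pvals[idx] * m / rank)
        q[idx] = prev
    return q


class TestSpearmanScreen:
    @staticmethod
    def table(n=10, seed=0, cols=3):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, cols)), columns=[f"t{i}" for i in range(cols)])

    def test_strictly_monotone_pair_has_rho_one(self):
        t = pd.DataFrame({"a": np.arange(8.0), "b": np.exp(np.arange(8.0)), "c": np.arange(8.0)[::-1]})
        res = integ.spearman_screen(t, bootstrap_reps=10).set_index(["trait_a", "trait_b"])
        assert res.loc[("a", "b"), "rho"] == pytest.approx(1.0)
        assert res.loc[("a", "c"), "rho"] == pytest.approx(-1.0)

    def test_constant_trait_skipped_with_marker(self):
        t = self.table()
        t["flat"] = 1.0
        res = integ.spearman_screen(t, bootstrap_reps=10)
        flat_rows = res[(res["trait_a"] == "flat") | (res["trait_b"] == "flat")]
        assert flat_rows["rho"].isna().all()

    def test_bh_adjustment_matches_step_up_oracle(self):
        pvals = np.array([0.01, 0.02, 0.04, 0.5])
        from statsmodels.stats.multitest import multipletests

        got = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(got, brute_force_bh(pvals), atol=1e-12)
        # and the screen's q-values obey the same fixed point: equal p -> equal q
        t = self.table(seed=3, cols=4)
        res = integ.spearman_screen(t, bootstrap_reps=5)
        tested = res.dropna(subset=["q_value"])
        np.testing.assert_allclose(
            tested["q_value"], brute_force_bh(tested["p_value"].to_numpy()), atol=1e-12
        )

    def test_q_monotone_in_p_and_at_least_p(self):
        t = self.table(n=12, seed=4, cols=5)
        res = integ.spearman_screen(t, bootstrap_reps=5).dropna(subset=["q_value"])
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()
        s = res.sort_values("p_value")
        assert s["q_value"].is_monotonic_increasing

    def test_bootstrap_ci_brackets_rho_for_strong_signal(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        t = pd.DataFrame({"a": x, "b": x + 0.1 * rng.normal(size=30)})
        res = integ.spearman_screen(t, bootstrap_reps=200, rng_seed=1)
        assert res.loc[0, "ci_low"] <= res.loc[0, "rho"] <= res.loc[0, "ci_high"]


class TestIsi:
    def test_two_accession_worked_example(self):
        rows = [
            ("A", 5.5, 0.6, 40.0), ("A", 7.0, 0.8, 40.0),
            ("B", 5.5, 0.5, 30.0), ("B", 7.0, 0.5, 30.0),
        ]
        res = integ.compute_isi(summary_frame(rows)).set_index("accession_id")
        assert res.loc["A", "stability"] == pytest.approx(1 / 1.2)
        assert res.loc["B", "stability"] == pytest.approx(1.0)
        assert res.loc["A", "isi"] == pytest.approx(2 / 3)
        assert res.loc["B", "isi"] == pytest.approx(1 / 3)
        assert res.loc["A", "rank"] == 1 and res.loc["B", "rank"] == 2

    def test_equal_establishment_gives_unit_stability(self):
        rows = [("A", 5.5, 0.4, 35.0), ("A", 7.0, 0.4, 20.0), ("B", 5.5, 0.1, 10.0), ("B", 7.0, 0.6, 22.0)]
        res = integ.compute_isi(summary_frame(rows)).set_index("accession_id")
        assert res.loc["A", "stability"] == pytest.approx(1.0)

    def test_all_components_maximal_gives_isi_one(self):
        rows = [
            ("A", 5.5, 0.9, 45.0), ("A", 7.0, 0.9, 45.0),
            ("B", 5.5, 0.2, 25.0), ("B", 7.0, 0.6, 30.0),
        ]
        res = integ.compute_isi(summary_frame(rows)).set_index("accession_id")
        assert res.loc["A", "isi"] == pytest.approx(1.0)

    def test_isi_bounds_and_rank_permutation(self, growth_records):
        from lupinest.growth_ph import filter_valid, ph_summary

        valid, _ = filter_valid(growth_records)
        res = integ.compute_isi(ph_summary(valid))
        assert ((res["isi"] >= 0) & (res["isi"] <= 1)).all()
        assert ((res["stability"] > 0.5) & (res["stability"] <= 1)).all()
        assert sorted(res["rank"]) == list(range(1, len(res) + 1))

    def test_invariant_to_affine_rescaling_of_component(self):
        rows = [("A", 5.5, 0.6, 40.0), ("A", 7.0, 0.8, 44.0), ("B", 5.5, 0.5, 30.0), ("B", 7.0, 0.5, 36.0), ("C", 5.5, 0.2, 20.0), ("C", 7.0, 0.4, 28.0)]
        base = integ.compute_isi(summary_frame(rows))
        scaled = summary_frame([(a, p, e, 3.0 * t + 7.0) for a, p, e, t in rows])
        after = integ.compute_isi(scaled)
        np.testing.assert_allclose(base["isi"], after["isi"], atol=1e-12)

    def test_monotone_in_single_component(self):
        rows = [("A", 5.5, 0.6, 40.0), ("A", 7.0, 0.8, 44.0), ("B", 5.5, 0.5, 30.0), ("B", 7.0, 0.5, 36.0), ("C", 5.5, 0.2, 20.0), ("C", 7.0, 0.4, 28.0)]
        base = integ.compute_isi(summary_frame(rows)).set_index("accession_id")
        bumped = summary_frame([(a, p, e, t + (5.0 if a == "B" else 0.0)) for a, p, e, t in rows])
        after = integ.compute_isi(bumped).set_index("accession_id")
        assert after.loc["B", "isi"] >= base.loc["B", "isi"] - 1e-12

    def test_constant_component_contributes_neutrally(self):
        rows = [("A", 5.5, 0.6, 40.0), ("A", 7.0, 0.6, 40.0), ("B", 5.5, 0.3, 30.0), ("B", 7.0, 0.3, 30.0)]
        res = integ.compute_isi(summary_frame(rows)).set_index("accession_id")
        # stability is 1 for both -> min-max degenerate -> neutral 0.5
        assert (res["norm_stability"] == 0.5).all()

    def test_accession_missing_a_ph_level_excluded_with_warning(self):
        rows = [("A", 5.5, 0.6, 40.0), ("A", 7.0, 0.8, 44.0), ("B", 5.5, 0.5, 30.0)]
        with pytest.warns(UserWarning, match="excluding"):
            res = integ.compute_isi(summary_frame(rows))
        assert list(res["accession_id"]) == ["A"]


class TestRecommendations:
    @staticmethod
    def matrix(values: dict, soil="MEC"):
        return pd.DataFrame({soil: pd.Series(values)})

    def test_identical_rankings_all_overlap(self):
        vals = {f"A{i}": 90.0 - i for i in range(6)}
        perf = pd.Series(vals)
        res = integ.recommend_accessions(self.matrix(vals), perf, "MEC", top_n=3)
        assert list(res["source"]) == ["overlap"] * 3
        assert list(res["accession_id"]) == ["A0", "A1", "A2"]

    def test_disjoint_top_sets_all_fill(self):
        soil_vals = {f"A{i}": 90.0 - i for i in range(6)}
        perf = pd.Series({f"A{i}": float(i) for i in range(6)})  # reversed ranking
        res = integ.recommend_accessions(self.matrix(soil_vals), perf, "MEC", top_n=3)
        assert list(res["source"]) == ["fill"] * 3
        assert list(res["accession_id"]) == ["A0", "A1", "A2"]  # soil order

    def test_half_overlap_hand_traced(self):
        # soil ranking: A,B,C,D,E; performance top-3: {A, C, E}
        soil_vals = {"A": 95.0, "B": 90.0, "C": 85.0, "D": 80.0, "E": 75.0}
        perf = pd.Series({"A": 0.9, "C": 0.8, "E": 0.7, "B": 0.2, "D": 0.1})
        res = integ.recommend_accessions(self.matrix(soil_vals), perf, "MEC", top_n=3)
        # overlap of the two top-3 sets = {A, C}, soil-ordered; fill with next soil-ranked = B
        assert list(res["accession_id"]) == ["A", "C", "B"]
        assert list(res["source"]) == ["overlap", "overlap", "fill"]

    def test_unknown_soil_and_empty_table_rejected(self):
        mat = self.matrix({"A": 50.0})
        with pytest.raises(ValueError, match="not in matrix"):
            integ.recommend_accessions(mat, pd.Series({"A": 1.0}), "BV")
        with pytest.raises(ValueError, match="empty"):
            integ.recommend_accessions(mat, pd.Series(dtype=float), "MEC")
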