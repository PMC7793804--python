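import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from oracles import pearson_sum_formula
from sctfscreen import DataError, NoTFContrastError
from sctfscreen.preprocess import NormalizedMatrix, log_normalize
from sctfscreen.target_screen import (
    ClusterProfile,
    call_targets,
    cluster_profiles,
    correlation_screen,
    default_candidate_pool,
    extreme_clusters,
)


class FakeClusters:
    def __init__(self, labels):
        self.labels = np.asarray(labels)


def _profile(rows, gene_ids=None):
    means = np.asarray(rows, dtype=float)
    if gene_ids is None:
        gene_ids = [f"G{i:03d}" for i in range(means.shape[0])]
    return ClusterProfile(means, list(gene_ids), np.ones(means.shape[1], dtype=int))


def _corr_frame(entries):
    return pd.DataFrame(
        entries,
        columns=["gene_id", "r", "r_squared", "n_clusters", "pass", "fail_reason"],
    )


class TestClusterProfiles:
    def test_single_cluster_equals_grand_mean(self, matrix_factory):
        rng = np.random.default_rng(60)
        m = matrix_factory(rng.poisson(3, size=(30, 8)) + 1)
        nm = log_normalize(m)
        prof = cluster_profiles(nm, FakeClusters([0] * 30))
        np.testing.assert_allclose(
            prof.means[:, 0], np.asarray(nm.values.mean(axis=0)).ravel()
        )

    def test_singleton_cluster_equals_cell_vector(self, matrix_factory):
        rng = np.random.default_rng(61)
        m = matrix_factory(rng.poisson(3, size=(5, 6)) + 1)
        nm = log_normalize(m)
        prof = cluster_profiles(nm, FakeClusters([0, 0, 0, 0, 1]))
        np.testing.assert_allclose(prof.means[:, 1], nm.values.toarray()[4])

    def test_matches_brute_force_loops(self, matrix_factory):
        rng = np.random.default_rng(62)
        m = matrix_factory(rng.poisson(2, size=(50, 10)) + 1)
        nm = log_normalize(m)
        labels = rng.integers(0, 3, size=50)
        prof = cluster_profiles(nm, FakeClusters(labels))
        dense = nm.values.toarray()
        for c in range(3):
            for g in range(10):
                assert prof.means[g, c] == pytest.approx(
                    dense[labels == c, g].mean(), rel=1e-12
                )


class TestExtremeClusters:
    def test_simple_argmin_argmax(self):
        prof = _profile([[0.1, 5.0, 2.0]], ["TF"])
        assert extreme_clusters(prof, "TF") == (0, 1)

    def test_tie_breaks_to_lowest_label(self):
        prof = _profile([[3.0, 3.0, 1.0]], ["TF"])
        assert extreme_clusters(prof, "TF") == (2, 0)

    def test_constant_profile_is_premise_error(self):
        prof = _profile([[2.0, 2.0, 2.0]], ["TF"])
        with pytest.raises(NoTFContrastError):
            extreme_clusters(prof, "TF")

    def test_needs_two_clusters(self):
        prof = ClusterProfile(np.array([[1.0]]), ["TF"], np.array([3]))
        with pytest.raises(DataError):
            extreme_clusters(prof, "TF")

    def test_invariant_under_consistent_relabeling(self):
        row = np.array([0.5, 4.0, 1.0, 2.5])
        prof = _profile([row], ["TF"])
        lo, hi = extreme_clusters(prof, "TF")
        perm = np.array([2, 0, 3, 1])  # new order of columns
        prof2 = _profile([row[perm]], ["TF"])
        lo2, hi2 = extreme_clusters(prof2, "TF")
        assert row[perm][lo2] == row[lo] and row[perm][hi2] == row[hi]


class TestCorrelationScreen:
    def test_proportional_profile_passes_with_r_one(self):
        tf = np.array([1.0, 2.0, 3.0, 4.0])
        prof = _profile([tf, 2.5 * tf], ["TF", "G000"])
        rec = correlation_screen(prof, "TF", ["G000"])
        assert rec.iloc[0]["pass"]
        assert rec.iloc[0]["r"] == pytest.approx(1.0)

    def test_anticorrelated_fails_under_positive_requirement(self):
        tf = np.array([1.0, 2.0, 3.0, 4.0])
        prof = _profile([tf, 10 - tf], ["TF", "G000"])
        rec = correlation_screen(prof, "TF", ["G000"])
        assert not rec.iloc[0]["pass"]
        assert rec.iloc[0]["fail_reason"] == "negative_r"
        assert rec.iloc[0]["r_squared"] == pytest.approx(1.0)
        # sign-blind mode admits it
        rec2 = correlation_screen(prof, "TF", ["G000"], require_positive=False)
        assert rec2.iloc[0]["pass"]

    def test_toy_vectors_match_closed_form(self):
        tf = [1.0, 2.0, 3.0, 4.0]
        cand = [1.1, 1.9, 3.2, 3.8]
        prof = _profile([tf, cand], ["TF", "G000"])
        rec = correlation_screen(prof, "TF", ["G000"])
        assert rec.iloc[0]["r"] == pytest.approx(
            pearson_sum_formula(tf, cand), abs=1e-12
        )

    def test_random_profiles_match_closed_form(self):
        rng = np.random.default_rng(63)
        tf = rng.random(13)
        cands = rng.random((40, 13))
        prof = _profile(np.vstack([tf, cands]), ["TF"] + [f"G{i:03d}" for i in range(40)])
        rec = correlation_screen(prof, "TF", [f"G{i:03d}" for i in range(40)])
        for i in range(40):
            assert rec.iloc[i]["r"] == pytest.approx(
                pearson_sum_formula(tf, cands[i]), abs=1e-12
            )

    def test_degenerate_candidate_recorded_as_missing(self):
        tf = np.array([1.0, 2.0, 3.0])
        prof = _profile([tf, [5.0, 5.0, 5.0]], ["TF", "G000"])
        rec = correlation_screen(prof, "TF", ["G000"])
        assert not rec.iloc[0]["pass"]
        assert rec.iloc[0]["fail_reason"] == "degenerate"
        assert np.isnan(rec.iloc[0]["r"])

    def test_constant_tf_is_premise_error(self):
        prof = _profile([[1.0, 1.0, 1.0], [1, 2, 3]], ["TF", "G000"])
        with pytest.raises(NoTFContrastError):
            correlation_screen(prof, "TF", ["G000"])

    def test_needs_three_clusters(self):
        prof = _profile([[1.0, 2.0], [1, 2]], ["TF", "G000"])
        with pytest.raises(DataError):
            correlation_screen(prof, "TF", ["G000"])

    def test_invariant_under_positive_affine_transform(self):
        rng = np.random.default_rng(64)
        tf = rng.random(8)
        cand = rng.random(8)
        base = _profile([tf, cand], ["TF", "G000"])
        scaled = _profile([tf, 3.7 * cand + 0.9], ["TF", "G000"])
        r1 = correlation_screen(base, "TF", ["G000"]).iloc[0]["r"]
        r2 = correlation_screen(scaled, "TF", ["G000"]).iloc[0]["r"]
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestCandidatePool:
    def _nm(self, counts):
        values = np.log1p(np.asarray(counts, dtype=float))
        return NormalizedMatrix(
            sparse.csr_matrix(values),
            1e4,
            [f"BC{i}" for i in range(len(counts))],
            [f"G{j:03d}" for j in range(len(counts[0]))],
        )

    def test_prevalence_rules(self):
        n = 1000
        counts = np.zeros((n, 3), dtype=float)
        counts[:, 0] = 1  # everywhere -> in
        counts[0, 1] = 1  # 1 cell of 1000 -> out
        counts[: n // 2, 2] = 1  # 50% -> in
        nm = self._nm(counts)
        pool = default_candidate_pool(nm, tf_gene="G002")
        assert "G000" in pool
        assert "G001" not in pool
        assert "G002" not in pool  # the TF is always excluded

    def test_matches_brute_force_prevalence(self):
        rng = np.random.default_rng(65)
        counts = (rng.random((200, 30)) < 0.15).astype(float)
        nm = self._nm(counts)
        pool = set(default_candidate_pool(nm, tf_gene="G000", min_cells_frac=0.10))
        expected = {
            f"G{j:03d}"
            for j in range(30)
            if (counts[:, j] > 0).mean() > 0.10 and j != 0
        }
        assert pool == expected

    def test_empty_pool_is_error(self):
        counts = np.zeros((50, 2))
        counts[0, 0] = 1
        counts[1, 1] = 1
        nm = self._nm(counts)
        with pytest.raises(DataError):
            default_candidate_pool(nm, tf_gene="G000")


class TestCallTargets:
    def test_set_intersection_with_evidence_rows(self):
        corr = _corr_frame(
            [
                ("A", 0.95, 0.9, 13, True, "none"),
                ("B", 0.92, 0.85, 13, True, "none"),
                ("C", 0.9, 0.81, 13, True, "none"),
                ("E", 0.2, 0.04, 13, False, "low_r2"),
            ]
        )
        strong = pd.DataFrame(
            {"gene_id": ["B", "C", "D"], "fold_change": [3.0, 2.5, 2.2],
             "fdr": [1e-5, 1e-4, 1e-3]}
        )
        calls = call_targets(corr, strong, tf_gene="TF")
        called = set(calls.loc[calls["final_call"], "gene_id"])
        assert called == {"B", "C"}
        assert set(calls["gene_id"]) == {"A", "B", "C", "D", "E"}
        assert not calls.set_index("gene_id").loc["A", "final_call"]
        assert not calls.set_index("gene_id").loc["D", "final_call"]

    def test_disjoint_sets_give_no_calls_but_evidence(self):
        corr = _corr_frame([("A", 0.95, 0.9, 13, True, "none")])
        strong = pd.DataFrame(
            {"gene_id": ["B"], "fold_change": [2.5], "fdr": [1e-4]}
        )
        calls = call_targets(corr, strong, tf_gene="TF")
        assert calls["final_call"].sum() == 0
        assert len(calls) == 2

    def test_tf_never_called(self):
        corr = _corr_frame([("TF", 1.0, 1.0, 13, True, "none")])
        strong = pd.DataFrame(
            {"gene_id": ["TF"], "fold_change": [9.0], "fdr": [1e-30]}
        )
        calls = call_targets(corr, strong, tf_gene="TF")
        assert calls["final_call"].sum() == 0

    def test_adding_irrelevant_gene_never_changes_calls(self):
        corr = _corr_frame(
            [("A", 0.95, 0.9, 13, True, "none"), ("B", 0.1, 0.01, 13, False, "low_r2")]
        )
        strong = pd.DataFrame({"gene_id": ["A"], "fold_change": [2.4], "fdr": [1e-4]})
        before = call_targets(corr, strong, tf_gene="TF")
        corr2 = pd.concat(
            [corr, _corr_frame([("Z", np.nan, np.nan, 13, False, "degenerate")])],
            ignore_index=True,
        )
        after = call_targets(corr2, strong, tf_gene="TF")
        merged = before.merge(after, on="gene_id", suffixes=("_a", "_b"))
        assert (merged["final_call_a"] == merged["final_call_b"]).all()

    def test_sorted_by_descending_r_squared(self):
        corr = _corr_frame(
            [
                ("B", 0.9, 0.81, 13, True, "none"),
                ("A", 0.95, 0.9025, 13, True, "none"),
            ]
        )
        strong = pd.DataFrame(
            {"gene_id": ["A", "B"], "fold_change": [2.1, 2.2], "fdr": [1e-3, 1e-3]}
        )
        calls = call_targets(corr, strong, tf_gene="TF")
        assert calls["gene_id"].tolist() == ["A", "B"]
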