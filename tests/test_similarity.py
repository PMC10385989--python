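"""Clustering, PCA and biological-emulation screening of system coefficients."""

import numpy as np
import pytest

from pampa_lfer import (
    SystemCoefficients,
    compare_to_biological,
    dprime,
    dprime_matrix,
    hierarchical_cluster,
    pca_coefficients,
    radial_plot_data,
)

# published PC1 loading magnitudes over (e, s, a, b, v)
PC1_MAGNITUDES = (0.020, 0.233, 0.466, 0.504, 0.688)


class TestHierarchicalCluster:
    def test_skin_systems_merge_first_below_one(self, pampa_systems, systems_by_id):
        tree = hierarchical_cluster(dprime_matrix(pampa_systems))
        merges = tree.merges()
        assert merges[0][0] == frozenset({"1", "2"})
        assert merges[0][1] < 1.0
        assert merges[0][1] == pytest.approx(
            dprime(systems_by_id["1"], systems_by_id["2"])
        )

    def test_hexadecane_dodecane_pair_is_second_cluster(self, pampa_systems):
        merges = hierarchical_cluster(dprime_matrix(pampa_systems)).merges()
        assert merges[1][0] == frozenset({"4", "5"})

    def test_lecithin_pair_clusters_next(self, pampa_systems):
        # systems 6 and 7 share the same membrane; they join at D' ~ 1.5
        merges = hierarchical_cluster(dprime_matrix(pampa_systems)).merges()
        assert merges[2][0] == frozenset({"6", "7"})
        assert 1.0 < merges[2][1] < 2.0

    def test_two_leaf_tree_merges_at_their_distance(self, systems_by_id):
        pair = [systems_by_id["1"], systems_by_id["3"]]
        tree = hierarchical_cluster(dprime_matrix(pair))
        assert tree.height == pytest.approx(dprime(*pair))
        assert sorted(tree.leaves()) == ["1", "3"]

    def test_upgma_heights_non_decreasing(self, pampa_systems):
        merges = hierarchical_cluster(dprime_matrix(pampa_systems)).merges()
        heights = [h for _, h in merges]
        assert heights == sorted(heights)

    def test_leaf_set_equals_input_ids(self, pampa_systems):
        tree = hierarchical_cluster(dprime_matrix(pampa_systems))
        assert sorted(tree.leaves()) == sorted(s.system_id for s in pampa_systems)

    def test_ultrametric_property(self, pampa_systems):
        """UPGMA cophenetic distances satisfy the ultrametric inequality."""
        from itertools import combinations

        tree = hierarchical_cluster(dprime_matrix(pampa_systems))
        merges = tree.merges()

        def coph(i, j):
            return min(h for leaves, h in merges if {i, j} <= leaves)

        ids = [s.system_id for s in pampa_systems]
        for i, j, k in combinations(ids, 3):
            assert coph(i, k) <= max(coph(i, j), coph(j, k)) + 1e-12

    def test_newick_round_trips_leaf_set(self, pampa_systems):
        import io as _io

        from Bio import Phylo

        tree = hierarchical_cluster(dprime_matrix(pampa_systems))
        parsed = Phylo.read(_io.StringIO(tree.to_newick()), "newick")
        names = sorted(t.name for t in parsed.get_terminals())
        assert names == sorted(s.system_id for s in pampa_systems)

    def test_unknown_linkage_rejected(self, pampa_systems):
        with pytest.raises(ValueError, match="linkage"):
            hierarchical_cluster(dprime_matrix(pampa_systems), linkage="ward")


class TestPca:
    def test_two_components_explain_printed_share(self, pampa_systems):
        res = pca_coefficients(pampa_systems, k=2)
        total = res.explained_variance_fraction.sum()
        # prints as 95% of total variance
        assert round(100 * total) >= 95

    def test_pc1_loading_magnitudes_match_published(self, pampa_systems):
        res = pca_coefficients(pampa_systems, k=2)
        for got, expected in zip(np.abs(res.loadings[0]), PC1_MAGNITUDES):
            assert abs(got - expected) < 0.05

    def test_loadings_orthonormal(self, pampa_systems):
        res = pca_coefficients(pampa_systems, k=5)
        gram = res.loadings @ res.loadings.T
        assert np.allclose(gram, np.eye(5), atol=1e-10)

    def test_full_rank_reconstruction_and_unit_sum(self, pampa_systems):
        res = pca_coefficients(pampa_systems, k=5)
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0)
        X = np.stack([s.vector() for s in pampa_systems])
        Xc = X - X.mean(axis=0)
        assert np.allclose(res.scores @ res.loadings, Xc, atol=1e-10)

    def test_fractions_non_increasing(self, pampa_systems):
        res = pca_coefficients(pampa_systems, k=5)
        f = res.explained_variance_fraction
        assert all(f[i] >= f[i + 1] - 1e-12 for i in range(len(f) - 1))

    def test_row_order_invariance_up_to_sign(self, pampa_systems):
        a = pca_coefficients(pampa_systems, k=2)
        b = pca_coefficients(list(reversed(pampa_systems)), k=2)
        assert np.allclose(np.abs(a.loadings), np.abs(b.loadings), atol=1e-10)
        assert np.allclose(
            a.explained_variance_fraction, b.explained_variance_fraction
        )

    def test_matches_sklearn_oracle(self, pampa_systems):
        from sklearn.decomposition import PCA

        res = pca_coefficients(pampa_systems, k=2)
        X = np.stack([s.vector() for s in pampa_systems])
        ref = PCA(n_components=2).fit(X)
        assert np.allclose(
            np.abs(res.loadings), np.abs(ref.components_), atol=1e-10
        )
        assert np.allclose(
            res.explained_variance_fraction,
            ref.explained_variance_ratio_,
            atol=1e-10,
        )

    def test_single_axis_variation(self):
        systems = [
            SystemCoefficients(system_id=f"s{i}", e=0.1, s=-0.5, a=-1.0,
                               b=-2.0, v=float(i))
            for i in range(4)
        ]
        res = pca_coefficients(systems, k=1)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)
        assert np.allclose(np.abs(res.loadings[0]), [0, 0, 0, 0, 1], atol=1e-12)

    def test_sign_convention_largest_loading_positive(self, pampa_systems):
        res = pca_coefficients(pampa_systems, k=5)
        for row in res.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_too_few_systems_rejected(self, systems_by_id):
        with pytest.raises(ValueError, match="at least 3"):
            pca_coefficients([systems_by_id["1"], systems_by_id["2"]])


class TestCompareToBiological:
    EXPECTED_FLAGS = {("10", "1"), ("10", "2"), ("11", "2"), ("14", "1"), ("14", "2")}

    def test_flagged_pairs_match_published_bold_cells(
        self, pampa_systems, biological_systems
    ):
        """Exactly the five published D' <= 1 pairs are flagged: both skin
        membranes against skin permeation and brain perfusion, plus the
        IPM membrane against the water-skin partition."""
        kept = [s for s in pampa_systems if s.system_id != "9"]
        entries = compare_to_biological(kept, biological_systems, threshold=1.0)
        flagged = {(e.biological_id, e.pampa_id) for e in entries if e.emulates}
        assert flagged == self.EXPECTED_FLAGS

    def test_zero_threshold_flags_nothing(self, pampa_systems, biological_systems):
        entries = compare_to_biological(pampa_systems, biological_systems, 0.0)
        assert not any(e.emulates for e in entries)

    def test_infinite_threshold_flags_everything(
        self, pampa_systems, biological_systems
    ):
        entries = compare_to_biological(
            pampa_systems, biological_systems, float("inf")
        )
        assert all(e.emulates for e in entries)

    def test_consistent_with_distance_matrix(
        self, pampa_systems, biological_systems, reference_systems
    ):
        m = dprime_matrix(reference_systems)
        entries = compare_to_biological(pampa_systems, biological_systems)
        for e in entries:
            assert e.dprime == pytest.approx(m.get(e.biological_id, e.pampa_id))

    def test_empty_list_rejected(self, pampa_systems):
        with pytest.raises(ValueError, match="non-empty"):
            compare_to_biological(pampa_systems, [])


class TestRadialPlotData:
    def test_identity_pass_through(self, pampa_systems):
        df = radial_plot_data(pampa_systems)
        assert list(df.columns) == ["e", "s", "a", "b", "v"]
        for s in pampa_systems:
            assert np.allclose(df.loc[s.system_id].to_numpy(), s.vector())

    def test_axis_order_stable_across_calls(self, pampa_systems):
        a = radial_plot_data(pampa_systems)
        b = radial_plot_data(list(reversed(pampa_systems)))
        assert list(a.columns) == list(b.columns)

    def test_hexadecane_p16_has_smallest_hydrophobicity(self, pampa_systems):
        df = radial_plot_data(pampa_systems)
        assert df["v"].abs().idxmin() == "9"
        assert df.loc["9", "v"] == pytest.approx(0.194)
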