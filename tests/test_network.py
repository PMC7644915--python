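"""Correlation networks: profiles, pcc, thresholding, fragmentation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transgressnet import (
    UsageError,
    build_network,
    compare_networks,
    fragmentation_metrics,
    pcc,
    temporal_profiles,
)
from transgressnet.network import CoexpressionNetwork, Edge


def direct_pearson(x, y):
    """Independent oracle: the textbook product-moment formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = np.sqrt(n * np.sum(x * x) - np.sum(x) ** 2) * np.sqrt(
        n * np.sum(y * y) - np.sum(y) ** 2
    )
    return num / den


class TestTemporalProfiles:
    def test_control_zero_prefix(self, default_run):
        genes = default_run.dataset.truth.module_genes[:3]
        with_zero = temporal_profiles(default_run.tensor, genes, "FL510")
        without = temporal_profiles(
            default_run.tensor, genes, "FL510", include_control_zero=False
        )
        assert with_zero.shape[1] == without.shape[1] + 1
        assert (with_zero.iloc[:, 0] == 0.0).all()
        np.testing.assert_allclose(
            with_zero.iloc[:, 1:].to_numpy(), without.to_numpy()
        )

    def test_order_preserved(self, default_run):
        genes = list(reversed(default_run.dataset.truth.module_genes))
        profiles = temporal_profiles(default_run.tensor, genes, "FL510")
        assert list(profiles.index) == genes

    def test_absent_gene_listed(self, default_run):
        with pytest.raises(UsageError, match="ghost"):
            temporal_profiles(default_run.tensor, ["ghost"], "FL510")


class TestPcc:
    def test_identity_and_negation(self):
        x = [0.0, 1, 2, 3, 4]
        assert pcc(x, x) == pytest.approx(1.0, abs=1e-12)
        assert pcc(x, [-v for v in x]) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula(self):
        x, y = [0.0, 1, 2, 3, 4], [0.0, 1, 2, 3, 6]
        assert pcc(x, y) == pytest.approx(direct_pearson(x, y), abs=1e-12)

    def test_thousand_random_pairs_against_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            x, y = rng.normal(size=(2, n))
            assert pcc(x, y) == pytest.approx(direct_pearson(x, y), abs=1e-12)

    def test_zero_variance_flagged_missing(self):
        assert np.isnan(pcc([1.0, 1, 1], [0.0, 1, 2]))

    def test_short_profile_rejected(self):
        with pytest.raises(UsageError):
            pcc([1.0, 2], [3.0, 4])

    @given(
        st.lists(st.floats(-10, 10), min_size=4, max_size=8),
        st.floats(0.1, 5),
        st.floats(-3, 3),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_affine_invariance(self, x, a, b):
        rng = np.random.default_rng(15)
        y = rng.normal(size=len(x))
        r0 = pcc(x, y)
        if np.isnan(r0):
            return
        r_pos = pcc([a * v + b for v in x], y)
        r_neg = pcc([-a * v + b for v in x], y)
        assert r_pos == pytest.approx(r0, abs=1e-9)
        assert r_neg == pytest.approx(-r0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(16)
        for _ in range(50):
            x, y = rng.normal(size=(2, 5))
            assert pcc(x, y) == pcc(y, x)


class TestBuildNetwork:
    def test_identical_profiles_complete_positive_triangle(self):
        profiles = pd.DataFrame(
            [[0, 1, 2, 3, 4]] * 3, index=["a", "b", "c"], dtype=float
        )
        net = build_network(profiles, 0.95, -0.95)
        assert len(net.edges) == 3
        assert all(e.sign == "positive" and e.r == pytest.approx(1.0) for e in net.edges)

    def test_threshold_is_inclusive(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=6)
        y = 0.8 * (x - x.mean()) + rng.normal(scale=0.5, size=6)
        profiles = pd.DataFrame([x, y], index=["a", "b"])
        r = float(np.corrcoef(profiles.to_numpy())[0, 1])
        at = build_network(profiles, pos_threshold=r, neg_threshold=-0.99)
        above = build_network(profiles, pos_threshold=np.nextafter(r, 1), neg_threshold=-0.99)
        assert len(at.edges) == 1  # r >= threshold, "at least" is inclusive
        assert len(above.edges) == 0

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(18)
        profiles = pd.DataFrame(
            rng.normal(size=(30, 5)), index=[f"g{i:02d}" for i in range(30)]
        )
        net = build_network(profiles, 0.6, -0.6)
        expected = set()
        for i in range(30):
            for j in range(i + 1, 30):
                r = direct_pearson(profiles.iloc[i], profiles.iloc[j])
                if r >= 0.6 or r <= -0.6:
                    a, b = sorted((profiles.index[i], profiles.index[j]))
                    expected.add((a, b, "positive" if r > 0 else "negative"))
        assert {(e.gene_a, e.gene_b, e.sign) for e in net.edges} == expected

    def test_gene_order_permutation_invariant(self):
        rng = np.random.default_rng(19)
        profiles = pd.DataFrame(
            rng.normal(size=(12, 5)), index=[f"g{i:02d}" for i in range(12)]
        )
        net1 = build_network(profiles, 0.7, -0.7)
        shuffled = profiles.sample(frac=1, random_state=1)
        net2 = build_network(shuffled, 0.7, -0.7)
        key = lambda n: {(e.gene_a, e.gene_b, round(e.r, 10)) for e in n.edges}
        assert key(net1) == key(net2)

    def test_isolated_nodes_kept(self):
        profiles = pd.DataFrame(
            [[0, 1, 2, 3, 4], [4, 1, 0, 3, 1], [0, 2, 4, 6, 8]],
            index=["a", "b", "c"], dtype=float,
        )
        net = build_network(profiles, 0.99, -0.99)
        assert set(net.nodes) == {"a", "b", "c"}

    def test_invalid_thresholds_rejected(self):
        profiles = pd.DataFrame([[0, 1, 2]], index=["a"], dtype=float)
        with pytest.raises(UsageError):
            build_network(profiles, -0.5, -0.9)


def _manual_network(nodes, edges):
    return CoexpressionNetwork(
        genotype="X", nodes=nodes,
        edges={Edge(a, b, r, "positive" if r > 0 else "negative") for a, b, r in edges},
        pos_threshold=0.9, neg_threshold=-0.9,
    )


class TestFragmentationMetrics:
    def test_complete_positive_graph(self):
        nodes = list("abcde")
        edges = [(x, y, 0.99) for i, x in enumerate(nodes) for y in nodes[i + 1:]]
        report = fragmentation_metrics(_manual_network(nodes, edges))
        assert report.n_components_positive == 1
        assert report.largest_positive_component_fraction == 1.0
        assert report.n_isolated_nodes == 0

    def test_two_cliques_bridged_by_negative_edge(self):
        """Two 3-node positive cliques joined only by one negative edge:
        7 edges total, hand-enumerated."""
        nodes = list("abcdef")
        pos = [("a", "b", 0.99), ("a", "c", 0.99), ("b", "c", 0.99),
               ("d", "e", 0.99), ("d", "f", 0.99), ("e", "f", 0.99)]
        neg = [("c", "d", -0.99)]
        report = fragmentation_metrics(_manual_network(nodes, pos + neg))
        assert report.n_components_positive == 2
        assert report.n_components_all == 1
        assert report.negative_edge_fraction == pytest.approx(1 / 7)
        assert report.largest_positive_component_fraction == pytest.approx(3 / 6)

    def test_edgeless_graph_convention(self):
        nodes = [f"n{i}" for i in range(10)]
        report = fragmentation_metrics(_manual_network(nodes, []))
        assert report.n_isolated_nodes == 10
        assert report.largest_positive_component_fraction == pytest.approx(0.1)
        assert report.negative_edge_fraction == 0.0

    def test_absent_hub_reported_zero(self):
        report = fragmentation_metrics(
            _manual_network(["a", "b"], [("a", "b", 0.95)]), hub_genes=["a", "zz"]
        )
        assert report.hub_degrees == {"a": 1, "zz": 0}


class TestCompareNetworks:
    def test_cohesive_ranks_first(self, default_run):
        truth = default_run.dataset.truth
        top = default_run.module_ranking.iloc[0]["genotype"]
        assert truth.module_regimes[top] == "coherent"

    def test_identical_reports_stable_order(self):
        nodes = ["a", "b"]
        reports = [
            fragmentation_metrics(_manual_network(nodes, [("a", "b", 0.95)]))
            for _ in range(3)
        ]
        for i, r in enumerate(reports):
            r.genotype = f"G{i}"
        table = compare_networks(reports)
        assert list(table["genotype"]) == ["G0", "G1", "G2"]

    def test_single_report_rejected(self):
        report = fragmentation_metrics(_manual_network(["a"], []))
        with pytest.raises(UsageError):
            compare_networks([report])

    def test_duplicate_genotype_rejected(self):
        reports = [fragmentation_metrics(_manual_network(["a"], [])) for _ in range(2)]
        with pytest.raises(UsageError):
            compare_networks(reports)


class TestPlantedDiscrimination:
    def test_coherent_module_is_one_component(self, default_run):
        truth = default_run.dataset.truth
        coherent = [g for g, r in truth.module_regimes.items() if r == "coherent"]
        for g in coherent:
            report = default_run.module_reports[g]
            assert report.largest_positive_component_fraction >= 0.95
            assert report.negative_edge_fraction == 0.0

    def test_fragmented_module_splits_with_negative_edges(self, default_run):
        truth = default_run.dataset.truth
        fragmented = [g for g, r in truth.module_regimes.items() if r == "fragmented"]
        assert fragmented
        for g in fragmented:
            report = default_run.module_reports[g]
            assert report.n_components_positive >= 2
            assert report.negative_edge_fraction > 0.0
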