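import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cervicomp import (
    AbundanceTable,
    CLRMatrix,
    DataError,
    build_network,
    filter_group_taxa,
    group_networks,
    network_metrics,
    spearman_clr,
)
from cervicomp.reference import (
    REFERENCE_NETWORKS,
    hr_hpv_positivity_percent,
    reference_network_inputs,
)


def counts_table(values, genera):
    values = np.asarray(values)
    return AbundanceTable(
        pd.DataFrame(values, index=[f"s{i}" for i in range(values.shape[0])],
                     columns=genera), mode="counts")


class TestFilterGroupTaxa:
    def test_prevalence_boundary_is_inclusive(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 50, size=(10, 1))
        sparse = np.zeros((10, 1), dtype=int)
        sparse[:3, 0] = [4, 9, 2]  # present in exactly 3 of 10 samples
        table = counts_table(np.hstack([base, sparse]), ["common", "boundary"])
        kept = filter_group_taxa(table, table.samples, prevalence_threshold=0.30)
        assert "boundary" in kept

    def test_zero_variance_genus_excluded(self):
        table = counts_table(
            np.column_stack([np.full(6, 7), np.arange(1, 7)]), ["flat", "varying"])
        kept = filter_group_taxa(table, table.samples, prevalence_threshold=0.30)
        assert kept == ["varying"]

    def test_cap_keeps_top_20_by_total_abundance(self):
        rng = np.random.default_rng(1)
        values = rng.integers(1, 100, size=(12, 25))
        genera = [f"g{i:02d}" for i in range(25)]
        table = counts_table(values, genera)
        kept = filter_group_taxa(table, table.samples, prevalence_threshold=0.0)
        assert len(kept) == 20
        totals = table.data.sum()
        assert min(totals[kept]) >= totals.drop(kept).max()

    def test_no_survivor_error(self):
        table = counts_table(np.column_stack([np.full(5, 3)]), ["flat"])
        with pytest.raises(DataError, match="no genus passes"):
            filter_group_taxa(table, table.samples)


class TestSpearman:
    def make_clr(self, values, genera):
        values = np.asarray(values, dtype=float)
        centred = values - values.mean(axis=1, keepdims=True)
        return CLRMatrix(pd.DataFrame(
            centred, index=[f"s{i}" for i in range(values.shape[0])],
            columns=genera))

    def test_monotone_pair_correlates_perfectly(self):
        rng = np.random.default_rng(0)
        a = np.sort(rng.normal(size=8))
        # rows already sum to zero; each column strictly monotone in a
        clr = CLRMatrix(pd.DataFrame(
            np.column_stack([a, 2 * a, -3 * a]),
            index=[f"s{i}" for i in range(8)], columns=["x", "y", "z"]))
        out = spearman_clr(clr)
        rho = out.set_index(["genus1", "genus2"])["rho"]
        assert rho[("x", "y")] == pytest.approx(1.0)
        assert rho[("x", "z")] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(15, 4))
        clr = self.make_clr(values, list("abcd"))
        out = spearman_clr(clr).set_index(["genus1", "genus2"])
        centred = values - values.mean(axis=1, keepdims=True)
        for (g1, g2), row in out.iterrows():
            i, j = "abcd".index(g1), "abcd".index(g2)
            expected = np.corrcoef(stats.rankdata(centred[:, i]),
                                   stats.rankdata(centred[:, j]))[0, 1]
            assert row["rho"] == pytest.approx(expected, abs=1e-12)

    def test_independent_vectors_stay_weak(self):
        rng = np.random.default_rng(3)
        clr = self.make_clr(rng.normal(size=(50, 10)),
                            [f"g{i}" for i in range(10)])
        out = spearman_clr(clr)
        assert (out["rho"].abs() < 0.5).all()

    def test_constant_vector_pairs_excluded(self):
        values = np.column_stack([np.arange(6.0), np.full(6, 2.0), np.arange(6.0)[::-1]])
        clr = self.make_clr(values, ["a", "flat", "c"])
        out = spearman_clr(clr)
        pairs = set(map(tuple, out[["genus1", "genus2"]].to_numpy()))
        assert pairs == {("a", "c")}

    def test_needs_three_samples(self):
        clr = self.make_clr(np.ones((2, 2)) * [[1, 2], [3, 4]], ["a", "b"])
        with pytest.raises(DataError, match="3 samples"):
            spearman_clr(clr)


class TestBuildNetwork:
    def corr(self, rows):
        frame = pd.DataFrame(rows, columns=["genus1", "genus2", "rho", "p_value"])
        frame["q_value"] = frame["p_value"]
        return frame

    def test_no_passing_edges(self):
        corr = self.corr([("a", "b", 0.2, 0.5)])
        net = build_network(corr, 0.6, 0.05, ["a", "b", "c"])
        assert len(net.edges) == 0
        assert net.density == 0.0
        assert net.n_components == 3

    def test_strong_negative_edge_retained_at_ccu_thresholds(self):
        corr = self.corr([("Anaerococcus", "Pseudomonas", -0.85454545, 0.0225)])
        net = build_network(corr, 0.70, 0.05, ["Anaerococcus", "Pseudomonas"])
        assert len(net.edges) == 1
        assert net.edges.loc[0, "rho"] == pytest.approx(-0.85454545)

    def test_threshold_boundary_between_groups(self):
        corr = self.corr([("a", "b", 0.65, 0.001)])
        assert len(build_network(corr, 0.70, 0.05, ["a", "b"]).edges) == 0  # CCU
        assert len(build_network(corr, 0.60, 0.05, ["a", "b"]).edges) == 1  # HSIL

    def test_invalid_thresholds(self):
        with pytest.raises(DataError, match="thresholds"):
            build_network(self.corr([]), 0.0, 0.05, ["a"])


class TestNetworkMetrics:
    def test_complete_graph(self):
        nodes = list("abcde")
        edges = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
        assert network_metrics(nodes, edges) == (5, 10, 1.0, 1)

    @pytest.mark.parametrize("group, density, components", [
        ("Normal", 0.0476, 6), ("LSIL", 0.0286, 12),
        ("HSIL", 0.0444, None), ("CCU", 0.0727, None),
    ])
    def test_reference_networks_reproduced(self, group, density, components):
        """Published per-group node counts and edge lists give the printed
        densities and component counts."""
        nodes, edges = reference_network_inputs(group)
        n, e, dens, comp = network_metrics(
            nodes, edges[["genus1", "genus2"]].itertuples(index=False))
        assert n == REFERENCE_NETWORKS[group]["n_nodes"]
        assert e == len(REFERENCE_NETWORKS[group]["edges"])
        assert dens == pytest.approx(density, abs=5e-5)
        if components is not None:
            assert comp == components

    def test_reference_networks_are_forests(self):
        # acyclic: components + edges == nodes
        for group in REFERENCE_NETWORKS:
            nodes, edges = reference_network_inputs(group)
            n, e, _, comp = network_metrics(
                nodes, edges[["genus1", "genus2"]].itertuples(index=False))
            assert comp + e == n


def test_group_networks_end_to_end(cohort):
    table, meta = cohort
    nets = group_networks(table, meta)
    assert set(nets) == {"Normal", "LSIL", "HSIL", "CCU"}
    for group, net in nets.items():
        assert 1 <= len(net.nodes) <= 20
        possible = len(net.nodes) * (len(net.nodes) - 1) / 2
        expected_density = len(net.edges) / possible if possible else 0.0
        assert net.density == pytest.approx(expected_density)
        assert 1 <= net.n_components <= len(net.nodes)
        if len(net.edges):
            assert (net.edges["q_value"] < 0.05).all()
            graph = net.graph
            assert graph.number_of_nodes() == len(net.nodes)


def test_hr_hpv_contingency_percentages():
    assert hr_hpv_positivity_percent("Normal") == pytest.approx(46.15, abs=0.005)
    assert hr_hpv_positivity_percent("LSIL") == pytest.approx(88.00, abs=0.005)
    assert hr_hpv_positivity_percent("HSIL") == 100.0
    assert hr_hpv_positivity_percent("CCU") == 100.0
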