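import numpy as np
import pytest
from scipy import stats

from sludgeco.network import (
    EdgeRecord,
    clr_transform,
    core_taxa,
    cross_plant_consensus,
    export_graph,
    intersect_methods,
    mb_network,
    network_stats,
    spearman_network,
)
from sludgeco.simulate import GraphSimSpec, simulate_graph_community

from conftest import make_table


def brute_force_spearman(x, y):
    """Independent oracle: mid-rank then Pearson + t-approximation p."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    r = np.corrcoef(rx, ry)[0, 1]
    n = len(x)
    t = r * np.sqrt((n - 2) / max(1e-300, 1 - r**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


class TestSpearman:
    def test_perfect_monotone_pair(self):
        # constant sample totals so closure preserves per-taxon ranks
        a = np.arange(1, 14)
        b = a**2
        c = 1000 - a - b
        t = make_table(np.vstack([a, b, c]))
        edges = spearman_network(t, min_mean_rel=0.0, alpha=0.05)
        pairs = {e.pair: e for e in edges}
        e12 = pairs[frozenset({"OTU_1", "OTU_2"})]
        assert e12.rho == pytest.approx(1.0) and e12.sign == "+"
        e13 = pairs[frozenset({"OTU_1", "OTU_3"})]
        assert e13.rho == pytest.approx(-1.0) and e13.sign == "-"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.integers(1, 100, size=(6, 10)))
        edges = spearman_network(t, min_mean_rel=0.0, alpha=1.0000001)
        rel = (t.counts / t.counts.sum(axis=0)).to_numpy()
        assert len(edges) == 15
        for e in edges:
            i = int(e.taxon_a.split("_")[1]) - 1
            j = int(e.taxon_b.split("_")[1]) - 1
            r, p = brute_force_spearman(rel[i], rel[j])
            assert e.rho == pytest.approx(r, abs=1e-12)
            assert e.p_value == pytest.approx(p, abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        # per-taxon monotone transforms with a filler row keeping sample
        # totals constant, so relative-abundance ranks are preserved
        rng = np.random.default_rng(1)
        arr = rng.integers(1, 50, size=(4, 12))
        with_filler = np.vstack([arr, 5000 - arr.sum(axis=0)])
        trans = arr**2 + 3
        with_filler2 = np.vstack([trans, 50000 - trans.sum(axis=0)])
        keep = {f"OTU_{i}" for i in range(1, 5)}
        e1 = {(e.pair, round(e.rho, 10))
              for e in spearman_network(make_table(with_filler), 0.0, 1.0)
              if e.pair <= keep}
        e2 = {(e.pair, round(e.rho, 10))
              for e in spearman_network(make_table(with_filler2), 0.0, 1.0)
              if e.pair <= keep}
        assert e1 == e2 and len(e1) == 6

    def test_zero_variance_taxon_excluded(self):
        # proportional rows: every relative abundance is constant
        arr = np.vstack([[1, 2, 4], [1, 2, 4], [2, 4, 8]])
        t = make_table(np.hstack([arr, arr]))
        with pytest.warns(UserWarning, match="zero-variance"):
            edges = spearman_network(t, 0.0, 1.0)
        assert edges == []


class TestClr:
    def test_equal_counts_give_zeros(self):
        z = clr_transform(make_table([[4, 4], [4, 4], [4, 4]]))
        assert np.allclose(z.to_numpy(), 0)

    def test_samples_sum_to_zero(self, random_table):
        z = clr_transform(random_table)
        assert np.allclose(z.sum(axis=0), 0, atol=1e-9)

    def test_hand_arithmetic(self):
        z = clr_transform(make_table([[1], [3]]), pseudocount=1)
        # ln2, ln4 centered at (ln2+ln4)/2 -> -/+ ln(2)/2
        assert z.iloc[0, 0] == pytest.approx(-np.log(2) / 2, abs=1e-12)
        assert z.iloc[1, 0] == pytest.approx(np.log(2) / 2, abs=1e-12)
        assert z.iloc[0, 0] == pytest.approx(-0.3466, abs=1e-4)


class TestMb:
    def test_full_shrinkage_gives_empty_graph(self):
        spec = GraphSimSpec(p=12, n_samples=60, graph="chain", seed=0, N=5000)
        table, _ = simulate_graph_community(spec)
        # a path collapsed to its top: lambda_min_ratio ~ 1 keeps only λ_max
        edges = mb_network(table, lambda_path=2, lambda_min_ratio=0.999999,
                           stars_B=5, seed=0)
        assert edges == set()

    def test_edge_set_near_nested_along_path(self):
        from sludgeco.network import _neighborhood_adjacency

        spec = GraphSimSpec(p=15, n_samples=80, graph="chain", seed=2, N=5000)
        table, _ = simulate_graph_community(spec)
        z = clr_transform(table).to_numpy().T
        z = z - z.mean(axis=0, keepdims=True)
        cov = (z.T @ z) / z.shape[0]
        lam_max = np.abs(cov - np.diag(np.diag(cov))).max()
        lams = np.logspace(np.log10(lam_max), np.log10(lam_max * 0.01), 20)
        adj = _neighborhood_adjacency(z, lams)
        counts = adj.sum(axis=(1, 2))
        # counts grow (graph densifies) as λ decreases, near-monotonically
        assert counts[0] <= 2
        assert (np.diff(counts) >= -2).all()
        assert counts[-1] > counts[0]

    def test_recovers_planted_chain(self):
        spec = GraphSimSpec(p=30, n_samples=200, graph="chain", strength=0.3,
                            N=25000, seed=5)
        table, truth = simulate_graph_community(spec)
        est = mb_network(table, seed=5)
        tp = len(est & truth)
        f1 = 2 * tp / (len(est) + len(truth))
        assert f1 >= 0.7

    def test_more_samples_improve_recovery(self):
        f1 = {}
        for n in (50, 200):
            scores = []
            for seed in (0, 1, 2):
                spec = GraphSimSpec(p=20, n_samples=n, graph="chain", strength=0.3,
                                    N=25000, seed=seed)
                table, truth = simulate_graph_community(spec)
                est = mb_network(table, stars_B=25, seed=seed)
                tp = len(est & truth)
                scores.append(2 * tp / max(1, len(est) + len(truth)))
            f1[n] = np.mean(scores)
        assert f1[200] > f1[50]


class TestIntersectAndCore:
    def _edges(self, pairs):
        return [EdgeRecord(a, b, rho=0.9, p_value=0.001) for a, b in pairs]

    def test_set_arithmetic(self):
        sp = self._edges([("A", "B"), ("A", "C"), ("B", "D")])
        mb = {frozenset(p) for p in [("A", "B"), ("B", "D"), ("C", "D")]}
        out = intersect_methods(sp, mb)
        assert {e.pair for e in out} == {frozenset({"A", "B"}), frozenset({"B", "D"})}
        assert all(e.methods == {"spearman", "mb"} for e in out)

    def test_idempotent_on_identical_sets(self):
        sp = self._edges([("A", "B"), ("C", "D")])
        out = intersect_methods(sp, {e.pair for e in sp})
        assert {e.pair for e in out} == {e.pair for e in sp}

    def test_disjoint_universes_error(self):
        with pytest.raises(ValueError, match="no taxa"):
            intersect_methods(self._edges([("A", "B")]), {frozenset({"X", "Y"})})

    def test_core_prevalence_arithmetic(self):
        n = 13
        base = np.full((2, n), 100)  # filler taxon keeps totals constant

        def table_with(presence):
            row = np.where(presence, 200, 0)  # 0.2% of ~100k totals
            filler = 100000 - row - 100 - 100
            return make_table(np.vstack([row, base, filler]),
                              taxa=["target", "f1", "f2", "f3"])

        eleven = np.array([1] * 11 + [0] * 2, dtype=bool)
        assert "target" in core_taxa(table_with(eleven))
        ten = np.array([1] * 10 + [0] * 3, dtype=bool)
        assert "target" not in core_taxa(table_with(ten))

    def test_core_boundary_is_strict(self):
        # exactly 0.1% everywhere -> excluded under strict >
        arr = np.vstack([np.full(13, 1), np.full(13, 999)])
        assert "OTU_1" not in core_taxa(make_table(arr), min_rel=1e-3)


class TestConsensus:
    def _edge(self, a, b, rho=0.8):
        return EdgeRecord(a, b, rho=rho, p_value=0.001, methods=frozenset({"spearman", "mb"}))

    def test_single_plant_edge_dropped(self):
        per_plant = {"ST": [self._edge("A", "B")], "TP": [], "YL": []}
        net = cross_plant_consensus(per_plant, core_sets={"ST": {"A"}}, min_plants=2)
        assert net.edges == []

    def test_guild_endpoint_edge_kept_with_provenance(self):
        e = self._edge("NOB1", "X")
        per_plant = {"ST": [e], "TP": [e], "YL": [e]}
        net = cross_plant_consensus(per_plant, guild_sets={"NOB": {"NOB1"}}, min_plants=2)
        assert len(net.edges) == 1
        assert net.edges[0].plants == {"ST", "TP", "YL"}
        assert net.node_frequency() == {"NOB1": 1, "X": 1}

    def test_sign_agreement_required(self):
        per_plant = {"ST": [self._edge("A", "B", rho=0.8)],
                     "TP": [self._edge("A", "B", rho=-0.8)]}
        net = cross_plant_consensus(per_plant, core_sets={"A"}, min_plants=2)
        assert net.edges == []
        relaxed = cross_plant_consensus(per_plant, core_sets={"A"}, min_plants=2,
                                        require_sign_agreement=False)
        assert len(relaxed.edges) == 1

    def test_no_privileged_endpoint_dropped(self):
        e = self._edge("A", "B")
        net = cross_plant_consensus({"ST": [e], "TP": [e]}, min_plants=2)
        assert net.edges == []


class TestStatsAndExport:
    def test_two_triangles_modularity(self):
        tri1 = [("a", "b"), ("b", "c"), ("a", "c")]
        tri2 = [("x", "y"), ("y", "z"), ("x", "z")]
        edges = [EdgeRecord(u, v, rho=0.5, p_value=0.01) for u, v in tri1 + tri2]
        s = network_stats(edges)
        assert s["n_modules"] == 2
        assert s["modularity"] == pytest.approx(0.5, abs=1e-12)
        assert s["positive_fraction"] == 1.0
        assert s["mean_degree"] == pytest.approx(2.0)

    def test_complete_graph_modularity_near_zero(self):
        nodes = list("abcde")
        edges = [EdgeRecord(u, v, rho=0.5, p_value=0.01)
                 for i, u in enumerate(nodes) for v in nodes[i + 1:]]
        s = network_stats(edges)
        assert abs(s["modularity"]) < 0.1

    def test_empty_graph_stats(self):
        s = network_stats([])
        assert s["n_edges"] == 0 and s["modularity"] is None

    def test_graphml_export_round_trip(self, tmp_path):
        import networkx as nx

        edges = [EdgeRecord("a", "b", rho=-0.7, p_value=0.003,
                            plants=frozenset({"ST", "TP"}))]
        export_graph(edges, tmp_path / "g.graphml")
        g = nx.read_graphml(tmp_path / "g.graphml")
        assert g["a"]["b"]["sign"] == "-"
        assert g["a"]["b"]["plants"] == "ST,TP"
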