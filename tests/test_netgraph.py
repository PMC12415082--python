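import networkx as nx
import numpy as np
import pytest

from bfmgel.lattice import audit
from bfmgel.netgraph import (biggest_molecule_cluster, bmc_metrics,
                             cycle_rank, defect_census, molecule_graph)
from bfmgel.synthetic import fixture_network

PRESETS = ["tree", "single_cycle", "multi_edge_pair", "two_components",
           "mini_gel"]


def gf2_cycle_space_dimension(graph: nx.MultiGraph) -> int:
    """Independent oracle: dimension of the cycle space over GF(2) as
    E - rank(incidence matrix), with parallel edges as separate columns."""
    nodes = {n: i for i, n in enumerate(graph.nodes)}
    edges = list(graph.edges(keys=True))
    if not edges:
        return 0
    m = np.zeros((len(nodes), len(edges)), dtype=np.uint8)
    for col, (u, v, _k) in enumerate(edges):
        if u != v:
            m[nodes[u], col] = 1
            m[nodes[v], col] = 1
    # Gaussian elimination over GF(2)
    rank = 0
    for col in range(m.shape[1]):
        pivots = np.flatnonzero(m[rank:, col]) + rank
        if len(pivots) == 0:
            continue
        p = pivots[0]
        m[[rank, p]] = m[[p, rank]]
        for r in range(m.shape[0]):
            if r != rank and m[r, col]:
                m[r] ^= m[rank]
        rank += 1
        if rank == m.shape[0]:
            break
    return len(edges) - rank


@pytest.mark.parametrize("preset", PRESETS)
class TestFixturePresets:
    def test_state_is_valid(self, preset):
        state, _ = fixture_network(preset)
        audit(state)

    def test_metrics_match_hand_counts(self, preset):
        state, expected = fixture_network(preset)
        g = molecule_graph(state)
        bmc = biggest_molecule_cluster(g)
        m = bmc_metrics(g, bmc, state=state)
        assert bmc.number_of_nodes() == expected["n_nodes_bmc"]
        assert m.n_edges_bmc == expected["n_edges_bmc"]
        assert m.cycle_rank == expected["cycle_rank"]
        assert m.f_hep_bmc == pytest.approx(expected["f_hep_bmc"])
        assert m.defects["multi_edges"] == expected["multi_edges"]
        assert m.defects["dangling_peg_arms"] == \
            expected["dangling_peg_arms"]
        assert (m.defects["unbound_peg"] + m.defects["unbound_hep"]
                == expected["unbound"])

    def test_cycle_rank_agrees_with_gf2_oracle(self, preset):
        state, _ = fixture_network(preset)
        bmc = biggest_molecule_cluster(molecule_graph(state))
        rank, _zeta = cycle_rank(bmc)
        assert rank == gf2_cycle_space_dimension(bmc)

    def test_edge_count_equals_crosslink_count(self, preset):
        state, _ = fixture_network(preset)
        g = molecule_graph(state)
        assert g.number_of_edges() == state.crosslink_count()


class TestCycleRankSmallGraphs:
    def test_parallel_edges(self):
        g = nx.MultiGraph()
        g.add_edge(0, 1)
        g.add_edge(0, 1)
        g.add_edge(0, 1)
        rank, zeta = cycle_rank(g)
        assert rank == 2 == gf2_cycle_space_dimension(g)
        assert zeta == pytest.approx(2 / 3)

    def test_random_connected_multigraphs(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            g = nx.MultiGraph()
            g.add_nodes_from(range(n))
            for k in range(n - 1):        # spanning tree first
                g.add_edge(int(rng.integers(0, k + 1)), k + 1)
            for _e in range(int(rng.integers(0, 7))):
                u, v = rng.integers(0, n, 2)
                if u != v:
                    g.add_edge(int(u), int(v))
            rank, _ = cycle_rank(g)
            assert rank == gf2_cycle_space_dimension(g)

    def test_disconnected_rejected(self):
        g = nx.MultiGraph()
        g.add_nodes_from([0, 1])
        with pytest.raises(ValueError):
            cycle_rank(g)


class TestBiggestCluster:
    def _graph(self, comps):
        g = nx.MultiGraph()
        for nodes, edges in comps:
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
        return g

    def test_largest_by_nodes(self):
        g = self._graph([
            (range(5), [(0, 1), (1, 2), (2, 3), (3, 4)]),
            (range(10, 13), [(10, 11), (11, 12)]),
            (range(20, 21), []),
        ])
        assert set(biggest_molecule_cluster(g).nodes) == set(range(5))

    def test_tie_broken_by_edges(self):
        g = self._graph([
            ((0, 1, 2, 3), [(0, 1), (1, 2), (2, 3)]),
            ((10, 11, 12, 13), [(10, 11), (11, 12), (12, 13), (13, 10)]),
        ])
        assert set(biggest_molecule_cluster(g).nodes) == {10, 11, 12, 13}

    def test_full_tie_broken_by_smallest_id(self):
        g = self._graph([
            ((0, 1), [(0, 1)]),
            ((10, 11), [(10, 11)]),
        ])
        assert set(biggest_molecule_cluster(g).nodes) == {0, 1}

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            biggest_molecule_cluster(nx.MultiGraph())


class TestMetricDefinitions:
    def test_hand_counted_bmc(self):
        # 2 PEG + 2 HEP joined by 4 bonds
        g = nx.MultiGraph()
        g.add_node("p0", species="PEG")
        g.add_node("p1", species="PEG")
        g.add_node("h0", species="HEP")
        g.add_node("h1", species="HEP")
        g.add_edges_from([("p0", "h0"), ("p0", "h1"), ("p1", "h0"),
                          ("p1", "h1")])
        m = bmc_metrics(g)
        assert m.gamma_bmc == pytest.approx(1.0)
        assert m.f_hep_bmc == pytest.approx(2.0)
        assert m.incorporation_peg == 1.0
        assert m.incorporation_hep == 1.0
        assert m.cycle_rank == 1

    def test_bmc_without_heparin_rejected(self):
        g = nx.MultiGraph()
        g.add_node("p0", species="PEG")
        with pytest.raises(ValueError):
            bmc_metrics(g)

    def test_same_species_crosslink_rejected(self):
        state, _ = fixture_network("tree")
        # corrupt one crosslink to join two heparin monomers
        cross = np.flatnonzero(state.bond_kind == 1)
        hep = np.flatnonzero(state.species == 1)
        state.bonds[cross[0]] = [hep[0], hep[1]]
        with pytest.raises(ValueError):
            molecule_graph(state)

    def test_p0_state_all_unbound(self):
        state, _ = fixture_network("two_components")
        state.bonds = state.bonds[state.bond_kind == 0]
        state.bond_kind = state.bond_kind[state.bond_kind == 0]
        g = molecule_graph(state)
        bmc = biggest_molecule_cluster(g)   # a single molecule
        census = defect_census(g, state, bmc)
        assert census["unbound_peg"] + census["unbound_hep"] \
            == state.n_molecules - 1
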