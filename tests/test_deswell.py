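import numpy as np
import pytest

from bfmgel.builders import build_starpeg, starpeg_template
from bfmgel.deswell import (WindingError, aggregate_and_void_stats,
                            deswell_run, extract_bmc, radius_of_gyration,
                            relocate_cluster, select_molecules,
                            unwrap_positions)
from bfmgel.lattice import (BOND_INTRA, EnergyModel, LatticeState,
                            SPECIES_PEG, audit, contact_energy, run_mcs)
from bfmgel.synthetic import fixture_network


def chain_state(positions, box=32, bonds=None):
    n = len(positions)
    if bonds is None:
        bonds = [(i, i + 1) for i in range(n - 1)]
    bonds = np.array(bonds, dtype=np.int32).reshape(-1, 2)
    return LatticeState(
        box_edge=box, positions=np.array(positions, dtype=np.int64),
        species=np.zeros(n, dtype=np.uint8),
        molecule_id=np.zeros(n, dtype=np.int32),
        bonds=bonds, bond_kind=np.zeros(len(bonds), dtype=np.uint8),
        reactive=np.zeros(n, dtype=bool), consumed=np.zeros(n, dtype=bool),
        rigid_species=())


class TestRadiusOfGyration:
    def test_single_point(self):
        assert radius_of_gyration([[3, 4, 5]]) == 0.0

    def test_two_points(self):
        assert radius_of_gyration([[0, 0, 0], [0, 0, 4]]) == pytest.approx(
            2.0)

    def test_collinear_closed_form(self):
        # N equally spaced collinear points: Rg = a sqrt((N^2-1)/12);
        # N=4, a=2 evaluates to sqrt(5)
        pts = [[0, 0, 0], [2, 0, 0], [4, 0, 0], [6, 0, 0]]
        assert radius_of_gyration(pts) == pytest.approx(np.sqrt(5.0))
        for n, a in ((7, 2), (11, 3)):
            pts = [[a * k, 0, 0] for k in range(n)]
            assert radius_of_gyration(pts) == pytest.approx(
                a * np.sqrt((n ** 2 - 1) / 12.0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.empty((0, 3)))


class TestUnwrap:
    def test_chain_across_boundary(self):
        # chain stepping +2 in x through the periodic wall
        pos = [[28, 4, 4], [30, 4, 4], [0, 4, 4], [2, 4, 4]]
        st = chain_state(pos)
        u = unwrap_positions(st)
        assert list(u[:, 0]) == [28, 30, 32, 34]

    def test_winding_ring_detected(self):
        # a ring closed through the periodic boundary has no unwrap
        pos = [[x, 4, 4] for x in range(0, 32, 2)]
        bonds = [(i, i + 1) for i in range(15)] + [(15, 0)]
        st = chain_state(pos, bonds=bonds)
        with pytest.raises(WindingError):
            unwrap_positions(st)

    def test_relocate_non_winding_cluster(self):
        st, _ = fixture_network("multi_edge_pair")
        big = relocate_cluster(st, 80)
        assert big.box_edge == 80
        audit(big)

    def test_relocate_too_small_box_rejected(self):
        st, _ = fixture_network("multi_edge_pair")
        with pytest.raises(ValueError):
            relocate_cluster(st, 12)


class TestExtractBmc:
    def test_keeps_largest_component_only(self):
        st, _ = fixture_network("two_components")
        sub = extract_bmc(st)
        assert sub.n_molecules == 3
        audit(sub)

    def test_selection_must_not_cut_bonds(self):
        st, _ = fixture_network("tree")
        with pytest.raises(ValueError):
            select_molecules(st, [0])   # star without its bonded rods


class TestAggregateVoidStats:
    def test_isolated_monomers_are_singleton_clusters(self):
        pos = [[4, 4, 4], [20, 20, 20], [4, 20, 4]]
        st = chain_state(pos, bonds=[])
        stats = aggregate_and_void_stats(st, n_probes=500, rng=1)
        assert list(stats.peg_cluster_sizes) == [1, 1, 1]

    def test_dumbbell_two_clusters_of_ten(self):
        # two 10-monomer blobs at contact spacing, far apart;
        # brute-force contact adjacency is the construction itself
        blob = [[2 * k, 0, 0] for k in range(10)]
        pos = np.array(blob + [[x + 0, y + 20, z] for x, y, z in blob])
        st = chain_state(pos, box=64, bonds=[])
        energy = EnergyModel(-0.3)
        stats = aggregate_and_void_stats(st, energy, n_probes=500, rng=1)
        assert list(stats.peg_cluster_sizes) == [10, 10]
        # brute-force oracle over all pairs
        shell = {tuple(v) for v in energy.contact_shell.tolist()}
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(range(len(pos)))
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                d = tuple(int(v) for v in
                          np.array(pos[j]) - np.array(pos[i]))
                if d in shell:
                    g.add_edge(i, j)
        sizes = sorted((len(c) for c in nx.connected_components(g)),
                       reverse=True)
        assert sizes == [10, 10]

    def test_empty_box_flagged_with_radius_cap(self):
        st = chain_state(np.empty((0, 3)), bonds=[])
        stats = aggregate_and_void_stats(st, n_probes=100, rng=1)
        assert stats.empty_box
        assert np.all(stats.void_radii == 16.0)   # box 32 -> cap L/2


class TestDeswellRun:
    def test_contact_energy_decreases_under_attraction(self):
        tmpl, coords = build_starpeg(seed=2, box_edge=48)
        n = 117
        st = LatticeState(
            box_edge=48, positions=coords % 48,
            species=np.zeros(n, dtype=np.uint8),
            molecule_id=np.zeros(n, dtype=np.int32),
            bonds=tmpl.intramolecular_bonds,
            bond_kind=np.zeros(len(tmpl.intramolecular_bonds),
                               dtype=np.uint8),
            reactive=np.zeros(n, dtype=bool),
            consumed=np.zeros(n, dtype=bool))
        energy = EnergyModel(-0.30)
        # relax athermally first: the as-grown star is artificially
        # compact, so the meaningful reference is the equilibrated coil
        run_mcs(st, 5_000, rng=7)
        e0 = contact_energy(st, energy)
        st, traj = deswell_run(st, n_mcs=30_000, energy=energy, rng=8)
        e_t = traj["energy_trajectory"][:, 1]
        assert e_t[-3:].mean() < e0
        audit(st)

    def test_single_star_collapses_relative_to_athermal(self):
        # paired seeded runs: same star, attractive vs athermal
        def final_rg(eps, seed):
            tmpl, coords = build_starpeg(seed=seed, box_edge=48)
            n = 117
            st = LatticeState(
                box_edge=48, positions=coords % 48,
                species=np.zeros(n, dtype=np.uint8),
                molecule_id=np.zeros(n, dtype=np.int32),
                bonds=tmpl.intramolecular_bonds,
                bond_kind=np.zeros(len(tmpl.intramolecular_bonds),
                                   dtype=np.uint8),
                reactive=np.zeros(n, dtype=bool),
                consumed=np.zeros(n, dtype=bool))
            energy = EnergyModel(eps) if eps else None
            rng = np.random.default_rng(seed)
            run_mcs(st, 30_000, energy=energy, rng=rng)
            rgs = []
            for _ in range(20):
                run_mcs(st, 2_000, energy=energy, rng=rng)
                rgs.append(radius_of_gyration(unwrap_positions(st)))
            return np.mean(rgs)

        rg_attr = np.mean([final_rg(-0.30, s) for s in (1, 2, 3)])
        rg_ath = np.mean([final_rg(0.0, s) for s in (1, 2, 3)])
        assert rg_attr < rg_ath
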