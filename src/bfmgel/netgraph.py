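"""Molecule-level network graph and gel-quality metrics.

Crosslinks are aggregated to a bipartite multigraph with one node per
molecule (starPEG or heparin) and one edge per crosslink bond, parallel
edges preserved.  The biggest molecule cluster (BMC) -- the largest
connected component -- is the gel-fraction proxy.  Derived metrics follow
network theory: the effective molar ratio gamma_BMC = nPEG,BMC / nHEP,BMC,
the heparin junction functionality f_HEP,BMC (crosslink bonds per heparin
in the BMC), per-species incorporation efficiencies, the cycle rank
E - V + 1 of the connected BMC (the elasticity-relevant connectivity
invariant of the phantom network model), and the census of primitive
defects (dangling starPEG arms, multiple bonds between one star and one
heparin, unbound molecules).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .builders import HEPARIN_MONOMERS, STARPEG_MONOMERS
from .lattice import BOND_CROSSLINK, SPECIES_PEG, LatticeState


@dataclass
class BMCMetrics:
    """Network-quality metrics of the biggest molecule cluster."""

    gamma_bmc: float
    f_hep_bmc: float
    f_hep_bmc_partners: float    # distinct-partner variant of f_HEP,BMC
    incorporation_peg: float
    incorporation_hep: float
    cycle_rank: int
    zeta_per_strand: float
    n_peg_bmc: int
    n_hep_bmc: int
    n_edges_bmc: int
    bmc_mass_fraction: float
    defects: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "gamma_bmc", "f_hep_bmc", "f_hep_bmc_partners",
            "incorporation_peg", "incorporation_hep", "cycle_rank",
            "zeta_per_strand", "n_peg_bmc", "n_hep_bmc", "n_edges_bmc",
            "bmc_mass_fraction")}
        d["defects"] = dict(self.defects)
        return d


def molecule_graph(state: LatticeState) -> nx.MultiGraph:
    """One node per molecule (attribute ``species``), one edge per
    crosslink bond; parallel edges preserved."""
    g = nx.MultiGraph()
    for mid, lo, _hi in state.molecule_ranges():
        sp = int(state.species[lo])
        g.add_node(int(mid), species="PEG" if sp == SPECIES_PEG else "HEP")
    cross = state.bonds[state.bond_kind == BOND_CROSSLINK]
    mid = state.molecule_id
    sp = state.species
    for i, j in cross:
        if sp[i] == sp[j]:
            raise ValueError(
                f"crosslink {i}-{j} joins two {('PEG', 'HEP')[sp[i]]} "
                f"monomers; the chemistry is strictly PEG-HEP")
        g.add_edge(int(mid[i]), int(mid[j]))
    return g


def biggest_molecule_cluster(graph: nx.MultiGraph) -> nx.MultiGraph:
    """Largest connected component; ties broken by edge count, then by the
    smallest contained molecule id (deterministic)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph has no biggest molecule cluster")
    best = None
    best_key = None
    for c in nx.connected_components(graph):
        key = (len(c), graph.subgraph(c).number_of_edges())
        if best is None or key > best_key \
                or (key == best_key and min(c) < min(best)):
            best, best_key = c, key
    return graph.subgraph(best).copy()


def _species_nodes(graph, species):
    return [n for n, d in graph.nodes(data=True) if d["species"] == species]


def cycle_rank(bmc: nx.MultiGraph, strand_count: int | None = None):
    """Cycle rank E - V + 1 of the connected BMC multigraph and the rank
    per elastically active strand (default strand count: crosslink edges)."""
    if bmc.number_of_nodes() and not nx.is_connected(bmc):
        raise ValueError("cycle rank is defined here for the connected BMC")
    rank = bmc.number_of_edges() - bmc.number_of_nodes() + 1
    if strand_count is None:
        strand_count = bmc.number_of_edges()
    zeta = rank / strand_count if strand_count else 0.0
    return rank, zeta


def defect_census(graph: nx.MultiGraph, state: LatticeState,
                  bmc: nx.MultiGraph | None = None) -> dict:
    """Primitive-defect counts.

    dangling_peg_arms: unreacted termini on starPEGs inside the BMC;
    multi_edges: extra bonds beyond the first between one PEG-HEP molecule
    pair; unbound_peg / unbound_hep: molecules outside the BMC.
    """
    if bmc is None:
        bmc = biggest_molecule_cluster(graph)
    bmc_nodes = set(bmc.nodes)
    peg_bmc = [n for n in bmc_nodes
               if graph.nodes[n]["species"] == "PEG"]
    mid = state.molecule_id
    termini = state.reactive & (state.species == SPECIES_PEG)
    dangling = 0
    for n in peg_bmc:
        sel = termini & (mid == n)
        dangling += int(np.sum(sel & ~state.consumed))
    multi = 0
    seen = {}
    for u, v in graph.edges():
        key = (u, v) if u <= v else (v, u)
        seen[key] = seen.get(key, 0) + 1
    multi = sum(c - 1 for c in seen.values() if c > 1)
    unbound_peg = sum(1 for n, d in graph.nodes(data=True)
                      if d["species"] == "PEG" and n not in bmc_nodes)
    unbound_hep = sum(1 for n, d in graph.nodes(data=True)
                      if d["species"] == "HEP" and n not in bmc_nodes)
    return {"dangling_peg_arms": dangling, "multi_edges": multi,
            "unbound_peg": unbound_peg, "unbound_hep": unbound_hep}


def bmc_metrics(graph: nx.MultiGraph, bmc: nx.MultiGraph | None = None,
                state: LatticeState | None = None) -> BMCMetrics:
    """All BMC quality metrics.

    ``state`` is needed for the dangling-arm census; initial molecule
    counts are taken from the full graph (= the reaction mixture).
    """
    if bmc is None:
        bmc = biggest_molecule_cluster(graph)
    if not set(bmc.nodes) <= set(graph.nodes):
        raise ValueError("bmc must be a subgraph of graph")
    n_peg_all = len(_species_nodes(graph, "PEG"))
    n_hep_all = len(_species_nodes(graph, "HEP"))
    n_peg = len(_species_nodes(bmc, "PEG"))
    n_hep = len(_species_nodes(bmc, "HEP"))
    if n_hep == 0:
        raise ValueError("BMC contains no heparin; gamma_BMC undefined")
    edges = bmc.number_of_edges()
    gamma_bmc = n_peg / n_hep
    f_hep = edges / n_hep
    # distinct-partner variant: count each PEG partner once per heparin
    partners = 0
    for n in _species_nodes(bmc, "HEP"):
        partners += len(set(bmc.neighbors(n)))
    f_hep_partners = partners / n_hep
    rank, zeta = cycle_rank(bmc)
    defects = (defect_census(graph, state, bmc) if state is not None
               else {})
    mono_bmc = n_peg * STARPEG_MONOMERS + n_hep * HEPARIN_MONOMERS
    mono_all = n_peg_all * STARPEG_MONOMERS + n_hep_all * HEPARIN_MONOMERS
    return BMCMetrics(
        gamma_bmc=gamma_bmc, f_hep_bmc=f_hep,
        f_hep_bmc_partners=f_hep_partners,
        incorporation_peg=n_peg / n_peg_all if n_peg_all else 0.0,
        incorporation_hep=n_hep / n_hep_all,
        cycle_rank=rank, zeta_per_strand=zeta,
        n_peg_bmc=n_peg, n_hep_bmc=n_hep, n_edges_bmc=edges,
        bmc_mass_fraction=mono_bmc / mono_all if mono_all else 0.0,
        defects=defects)


def write_edge_list(graph: nx.MultiGraph, path) -> None:
    with open(path, "w") as fh:
        for u, v in graph.edges():
            fh.write(f"{u} {v}\n")
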