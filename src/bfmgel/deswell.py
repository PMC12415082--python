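"""Poor-solvent deswelling of the extracted gel cluster.

Dehydration in ethanol is modelled as an attractive contact interaction of
-0.30 k_BT between starPEG monomers, which drives the self-aggregation of
PEG into dense domains while the charged heparin rods stay non-attractive.
The module also provides the collapse observables: radius of gyration of
unwrapped clusters, PEG aggregate statistics under the contact-shell
adjacency, and void sizes measured as largest-empty-sphere radii.

Extraction of the biggest molecule cluster (BMC) keeps only molecules of
the largest connected network component.  By default the collapse runs in
the original periodic box (the gel percolates its box, so it cannot in
general be unwrapped into a larger one); for non-percolating clusters
``relocate_cluster`` re-centres the unwrapped cluster in a larger box as
well.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage

from .lattice import (SPECIES_PEG, EnergyModel, LatticeState,
                      SimContext, contact_energy, min_image, run_mcs,
                      _normalize_rng)
from .netgraph import biggest_molecule_cluster, molecule_graph


class WindingError(ValueError):
    """Cluster wraps around the periodic box; it has no consistent unwrap."""


def select_molecules(state: LatticeState, molecule_ids) -> LatticeState:
    """Sub-state containing only the given molecules (indices remapped,
    same box)."""
    keep_mol = set(int(m) for m in molecule_ids)
    mask = np.isin(state.molecule_id, list(keep_mol))
    idx_map = -np.ones(state.n_monomers, dtype=np.int64)
    idx_map[mask] = np.arange(int(mask.sum()))
    bsel = mask[state.bonds[:, 0]] & mask[state.bonds[:, 1]]
    # a bond between kept and dropped molecules cannot exist: crosslinks
    # only join molecules of one component
    if np.any(mask[state.bonds[:, 0]] != mask[state.bonds[:, 1]]):
        raise ValueError("selection cuts a bond; molecule set is not a "
                         "union of connected components")
    return LatticeState(
        box_edge=state.box_edge,
        positions=state.positions[mask],
        species=state.species[mask],
        molecule_id=state.molecule_id[mask],
        bonds=idx_map[state.bonds[bsel]].astype(np.int32),
        bond_kind=state.bond_kind[bsel],
        reactive=state.reactive[mask],
        consumed=state.consumed[mask],
        periodic=state.periodic,
        rigid_species=state.rigid_species)


def extract_bmc(state: LatticeState) -> LatticeState:
    """Keep only the biggest molecule cluster, in the same periodic box."""
    g = molecule_graph(state)
    bmc = biggest_molecule_cluster(g)
    return select_molecules(state, bmc.nodes)


def unwrap_positions(state: LatticeState, indices=None) -> np.ndarray:
    """Unwrap monomer coordinates across periodic boundaries by traversing
    the bond graph (minimum-image steps from a spanning tree).

    Raises :class:`WindingError` if any closure bond disagrees with the
    spanning-tree unwrap by a box vector (the cluster winds the torus).
    """
    N = state.n_monomers
    if indices is None:
        indices = np.arange(N)
    idx = np.asarray(indices)
    sub = set(idx.tolist())
    g = nx.Graph()
    g.add_nodes_from(idx.tolist())
    for (i, j) in state.bonds:
        if int(i) in sub and int(j) in sub:
            g.add_edge(int(i), int(j))
    L = state.box_edge
    pos = state.positions
    out = {}
    for comp in nx.connected_components(g):
        root = min(comp)
        out[root] = pos[root].astype(np.int64)
        for u, v in nx.bfs_edges(g, root):
            step = min_image(pos[v] - pos[u], L)
            out[v] = out[u] + step
    for u, v in g.edges():
        d = out[v] - out[u]
        if np.any(min_image(pos[v] - pos[u], L) != d):
            raise WindingError(
                "cluster winds the periodic box; no consistent unwrapped "
                "coordinates exist")
    return np.stack([out[int(i)] for i in idx])


def relocate_cluster(state: LatticeState, new_box_edge: int) -> LatticeState:
    """Re-centre the unwrapped cluster in a larger box (the full-scale
    protocol: the extracted BMC is placed in a box twice the original
    edge).  Requires a non-winding cluster whose extent fits the new box
    with margin."""
    unwrapped = unwrap_positions(state)
    extent = unwrapped.max(axis=0) - unwrapped.min(axis=0)
    if np.any(extent + 4 >= new_box_edge):
        raise ValueError(
            f"new box edge {new_box_edge} too small for cluster extent "
            f"{extent.tolist()}")
    center = (unwrapped.min(axis=0) + unwrapped.max(axis=0)) // 2
    shifted = unwrapped - center + new_box_edge // 2
    st = state.copy()
    st.box_edge = int(new_box_edge)
    st.positions = np.mod(shifted, new_box_edge).astype(np.int64)
    return st


def deswell_run(bmc_state: LatticeState, n_mcs: int,
                energy: EnergyModel | None = None, rng=None,
                n_snapshots: int = 0):
    """Collapse the cluster under attractive PEG-PEG contacts.

    Runs ``n_mcs`` MCS with the deswelling energy model (default
    epsilon_pp = -0.30 k_BT) and returns ``(state, trajectory)`` where
    trajectory is a list of ``(mcs, contact_energy)`` checkpoints (plus
    snapshot copies if ``n_snapshots > 0``).  The state is modified in
    place.
    """
    if energy is None:
        energy = EnergyModel(epsilon_pp=-0.30)
    rng = _normalize_rng(rng)
    ctx = SimContext(bmc_state, energy)
    n_check = max(1, n_snapshots) if n_snapshots else 10
    chunk = max(1, n_mcs // n_check)
    traj = []
    snapshots = []
    done = 0
    while done < n_mcs:
        step = min(chunk, n_mcs - done)
        run_mcs(bmc_state, step, energy=energy, rng=rng, context=ctx)
        done += step
        traj.append((done, contact_energy(bmc_state, energy)))
        if n_snapshots:
            snapshots.append(bmc_state.copy())
    return bmc_state, {"energy_trajectory": np.array(traj),
                       "snapshots": snapshots}


def radius_of_gyration(positions, in_nm: bool = False) -> float:
    """Rg = sqrt(mean squared distance to the centroid) of unwrapped
    coordinates (lattice units, or nm with ``in_nm``)."""
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 1:
        pos = pos.reshape(1, -1)
    if len(pos) == 0:
        raise ValueError("radius of gyration of an empty set")
    c = pos.mean(axis=0)
    rg = float(np.sqrt(((pos - c) ** 2).sum(axis=1).mean()))
    if in_nm:
        from .builders import to_nm
        rg = to_nm(rg)
    return rg


@dataclass
class AggregateVoidStats:
    """Aggregate/void summary of a (collapsed) state."""

    peg_cluster_sizes: np.ndarray     # monomers per PEG aggregate
    void_radii: np.ndarray            # lattice units, one per probe point
    mean_void_radius: float
    density_profile: np.ndarray       # coarse 3D monomer-count histogram
    empty_box: bool = False


def _peg_adjacency_clusters(state: LatticeState,
                            shell: np.ndarray) -> np.ndarray:
    L = state.box_edge
    peg_idx = np.flatnonzero(state.species == SPECIES_PEG)
    if len(peg_idx) == 0:
        return np.empty(0, dtype=np.int64)
    pos = state.positions[peg_idx]
    grid = -np.ones((L, L, L), dtype=np.int64)
    grid[pos[:, 0], pos[:, 1], pos[:, 2]] = np.arange(len(peg_idx))
    g = nx.Graph()
    g.add_nodes_from(range(len(peg_idx)))
    for off in shell:
        x = (pos[:, 0] + off[0]) % L
        y = (pos[:, 1] + off[1]) % L
        z = (pos[:, 2] + off[2]) % L
        hit = grid[x, y, z]
        src = np.flatnonzero(hit >= 0)
        for s in src:
            g.add_edge(int(s), int(hit[s]))
    sizes = sorted((len(c) for c in nx.connected_components(g)),
                   reverse=True)
    return np.array(sizes, dtype=np.int64)


def aggregate_and_void_stats(state: LatticeState,
                             energy: EnergyModel | None = None,
                             n_probes: int = 10_000,
                             density_bins: int = 16,
                             rng=None) -> AggregateVoidStats:
    """PEG aggregates (contact-shell adjacency components), void radii
    (largest empty sphere at random probe points, via a periodic Euclidean
    distance transform), and a coarse density profile."""
    if energy is None:
        energy = EnergyModel(epsilon_pp=-0.30)
    rng = _normalize_rng(rng)
    L = state.box_edge
    sizes = _peg_adjacency_clusters(state, energy.contact_shell)

    occupied = np.zeros((L, L, L), dtype=bool)
    pos = state.positions
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                occupied[(pos[:, 0] + dx) % L, (pos[:, 1] + dy) % L,
                         (pos[:, 2] + dz) % L] = True
    empty_box = not occupied.any()
    if empty_box:
        radii = np.full(n_probes, float(L) / 2.0)
    else:
        pad = min(L // 2, 48)
        padded = np.pad(~occupied, pad, mode="wrap")
        edt = ndimage.distance_transform_edt(padded)
        core = edt[pad:pad + L, pad:pad + L, pad:pad + L]
        probes = _normalize_rng(rng).integers(0, L, size=(n_probes, 3))
        radii = core[probes[:, 0], probes[:, 1], probes[:, 2]]

    hist, _ = np.histogramdd(pos % L, bins=density_bins,
                             range=[(0, L)] * 3)
    return AggregateVoidStats(
        peg_cluster_sizes=sizes, void_radii=np.asarray(radii, dtype=float),
        mean_void_radius=float(np.mean(radii)),
        density_profile=hist, empty_box=empty_box)
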