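"""Molecule construction and solution assembly.

starPEG is a tetra-functional star: one central monomer plus four flexible
arms of 29 monomers each (117 monomers); the four arm termini are the
reactive thiol ends.  Heparin is a bulky rigid rod built as a two-strand
ladder of 2 x 45 monomers whose long-axis spacing is chosen so the mapped
end-to-end extent falls in the 14-17 nm window reported for a heparin of
this molar mass; 28 of its 90 monomers are labelled reactive (the
maleimide-functionalizable carboxylic acid sites), sampled uniformly per
molecule.

The length mapping follows the PEG segment length: one lattice unit is
0.3 nm.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.constants import Avogadro

from .lattice import (SPECIES_HEP, SPECIES_PEG, BOND_INTRA, LatticeState,
                      run_mcs)

#: physical size of one lattice unit (nm); PEG segment length 0.71 nm / 2.37
LATTICE_UNIT_NM = 0.3

STARPEG_ARMS = 4
STARPEG_ARM_LENGTH = 29
STARPEG_MONOMERS = STARPEG_ARMS * STARPEG_ARM_LENGTH + 1
STARPEG_MOLAR_MASS = 10_000.0  # g/mol

HEPARIN_MONOMERS = 90
HEPARIN_REACTIVE_SITES = 28
HEPARIN_MOLAR_MASS = 14_000.0  # g/mol


class PackingError(RuntimeError):
    """Random placement failed (requested density too high for the box)."""


def map_length(value_nm: float) -> float:
    """Convert a physical length in nm to lattice units (1 u = 0.3 nm)."""
    if value_nm < 0:
        raise ValueError("length must be non-negative")
    return value_nm / LATTICE_UNIT_NM


def to_nm(lattice_units: float) -> float:
    """Convert lattice units back to nm."""
    if lattice_units < 0:
        raise ValueError("length must be non-negative")
    return lattice_units * LATTICE_UNIT_NM


@dataclass
class MoleculeTemplate:
    """Topology recipe for one molecular species."""

    species: str                       # 'PEG' or 'HEP'
    monomer_count: int
    intramolecular_bonds: np.ndarray   # (B, 2) int
    reactive_indices: np.ndarray       # (R,) int
    rigidity: str                      # 'flexible' or 'rod'
    molar_mass_g_mol: float


def starpeg_template() -> MoleculeTemplate:
    """Tetra-functional star: centre 0, arm ``a`` occupies indices
    ``1+29a .. 29+29a``; the four termini are reactive."""
    bonds = []
    for a in range(STARPEG_ARMS):
        start = 1 + a * STARPEG_ARM_LENGTH
        bonds.append((0, start))
        for k in range(STARPEG_ARM_LENGTH - 1):
            bonds.append((start + k, start + k + 1))
    termini = [a * STARPEG_ARM_LENGTH + STARPEG_ARM_LENGTH
               for a in range(STARPEG_ARMS)]
    return MoleculeTemplate(
        species="PEG", monomer_count=STARPEG_MONOMERS,
        intramolecular_bonds=np.array(bonds, dtype=np.int32),
        reactive_indices=np.array(termini, dtype=np.int64),
        rigidity="flexible", molar_mass_g_mol=STARPEG_MOLAR_MASS)


def _heparin_strand_profile():
    """(x, y) coordinates of one 45-monomer strand.

    A y-zigzag of (1, +-2, 0) steps with a straight (2, 0, 0) step every
    sixth bond; the 44 bonds advance 51 lattice units along x, i.e. a
    15.3 nm rod at 0.3 nm per unit.
    """
    xy = []
    x, y = 0, 0
    for k in range(45):
        xy.append((x, y))
        if k == 44:
            break
        if (k + 1) % 6 == 0:
            x += 2
        else:
            x += 1
            y = 2 - y
    return xy


def heparin_local_coords() -> np.ndarray:
    """Canonical heparin conformation: two ladder strands 2 units apart in z
    (indices 0-44 strand A at z=0, 45-89 strand B at z=2)."""
    xy = _heparin_strand_profile()
    coords = [(x, y, 0) for x, y in xy] + [(x, y, 2) for x, y in xy]
    return np.array(coords, dtype=np.int64)


def heparin_template(seed=None) -> MoleculeTemplate:
    """Rigid heparin rod with 28 uniformly sampled reactive monomers."""
    rng = np.random.default_rng(seed)
    bonds = []
    for s in (0, 45):
        for k in range(44):
            bonds.append((s + k, s + k + 1))
    for k in range(45):
        bonds.append((k, 45 + k))
    reactive = np.sort(rng.choice(HEPARIN_MONOMERS, HEPARIN_REACTIVE_SITES,
                                  replace=False))
    return MoleculeTemplate(
        species="HEP", monomer_count=HEPARIN_MONOMERS,
        intramolecular_bonds=np.array(bonds, dtype=np.int32),
        reactive_indices=reactive.astype(np.int64),
        rigidity="rod", molar_mass_g_mol=HEPARIN_MOLAR_MASS)


def heparin_extent_nm() -> float:
    """Mapped long-axis extent (centre to centre) of the heparin rod."""
    coords = heparin_local_coords()
    return to_nm(float(coords[:, 0].max() - coords[:, 0].min()))


def _rotation_matrices():
    """The 24 proper rotations of the cubic lattice (signed permutations
    with determinant +1)."""
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=np.int64)
            for i, p in enumerate(perm):
                m[i, p] = signs[i]
            if round(np.linalg.det(m)) == 1:
                mats.append(m)
    return mats


_ROTATIONS = _rotation_matrices()


def molar_to_count(c_mM: float, box_edge_lattice: int) -> int:
    """Molecule count for concentration ``c_mM`` in a cubic box of edge
    ``box_edge_lattice`` lattice units (0.3 nm each)."""
    if c_mM <= 0 or box_edge_lattice <= 0:
        raise ValueError("concentration and box edge must be positive")
    edge_m = box_edge_lattice * LATTICE_UNIT_NM * 1e-9
    vol_litres = edge_m ** 3 * 1e3
    count = int(round(c_mM * 1e-3 * Avogadro * vol_litres))
    if count < 1:
        raise ValueError(
            f"box of edge {box_edge_lattice} is below one molecule at "
            f"{c_mM} mM; enlarge the box")
    return count


@dataclass
class SolutionSpec:
    """Precursor-solution recipe: molar ratio gamma = nPEG/nHEP at heparin
    concentration ``c_hep_mM`` in a periodic cubic box."""

    gamma: float
    c_hep_mM: float = 1.5
    box_edge: int = 128
    equilibration_mcs: int = 20_000
    seed: int = 0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.c_hep_mM <= 0:
            raise ValueError("heparin concentration must be > 0")
        if self.box_edge % 2 != 0:
            raise ValueError("box edge must be even")
        rod = heparin_local_coords()[:, 0].max() + 2
        if self.box_edge <= rod:
            raise ValueError(
                f"box edge {self.box_edge} cannot hold a heparin rod of "
                f"extent {rod} lattice units")


# ---------------------------------------------------------------------------
# placement helpers


def _blocks_free(grid, coords, L):
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                x = (coords[:, 0] + dx) % L
                y = (coords[:, 1] + dy) % L
                z = (coords[:, 2] + dz) % L
                if grid[x, y, z].any():
                    return False
    return True


def _blocks_mark(grid, coords, L, value=True):
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                grid[(coords[:, 0] + dx) % L, (coords[:, 1] + dy) % L,
                     (coords[:, 2] + dz) % L] = value


_AXIAL_STEPS = np.array([[2, 0, 0], [-2, 0, 0], [0, 2, 0], [0, -2, 0],
                         [0, 0, 2], [0, 0, -2]], dtype=np.int64)


def _grow_star(grid, L, rng, max_molecule_retries=100):
    """Grow one starPEG as a self-avoiding walk of stride-2 axial steps.

    Returns (117, 3) folded coordinates ordered as the template, or raises
    :class:`PackingError`.
    """
    one = np.zeros((1, 3), dtype=np.int64)
    for _ in range(max_molecule_retries):
        center = rng.integers(0, L, size=3)
        one[0] = center
        if not _blocks_free(grid, one, L):
            continue
        placed = [center.copy()]
        _blocks_mark(grid, one, L)
        ok = True
        for _arm in range(STARPEG_ARMS):
            cur = center.copy()
            for _k in range(STARPEG_ARM_LENGTH):
                order = rng.permutation(6)
                for d in order:
                    nxt = (cur + _AXIAL_STEPS[d]) % L
                    one[0] = nxt
                    if _blocks_free(grid, one, L):
                        _blocks_mark(grid, one, L)
                        placed.append(nxt.copy())
                        cur = nxt
                        break
                else:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return np.array(placed, dtype=np.int64)
        # undo and retry from a new anchor
        arr = np.array(placed, dtype=np.int64)
        _blocks_mark(grid, arr, L, value=False)
    raise PackingError("could not place starPEG after bounded retries")


def build_starpeg(seed=None, box_edge: int = 256):
    """Fresh starPEG template plus a self-avoiding initial conformation."""
    rng = np.random.default_rng(seed)
    grid = np.zeros((box_edge, box_edge, box_edge), dtype=bool)
    coords = _grow_star(grid, box_edge, rng)
    return starpeg_template(), coords


def build_heparin(seed=None):
    """Heparin template (seeded reactive sites) plus canonical coordinates."""
    return heparin_template(seed), heparin_local_coords()


def assemble_solution(spec: SolutionSpec) -> LatticeState:
    """Assemble and equilibrate a precursor solution.

    nHEP molecules follow from the concentration, nPEG = round(gamma *
    nHEP).  Molecules are placed at random without overlap (heparin with a
    random lattice rotation, starPEG grown as a self-avoiding walk) and the
    solution is equilibrated athermally (good solvent) for
    ``spec.equilibration_mcs`` MCS.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.box_edge
    n_hep = molar_to_count(spec.c_hep_mM, L)
    n_peg = int(round(spec.gamma * n_hep))

    n_total = n_hep * HEPARIN_MONOMERS + n_peg * STARPEG_MONOMERS
    phi = 8.0 * n_total / L ** 3
    if phi >= 0.5:
        raise PackingError(
            f"occupied volume fraction {phi:.2f} exceeds the BFM mobility "
            f"bound 0.5")

    grid = np.zeros((L, L, L), dtype=bool)
    hep_local = heparin_local_coords()
    hep_local = hep_local - hep_local.mean(axis=0).round().astype(np.int64)

    positions = np.zeros((n_total, 3), dtype=np.int64)
    species = np.zeros(n_total, dtype=np.uint8)
    molecule_id = np.zeros(n_total, dtype=np.int32)
    reactive = np.zeros(n_total, dtype=bool)
    bonds = []
    bond_off = 0
    idx = 0

    for mol in range(n_hep):
        tmpl = heparin_template(rng.integers(2 ** 31))
        placed = False
        for _ in range(500):
            rot = _ROTATIONS[rng.integers(len(_ROTATIONS))]
            anchor = rng.integers(0, L, size=3)
            coords = (hep_local @ rot.T + anchor) % L
            if _blocks_free(grid, coords, L):
                _blocks_mark(grid, coords, L)
                placed = True
                break
        if not placed:
            raise PackingError(f"could not place heparin molecule {mol}")
        sl = slice(idx, idx + HEPARIN_MONOMERS)
        positions[sl] = coords
        species[sl] = SPECIES_HEP
        molecule_id[sl] = mol
        reactive[np.asarray(tmpl.reactive_indices) + idx] = True
        bonds.append(tmpl.intramolecular_bonds + bond_off)
        bond_off += HEPARIN_MONOMERS
        idx += HEPARIN_MONOMERS

    peg_tmpl = starpeg_template()
    for mol in range(n_peg):
        coords = _grow_star(grid, L, rng)
        sl = slice(idx, idx + STARPEG_MONOMERS)
        positions[sl] = coords
        species[sl] = SPECIES_PEG
        molecule_id[sl] = n_hep + mol
        reactive[np.asarray(peg_tmpl.reactive_indices) + idx] = True
        bonds.append(peg_tmpl.intramolecular_bonds + bond_off)
        bond_off += STARPEG_MONOMERS
        idx += STARPEG_MONOMERS

    all_bonds = (np.concatenate(bonds) if bonds
                 else np.empty((0, 2), dtype=np.int32))
    state = LatticeState(
        box_edge=L, positions=positions, species=species,
        molecule_id=molecule_id, bonds=all_bonds,
        bond_kind=np.full(len(all_bonds), BOND_INTRA, dtype=np.uint8),
        reactive=reactive, consumed=np.zeros(n_total, dtype=bool))
    if spec.equilibration_mcs > 0:
        run_mcs(state, spec.equilibration_mcs, energy=None, rng=rng)
    return state


def linear_chain_state(n_monomers: int, box_edge: int,
                       species: str = "PEG") -> LatticeState:
    """Straight flexible test chain with (2,0,0) bonds (convenience)."""
    pos = np.zeros((n_monomers, 3), dtype=np.int64)
    pos[:, 0] = (2 * np.arange(n_monomers)) % box_edge
    bonds = np.column_stack([np.arange(n_monomers - 1),
                             np.arange(1, n_monomers)]).astype(np.int32)
    st = LatticeState(
        box_edge=box_edge, positions=pos,
        species=np.full(n_monomers, SPECIES_PEG if species == "PEG"
                        else SPECIES_HEP, dtype=np.uint8),
        molecule_id=np.zeros(n_monomers, dtype=np.int32),
        bonds=bonds, bond_kind=np.zeros(len(bonds), dtype=np.uint8),
        reactive=np.zeros(n_monomers, dtype=bool),
        consumed=np.zeros(n_monomers, dtype=bool))
    if species != "PEG":
        st.rigid_species = ()
    return st
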