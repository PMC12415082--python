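"""Bond Fluctuation Model (BFM) core: state container and Monte Carlo engine.

The BFM represents each coarse-grained monomer as a 2x2x2 cube of sites on a
periodic simple-cubic lattice.  Bonds are restricted to the classic allowed
vector set (signed permutations of (2,0,0), (2,1,0), (2,1,1), (2,2,1),
(3,0,0), (3,1,0); 108 vectors), which together with excluded volume
guarantees self-avoidance and topology preservation (chains cannot cross).
One Monte Carlo step (MCS) is one attempted move per monomer on average.

Heparin rods are rigid bodies: they move by whole-molecule unit
translations attempted at a rate of one per rod per MCS, so the rod keeps
its exact shape while still diffusing.  starPEG monomers move by the
standard single-monomer unit-step moves.

An optional attractive contact energy between PEG monomers (used to model
deswelling in a poor solvent) acts on centre-centre offsets with squared
length in {4, 5, 6} -- the nearest non-overlapping approach shells -- with
Metropolis acceptance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import mc_kernel, single_move_kernel

SPECIES_PEG = 0
SPECIES_HEP = 1
SPECIES_NAMES = {SPECIES_PEG: "PEG", SPECIES_HEP: "HEP"}
SPECIES_CODES = {"PEG": SPECIES_PEG, "HEP": SPECIES_HEP}

BOND_INTRA = 0
BOND_CROSSLINK = 1
BOND_KIND_NAMES = {BOND_INTRA: "intra", BOND_CROSSLINK: "cross"}
BOND_KIND_CODES = {v: k for k, v in BOND_KIND_NAMES.items()}

#: the six classic BFM bond-vector classes
BOND_CLASSES = ((2, 0, 0), (2, 1, 0), (2, 1, 1), (2, 2, 1), (3, 0, 0),
                (3, 1, 0))

MAX_DEGREE = 6


def _rotation_90_matrices() -> np.ndarray:
    """The six +-90 degree lattice rotations about x, y, z (used as rigid
    reorientation proposals for the heparin rods)."""
    mats = []
    for axis in range(3):
        for sgn in (1, -1):
            m = np.zeros((3, 3), dtype=np.int64)
            m[axis, axis] = 1
            a, b = [i for i in range(3) if i != axis]
            m[a, b] = -sgn
            m[b, a] = sgn
            mats.append(m)
    return np.stack(mats)


ROT_MATS_90 = _rotation_90_matrices()


_DIRECTIONS = {
    "+x": (0, 1), "-x": (0, -1),
    "+y": (1, 1), "-y": (1, -1),
    "+z": (2, 1), "-z": (2, -1),
}


class AuditError(AssertionError):
    """A lattice-state invariant is violated."""


def allowed_bond_set() -> frozenset:
    """All 108 allowed BFM bond vectors (closed under sign and permutation)."""
    vecs = set()
    for cls in BOND_CLASSES:
        for perm in itertools.permutations(cls):
            for signs in itertools.product((1, -1), repeat=3):
                vecs.add(tuple(s * c for s, c in zip(signs, perm)))
    return frozenset(vecs)


def allowed_bond_array() -> np.ndarray:
    """Allowed vectors as an (108, 3) int64 array in deterministic order."""
    return np.array(sorted(allowed_bond_set()), dtype=np.int64)


def _allowed_table() -> np.ndarray:
    tab = np.zeros((7, 7, 7), dtype=np.uint8)
    for v in allowed_bond_set():
        tab[v[0] + 3, v[1] + 3, v[2] + 3] = 1
    return tab


_ALLOWED_TABLE = _allowed_table()
_ALLOWED_SET = allowed_bond_set()


def contact_shell_offsets(squared_lengths=(4, 5, 6)) -> np.ndarray:
    """Centre-centre offsets defining a PEG-PEG contact (symmetric set)."""
    offs = []
    for v in itertools.product(range(-3, 4), repeat=3):
        if v[0] ** 2 + v[1] ** 2 + v[2] ** 2 in set(squared_lengths):
            offs.append(v)
    return np.array(sorted(offs), dtype=np.int64)


@dataclass
class EnergyModel:
    """Contact-energy model for PEG-PEG attraction (in units of k_BT).

    ``epsilon_pp`` defaults to the deswelling value of -0.30 k_BT; use
    ``epsilon_pp=0`` (or pass ``energy=None`` to the engine) for athermal
    good-solvent runs.
    """

    epsilon_pp: float = -0.30
    shell_squared_lengths: tuple = (4, 5, 6)

    def __post_init__(self):
        self.contact_shell = contact_shell_offsets(self.shell_squared_lengths)
        neg = set(map(tuple, (-self.contact_shell).tolist()))
        if neg != set(map(tuple, self.contact_shell.tolist())):
            raise ValueError("contact shell must be symmetric under negation")

    @property
    def athermal(self) -> bool:
        return self.epsilon_pp == 0.0


def _shell_diff_offsets(shell: np.ndarray):
    """Per-direction add/remove offset lists for incremental contact counts.

    For a unit step e the contact count changes only on the symmetric
    difference of the old and new shells: ``add = (e + S) \\ S`` and
    ``rem = S \\ (e + S)``, both relative to the old position.
    """
    sset = set(map(tuple, shell.tolist()))
    adds, rems = [], []
    for axis in range(3):
        for sgn in (1, -1):
            e = np.zeros(3, dtype=np.int64)
            e[axis] = sgn
            shifted = {tuple((np.array(o) + e).tolist()) for o in sset}
            add = sorted(shifted - sset)
            rem = sorted(sset - shifted)
            adds.append(add)
            rems.append(rem)
    n = max(len(a) for a in adds)
    assert all(len(a) == n and len(r) == n for a, r in zip(adds, rems))
    add_arr = np.array(adds, dtype=np.int64).reshape(6, n, 3)
    rem_arr = np.array(rems, dtype=np.int64).reshape(6, n, 3)
    return add_arr, rem_arr


_DEFAULT_SHELL = contact_shell_offsets()
_DEFAULT_ADD, _DEFAULT_REM = _shell_diff_offsets(_DEFAULT_SHELL)


@dataclass
class LatticeState:
    """Full BFM microstate.

    positions are integer monomer anchors wrapped into ``[0, box_edge)``;
    monomer ``i`` occupies sites ``{x..x+1} x {y..y+1} x {z..z+1}``
    (periodic).  Monomers of one molecule occupy a contiguous index range.
    """

    box_edge: int
    positions: np.ndarray          # (N, 3) int64
    species: np.ndarray            # (N,) uint8, 0=PEG 1=HEP
    molecule_id: np.ndarray        # (N,) int32
    bonds: np.ndarray              # (B, 2) int32
    bond_kind: np.ndarray          # (B,) uint8, 0=intra 1=crosslink
    reactive: np.ndarray           # (N,) bool
    consumed: np.ndarray           # (N,) bool
    periodic: tuple = (True, True, True)
    rigid_species: tuple = (SPECIES_HEP,)

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.int64)
        self.species = np.ascontiguousarray(self.species, dtype=np.uint8)
        self.molecule_id = np.ascontiguousarray(self.molecule_id,
                                                dtype=np.int32)
        self.bonds = np.ascontiguousarray(
            self.bonds, dtype=np.int32).reshape(-1, 2)
        self.bond_kind = np.ascontiguousarray(self.bond_kind, dtype=np.uint8)
        self.reactive = np.ascontiguousarray(self.reactive, dtype=bool)
        self.consumed = np.ascontiguousarray(self.consumed, dtype=bool)

    @property
    def n_monomers(self) -> int:
        return self.positions.shape[0]

    @property
    def n_molecules(self) -> int:
        return len(np.unique(self.molecule_id))

    def species_counts(self) -> dict:
        return {name: int(np.sum(self.species == code))
                for code, name in SPECIES_NAMES.items()}

    def volume_fraction(self) -> float:
        return 8.0 * self.n_monomers / self.box_edge ** 3

    def crosslink_count(self) -> int:
        return int(np.sum(self.bond_kind == BOND_CROSSLINK))

    def copy(self) -> "LatticeState":
        return LatticeState(
            box_edge=self.box_edge,
            positions=self.positions.copy(),
            species=self.species.copy(),
            molecule_id=self.molecule_id.copy(),
            bonds=self.bonds.copy(),
            bond_kind=self.bond_kind.copy(),
            reactive=self.reactive.copy(),
            consumed=self.consumed.copy(),
            periodic=self.periodic,
            rigid_species=self.rigid_species,
        )

    def molecule_ranges(self) -> np.ndarray:
        """(n_mol, 3) array of (molecule_id, lo, hi) contiguous index ranges."""
        mid = self.molecule_id
        if len(mid) == 0:
            return np.empty((0, 3), dtype=np.int64)
        change = np.flatnonzero(np.diff(mid)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(mid)]))
        ids = mid[starts]
        if len(np.unique(ids)) != len(ids):
            raise AuditError("molecule monomers are not index-contiguous")
        return np.stack([ids.astype(np.int64), starts, ends], axis=1)


def _wrap(a: np.ndarray, L: int) -> np.ndarray:
    return np.mod(a, L)


def min_image(d, L: int) -> np.ndarray:
    """Component-wise minimum-image displacement for box edge ``L``.

    Valid for arbitrary integer displacements; the tie at exactly L/2
    maps to -L/2."""
    d = np.asarray(d, dtype=np.int64)
    h = L // 2
    return np.mod(d + h, L) - h


_min_image_int = min_image


def build_occupancy(state: LatticeState, dtype=np.int32) -> np.ndarray:
    """(L, L, L) grid with ``monomer_index + 1`` on every occupied site.

    Raises :class:`AuditError` on any excluded-volume violation.
    """
    L = state.box_edge
    grid = np.zeros((L, L, L), dtype=dtype)
    pos = state.positions
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                x = _wrap(pos[:, 0] + dx, L)
                y = _wrap(pos[:, 1] + dy, L)
                z = _wrap(pos[:, 2] + dz, L)
                if np.any(grid[x, y, z] != 0):
                    raise AuditError("excluded-volume violation: "
                                     "overlapping 2x2x2 blocks")
                grid[x, y, z] = np.arange(1, state.n_monomers + 1)
    return grid


def _adjacency(state: LatticeState):
    N = state.n_monomers
    nbr = np.full((N, MAX_DEGREE), -1, dtype=np.int32)
    cnt = np.zeros(N, dtype=np.int32)
    for i, j in state.bonds:
        for a, b in ((i, j), (j, i)):
            if cnt[a] >= MAX_DEGREE:
                raise AuditError(f"monomer {a} exceeds max degree "
                                 f"{MAX_DEGREE}")
            nbr[a, cnt[a]] = b
            cnt[a] += 1
    return nbr, cnt


class SimContext:
    """Prepared kernel arrays for a state (occupancy, adjacency, grids).

    The context aliases ``state.positions``: kernels mutate the state's
    position array in place.  Bond topology is never touched by moves.
    """

    def __init__(self, state: LatticeState, energy: EnergyModel | None = None):
        self.state = state
        self.L = int(state.box_edge)
        N = state.n_monomers
        self.N = N
        occ3 = build_occupancy(state, dtype=np.int32)
        self.occ = np.ascontiguousarray((occ3 != 0).ravel(), dtype=np.uint8)
        pegc = np.zeros(self.L ** 3, dtype=np.uint8)
        pos = state.positions
        peg = state.species == SPECIES_PEG
        idx = (pos[peg, 0] * self.L + pos[peg, 1]) * self.L + pos[peg, 2]
        pegc[idx] = 1
        self.pegc = pegc
        self.nbr, self.ncnt = _adjacency(state)

        rigid = np.zeros(N, dtype=np.uint8)
        for sp in state.rigid_species:
            rigid |= (state.species == sp).astype(np.uint8)
        self.rigid = rigid
        mol_lo = np.zeros(N, dtype=np.int32)
        mol_hi = np.zeros(N, dtype=np.int32)
        max_mol = 1
        for _, lo, hi in state.molecule_ranges():
            mol_lo[lo:hi] = lo
            mol_hi[lo:hi] = hi
            max_mol = max(max_mol, int(hi - lo))
        self.mol_lo, self.mol_hi = mol_lo, mol_hi
        self.max_mol = max_mol

        if energy is None or energy.athermal:
            self.use_energy = False
            self.eps = 0.0
            self.add_off, self.rem_off = _DEFAULT_ADD, _DEFAULT_REM
            self.exptab = np.ones(1 + _DEFAULT_ADD.shape[1] * 2)
        else:
            self.use_energy = True
            self.eps = float(energy.epsilon_pp)
            self.add_off, self.rem_off = _shell_diff_offsets(
                energy.contact_shell)
            kmax = energy.contact_shell.shape[0]
            self.exptab = np.exp(-abs(self.eps) * np.arange(kmax + 1))
        self.allowed = _ALLOWED_TABLE

    def kernel_args(self):
        return (self.state.positions, self.state.species, self.rigid,
                self.mol_lo, self.mol_hi, self.nbr, self.ncnt,
                self.occ, self.pegc, self.L)

    def energy_args(self):
        return (self.use_energy, self.eps < 0, self.exptab,
                self.add_off, self.rem_off, self.allowed)


_NO_REACT = dict(
    do_react=False,
    reactive=np.zeros(1, dtype=np.uint8),
    consumed=np.zeros(1, dtype=np.uint8),
    hq=np.zeros(1, dtype=np.uint8),
    hid=np.zeros(1, dtype=np.int32),
    scan_off=np.zeros((1, 3), dtype=np.int64),
    term_list=np.zeros(0, dtype=np.int64),
    sweep_every=0,
    target_bonds=np.iinfo(np.int64).max,
    n_bonds=0,
    ev_peg=np.zeros(1, dtype=np.int32),
    ev_hep=np.zeros(1, dtype=np.int32),
    ev_mcs=np.zeros(1, dtype=np.float64),
    n_ev=0,
    p_react=1.0,
)


def _normalize_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2 ** 31 - 1))


def run_mcs(state: LatticeState, n_mcs: int, energy: EnergyModel | None = None,
            rng=None, context: SimContext | None = None,
            max_attempts_per_call: int = 2 ** 62) -> LatticeState:
    """Run ``n_mcs`` Monte Carlo steps (``n_mcs * N`` attempted moves).

    The state is updated in place and also returned.  Pass a ``context``
    to continue a run without rebuilding grids (positions must not have
    been modified outside the engine in between).
    """
    if n_mcs < 0:
        raise ValueError("n_mcs must be >= 0")
    rng = _normalize_rng(rng)
    if state.n_monomers == 0 or n_mcs == 0:
        return state
    ctx = context if context is not None else SimContext(state, energy)
    attempts = int(n_mcs) * ctx.N
    mc_kernel(*ctx.kernel_args(), attempts, *ctx.energy_args(),
              **_NO_REACT, attempts_base=0, rot_mats=ROT_MATS_90,
              max_mol=ctx.max_mol, seed=_kernel_seed(rng))
    return state


def attempt_move(state: LatticeState, monomer: int, direction,
                 energy: EnergyModel | None = None, rng=None,
                 context: SimContext | None = None) -> bool:
    """Attempt one move of ``monomer`` along a unit ``direction``.

    ``direction`` is one of '+x', '-x', '+y', '-y', '+z', '-z' or an
    equivalent integer triple.  For rigid (heparin) monomers this attempts
    a rigid-body translation of the whole molecule.  Returns True iff the
    move was accepted (state updated in place).
    """
    if not (0 <= monomer < state.n_monomers):
        raise IndexError(f"monomer index {monomer} out of range")
    if isinstance(direction, str):
        if direction not in _DIRECTIONS:
            raise ValueError(f"invalid direction {direction!r}")
        axis, sgn = _DIRECTIONS[direction]
    else:
        d = tuple(int(v) for v in direction)
        if sorted(map(abs, d)) != [0, 0, 1]:
            raise ValueError(f"direction must be a unit lattice step, "
                             f"got {d}")
        axis = max(range(3), key=lambda a: abs(d[a]))
        sgn = d[axis]
    rng = _normalize_rng(rng)
    ctx = context if context is not None else SimContext(state, energy)
    acc = single_move_kernel(*ctx.kernel_args(), monomer, axis, sgn,
                             *ctx.energy_args(), _kernel_seed(rng))
    return bool(acc)


def contact_energy(state: LatticeState, energy: EnergyModel) -> float:
    """Total PEG-PEG contact energy in k_BT.

    Sums ``epsilon_pp`` over unordered PEG pairs whose minimum-image
    centre separation lies in the contact shell.
    """
    if energy.athermal:
        return 0.0
    L = state.box_edge
    peg = state.positions[state.species == SPECIES_PEG]
    if len(peg) == 0:
        return 0.0
    grid = np.zeros((L, L, L), dtype=np.uint8)
    grid[peg[:, 0], peg[:, 1], peg[:, 2]] = 1
    npairs2 = 0
    for off in energy.contact_shell:
        x = _wrap(peg[:, 0] + off[0], L)
        y = _wrap(peg[:, 1] + off[1], L)
        z = _wrap(peg[:, 2] + off[2], L)
        npairs2 += int(grid[x, y, z].sum())
    return energy.epsilon_pp * npairs2 / 2.0


def audit(state: LatticeState, reference: LatticeState | None = None) -> None:
    """Verify all lattice-state invariants; raise :class:`AuditError`.

    With ``reference`` additionally checks topology preservation: the
    intramolecular bond set is unchanged and crosslinks only ever grow.
    """
    L = state.box_edge
    build_occupancy(state)  # raises on overlap
    d = _min_image_int(state.positions[state.bonds[:, 1]]
                       - state.positions[state.bonds[:, 0]], L)
    for vec in map(tuple, d.tolist()):
        if vec not in _ALLOWED_SET:
            raise AuditError(f"disallowed bond vector {vec}")
    if np.any(state.consumed & ~state.reactive):
        raise AuditError("consumed monomer that is not reactive")
    cross = state.bonds[state.bond_kind == BOND_CROSSLINK]
    if cross.size:
        sp = state.species
        if np.any(sp[cross[:, 0]] == sp[cross[:, 1]]):
            raise AuditError("crosslink joins two monomers of one species")
    state.molecule_ranges()
    if reference is not None:
        def _bondset(s, kind):
            sel = s.bond_kind == kind
            return {tuple(sorted(b)) for b in s.bonds[sel].tolist()}
        if _bondset(state, BOND_INTRA) != _bondset(reference, BOND_INTRA):
            raise AuditError("intramolecular bond topology changed")
        if not _bondset(state, BOND_CROSSLINK) >= _bondset(reference,
                                                           BOND_CROSSLINK):
            raise AuditError("crosslink bonds were removed")


# ---------------------------------------------------------------------------
# lattice-state text format


def write_state(state: LatticeState, path) -> None:
    """Write the plain-text lattice-state format (bit-exact round trip)."""
    lines = [f"box {state.box_edge}",
             "periodic " + " ".join("1" if p else "0"
                                    for p in state.periodic)]
    for i in range(state.n_monomers):
        x, y, z = state.positions[i]
        lines.append(
            f"{i} {x} {y} {z} {SPECIES_NAMES[int(state.species[i])]} "
            f"{int(state.molecule_id[i])} {int(state.reactive[i])} "
            f"{int(state.consumed[i])}")
    for (i, j), k in zip(state.bonds, state.bond_kind):
        lines.append(f"{i} {j} {BOND_KIND_NAMES[int(k)]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_state(path) -> LatticeState:
    """Read the plain-text lattice-state format written by ``write_state``."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("box "):
        raise ValueError("not a lattice-state file: missing 'box' header")
    box = int(lines[0].split()[1])
    periodic = tuple(v == "1" for v in lines[1].split()[1:4])
    mono, bonds = [], []
    for ln in lines[2:]:
        parts = ln.split()
        if not parts:
            continue
        if len(parts) == 8:
            mono.append(parts)
        elif len(parts) == 3:
            bonds.append(parts)
        else:
            raise ValueError(f"unparseable line: {ln!r}")
    n = len(mono)
    positions = np.zeros((n, 3), dtype=np.int64)
    species = np.zeros(n, dtype=np.uint8)
    mol = np.zeros(n, dtype=np.int32)
    reactive = np.zeros(n, dtype=bool)
    consumed = np.zeros(n, dtype=bool)
    for row in mono:
        i = int(row[0])
        positions[i] = [int(row[1]), int(row[2]), int(row[3])]
        species[i] = SPECIES_CODES[row[4]]
        mol[i] = int(row[5])
        reactive[i] = row[6] == "1"
        consumed[i] = row[7] == "1"
    b = np.array([[int(r[0]), int(r[1])] for r in bonds],
                 dtype=np.int32).reshape(-1, 2)
    bk = np.array([BOND_KIND_CODES[r[2]] for r in bonds], dtype=np.uint8)
    return LatticeState(box_edge=box, positions=positions, species=species,
                        molecule_id=mol, bonds=b, bond_kind=bk,
                        reactive=reactive, consumed=consumed,
                        periodic=periodic)
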