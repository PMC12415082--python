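"""Michael-type crosslinking as collision-triggered permanent bonding.

A permanent bond forms when an unconsumed starPEG terminus and an
unconsumed heparin reactive site come within one allowed BFM bond vector
of each other ("direct collision"): the check runs event-driven after
every accepted move of a terminus, plus a periodic safety sweep that also
catches collisions produced by rigid heparin motion.  Each reactive site
reacts at most once; simultaneous candidates are tie-broken uniformly at
random.  The reaction runs athermally (good solvent), matching the order
of operations crosslink-then-deswell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import mc_kernel
from .lattice import (BOND_CROSSLINK, ROT_MATS_90, SPECIES_HEP,
                      SPECIES_PEG, EnergyModel, LatticeState, SimContext,
                      allowed_bond_array, _normalize_rng, _kernel_seed)


@dataclass
class ReactionLog:
    """Ordered record of crosslink events and the extent-of-reaction
    trajectory."""

    mcs: np.ndarray          # event times (MCS, float)
    peg_monomer: np.ndarray  # terminus index per event
    hep_monomer: np.ndarray  # heparin site index per event
    p_trajectory: np.ndarray  # (K, 2): cumulative MCS, extent of reaction
    completed: bool = True

    @property
    def n_events(self) -> int:
        return len(self.mcs)

    def events_to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"mcs": self.mcs, "peg_idx": self.peg_monomer,
                      "hep_idx": self.hep_monomer}).to_csv(path, index=False)

    def trajectory_to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.p_trajectory,
                     columns=["mcs", "p"]).to_csv(path, index=False)


def n_peg_termini(state: LatticeState) -> int:
    return int(np.sum(state.reactive & (state.species == SPECIES_PEG)))


def extent_of_reaction(state: LatticeState) -> float:
    """p = crosslink bonds / all starPEG terminal groups (0 if no PEG)."""
    termini = n_peg_termini(state)
    if termini == 0:
        warnings.warn("state has no starPEG termini; extent of reaction "
                      "reported as 0")
        return 0.0
    return state.crosslink_count() / termini


FACE_CONTACT_VECTORS = np.array(
    [[2, 0, 0], [-2, 0, 0], [0, 2, 0], [0, -2, 0], [0, 0, 2], [0, 0, -2]],
    dtype=np.int64)


def crosslink_until(state: LatticeState, p_target: float = 0.90,
                    max_mcs: int = 10_000_000, rng=None,
                    capture: str = "face", p_react: float = 0.05,
                    sweep_interval_mcs: int = 2,
                    chunk_mcs: int = 2_000,
                    energy: EnergyModel | None = None):
    """Simulate until the extent of reaction reaches ``p_target``.

    Returns ``(state, ReactionLog)``; the state is modified in place
    (positions, consumed flags, and appended crosslink bonds).  If
    ``max_mcs`` is exhausted first the partial result is returned with
    ``log.completed = False`` and a warning.

    ``capture`` selects the collision criterion: ``"face"`` (default)
    requires the two reactive cubes to touch face-on (separation one of
    the six (+-2,0,0) vectors, the closest approach the lattice allows),
    ``"bond"`` accepts any separation in the allowed 108-vector bond set.
    ``p_react`` is the reaction probability per collision check; values
    well below 1 put the reaction in the chemistry-controlled regime, in
    which arms explore locally before binding.  Either way the formed
    bond is a legal BFM bond at creation.
    """
    if not 0.0 <= p_target <= 1.0:
        raise ValueError("p_target must lie in [0, 1]")
    rng = _normalize_rng(rng)

    termini = n_peg_termini(state)
    existing = state.crosslink_count()
    target_bonds = math.ceil(p_target * termini - 1e-9)
    if p_target == 0 or target_bonds <= existing or termini == 0:
        return state, ReactionLog(
            mcs=np.empty(0), peg_monomer=np.empty(0, dtype=np.int32),
            hep_monomer=np.empty(0, dtype=np.int32),
            p_trajectory=np.array([[0.0, extent_of_reaction(state)]]))

    hep_sites = int(np.sum(state.reactive & ~state.consumed
                           & (state.species == SPECIES_HEP)))
    free_termini = int(np.sum(state.reactive & ~state.consumed
                              & (state.species == SPECIES_PEG)))
    needed = target_bonds - existing
    if hep_sites < needed or free_termini < needed:
        raise ValueError(
            f"p_target {p_target} unreachable: need {needed} more bonds "
            f"but only {free_termini} free termini and {hep_sites} free "
            f"heparin sites remain")

    ctx = SimContext(state, energy)
    L = ctx.L
    pos = state.positions
    hq = np.zeros(L ** 3, dtype=np.uint8)
    hid = np.zeros(L ** 3, dtype=np.int32)
    hep_mask = state.reactive & ~state.consumed & (state.species
                                                   == SPECIES_HEP)
    hs = (pos[hep_mask, 0] * L + pos[hep_mask, 1]) * L + pos[hep_mask, 2]
    hq[hs] = 1
    hid[hs] = np.flatnonzero(hep_mask).astype(np.int32) + 1
    term_list = np.flatnonzero(
        state.reactive & (state.species == SPECIES_PEG)).astype(np.int64)

    cap = termini
    ev_peg = np.zeros(cap, dtype=np.int32)
    ev_hep = np.zeros(cap, dtype=np.int32)
    ev_mcs = np.zeros(cap, dtype=np.float64)
    n_ev = 0
    n_bonds = existing
    if capture == "face":
        scan_off = FACE_CONTACT_VECTORS
    elif capture == "bond":
        scan_off = allowed_bond_array()
    else:
        raise ValueError(f"unknown capture mode {capture!r}")
    sweep_every = int(sweep_interval_mcs) * ctx.N

    attempts_base = 0
    total_attempts = int(max_mcs) * ctx.N
    traj = [(0.0, n_bonds / termini)]
    while n_bonds < target_bonds and attempts_base < total_attempts:
        chunk = min(int(chunk_mcs) * ctx.N, total_attempts - attempts_base)
        done, _acc, n_ev, n_bonds = mc_kernel(
            *ctx.kernel_args(), chunk, *ctx.energy_args(),
            do_react=True, reactive=state.reactive, consumed=state.consumed,
            hq=hq, hid=hid, scan_off=scan_off, term_list=term_list,
            sweep_every=sweep_every, target_bonds=target_bonds,
            n_bonds=n_bonds, ev_peg=ev_peg, ev_hep=ev_hep, ev_mcs=ev_mcs,
            n_ev=n_ev, attempts_base=attempts_base, p_react=float(p_react),
            rot_mats=ROT_MATS_90, max_mol=ctx.max_mol,
            seed=_kernel_seed(rng))
        attempts_base += done
        traj.append((attempts_base / ctx.N, n_bonds / termini))

    completed = n_bonds >= target_bonds
    if not completed:
        warnings.warn(
            f"crosslinking stopped at p = {n_bonds / termini:.3f} after "
            f"{max_mcs} MCS without reaching p_target = {p_target}; "
            f"partial result returned")

    if n_ev:
        new_bonds = np.column_stack([ev_peg[:n_ev],
                                     ev_hep[:n_ev]]).astype(np.int32)
        state.bonds = np.vstack([state.bonds, new_bonds]).astype(np.int32)
        state.bond_kind = np.concatenate(
            [state.bond_kind,
             np.full(n_ev, BOND_CROSSLINK, dtype=np.uint8)])
    log = ReactionLog(mcs=ev_mcs[:n_ev].copy(),
                      peg_monomer=ev_peg[:n_ev].copy(),
                      hep_monomer=ev_hep[:n_ev].copy(),
                      p_trajectory=np.array(traj), completed=completed)
    return state, log
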