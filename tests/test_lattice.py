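import numpy as np
import pytest

from bfmgel.builders import linear_chain_state
from bfmgel.lattice import (AuditError, EnergyModel, LatticeState,
                            SimContext, allowed_bond_set, attempt_move,
                            audit, contact_energy, min_image, read_state,
                            run_mcs, write_state)


def two_monomer_state(p0, p1, box=16, bond=False, species=(0, 0)):
    bonds = np.array([[0, 1]], dtype=np.int32) if bond \
        else np.empty((0, 2), dtype=np.int32)
    return LatticeState(
        box_edge=box,
        positions=np.array([p0, p1], dtype=np.int64),
        species=np.array(species, dtype=np.uint8),
        molecule_id=np.array([0, 1], dtype=np.int32) if not bond
        else np.array([0, 0], dtype=np.int32),
        bonds=bonds, bond_kind=np.zeros(len(bonds), dtype=np.uint8),
        reactive=np.zeros(2, dtype=bool), consumed=np.zeros(2, dtype=bool),
        rigid_species=())


class TestAllowedBondSet:
    def test_membership(self):
        s = allowed_bond_set()
        assert (2, 0, 0) in s
        assert (-3, 1, 0) in s
        assert (2, 2, 2) not in s          # length^2 = 12 is not a class

    def test_size_matches_bruteforce_enumeration(self):
        import itertools
        classes = [(2, 0, 0), (2, 1, 0), (2, 1, 1), (2, 2, 1), (3, 0, 0),
                   (3, 1, 0)]
        brute = set()
        for cls in classes:
            for perm in itertools.permutations(cls):
                for signs in itertools.product((1, -1), repeat=3):
                    brute.add(tuple(s * c for s, c in zip(signs, perm)))
        assert allowed_bond_set() == brute
        assert len(brute) == 108

    def test_closed_under_negation(self):
        s = allowed_bond_set()
        assert {tuple(-c for c in v) for v in s} == s


class TestAttemptMove:
    def test_free_monomer_moves_every_direction(self):
        for d in ("+x", "-x", "+y", "-y", "+z", "-z"):
            st = two_monomer_state((4, 4, 4), (10, 10, 10))
            assert attempt_move(st, 0, d, rng=1)

    def test_bond_stretch_rejected(self):
        # (3,1,0) -> (4,1,0) leaves the allowed set
        st = two_monomer_state((4, 4, 4), (7, 5, 4), bond=True)
        assert not attempt_move(st, 1, "+x", rng=1)
        assert attempt_move(st, 1, "-x", rng=1)   # (2,1,0) is allowed

    def test_excluded_volume_rejected(self):
        st = two_monomer_state((4, 4, 4), (6, 4, 4))
        assert not attempt_move(st, 0, "+x", rng=1)

    def test_invalid_requests(self):
        st = two_monomer_state((4, 4, 4), (10, 10, 10))
        with pytest.raises(IndexError):
            attempt_move(st, 5, "+x")
        with pytest.raises(ValueError):
            attempt_move(st, 0, "+q")
        with pytest.raises(ValueError):
            attempt_move(st, 0, (1, 1, 0))

    def test_metropolis_acceptance_frequency(self):
        # breaking one PEG-PEG contact costs 0.30 kBT:
        # P(accept) = exp(-0.30) ~ 0.741
        energy = EnergyModel(epsilon_pp=-0.30)
        st = two_monomer_state((4, 4, 4), (6, 4, 4))
        ctx = SimContext(st, energy)
        L = 16
        rng = np.random.default_rng(77)

        def sidx(x, y, z):
            return (x % L * L + y % L) * L + z % L

        # on accept, undo the +x move of monomer 1 by direct array
        # surgery so one prepared context serves all trials
        claimed = [sidx(8, 4 + dy, 4 + dz) for dy in (0, 1)
                   for dz in (0, 1)]
        vacated = [sidx(6, 4 + dy, 4 + dz) for dy in (0, 1)
                   for dz in (0, 1)]
        n, acc = 100_000, 0
        for _ in range(n):
            if attempt_move(st, 1, "+x", energy=energy, rng=rng,
                            context=ctx):
                acc += 1
                st.positions[1] = (6, 4, 4)
                for s_ in claimed:
                    ctx.occ[s_] = 0
                for s_ in vacated:
                    ctx.occ[s_] = 1
                ctx.pegc[sidx(7, 4, 4)] = 0
                ctx.pegc[sidx(6, 4, 4)] = 1
        p_emp = acc / n
        p_th = np.exp(-0.30)
        assert abs(p_emp - p_th) < 4 * np.sqrt(p_th * (1 - p_th) / n)


class TestRunMcs:
    def test_zero_mcs_is_identity(self):
        st = linear_chain_state(10, 32)
        before = st.positions.copy()
        run_mcs(st, 0, rng=1)
        assert np.array_equal(st.positions, before)

    def test_invariants_after_long_run(self):
        st = linear_chain_state(30, 64)
        ref = st.copy()
        run_mcs(st, 20_000, rng=3)
        audit(st, reference=ref)
        assert not np.array_equal(st.positions, ref.positions)

    def test_mean_square_bond_length_athermal(self):
        # athermal BFM equilibrium: <b^2> ~ 6.9 (melt) to ~7.5 (dilute);
        # a single free chain sits at the dilute end of the range
        st = linear_chain_state(30, 64)
        rng = np.random.default_rng(11)
        run_mcs(st, 20_000, rng=rng)
        vals = []
        for _ in range(150):
            run_mcs(st, 200, rng=rng)
            d = min_image(st.positions[st.bonds[:, 1]]
                          - st.positions[st.bonds[:, 0]], 64)
            vals.append((d ** 2).sum(axis=1).mean())
        assert 6.9 <= np.mean(vals) <= 7.6
        # stationarity: halves agree within sampling error
        a, b = np.mean(vals[:75]), np.mean(vals[75:])
        assert abs(a - b) < 0.25

    def test_self_avoiding_scaling(self):
        # <R^2> grows superlinearly with N (SAW exponent 2*nu ~ 1.18)
        rng = np.random.default_rng(5)
        r2 = {}
        for n in (8, 16, 32):
            st = linear_chain_state(n, 64)
            run_mcs(st, 5_000, rng=rng)
            samples = []
            for _ in range(120):
                run_mcs(st, 300, rng=rng)
                d = min_image(st.positions[-1] - st.positions[0], 64)
                samples.append((d.astype(float) ** 2).sum())
            r2[n] = np.mean(samples)
        assert r2[16] / r2[8] > 2.0
        assert r2[32] / r2[16] > 2.0
        assert r2[32] / r2[8] > 4.4

    def test_detailed_balance_dimer_class_frequencies(self):
        # stationary distribution is uniform over reachable dimer states,
        # so bond-vector classes appear proportionally to their reachable
        # multiplicity; the reachable set comes from a BFS oracle
        allowed = allowed_bond_set()

        def neighbors(v):
            out = []
            for axis in range(3):
                for s in (1, -1):
                    w = list(v)
                    w[axis] += s
                    if tuple(w) in allowed:
                        out.append(tuple(w))
            return out

        start = (2, 0, 0)
        reach = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            for w in neighbors(v):
                if w not in reach:
                    reach.add(w)
                    stack.append(w)

        def vclass(v):
            return tuple(sorted(map(abs, v)))

        from collections import Counter
        mult = Counter(vclass(v) for v in reach)
        st = two_monomer_state((4, 4, 4), (6, 4, 4), box=8, bond=True)
        rng = np.random.default_rng(9)
        run_mcs(st, 500, rng=rng)
        counts = Counter()
        n_samples = 20_000
        for _ in range(n_samples):
            run_mcs(st, 25, rng=rng)
            d = tuple(min_image(st.positions[1] - st.positions[0], 8))
            assert d in reach
            counts[vclass(d)] += 1
        n_eff = n_samples / 2          # allowance for autocorrelation
        for cls, m in mult.items():
            p = m / len(reach)
            se = np.sqrt(p * (1 - p) / n_eff)
            assert abs(counts[cls] / n_samples - p) < 3 * se, cls


class TestContactEnergy:
    def test_no_peg_no_energy(self):
        st = linear_chain_state(5, 32, species="HEP")
        assert contact_energy(st, EnergyModel()) == 0.0

    def test_single_contact_pair(self):
        st = two_monomer_state((4, 4, 4), (6, 4, 4))
        assert contact_energy(st, EnergyModel(-0.30)) == pytest.approx(
            -0.30)

    def test_matches_bruteforce_double_loop(self):
        st = linear_chain_state(10, 64)
        energy = EnergyModel(-0.30)
        shell = {tuple(v) for v in energy.contact_shell.tolist()}
        total = 0.0
        pos = st.positions
        for i in range(10):
            for j in range(i + 1, 10):
                if tuple(min_image(pos[j] - pos[i], 64)) in shell:
                    total += energy.epsilon_pp
        assert contact_energy(st, energy) == pytest.approx(total)
        # after scrambling with dynamics the equality must still hold
        run_mcs(st, 2000, rng=4)
        total = 0.0
        pos = st.positions
        for i in range(10):
            for j in range(i + 1, 10):
                if tuple(min_image(pos[j] - pos[i], 64)) in shell:
                    total += energy.epsilon_pp
        assert contact_energy(st, energy) == pytest.approx(total)


class TestAudit:
    def test_overlap_detected(self):
        st = two_monomer_state((4, 4, 4), (5, 4, 4))
        with pytest.raises(AuditError):
            audit(st)

    def test_bad_bond_detected(self):
        st = two_monomer_state((4, 4, 4), (8, 4, 4), bond=True)
        with pytest.raises(AuditError):
            audit(st)

    def test_consumed_requires_reactive(self):
        st = two_monomer_state((4, 4, 4), (10, 4, 4))
        st.consumed[0] = True
        with pytest.raises(AuditError):
            audit(st)


class TestStateIO:
    def test_round_trip_bit_exact(self, tmp_path):
        from bfmgel.synthetic import fixture_network
        st, _ = fixture_network("mini_gel")
        p1 = tmp_path / "a.txt"
        p2 = tmp_path / "b.txt"
        write_state(st, p1)
        back = read_state(p1)
        write_state(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert np.array_equal(back.positions, st.positions)
        assert np.array_equal(back.bonds, st.bonds)
        assert np.array_equal(back.reactive, st.reactive)
        assert np.array_equal(back.consumed, st.consumed)

    def test_rejects_garbage(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("not a state\n")
        with pytest.raises(ValueError):
            read_state(p)
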