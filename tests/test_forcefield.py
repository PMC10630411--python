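"""Potential, forces, virial stress, neighbor list."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import silkcg as s
from silkcg.forcefield import (
    AngleParam,
    BondParam,
    DihedralParam,
    Evaluator,
    ExclusionPolicy,
    ForceField,
    NonFiniteEnergyError,
    PairParam,
    mix_pair,
    wrap_angle_deg,
)
from silkcg.units import KCAL_A3_TO_GPA

from conftest import random_chain_system


def two_bead_system(r, K=100.0, r0=3.8, box=30.0):
    topo = s.build_chain("GG")
    ff = ForceField(bonds={"1-2": BondParam(K, r0)}, cutoff=5.0)
    state = s.SimState(
        positions=np.array([[15.0, 15, 10], [15.0, 15, 10 + r]]),
        box=[box] * 3,
    )
    return topo, state, ff


class TestParams:
    def test_param_validation(self):
        with pytest.raises(ValueError):
            BondParam(-1.0, 3.8)
        with pytest.raises(ValueError):
            BondParam(10.0, 0.0)
        with pytest.raises(ValueError):
            AngleParam(1.0, 181.0)
        with pytest.raises(ValueError):
            DihedralParam(1.0, -180.0)
        with pytest.raises(ValueError):
            PairParam(0.5, -1.0)

    def test_cutoff_must_exceed_sigma(self):
        with pytest.raises(ValueError, match="cutoff"):
            ForceField(pairs={"G": PairParam(0.5, 13.0)}, cutoff=12.0)

    def test_wrap_angle(self):
        assert wrap_angle_deg(185.0) == pytest.approx(-175.0)
        assert wrap_angle_deg(-185.0) == pytest.approx(175.0)
        assert wrap_angle_deg(180.0) == 180.0
        assert wrap_angle_deg(540.0) == 180.0


class TestMixing:
    def test_geometric_mean_example(self):
        m = mix_pair(PairParam(1.0, 4.0), PairParam(4.0, 4.0))
        assert (m.epsilon, m.sigma) == (2.0, 4.0)

    def test_diagonal_idempotent(self):
        p = PairParam(0.7, 5.1)
        m = mix_pair(p, p)
        assert m.epsilon == pytest.approx(p.epsilon)
        assert m.sigma == pytest.approx(p.sigma)

    @settings(max_examples=50, deadline=None)
    @given(
        e1=st.floats(0.01, 10), s1=st.floats(1, 8),
        e2=st.floats(0.01, 10), s2=st.floats(1, 8),
    )
    def test_symmetry(self, e1, s1, e2, s2):
        a, b = PairParam(e1, s1), PairParam(e2, s2)
        ab, ba = mix_pair(a, b), mix_pair(b, a)
        assert ab.epsilon == pytest.approx(ba.epsilon)
        assert ab.sigma == pytest.approx(ba.sigma)


class TestTotalEnergy:
    def test_bond_at_equilibrium_gives_offset(self):
        topo, state, ff = two_bead_system(3.8)
        ff.energy_offset = 2.5
        comps = s.total_energy(state, topo, ff)
        assert comps.total == pytest.approx(2.5)
        assert comps.bond == pytest.approx(0.0)

    def test_lj_zero_crossing_at_sigma(self):
        topo = s.build_chain("GG")
        topo.bonds = []  # isolated non-bonded pair
        ff = ForceField(pairs={"G": PairParam(0.5, 5.0)}, cutoff=12.0)
        state = s.SimState(
            positions=np.array([[15.0, 15, 10], [15.0, 15, 15.0]]), box=[40.0] * 3
        )
        assert s.total_energy(state, topo, ff).vdw == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum_depth(self):
        topo = s.build_chain("GG")
        topo.bonds = []
        eps, sig = 0.5, 5.0
        ff = ForceField(pairs={"G": PairParam(eps, sig)}, cutoff=12.0)
        state = s.SimState(
            positions=np.array([[15.0, 15, 10], [15, 15, 10 + 2 ** (1 / 6) * sig]]),
            box=[40.0] * 3,
        )
        assert s.total_energy(state, topo, ff).vdw == pytest.approx(-eps)

    def test_overlap_raises(self):
        topo = s.build_chain("GG")
        topo.bonds = []
        ff = ForceField(pairs={"G": PairParam(0.5, 5.0)}, cutoff=12.0)
        state = s.SimState(
            positions=np.array([[15.0, 15, 10], [15.0, 15, 10]]), box=[40.0] * 3
        )
        with pytest.raises(NonFiniteEnergyError):
            s.total_energy(state, topo, ff)

    def test_translation_and_box_shift_invariance(self, short_seq, short_ff):
        topo, state = random_chain_system(short_seq, short_ff, seed=5)
        e0 = s.total_energy(state, topo, short_ff).total
        shifted = state.copy()
        shifted.positions = shifted.positions + np.array([3.1, -7.2, 11.9])
        assert s.total_energy(shifted, topo, short_ff).total == pytest.approx(
            e0, rel=1e-12
        )
        by_box = state.copy()
        by_box.positions = by_box.positions + by_box.box * np.array([2, -1, 3])
        assert s.total_energy(by_box, topo, short_ff).total == pytest.approx(
            e0, rel=1e-12
        )

    def test_rotation_invariance_free_cluster(self, short_seq, short_ff):
        from scipy.spatial.transform import Rotation

        topo, state = random_chain_system(short_seq, short_ff, seed=6)
        state.periodic = np.array([False, False, False])
        e0 = s.total_energy(state, topo, short_ff).total
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        state2 = state.copy()
        state2.positions = rot.apply(state2.positions)
        assert s.total_energy(state2, topo, short_ff).total == pytest.approx(
            e0, rel=1e-9
        )


class TestForces:
    def test_bond_at_equilibrium_zero_force(self):
        topo, state, ff = two_bead_system(3.8)
        f = s.forces(state, topo, ff)
        assert np.allclose(f, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_central_differences(self, short_seq, short_ff, seed):
        topo, state = random_chain_system(short_seq, short_ff, seed=seed)
        ev = Evaluator(topo, short_ff)
        _, f, _ = ev.evaluate(state)
        h = 1e-5
        scale = np.abs(f).max()
        for i in range(topo.n_beads):
            for a in range(3):
                state.positions[i, a] += h
                ep = ev.energy(state)
                state.positions[i, a] -= 2 * h
                em = ev.energy(state)
                state.positions[i, a] += h
                assert f[i, a] == pytest.approx(
                    -(ep - em) / (2 * h), abs=1e-6 * scale
                )

    def test_newtons_third_law(self, bundle16, masp1_ff):
        topo, state = bundle16
        f = s.forces(state, topo, masp1_ff)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9 * max(np.abs(f).max(), 1))

    def test_net_torque_vanishes_for_free_cluster(self, short_seq, short_ff):
        topo, state = random_chain_system(short_seq, short_ff, seed=9)
        state.periodic = np.array([False, False, False])
        f = s.forces(state, topo, short_ff)
        torque = np.cross(state.positions - state.positions.mean(axis=0), f).sum(axis=0)
        assert np.allclose(torque, 0.0, atol=1e-8 * max(np.abs(f).max(), 1))


class TestVirialStress:
    def test_single_bond_closed_form(self):
        K, r0, delta = 150.0, 3.8, 0.25
        topo, state, ff = two_bead_system(r0 + delta, K=K, r0=r0)
        sig = s.virial_stress(state, topo, ff)
        expected = 2 * K * delta * (r0 + delta) / state.volume * KCAL_A3_TO_GPA
        assert sig[2, 2] == pytest.approx(expected, rel=1e-12)
        assert sig[0, 0] == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("axis", [0, 1, 2])
    def test_matches_strain_derivative(self, short_seq, short_ff, axis):
        topo, state = random_chain_system(short_seq, short_ff, seed=3)
        ev = Evaluator(topo, short_ff)
        sig = ev.stress(state)
        h = 1e-6
        energies = []
        for sign in (1, -1):
            trial = state.copy()
            trial.box[axis] *= 1 + sign * h
            trial.positions[:, axis] *= 1 + sign * h
            energies.append(ev.energy(trial))
        fd = (energies[0] - energies[1]) / (2 * h) / state.volume * KCAL_A3_TO_GPA
        assert sig[axis, axis] == pytest.approx(fd, rel=1e-4)

    def test_multi_image_regime_matches_strain_derivative(
        self, bundle16_minimized, masp1_ff
    ):
        topo, state = bundle16_minimized
        ev = Evaluator(topo, masp1_ff)
        sig = ev.stress(state)
        h = 1e-6
        energies = []
        for sign in (1, -1):
            trial = state.copy()
            trial.box[2] *= 1 + sign * h
            trial.positions[:, 2] *= 1 + sign * h
            energies.append(ev.energy(trial))
        fd = (energies[0] - energies[1]) / (2 * h) / state.volume * KCAL_A3_TO_GPA
        assert sig[2, 2] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestNeighborList:
    def test_pair_within_cutoff_present(self):
        state = s.SimState(
            positions=np.array([[5.0, 5, 5], [5.0, 5, 5 + 0.9 * 10]]), box=[50.0] * 3
        )
        nl = s.build_neighbor_list(state, cutoff=10.0, skin=1.0)
        assert [tuple(p) for p in nl.pairs] == [(0, 1)]

    def test_pair_beyond_cutoff_plus_skin_absent(self):
        state = s.SimState(
            positions=np.array([[5.0, 5, 5], [5.0, 5, 5 + 11.2]]), box=[50.0] * 3
        )
        nl = s.build_neighbor_list(state, cutoff=10.0, skin=1.0)
        assert nl.pairs.shape[0] == 0

    def test_rebuild_on_large_displacement(self):
        state = s.SimState(
            positions=np.array([[5.0, 5, 5], [5.0, 5, 18.0]]), box=[50.0] * 3
        )
        nl = s.build_neighbor_list(state, cutoff=10.0, skin=2.0)
        assert nl.pairs.shape[0] == 0
        state.positions[1, 2] -= 8.0
        assert nl.update(state) is True
        assert nl.pairs.shape[0] == 1

    @pytest.mark.parametrize("seed", [0, 1])
    def test_energy_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        box = np.array([26.0, 30.0, 34.0])
        topo = s.build_chain("G" * n)
        topo.bonds, topo.angles, topo.dihedrals = [], [], []
        eps, sigma, cutoff = 0.4, 3.0, 8.0
        ff = ForceField(pairs={"G": PairParam(eps, sigma)}, cutoff=cutoff)
        # well-separated gas to keep energies finite
        pos = rng.uniform(0, box, (n, 3))
        state = s.SimState(positions=pos, box=box)
        e_nl = s.total_energy(state, topo, ff).vdw
        e_ref = 0.0
        for i in range(n):
            d = pos[i + 1 :] - pos[i]
            d -= box * np.round(d / box)
            r2 = (d * d).sum(axis=1)
            r2 = r2[r2 <= cutoff**2]
            sr6 = (sigma**2 / r2) ** 3
            e_ref += float((4 * eps * (sr6 * sr6 - sr6)).sum())
        assert e_nl == pytest.approx(e_ref, rel=1e-12, abs=1e-10)

    def test_small_box_multiple_images_match_brute_force(self):
        import itertools

        rng = np.random.default_rng(4)
        n = 30
        box = np.array([7.0, 8.0, 9.0])
        topo = s.build_chain("G" * n)
        topo.bonds, topo.angles, topo.dihedrals = [], [], []
        eps, sigma, cutoff = 0.3, 2.0, 3.5
        ff = ForceField(pairs={"G": PairParam(eps, sigma)}, cutoff=cutoff)
        pos = rng.uniform(0, box, (n, 3))
        state = s.SimState(positions=pos, box=box)
        e_nl = s.total_energy(state, topo, ff).vdw
        e_ref = 0.0
        for i in range(n):
            for j in range(i, n):
                for shift in itertools.product((-1, 0, 1), repeat=3):
                    if i == j and shift <= (0, 0, 0):
                        continue
                    d = pos[j] - pos[i] + np.array(shift) * box
                    r2 = float((d * d).sum())
                    if r2 <= cutoff**2:
                        sr6 = (sigma**2 / r2) ** 3
                        e_ref += 4 * eps * (sr6 * sr6 - sr6)
        assert e_nl == pytest.approx(e_ref, rel=1e-10)


class TestExclusions:
    def test_zero_epsilon_equals_exclusion(self, short_seq):
        # an excluded pair and an eps=0 pair contribute identically (zero)
        topo = s.build_chain(short_seq)
        state = s.chain_state(topo)
        base = dict(
            bonds={b.type_key: BondParam(100, 3.8) for b in topo.bonds},
            angles={a.type_key: AngleParam(20, 150) for a in topo.angles},
            dihedrals={d.type_key: DihedralParam(5, 170) for d in topo.dihedrals},
            cutoff=12.0,
        )
        with_13 = ForceField(
            pairs={c: PairParam(0.5, 4.5) for c in set(short_seq)},
            exclusions=ExclusionPolicy(exclude_13=True, exclude_14=False),
            **base,
        )
        e_excluded = s.total_energy(state, topo, with_13).total

        # separation-dependent check: disable 1-3 exclusion but set eps = 0
        # for every species, then add back the non-1-3 interactions by hand
        no_excl = ForceField(
            pairs={c: PairParam(0.5, 4.5) for c in set(short_seq)},
            exclusions=ExclusionPolicy(exclude_13=False, exclude_14=False),
            **base,
        )
        e_all = s.total_energy(state, topo, no_excl).total
        # manual 1-3 LJ sum (all species share parameters here)
        e13 = 0.0
        for a in topo.angles:
            d = state.positions[a.k] - state.positions[a.i]
            d -= state.box * np.round(d / state.box)
            r2 = float((d * d).sum())
            if r2 <= 12.0**2:
                sr6 = (4.5**2 / r2) ** 3
                e13 += 4 * 0.5 * (sr6 * sr6 - sr6)
        assert e_all - e13 == pytest.approx(e_excluded, rel=1e-10)

    def test_excluded_pairs_contribute_zero(self):
        # two bonded beads far inside the cutoff: only the bond counts
        topo, state, ff = two_bead_system(3.8)
        ff.pairs = {"G": PairParam(5.0, 4.5)}
        assert s.total_energy(state, topo, ff).vdw == 0.0
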