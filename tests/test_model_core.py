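"""Force-field unit tests: potentials, energies, neighbor search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chromkin as ck
from chromkin import model_core
from chromkin.state import E, H, SimulationState

WCA_CUT = 2.0 ** (1.0 / 6.0)


class TestPairPotential:
    @pytest.mark.parametrize(
        "mi, mj, r, expected",
        [
            (E, H, 1.5, 0.0),  # beyond the repulsive cutoff
            (E, H, WCA_CUT, 0.0),  # shifted WCA minimum touches zero
            (H, E, 3.0, 0.0),
        ],
    )
    def test_truncation_and_shift(self, mi, mj, r, expected, model_params):
        assert ck.pair_potential(mi, mj, r, model_params) == pytest.approx(expected, abs=1e-12)

    def test_hh_minimum_shifted_by_tail(self, model_params):
        # 4*eps*[r^-12 - r^-6] at the minimum is -eps; the shift removes
        # the tail value at the 2.5 sigma cutoff
        tail = 4.0 * (2.5**-12 - 2.5**-6)
        expected = -1.0 - tail
        assert ck.pair_potential(H, H, WCA_CUT, model_params) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(-0.9837, abs=5e-4)

    def test_symmetry_and_eps_ordering(self, model_params):
        rs = np.linspace(0.9, 2.4, 40)
        for r in rs:
            assert ck.pair_potential(E, H, r, model_params) == pytest.approx(
                ck.pair_potential(H, E, r, model_params)
            )
        v_hh = min(ck.pair_potential(H, H, r, model_params) for r in rs)
        v_ee = min(ck.pair_potential(E, E, r, model_params) for r in rs)
        v_eh = min(ck.pair_potential(E, H, r, model_params) for r in rs)
        assert v_hh < v_ee < 0.0 <= v_eh

    def test_continuity_at_cutoff(self, model_params):
        for mi, mj in [(E, E), (E, H), (H, H)]:
            cut = model_params.cut_matrix()[mi, mj]
            assert abs(ck.pair_potential(mi, mj, cut - 1e-9, model_params)) < 1e-6

    def test_invalid_distance(self, model_params):
        with pytest.raises(ValueError):
            ck.pair_potential(E, E, 0.0, model_params)


class TestBondPotential:
    def test_zero_extension(self, model_params):
        assert ck.bond_potential(0.0, model_params) == pytest.approx(0.0)

    def test_known_value(self, model_params):
        # FENE at r=0.9, K=30, R0=1.5: -0.5*30*2.25*ln(1-0.36); the call
        # also includes the WCA core of an E-E pair at 0.9
        fene = -0.5 * 30.0 * 2.25 * np.log(1.0 - 0.36)
        wca = 4 * 0.3 * (0.9**-12 - 0.9**-6) + 0.3
        assert fene == pytest.approx(15.06, abs=5e-3)
        assert ck.bond_potential(0.9, model_params) == pytest.approx(fene + wca, rel=1e-9)

    def test_divergence_near_r0(self, model_params):
        # logarithmic divergence as r -> R0
        v1 = ck.bond_potential(1.5 - 1e-4, model_params)
        v2 = ck.bond_potential(1.5 - 1e-9, model_params)
        assert v2 > v1 > 100.0

    def test_overextension_raises(self, model_params):
        with pytest.raises(ck.OverextensionError):
            ck.bond_potential(1.5, model_params)

    @given(r=st.floats(min_value=0.9, max_value=1.45))
    @settings(max_examples=30, deadline=None)
    def test_strictly_increasing_beyond_core(self, r):
        p = ck.ModelParams()
        assert ck.bond_potential(r + 0.01, p) > ck.bond_potential(r, p)


class TestNeighborList:
    def test_far_pair_empty(self):
        pos = np.array([[0, 0, 0], [5.0, 0, 0]])
        nl = ck.build_neighbor_list(pos, cutoff=2.5, skin=0.5)
        assert len(nl.pairs) == 0

    def test_collinear_chain(self):
        pos = np.array([[0, 0, 0], [2.25, 0, 0], [4.5, 0, 0]])
        nl = ck.build_neighbor_list(pos, cutoff=2.5, skin=0.0)
        assert {tuple(p) for p in nl.pairs} == {(0, 1), (1, 2)}

    def test_matches_brute_force(self, rng):
        pos = rng.uniform(0, 8, size=(200, 3))
        nl = ck.build_neighbor_list(pos, cutoff=2.5, skin=0.0)
        d = np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(-1))
        iu = np.triu_indices(200, k=1)
        brute = {(i, j) for i, j in zip(*iu) if d[i, j] < 2.5}
        assert {tuple(p) for p in nl.pairs} == brute

    def test_nonfinite_rejected(self):
        pos = np.array([[0, 0, 0], [np.nan, 0, 0]])
        with pytest.raises(ValueError):
            ck.build_neighbor_list(pos, cutoff=2.5)


class TestTotalEnergy:
    def test_two_distant_unbonded_beads(self, model_params):
        state = SimulationState(
            positions=np.array([[1.0, 1, 1], [6.0, 1, 1]]),
            marks=np.array([H, H], dtype=np.uint8),
        )
        b, nb, tot = ck.total_energy(state, model_params, bonds=np.empty((0, 2), dtype=int))
        assert (b, nb) == (0.0, 0.0)

    def test_isolated_bonded_pair(self, model_params):
        state = SimulationState(
            positions=np.array([[1.0, 1, 1], [2.0, 1, 1]]),
            marks=np.array([E, E], dtype=np.uint8),
        )
        b, nb, tot = ck.total_energy(state, model_params)
        expected_bond = model_core.bond_potential(1.0, model_params, E, E)
        assert b == pytest.approx(expected_bond, rel=1e-9)
        assert nb == 0.0  # the bonded pair is excluded from the nonbonded sum

    def test_neighbor_list_matches_all_pairs(self, model_params, rng):
        n = 50
        pos = rng.uniform(2, 10, size=(n, 3))
        # spread beads so bonds stay under the FENE limit
        pos = np.cumsum(rng.normal(scale=0.4, size=(n, 3)), axis=0)
        pos -= pos.min(axis=0) - 1.0
        pos = np.clip(pos, 0.0, None)
        # rescale consecutive distances to ~sigma
        for i in range(1, n):
            d = pos[i] - pos[i - 1]
            pos[i] = pos[i - 1] + d / np.linalg.norm(d)
        marks = rng.integers(0, 2, n).astype(np.uint8)
        state = SimulationState(positions=pos, marks=marks)
        params = ck.ModelParams(box_side=float(pos.max() + 5))
        nl = ck.build_neighbor_list(pos, params.cut_attractive, skin=0.3)
        res_nl = ck.total_energy(state, params, nl=nl)
        res_brute = ck.total_energy(state, params, nl=None)
        assert res_nl[2] == pytest.approx(res_brute[2], rel=1e-9)

    def test_stale_list_rejected(self, model_params):
        pos = np.array([[1.0, 1, 1], [2.0, 1, 1]])
        state = SimulationState(positions=pos + 3.0, marks=np.array([E, E], dtype=np.uint8))
        nl = ck.build_neighbor_list(pos, 2.5, skin=0.1)
        with pytest.raises(model_core.StaleNeighborListError):
            ck.total_energy(state, model_params, nl=nl)


class TestKernelAgreement:
    """The float32 production kernels must match the float64 references."""

    def _random_chain(self, rng, n=60):
        pos = np.zeros((n, 3))
        for i in range(1, n):
            v = rng.standard_normal(3)
            pos[i] = pos[i - 1] + v / np.linalg.norm(v)
        pos -= pos.min(axis=0) - 2.0
        marks = rng.integers(0, 2, n).astype(np.uint8)
        return pos, marks

    def test_forces_match_reference(self, rng):
        from chromkin import _kernels
        from chromkin.dynamics import _kernel_args

        pos, marks = self._random_chain(rng)
        params = ck.ModelParams(box_side=float(pos.max() + 5))
        box, per, eps, cut2, shift, K, R0, wca2 = _kernel_args(params, len(pos))
        nl = ck.build_neighbor_list(pos, params.cut_attractive, skin=0.4, box_side=box)
        ref = model_core.compute_forces(pos, marks, params, nl)

        pi = np.empty(4096, np.int32)
        pj = np.empty(4096, np.int32)
        m = _kernels.build_pairs(pos, (params.cut_attractive + 0.4) ** 2, box, per, pi, pj)
        f32 = np.empty((len(pos), 3), np.float32)
        code = _kernels._forces32(
            pos.astype(np.float32), marks, m, pi, pj,
            np.float32(eps[0, 0]), np.float32(eps[0, 1]), np.float32(eps[1, 1]),
            np.float32(cut2[0, 0]), np.float32(cut2[0, 1]), np.float32(cut2[1, 1]),
            np.float32(K), np.float32(R0), np.float32(wca2),
            np.float32(box), per, f32, np.float32(0.0),
        )
        assert code == 0
        scale = np.abs(ref).max() + 1.0
        assert np.allclose(f32, ref, atol=2e-3 * scale)

    def test_exchange_delta_e_matches_total_energy(self, rng):
        from chromkin.kinetics import swap_delta_energy

        pos, marks = self._random_chain(rng)
        params = ck.ModelParams(box_side=float(pos.max() + 5))
        state = SimulationState(positions=pos, marks=marks)
        i, j = 3, 40
        if marks[i] == marks[j]:
            marks[j] = 1 - marks[j]
        de = swap_delta_energy(state, i, j, params)
        e0 = ck.total_energy(state, params)[2]
        state.marks[i], state.marks[j] = state.marks[j], state.marks[i]
        e1 = ck.total_energy(state, params)[2]
        assert de == pytest.approx(e1 - e0, rel=1e-6, abs=1e-8)
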