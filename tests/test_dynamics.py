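"""Integrator and scheduler tests: drift, Einstein relation, conservation,
determinism, relaxation behaviour."""

import numpy as np
import pytest

import chromkin as ck
from chromkin.dynamics import brownian_step, run_protocol
from chromkin.params import Phase, Protocol
from chromkin.state import H, SimulationState


def _free_beads(n, spacing=50.0):
    """Beads far apart with no bonds: ideal Brownian particles."""
    side = spacing * (int(np.ceil(n ** (1 / 3))) + 1)
    g = int(np.ceil(n ** (1 / 3)))
    pts = []
    for i in range(g):
        for j in range(g):
            for k in range(g):
                pts.append([spacing * (i + 1), spacing * (j + 1), spacing * (k + 1)])
                if len(pts) == n:
                    break
            if len(pts) == n:
                break
        if len(pts) == n:
            break
    state = SimulationState(
        positions=np.array(pts), marks=np.zeros(n, dtype=np.uint8)
    )
    params = ck.ModelParams(box_side=side + spacing)
    return state, params, np.empty((0, 2), dtype=int)


class TestBrownianStep:
    def test_no_force_no_noise_is_identity(self, rng):
        state, params, bonds = _free_beads(8)
        dyn = ck.DynamicsParams()
        new = brownian_step(state, params, dyn, rng, noise=False, bonds=bonds)
        assert np.allclose(new.positions, state.positions)
        assert new.step == state.step + 1

    def test_constant_force_overdamped_drift(self, rng):
        state, params, bonds = _free_beads(4)
        dyn = ck.DynamicsParams()
        f = np.zeros((4, 3))
        f[:, 0] = 2.0
        new = brownian_step(state, params, dyn, rng, noise=False, external_force=f, bonds=bonds)
        expected = dyn.mobility * 2.0 * dyn.dt_reduced
        assert np.allclose(new.positions[:, 0] - state.positions[:, 0], expected)

    def test_einstein_relation_msd(self, rng):
        """MSD of free beads after n steps is 6 D n dt within 3 SE."""
        n_beads, n_steps = 1500, 40
        state, params, bonds = _free_beads(n_beads, spacing=20.0)
        dyn = ck.DynamicsParams()
        start = state.positions.copy()
        for _ in range(n_steps):
            state = brownian_step(state, params, dyn, rng, bonds=bonds)
        sq = ((state.positions - start) ** 2).sum(axis=1)
        expected = 6.0 * dyn.d_bead * n_steps * dyn.dt_reduced
        se = sq.std(ddof=1) / np.sqrt(n_beads)
        assert abs(sq.mean() - expected) < 3 * se


class TestRunProtocol:
    def test_zero_steps_single_frame(self, small_relaxed):
        track, state, params, dyn = small_relaxed
        proto = Protocol([Phase(n_steps=0, frame_stride=100)])
        traj = run_protocol(state.copy(), params, dyn, proto, seed=5)
        assert traj.n_frames == 1
        assert np.array_equal(traj.marks[0], state.marks)

    def test_kawasaki_conservation_exact(self, small_relaxed):
        track, state, params, dyn = small_relaxed
        proto = Protocol([Phase(n_steps=3000, gamma_ac=0.0, gamma_me=0.0, frame_stride=500)])
        traj = run_protocol(state.copy(), params, dyn, proto, seed=6)
        h_counts = (traj.marks == H).sum(axis=1)
        assert (h_counts == h_counts[0]).all()
        # exchange actually happened (marks permuted), not a frozen run
        assert any(
            not np.array_equal(traj.marks[i], traj.marks[0]) for i in range(1, traj.n_frames)
        )

    def test_determinism_same_seed(self, small_relaxed):
        track, state, params, dyn = small_relaxed
        proto = Protocol([Phase(n_steps=1500, gamma_ac=1.0, gamma_me=1.0, frame_stride=300)])
        t1 = run_protocol(state.copy(), params, dyn, proto, seed=42)
        t2 = run_protocol(state.copy(), params, dyn, proto, seed=42)
        assert np.array_equal(t1.marks, t2.marks)
        assert np.array_equal(t1.positions, t2.positions)
        t3 = run_protocol(state.copy(), params, dyn, proto, seed=43)
        assert not np.array_equal(t1.positions, t3.positions)

    def test_frames_strictly_increasing_and_final_state_recorded(self, small_relaxed):
        track, state, params, dyn = small_relaxed
        proto = Protocol([Phase(n_steps=1050, frame_stride=500)])
        traj = run_protocol(state.copy(), params, dyn, proto, seed=1)
        assert (np.diff(traj.steps) > 0).all()
        assert traj.steps[-1] == state.step + 1050

    def test_composition_relaxes_to_rate_ratio(self, small_relaxed):
        """H fraction drifts toward gamma_me/(gamma_me+gamma_ac)."""
        track, state, params, dyn = small_relaxed
        # strong methylation: target H fraction 0.8, start at 0.5
        proto = Protocol([
            Phase(n_steps=30_000, gamma_ac=1.0, gamma_me=4.0, reaction_every=50, frame_stride=3000)
        ])
        traj = run_protocol(state.copy(), params, dyn, proto, seed=9)
        h_frac = (traj.marks == H).mean(axis=1)
        assert h_frac[-1] > h_frac[0] + 0.1
        assert abs(h_frac[-1] - 0.8) < 0.15


class TestRelax:
    def test_energy_decreases_from_stretched_chain(self):
        n = 50
        track = ck.make_prototype_track(n, 0.5, 5.0, seed=2)
        params = ck.ModelParams(box_side=60.0)
        pos = np.zeros((n, 3))
        pos[:, 0] = 5.0 + 1.35 * np.arange(n)  # stretched bonds, high FENE energy
        pos[:, 1] = pos[:, 2] = 30.0
        state = SimulationState(positions=pos, marks=track.marks.copy())
        e0 = ck.total_energy(state, params)[2]
        dyn = ck.DynamicsParams()
        relaxed, _ = ck.relax(state, params, dyn, max_steps=4000, block_steps=1000, seed=3)
        e1 = ck.total_energy(relaxed, params)[2]
        assert e1 < e0

    def test_relaxed_state_plateaus_quickly(self, small_relaxed):
        track, state, params, dyn = small_relaxed
        _, plateaued = ck.relax(
            state.copy(), params, dyn, max_steps=6000, block_steps=1500, seed=11
        )
        assert plateaued

    def test_genomic_spatial_curve_concave_after_relaxation(self, small_relaxed):
        """Mean spatial distance grows sublinearly with genomic separation."""
        track, state, params, dyn = small_relaxed
        proto = Protocol([Phase(n_steps=2000, exchange_every=0, frame_stride=500)])
        traj = run_protocol(state.copy(), params, dyn, proto, seed=13)
        sep, curve = ck.genomic_spatial_curve(traj)
        n = len(sep)
        # growth at short separations, plateau at long ones
        assert curve[5] > curve[1]
        short_slope = (curve[10] - curve[1]) / 9
        long_slope = (curve[n // 2 + 20] - curve[n // 2]) / 20 if n // 2 + 20 < n else 0.0
        assert long_slope < short_slope

    def test_checkerboard_direction_in_contacts(self, small_relaxed):
        """Within-type contacts beat between-type after phase separation."""
        from chromkin.analysis import checkerboard_contrast, distance_and_contact_maps

        track, state, params, dyn = small_relaxed
        proto = Protocol([Phase(n_steps=4000, frame_stride=800)])
        traj = run_protocol(state.copy(), params, dyn, proto, seed=17)
        _, cont = distance_and_contact_maps(traj, r_contact=2.0)
        assert checkerboard_contrast(cont, traj.marks[-1]) > 1.0


class TestFreeChainScaling:
    def test_self_avoiding_swelling_exponent(self):
        """End-to-end exponent >= 0.5 with attraction tails cut off (pure WCA):
        shrinking the like-pair cutoff to the potential minimum leaves only
        excluded volume."""
        params = ck.ModelParams(eps_EE=0.3, eps_EH=1.0, eps_HH=1.0,
                                cut_attractive=1.1226, density=0.002)
        dyn = ck.DynamicsParams()
        sizes = [32, 64, 128]
        r2_means = []
        for n in sizes:
            track = ck.make_prototype_track(n, 0.0, 5.0, seed=n)
            vals = []
            for seed in range(3):
                state = ck.init_conformation(track, params, np.random.default_rng(seed))
                state, _ = ck.relax(state, params, dyn, max_steps=4000, block_steps=2000, seed=seed)
                proto = Protocol([Phase(n_steps=4000, exchange_every=0, frame_stride=400)])
                traj = run_protocol(state, params, dyn, proto, seed=seed + 100)
                ee = np.linalg.norm(
                    traj.positions[:, -1].astype(float) - traj.positions[:, 0].astype(float),
                    axis=1,
                )
                vals.append((ee**2).mean())
            r2_means.append(np.mean(vals))
        slope = np.polyfit(np.log(sizes), np.log(r2_means), 1)[0]
        assert slope / 2.0 >= 0.5
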