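"""Trajectory-statistic tests with brute-force oracles."""

import numpy as np
import pytest

import chromkin as ck
from chromkin import analysis
from chromkin.state import E, H, Trajectory


def _traj_from_frames(pos_frames, marks_frames, labels=None):
    f = len(pos_frames)
    return Trajectory(
        positions=np.asarray(pos_frames, dtype=np.float32),
        marks=np.asarray(marks_frames, dtype=np.uint8),
        steps=np.arange(f, dtype=np.int64),
        times=np.arange(f, dtype=float),
        labels=None if labels is None else np.asarray(labels, dtype=np.int32),
    )


class TestRadiusOfGyration:
    def test_single_point(self):
        assert ck.radius_of_gyration([[1.0, 2, 3]]) == 0.0

    def test_two_points(self):
        assert ck.radius_of_gyration([[0, 0, 0], [2.0, 0, 0]]) == pytest.approx(1.0)

    def test_unit_square(self):
        pts = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]
        assert ck.radius_of_gyration(pts) == pytest.approx(np.sqrt(0.5))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ck.radius_of_gyration(np.empty((0, 3)))


class TestDetectDomains:
    def test_pair_domain(self):
        pos = np.array([[0, 0, 0], [0.5, 0, 0], [9, 9, 9]])
        marks = np.array([H, H, E], np.uint8)
        ds = ck.detect_domains(pos, marks, r_c=1.8, min_size=2)
        assert len(ds.clusters) == 1 and set(ds.clusters[0]) == {0, 1}

    def test_all_e_no_domains(self, rng):
        ds = ck.detect_domains(rng.uniform(0, 5, (20, 3)), np.zeros(20, np.uint8))
        assert ds.clusters == []

    def test_matches_brute_force_union_find(self, rng):
        n = 100
        pos = rng.uniform(0, 6, (n, 3))
        marks = np.ones(n, np.uint8)
        r_c = 1.3
        ds = ck.detect_domains(pos, marks, r_c=r_c, min_size=2)
        # brute-force connected components over the all-pairs distance matrix
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        d = np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(-1))
        for i in range(n):
            for j in range(i + 1, n):
                if d[i, j] < r_c:
                    parent[find(i)] = find(j)
        from collections import defaultdict

        comps = defaultdict(set)
        for i in range(n):
            comps[find(i)].add(i)
        brute = {frozenset(c) for c in comps.values() if len(c) >= 2}
        assert {frozenset(c.tolist()) for c in ds.clusters} == brute


class TestDomainRadiusSeries:
    def test_two_bead_domain(self):
        traj = _traj_from_frames(
            [[[0, 0, 0], [1.0, 0, 0]]], [[H, H]],
        )
        stats = ck.domain_radius_series(traj, r_c=1.8, min_size=2)
        assert stats.mean_rd[0] == pytest.approx(0.5)

    def test_two_rigid_clusters_closed_form(self):
        # cluster A: unit square (Rg = sqrt(0.5)); cluster B: two beads 1 apart (Rg = 0.5)
        pos = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [20, 0, 0], [21, 0, 0]]
        traj = _traj_from_frames([pos], [[H] * 6])
        stats = ck.domain_radius_series(traj, r_c=1.8, min_size=2)
        assert stats.mean_rd[0] == pytest.approx((np.sqrt(0.5) + 0.5) / 2)
        assert stats.mean_rd_bead_weighted[0] == pytest.approx(
            (4 * np.sqrt(0.5) + 2 * 0.5) / 6
        )

    def test_empty_frames_flagged_nan(self):
        traj = _traj_from_frames([[[0, 0, 0], [5, 5, 5]]], [[E, E]])
        stats = ck.domain_radius_series(traj, min_size=2)
        assert np.isnan(stats.mean_rd[0])
        with pytest.raises(ValueError):
            stats.steady_state_mean()


class TestKymographAndConservation:
    def test_kymograph_shape_and_column_sums(self, rng):
        marks = rng.integers(0, 2, (5, 12)).astype(np.uint8)
        traj = _traj_from_frames(np.zeros((5, 12, 3)), marks)
        k = ck.kymograph(traj)
        assert k.shape == (12, 5)
        assert np.array_equal(k.sum(axis=0), marks.sum(axis=1))

    def test_single_flip_at_frame(self):
        marks = np.zeros((4, 3), np.uint8)
        marks[2:, 1] = H
        traj = _traj_from_frames(np.zeros((4, 3, 3)), marks)
        k = ck.kymograph(traj)
        assert list(k[1]) == [0, 0, 1, 1]

    @pytest.mark.parametrize(
        "a, b, expected",
        [([H, H], [H, H], 1.0), ([H, E], [E, H], 0.0), ([H, H, E, E], [H, H, E, H], 0.75)],
    )
    def test_conservation_fraction(self, a, b, expected):
        assert ck.conservation_fraction(a, b) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ck.conservation_fraction([H], [H, E])


class TestFlippingScore:
    def test_full_flip_significant(self):
        init = np.array([H], np.uint8)
        finals = np.zeros((10, 1), np.uint8)  # all end E
        res = ck.flipping_score(init, finals)
        assert res.scores[0] == pytest.approx(2.0)
        assert res.significant[0]

    def test_no_flip_zero(self):
        init = np.array([E, H], np.uint8)
        res = ck.flipping_score(init, np.tile(init, (5, 1)))
        assert np.allclose(res.scores, 0.0)

    def test_boundary_convention_strict(self):
        init = np.array([E], np.uint8)
        finals6 = np.array([[H]] * 6 + [[E]] * 4, np.uint8)
        res6 = ck.flipping_score(init, finals6)
        assert res6.scores[0] == pytest.approx(-1.2)
        assert res6.significant[0]
        finals5 = np.array([[H]] * 5 + [[E]] * 5, np.uint8)
        res5 = ck.flipping_score(init, finals5)
        assert res5.scores[0] == pytest.approx(-1.0)
        assert not res5.significant[0]  # strict inequality at the threshold

    def test_sign_convention(self):
        init = np.array([H, E], np.uint8)
        finals = np.array([[E, H]], np.uint8)
        res = ck.flipping_score(init, finals)
        assert res.scores[0] > 0 and res.scores[1] < 0

    def test_averaging_suppresses_sporadic_flips(self, rng):
        """Adding flip-free replicates weakly shrinks the significant set."""
        init = rng.integers(0, 2, 50).astype(np.uint8)
        flips = (rng.random((4, 50)) < 0.4).astype(np.uint8)
        finals = np.where(flips, 1 - init[None, :], init[None, :]).astype(np.uint8)
        quiet = np.tile(init, (8, 1))
        frac_few = ck.flipping_score(init, finals).significant_fraction
        frac_many = ck.flipping_score(init, np.vstack([finals, quiet])).significant_fraction
        assert frac_many <= frac_few

    def test_replicate_length_mismatch(self):
        with pytest.raises(ValueError):
            ck.flipping_score(np.zeros(3, np.uint8), np.zeros((2, 4), np.uint8))


class TestClassifyMemory:
    def _kymo(self, rows):
        return np.asarray(rows, dtype=np.uint8)

    def test_three_classes(self):
        times = np.arange(5.0)  # t' = 2, 2t' = 4
        kymo = self._kymo([
            [H, H, H, H, H],  # conserved
            [H, E, E, E, E],  # memory: flips in phase 1, never returns
            [H, E, E, H, H],  # recovered
            [H, H, H, E, E],  # flips only in phase 2 -> other
        ])
        res = ck.classify_memory(kymo, times, t_prime=2.0)
        assert list(res.labels) == ["conserved", "memory", "recovered", "other"]
        assert res.counts == {"conserved": 1, "memory": 1, "recovered": 1, "other": 1}

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            ck.classify_memory(self._kymo([[H, H]]), np.array([0.0, 1.0]), 0.5)


class TestMapsAndCurves:
    def test_frozen_pair(self):
        traj = _traj_from_frames(
            [[[0, 0, 0], [1.0, 0, 0]]] * 3, [[H, E]] * 3
        )
        dist, cont = ck.distance_and_contact_maps(traj, r_contact=2.0)
        assert dist[0, 1] == pytest.approx(1.0)
        assert cont[0, 1] == 1.0
        assert dist[0, 0] == 0.0 and cont[0, 0] == 1.0

    def test_matches_single_frame_brute_force(self, rng):
        pos = rng.uniform(0, 4, (30, 3))
        traj = _traj_from_frames([pos], [np.zeros(30)])
        dist, cont = ck.distance_and_contact_maps(traj, r_contact=1.5)
        d = np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(-1))
        off = ~np.eye(30, dtype=bool)
        assert np.allclose(dist[off], d[off], atol=1e-5)
        assert np.array_equal(cont[off] > 0.5, d[off] < 1.5)

    def test_genomic_spatial_curve_oracle(self, rng):
        n = 50
        pos = np.cumsum(rng.standard_normal((n, 3)), axis=0)
        traj = _traj_from_frames([pos], [np.zeros(n)])
        sep, curve = ck.genomic_spatial_curve(traj)
        assert curve[0] == 0.0
        d = np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(-1))
        for s in (1, 7, 25):
            expected = np.mean([d[i, i + s] for i in range(n - s)])
            assert curve[s] == pytest.approx(expected, rel=1e-5)

    def test_two_bead_chain_curve(self):
        traj = _traj_from_frames([[[0, 0, 0], [1.0, 0, 0]]], [[E, E]])
        _, curve = ck.genomic_spatial_curve(traj)
        assert curve[1] == pytest.approx(1.0)


class TestBoundaryStats:
    def _track(self, marks):
        from chromkin.genome_io import CompartmentTrack

        return CompartmentTrack(chrom="c", marks=np.array(marks, np.uint8))

    def test_adjacent_bead_distance_zero(self):
        track = self._track([H, H, E, E])
        res = ck.boundary_distance_stats(track, [1], window_bp=10_000)
        assert res["distances_bp"][0] == 0.0

    def test_toy_track_all_within_window(self):
        track = self._track([H, H, E, E, H])
        res = ck.boundary_distance_stats(track, [2, 3], window_bp=10_000)
        assert res["fraction_within_window"] == 1.0

    def test_block_center_flips_outside_one_bin(self):
        marks = ([H] * 21 + [E] * 21) * 5
        track = self._track(marks)
        centers = [10 + 42 * k for k in range(5)]
        res = ck.boundary_distance_stats(track, centers, window_bp=10_000)
        assert res["fraction_within_window"] == 0.0

    def test_uniform_track_raises(self):
        with pytest.raises(ValueError):
            ck.boundary_distance_stats(self._track([H, H, H]), [0])

    def test_enrichment_detects_boundary_concentration(self):
        marks = ([H] * 20 + [E] * 20) * 6
        track = self._track(marks)
        bounds_bins = np.flatnonzero(np.diff(track.marks.astype(np.int8)) != 0)
        flipped = np.concatenate([bounds_bins, bounds_bins + 1])
        res = ck.boundary_enrichment_test(track, flipped, n_permutations=500, seed=1)
        assert res["p_value"] < 0.05
        assert res["median_bp"] <= res["null_median_bp"]


class TestScalingFit:
    def test_exact_linear_records(self):
        recs = [
            analysis.ScalingRecord(d_eff=d, gamma_ac=1.0, gamma_me=1.5, mean_rd=2.0 * np.sqrt(d / 1.0 * 1.5 / 2.5))
            for d in (0.5, 1.0, 2.0, 4.0)
        ]
        fit = ck.fit_domain_scaling(recs)
        assert fit["slope"] == pytest.approx(2.0)
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_doubling_d_scales_sqrt2(self):
        r1 = analysis.ScalingRecord(1.0, 1.0, 1.5, 1.0)
        r2 = analysis.ScalingRecord(2.0, 1.0, 1.5, 1.0)
        assert r2.predictor / r1.predictor == pytest.approx(np.sqrt(2.0))

    def test_degenerate_predictor(self):
        recs = [analysis.ScalingRecord(1.0, 1.0, 1.0, r) for r in (1.0, 2.0, 3.0)]
        with pytest.raises(ValueError):
            ck.fit_domain_scaling(recs)
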