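"""Tank and pair geometry: wall impacts, stimulus angles, neighbor graphs."""

import numpy as np
import pytest

from ptwschool import (FishState, TankGeometry, neighbor_graph, pair_stimuli,
                       wall_impact, wrap_angle)
from ptwschool.geometry import pair_stimuli_arrays, wall_impact_arrays


def random_interior_states(rng, n, radius=2.0, margin=1e-3):
    r = (radius - margin) * np.sqrt(rng.random(n))
    a = rng.uniform(-np.pi, np.pi, n)
    pos = np.stack([r * np.cos(a), r * np.sin(a)], axis=1)
    headings = rng.uniform(-np.pi, np.pi, n)
    return pos, headings


class TestWrapAngle:
    def test_interval_is_half_open(self):
        assert wrap_angle(np.pi) == pytest.approx(np.pi)
        assert wrap_angle(-np.pi) == pytest.approx(np.pi)
        assert wrap_angle(3 * np.pi) == pytest.approx(np.pi)

    def test_idempotent_on_range(self, rng):
        a = rng.uniform(-np.pi + 1e-9, np.pi, 100)
        np.testing.assert_allclose(wrap_angle(a), a, atol=1e-15)


class TestWallImpact:
    @pytest.mark.parametrize("heading", [0.0, 1.1, -2.5, np.pi])
    def test_center_is_radial(self, tank, heading):
        ws = wall_impact(FishState([0, 0], heading, 0, 0.5), tank)
        assert ws.dist_to_impact == pytest.approx(2.0)
        assert ws.angle_to_normal == pytest.approx(0.0)
        assert ws.time_to_impact == pytest.approx(4.0)

    def test_head_on_ray(self, tank):
        ws = wall_impact(FishState([1.0, 0.0], 0.0, 0, 0.5), tank)
        assert ws.dist_to_impact == pytest.approx(1.0)
        assert ws.angle_to_normal == pytest.approx(0.0)

    def test_worked_example(self, tank):
        # fish at (1, 0) heading +y in an R=2 tank: impact at (1, sqrt(3))
        ws = wall_impact(FishState([1.0, 0.0], np.pi / 2, 0, 0.5), tank)
        assert ws.dist_to_impact == pytest.approx(np.sqrt(3.0), abs=1e-12)
        assert ws.angle_to_normal == pytest.approx(np.pi / 6, abs=1e-12)

    def test_quadratic_formula_oracle(self, tank, rng):
        # independent ray-circle solution on 10^4 random interior states
        pos, th = random_interior_states(rng, 10_000)
        lam, thw, tti = wall_impact_arrays(pos, th, np.full(len(pos), 0.5), tank)
        assert np.all(lam > 0)
        h = np.stack([np.cos(th), np.sin(th)], axis=1)
        a, b, c = 1.0, 2 * np.sum(pos * h, axis=1), np.sum(pos**2, axis=1) - 4.0
        lam_oracle = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
        np.testing.assert_allclose(lam, lam_oracle, atol=1e-12)
        impact = pos + lam[:, None] * h
        np.testing.assert_allclose(np.hypot(*impact.T), 2.0, atol=1e-12)
        assert np.all(np.abs(thw) < np.pi / 2)

    def test_position_outside_is_error(self, tank):
        with pytest.raises(ValueError, match="outside"):
            wall_impact(FishState([2.5, 0.0], 0.0, 0, 0.5), tank)
        with pytest.raises(ValueError, match="outside"):
            wall_impact(FishState([2.0, 0.0], 0.0, 0, 0.5), tank)

    def test_unbounded_tank_unsupported(self):
        open_tank = TankGeometry(radius=2.0, bounded=False)
        with pytest.raises(ValueError, match="unbounded"):
            wall_impact(FishState([0, 0], 0.0, 0, 0.5), open_tank)


class TestPairStimuli:
    def test_directly_ahead(self):
        i = FishState([0, 0], 0.0, 0, 0.5)
        j = FishState([1, 0], 0.0, 0, 0.5)
        ps = pair_stimuli(i, j)
        assert (ps.distance, ps.bearing, ps.heading_diff) == (1.0, 0.0, 0.0)

    def test_left_of_focal_is_positive_bearing(self):
        ps = pair_stimuli(FishState([0, 0], 0.0, 0, 0.5),
                          FishState([0, 1], 0.0, 0, 0.5))
        assert ps.distance == pytest.approx(1.0)
        assert ps.bearing == pytest.approx(np.pi / 2)
        assert ps.heading_diff == pytest.approx(0.0)

    def test_worked_example(self):
        ps = pair_stimuli(FishState([0, 0], 0.0, 0, 0.5),
                          FishState([3, 4], np.pi, 0, 0.5))
        assert ps.distance == pytest.approx(5.0)
        assert ps.bearing == pytest.approx(np.arctan2(4, 3))
        assert ps.heading_diff == pytest.approx(np.pi)

    def test_coincident_positions_flagged(self):
        with pytest.warns(UserWarning, match="coincident"):
            ps = pair_stimuli(FishState([1, 1], 0.3, 0, 0.5),
                              FishState([1, 1], 1.0, 0, 0.5))
        assert ps.coincident and ps.bearing == 0.0 and ps.distance == 0.0

    def test_heading_diff_antisymmetry(self, rng):
        for _ in range(20):
            a = FishState(rng.normal(size=2), rng.uniform(-np.pi, np.pi), 0, 0.5)
            b = FishState(rng.normal(size=2), rng.uniform(-np.pi, np.pi), 0, 0.5)
            assert pair_stimuli(a, b).heading_diff == pytest.approx(
                wrap_angle(-pair_stimuli(b, a).heading_diff))

    def test_frame_invariance_under_rotation(self, rng):
        pos, th = random_interior_states(rng, 12)
        d0, psi0, phi0 = pair_stimuli_arrays(pos, th)
        beta = 1.2345
        R = np.array([[np.cos(beta), -np.sin(beta)], [np.sin(beta), np.cos(beta)]])
        d1, psi1, phi1 = pair_stimuli_arrays(pos @ R.T, th + beta)
        np.testing.assert_allclose(d1, d0, atol=1e-12)
        np.testing.assert_allclose(np.sin(psi1), np.sin(psi0), atol=1e-12)
        np.testing.assert_allclose(np.sin(phi1), np.sin(phi0), atol=1e-12)


def brute_force_voronoi_adjacent(pos, i, j):
    """Exact 1D feasibility test: cells i and j share an edge iff some point
    of the (i, j) bisector is at least as close to them as to every other
    site, with nonempty interior."""
    m = (pos[i] + pos[j]) / 2
    d = pos[j] - pos[i]
    t_dir = np.array([-d[1], d[0]])
    t_dir = t_dir / np.linalg.norm(t_dir)
    lo, hi = -1e9, 1e9
    for k in range(len(pos)):
        if k in (i, j):
            continue
        # |x - p_i|^2 <= |x - p_k|^2 is linear in t for x = m + t * t_dir:
        # A t <= B with the coefficients below
        A = 2.0 * t_dir @ (pos[k] - pos[i])
        B = (pos[k] @ pos[k] - pos[i] @ pos[i]) - 2.0 * m @ (pos[k] - pos[i])
        if abs(A) < 1e-14:
            if B < 0:
                return False
            continue
        if A > 0:
            hi = min(hi, B / A)
        else:
            lo = max(lo, B / A)
    return hi - lo > 1e-9


class TestNeighborGraph:
    def test_two_points_any_method(self):
        pos = [[0, 0], [1, 0]]
        for method, k in (("all", None), ("voronoi_shell1", None), ("knn", 1)):
            g = neighbor_graph(pos, method, k)
            assert list(g.counts) == [1, 1]
            assert g.neighbors(0).tolist() == [1]

    def test_triangle_is_complete(self):
        g = neighbor_graph([[0, 0], [1, 0], [0.3, 0.9]], "voronoi_shell1")
        assert g.adjacency.sum() == 6

    def test_all_to_all_counts(self):
        g = neighbor_graph(np.random.default_rng(0).normal(size=(7, 2)), "all")
        assert np.all(g.counts == 6)

    @pytest.mark.parametrize("seed", range(8))
    def test_voronoi_against_bisector_oracle(self, seed):
        pos = np.random.default_rng(seed).uniform(-1, 1, size=(6, 2))
        g = neighbor_graph(pos, "voronoi_shell1")
        for i in range(6):
            for j in range(i + 1, 6):
                assert g.adjacency[i, j] == brute_force_voronoi_adjacent(pos, i, j), \
                    f"pair ({i},{j}) disagrees with the half-plane oracle"

    def test_voronoi_symmetric_knn_directed(self, rng):
        pos = rng.normal(size=(10, 2))
        gv = neighbor_graph(pos, "voronoi_shell1")
        assert np.array_equal(gv.adjacency, gv.adjacency.T)
        gk = neighbor_graph(pos, "knn", 3)
        assert np.all(gk.counts == 3)  # directed: row counts fixed, columns not

    def test_knn_k_capped(self):
        g = neighbor_graph([[0, 0], [1, 0], [2, 0]], "knn", 10)
        assert np.all(g.counts == 2)

    def test_collinear_chain_fallback(self):
        pos = np.array([[0.0, 0.0], [3.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        g = neighbor_graph(pos, "voronoi_shell1")
        # sorted along the line: 0-2-3-1
        assert g.neighbors(0).tolist() == [2]
        assert sorted(g.neighbors(2).tolist()) == [0, 3]
        assert sorted(g.neighbors(3).tolist()) == [1, 2]

    def test_duplicates_rejected_under_voronoi(self):
        with pytest.raises(ValueError, match="duplicate"):
            neighbor_graph([[0, 0], [0, 0], [1, 1], [2, 0]], "voronoi_shell1")

    def test_single_point_is_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            neighbor_graph([[0, 0]], "all")
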