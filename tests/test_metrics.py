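"""Eye-movement variables: FDM, entropies, transitions, center bias,
summaries and aggregation."""

import math

import numpy as np
import pytest
from scipy import integrate

from aerialgaze.metrics import (
    AOITransition,
    aggregate,
    aoi_index,
    build_fdm,
    build_transitions,
    center_bias,
    expected_uniform_center_distance,
    fdm_entropy,
    gaze_transition_entropy,
    records_to_frame,
    summarize,
)
from conftest import make_fixation, make_saccade, make_trial


class TestFDM:
    def test_single_fixation_peak_and_mass(self):
        fdm = build_fdm([make_fixation(300, 300)], (600, 600))
        assert fdm.grid.sum() == pytest.approx(1.0, abs=1e-12)
        r, c = np.unravel_index(np.argmax(fdm.grid), fdm.grid.shape)
        assert (r, c) == (300, 300)

    def test_mirror_symmetry(self):
        fdm = build_fdm(
            [make_fixation(200, 300), make_fixation(399, 300)], (600, 600)
        )
        np.testing.assert_allclose(fdm.grid, fdm.grid[:, ::-1], atol=1e-12)

    def test_edge_truncation_renormalized(self):
        # kernel clipped at the image border still yields unit mass
        fdm = build_fdm(
            [make_fixation(2, 2), make_fixation(599, 0), make_fixation(300, 300)],
            (600, 600),
        )
        assert fdm.grid.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_fixations_error(self):
        with pytest.raises(ValueError):
            build_fdm([], (600, 600))


class TestFDMEntropy:
    def test_point_mass_zero_bits(self):
        g = np.zeros((10, 10))
        g[3, 4] = 1.0
        assert fdm_entropy(g) == 0.0

    def test_uniform_map_analytic(self):
        g = np.full((600, 600), 1.0 / 360000.0)
        assert fdm_entropy(g) == pytest.approx(math.log2(360000), rel=1e-12)

    def test_three_pixel_analytic(self):
        g = np.zeros((5, 5))
        g[0, 0], g[1, 1], g[2, 2] = 0.5, 0.25, 0.25
        assert fdm_entropy(g) == pytest.approx(1.5, abs=1e-12)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            fdm_entropy(np.full((4, 4), 1.0))


class TestTransitions:
    def test_single_aoi_self_transition(self):
        fixes = [make_fixation(10 + k, 10, onset=k * 100.0) for k in range(5)]
        t = build_transitions(fixes, n_segments=6, image_size_px=(600, 600))
        assert t.v[0] == 1.0
        assert t.M[0, 0] == 1.0
        assert gaze_transition_entropy(t) == 0.0

    def test_alternating_two_aois_hand_count(self):
        # A,B,A,B over two AOIs: v = (1/2, 1/2); rows deterministic
        a, b = (10, 10), (590, 10)
        fixes = [
            make_fixation(*p, onset=k * 100.0)
            for k, p in enumerate([a, b, a, b])
        ]
        t = build_transitions(fixes, n_segments=6, image_size_px=(600, 600))
        ia = aoi_index(*a, 6, (600, 600))
        ib = aoi_index(*b, 6, (600, 600))
        assert t.v[ia] == t.v[ib] == 0.5
        assert t.M[ia, ib] == 1.0 and t.M[ib, ia] == 1.0
        assert gaze_transition_entropy(t) == 0.0  # deterministic scanpath

    def test_boundary_goes_to_higher_index_cell(self):
        # x = 100 is exactly the 6-segment boundary of a 600 px image
        assert aoi_index(100.0, 0.0, 6, (600, 600)) == 1
        assert aoi_index(99.999, 0.0, 6, (600, 600)) == 0

    def test_uniform_scanpath_rows_approach_occupancy(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 600, size=(100_000, 2))
        fixes = [make_fixation(x, y, onset=k) for k, (x, y) in enumerate(xy)]
        t = build_transitions(fixes, n_segments=3, image_size_px=(600, 600))
        for i in range(9):
            np.testing.assert_allclose(t.M[i], t.v, atol=0.02)

    def test_fewer_than_two_fixations_error(self):
        with pytest.raises(ValueError):
            build_transitions([make_fixation(1, 1)], 6, (600, 600))


class TestGTE:
    def test_uniform_everything_gives_one(self):
        N = 36
        t = AOITransition(6, np.full(N, 1 / N), np.full((N, N), 1 / N))
        assert gaze_transition_entropy(t) == pytest.approx(1.0, rel=1e-12)

    def test_two_state_chain_hand_evaluation(self):
        # stationary distribution of [[0.9, 0.1], [0.5, 0.5]] is (5/6, 1/6)
        M = np.zeros((4, 4))
        M[0, 0], M[0, 1] = 0.9, 0.1
        M[1, 0], M[1, 1] = 0.5, 0.5
        v = np.array([5 / 6, 1 / 6, 0.0, 0.0])
        t = AOITransition(2, v, M)
        h = lambda p: -sum(x * math.log2(x) for x in p if x > 0)
        expected = (5 / 6) * h([0.9, 0.1]) + (1 / 6) * h([0.5, 0.5])
        assert gaze_transition_entropy(t, normalized=False) == pytest.approx(expected)
        assert gaze_transition_entropy(t) == pytest.approx(expected / 2.0)

    def test_relabel_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 20, size=(9, 9)).astype(float)
        v = counts.sum(axis=1)
        v /= v.sum()
        M = counts / counts.sum(axis=1, keepdims=True)
        perm = rng.permutation(9)
        t1 = AOITransition(3, v, M)
        t2 = AOITransition(3, v[perm], M[np.ix_(perm, perm)])
        assert gaze_transition_entropy(t1) == pytest.approx(
            gaze_transition_entropy(t2), rel=1e-12
        )


class TestCenterBias:
    def test_all_center_scores_100(self):
        fixes = [make_fixation(300, 300) for _ in range(100)]
        score, se = center_bias(fixes, (600, 600), n_bootstrap=50, seed=0)
        assert score == 100.0
        assert se == 0.0

    def test_uniform_sample_scores_near_zero(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 600, size=(10**6, 2))
        score, _ = center_bias(xy, (600, 600), n_bootstrap=2, seed=0)
        assert abs(score) < 1.0

    def test_corner_sample_negative_closed_form(self):
        fixes = [make_fixation(0, 0) for _ in range(10)]
        score, _ = center_bias(fixes, (600, 600), n_bootstrap=2, seed=0)
        expected = 100.0 * (
            1.0 - 300.0 * math.sqrt(2) / expected_uniform_center_distance((600, 600))
        )
        assert score == pytest.approx(expected, rel=1e-12)
        assert score < 0

    def test_uniform_expectation_matches_quadrature(self):
        closed = expected_uniform_center_distance((600, 600))
        quad, _ = integrate.dblquad(
            lambda y, x: math.hypot(x - 300, y - 300) / 360000.0,
            0, 600, 0, 600,
        )
        assert closed == pytest.approx(quad, rel=1e-9)
        # non-square rectangle against quadrature too
        closed_rect = expected_uniform_center_distance((400, 200))
        quad_rect, _ = integrate.dblquad(
            lambda y, x: math.hypot(x - 200, y - 100) / 80000.0, 0, 400, 0, 200
        )
        assert closed_rect == pytest.approx(quad_rect, rel=1e-9)

    def test_rotation_about_center_invariant(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(50, 550, size=(200, 2))
        rotated = np.column_stack([xy[:, 1], 600.0 - xy[:, 0]])
        s1, _ = center_bias(xy, (600, 600), n_bootstrap=2, seed=0)
        s2, _ = center_bias(rotated, (600, 600), n_bootstrap=2, seed=0)
        assert s1 == pytest.approx(s2, rel=1e-9)


class TestSummarizeAndAggregate:
    def _trial(self, pid="p00", img="img0"):
        fixes = [
            make_fixation(100, 100, onset=100, dur=200, pid=pid, img=img),
            make_fixation(500, 100, onset=330, dur=250, pid=pid, img=img),
            make_fixation(100, 500, onset=610, dur=150, pid=pid, img=img),
            make_fixation(500, 500, onset=790, dur=200, pid=pid, img=img),
        ]
        sacc = [
            make_saccade(100, 100, 500, 100, onset=300, amp=10.0, pid=pid, img=img),
            make_saccade(500, 100, 100, 500, onset=580, amp=14.1, pid=pid, img=img),
        ]
        return make_trial(fixes, sacc, pid=pid, img=img)

    def test_summary_matches_hand_computation(self):
        rec = summarize(self._trial(), n_bootstrap=2, seed=0)
        assert rec.n_fixations == 4
        assert rec.mean_fixation_duration_ms == pytest.approx(200.0)
        assert rec.mean_saccade_amplitude_dva == pytest.approx((10.0 + 14.1) / 2)
        # scanpath visits 4 distinct AOIs once each, all transitions
        # deterministic -> GTE 0
        assert rec.gte_normalized == 0.0
        fdm = build_fdm([f for f in self._trial().fixations], (600, 600))
        assert rec.fdm_entropy_bits == pytest.approx(fdm_entropy(fdm))

    def test_identical_trials_identical_records(self):
        r1 = summarize(self._trial(), n_bootstrap=2, seed=0)
        r2 = summarize(self._trial(), n_bootstrap=2, seed=0)
        assert r1 == r2

    def test_constant_duration_trial(self):
        fixes = [
            make_fixation(300, 300 + 10 * k, onset=100 + 240 * k, dur=200)
            for k in range(5)
        ]
        rec = summarize(make_trial(fixes), n_bootstrap=2, seed=0)
        assert rec.mean_fixation_duration_ms == 200.0
        assert rec.n_fixations == 5
        assert math.isnan(rec.mean_saccade_amplitude_dva)  # no saccades, logged

    def test_aggregate_arithmetic(self):
        recs = []
        for pid in ("p00", "p01", "p02"):
            for img, base in (("imgA", 100.0), ("imgB", 200.0)):
                r = summarize(self._trial(pid=pid, img=img), n_bootstrap=2, seed=0)
                r.mean_fixation_duration_ms = base + 10 * int(pid[1:])
                recs.append(r)
        per_image = aggregate(recs, level="image")
        assert per_image.loc["imgA", "mean_fixation_duration_ms"] == pytest.approx(110.0)
        assert per_image.loc["imgB", "mean_fixation_duration_ms"] == pytest.approx(210.0)
        per_cat = aggregate(
            recs, level="category",
            image_categories={"imgA": "c1", "imgB": "c1"},
        )
        assert per_cat.loc["c1", "mean_fixation_duration_ms"] == pytest.approx(160.0)

    def test_single_observer_image_value_is_that_observer(self):
        rec = summarize(self._trial(), n_bootstrap=2, seed=0)
        per_image = aggregate([rec], level="image")
        assert per_image.loc["img0", "n_fixations"] == rec.n_fixations


def test_center_bias_monotone_in_concentration():
    """Tighter central clusters must score strictly higher."""
    rng = np.random.default_rng(4)
    scores = []
    for sigma in (300.0, 150.0, 80.0, 30.0):
        xy = rng.normal(300.0, sigma, size=(4000, 2))
        xy = xy[((xy >= 0) & (xy < 600)).all(axis=1)]
        s, _ = center_bias(xy, (600, 600), n_bootstrap=2, seed=0)
        scores.append(s)
    assert scores == sorted(scores)
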