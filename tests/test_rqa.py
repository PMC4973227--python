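"""Recurrence structure, radius solving and RQA statistics.

The heavy cross-checks run against the brute-force double-loop oracle in
``tests/oracles.py``, which shares no code with the package.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from lamflow.embedding import EmbeddingSpec, embed
from lamflow.exceptions import DegenerateSeriesError
from lamflow.rqa import (
    determinism,
    distance_field,
    laminarity,
    measures_for_epoch,
    recurrence_rate,
    recurrence_structure,
    solve_radius_for_rec,
    structure_from_matrix,
    trapping_time,
    vmax,
)


class TestDistanceField:
    def test_two_points(self):
        df = distance_field(np.array([[0.0], [3.0]]))
        np.testing.assert_allclose(df.dense(), [[0, 1], [1, 0]])
        assert df.max_distance == 3.0

    def test_symmetric_zero_diagonal(self, rng):
        pts = rng.normal(size=(20, 3))
        dm = distance_field(pts).dense()
        np.testing.assert_allclose(dm, dm.T)
        np.testing.assert_allclose(np.diag(dm), 0.0)

    def test_matches_brute_force(self, rng):
        pts = rng.normal(size=(5, 3))
        dm = distance_field(pts).dense()
        brute, _ = oracles.brute_distances(pts.tolist())
        np.testing.assert_allclose(dm, brute, atol=1e-12)

    def test_identical_vectors_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            distance_field(np.ones((4, 2)))


class TestRecurrenceStructure:
    def test_saturation(self, rng):
        pts = rng.normal(size=(30, 2))
        s = recurrence_structure(distance_field(pts), 100.0, theiler_w=0)
        assert recurrence_rate(s) == pytest.approx(100.0)

    def test_tiny_radius_empty(self, rng):
        pts = rng.normal(size=(30, 2))
        s = recurrence_structure(distance_field(pts), 1e-9, theiler_w=0)
        assert recurrence_rate(s) == 0.0
        assert laminarity(s) == 0.0

    def test_vertical_histogram_matches_brute_force(self, rng):
        # logistic-map embedding, moderate radius
        x = [0.4]
        for _ in range(60):
            x.append(3.99 * x[-1] * (1 - x[-1]))
        pts = embed(np.array(x), EmbeddingSpec(m=2, tau=1)).vectors[:50]
        s = recurrence_structure(distance_field(pts), 10.0, theiler_w=4)
        runs = oracles.brute_vertical_runs(pts.tolist(), 10.0, 4)
        expected = np.bincount(runs, minlength=s.vertical_hist.size)
        np.testing.assert_array_equal(s.vertical_hist[1:], expected[1:s.vertical_hist.size])


class TestLineStatistics:
    def test_single_vertical_run(self):
        # column 0 recurrent with rows 10..16 -> one run of 7 (plus its
        # symmetric image in row 0)
        R = np.zeros((25, 25), dtype=bool)
        R[10:17, 0] = True
        s = structure_from_matrix(R, rad_pct=5.0, theiler_w=2)
        assert vmax(s) == 7
        assert trapping_time(s) == 7.0

    def test_hand_counted_runs(self):
        # vertical runs {2, 2, 6} -> vmax 6, tt 10/3
        R = np.zeros((30, 30), dtype=bool)
        R[10:12, 0] = True
        R[20:22, 3] = True
        R[12:18, 25] = True
        s = structure_from_matrix(R, rad_pct=5.0, theiler_w=2)
        assert vmax(s) == 6
        assert trapping_time(s) == pytest.approx(10.0 / 3.0)

    def test_isolated_points_give_zero_lam_det(self):
        R = np.zeros((20, 20), dtype=bool)
        for i, j in [(0, 5), (3, 12), (8, 17)]:
            R[i, j] = True
        s = structure_from_matrix(R, rad_pct=5.0, theiler_w=1)
        assert laminarity(s) == 0.0
        assert determinism(s) == 0.0
        assert trapping_time(s) == 0.0

    def test_unbroken_columns_give_full_laminarity(self):
        # one off-band block: every recurrent column is a single run >= 2
        R = np.zeros((15, 15), dtype=bool)
        R[10:14, 0:4] = True
        s = structure_from_matrix(R, rad_pct=100.0, theiler_w=1)
        assert laminarity(s) == 1.0

    def test_tt_never_exceeds_vmax(self, rng):
        for _ in range(5):
            pts = rng.normal(size=(40, 2))
            s = recurrence_structure(distance_field(pts), 30.0, theiler_w=2)
            assert trapping_time(s) <= vmax(s) + 1e-12

    def test_periodic_signal_determinism_near_one(self):
        t = np.arange(400)
        x = np.sin(2 * np.pi * t / 40.0)
        spec = EmbeddingSpec(m=3, tau=10)
        pts = embed(x, spec)
        s = recurrence_structure(distance_field(pts), 10.0, spec.theiler_w)
        assert determinism(s) > 0.95


class TestRadiusSolver:
    def test_target_100(self, rng):
        pts = rng.normal(size=(20, 2))
        sol = solve_radius_for_rec(distance_field(pts), 100.0)
        assert sol.rad_pct == 100.0

    def test_rec_monotone_in_radius(self, rng):
        pts = rng.normal(size=(60, 3))
        df = distance_field(pts)
        recs = [
            recurrence_rate(recurrence_structure(df, r, theiler_w=2))
            for r in (1.0, 5.0, 20.0, 50.0, 100.0)
        ]
        assert all(a <= b for a, b in zip(recs, recs[1:]))

    def test_matches_quantile_oracle(self):
        from lamflow.synthetic import generate_ar_linear
        x = generate_ar_linear(220, (0.9,), seed=3)
        pts = embed(x, EmbeddingSpec(m=3, tau=2)).vectors  # 216 states
        sol = solve_radius_for_rec(distance_field(pts), 1.0, theiler_w=4)
        ref = oracles.quantile_radius(pts.tolist(), 1.0, 4)
        assert abs(sol.rad_pct - ref) < 0.02  # tol on normalized scale
        assert 0.95 <= sol.achieved_rec_pct <= 1.05
        assert sol.attained


@settings(max_examples=12, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=8, max_value=40),
    rad=st.floats(min_value=5.0, max_value=80.0),
    w=st.integers(min_value=0, max_value=3),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_all_statistics_match_brute_force(n, rad, w, seed):
    """REC/LAM/VMAX/TT/DET equal the double-loop oracle on random clouds."""
    pts = np.random.default_rng(seed).normal(size=(n, 2))
    s = recurrence_structure(distance_field(pts), rad, theiler_w=w)
    p = pts.tolist()
    assert recurrence_rate(s) == pytest.approx(oracles.brute_rec_pct(p, rad, w))
    assert laminarity(s) == pytest.approx(oracles.brute_lam(p, rad, w))
    assert vmax(s) == oracles.brute_vmax(p, rad, w)
    assert trapping_time(s) == pytest.approx(oracles.brute_tt(p, rad, w))
    assert determinism(s) == pytest.approx(oracles.brute_det(p, rad, w))


def test_statistics_invariant_under_time_relabeling(rng):
    """Reversing state order leaves all line statistics unchanged."""
    pts = rng.normal(size=(50, 3))
    a = recurrence_structure(distance_field(pts), 25.0, theiler_w=2)
    b = recurrence_structure(distance_field(pts[::-1]), 25.0, theiler_w=2)
    assert recurrence_rate(a) == pytest.approx(recurrence_rate(b))
    assert laminarity(a) == pytest.approx(laminarity(b))
    assert vmax(a) == vmax(b)
    assert determinism(a) == pytest.approx(determinism(b))


class TestMeasuresForEpoch:
    def test_constant_epoch_flagged_degenerate(self):
        meas = measures_for_epoch(np.ones(2000))
        assert meas.degenerate
        assert np.isnan(meas.lam)

    def test_deterministic_given_fixture(self):
        from lamflow.synthetic import generate_ar_linear
        x = generate_ar_linear(2400, (0.9,), seed=8)
        a = measures_for_epoch(x)
        b = measures_for_epoch(x)
        assert a == b

    def test_intermittent_exceeds_ar_laminarity(self):
        from lamflow.synthetic import generate_ar_linear, generate_intermittent_map
        xm = generate_intermittent_map(4800, seed=21)
        xa = generate_ar_linear(4800, (0.9,), seed=21)
        xa = xa / np.std(xa) * np.std(xm)  # variance-matched
        mm = measures_for_epoch(xm)
        ma = measures_for_epoch(xa)
        assert mm.lam_over_rad > ma.lam_over_rad

    def test_scale_invariance_of_rqa(self):
        from lamflow.synthetic import generate_ar_linear
        x = generate_ar_linear(1200, (0.9,), seed=5)
        a = measures_for_epoch(x)
        b = measures_for_epoch(1000.0 * x)
        assert a.rad_pct == pytest.approx(b.rad_pct, rel=1e-9)
        assert a.lam == pytest.approx(b.lam, rel=1e-9)
        assert a.det == pytest.approx(b.det, rel=1e-9)
        assert a.rec_pct == pytest.approx(b.rec_pct, rel=1e-9)
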