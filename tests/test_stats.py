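"""Track behaviour responses, the Mann-Whitney U test and evidence nodes."""

import io
import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from gsnfit import (
    CellTrack,
    EdgeTypingError,
    InvalidArgumentError,
    NodeKind,
    attach_evidence,
    compare_groups,
    create_graph,
    mann_whitney_u,
    partition,
    read_tracks_csv,
    summarize,
    synthesize_tracks,
    validate,
    write_tracks_csv,
)


def brute_force_u(x, y):
    """Independent oracle: literal pairwise-win count, ties one half."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def track(points, interval=1.0, tid="t1"):
    return CellTrack(track_id=tid, positions=np.array(points, float),
                     interval_min=interval)


class TestSummarize:
    def test_3_4_5_triangle(self):
        s = summarize(track([(0, 0), (3, 4)]))
        assert s.velocity == pytest.approx(5.0)
        assert s.displacement == pytest.approx(5.0)

    def test_out_and_back(self):
        s = summarize(track([(0, 0), (0, 5), (0, 0)]))
        assert s.velocity == pytest.approx(5.0)
        assert s.displacement == pytest.approx(0.0)

    def test_interval_scales_velocity(self):
        s = summarize(track([(0, 0), (0, 6)], interval=3.0))
        assert s.velocity == pytest.approx(2.0)

    def test_single_position_rejected(self):
        with pytest.raises(InvalidArgumentError):
            track([(0, 0)])

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_displacement_bounded_by_path(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 5, (20, 2))
        s = summarize(track(pts))
        path = s.velocity * 19  # interval 1 min
        assert s.displacement <= path + 1e-9


class TestPartition:
    def test_strict_threshold(self):
        near = track([(49.9, 0), (50, 0)], tid="near")
        boundary = track([(50.0, 0), (51, 0)], tid="boundary")
        p = partition([near, boundary], centre=(0.0, 0.0), threshold_um=50.0)
        assert p.near == ("near",)
        assert p.far == ("boundary",)

    def test_empty_input(self):
        p = partition([], centre=(0, 0))
        assert p.near == () and p.far == ()

    def test_uses_first_position(self):
        # wanders inside the radius later, but starts far: stays far
        t = track([(100, 0), (10, 0), (5, 0)], tid="w")
        p = partition([t], centre=(0, 0))
        assert p.far == ("w",)


class TestMannWhitneyU:
    def test_pairwise_win_example(self):
        r = mann_whitney_u([3, 4, 5], [1, 2, 6])
        assert r.u_statistic == 6.0

    def test_complete_separation_gives_zero(self):
        assert mann_whitney_u([1, 2], [3, 4]).u_statistic == 0.0

    def test_single_tie_counts_half(self):
        r = mann_whitney_u([5], [5])
        assert r.u_statistic == 0.5

    def test_exact_p_complete_separation_n3(self):
        # 2 of the C(6,3)=20 assignments are at least as extreme
        r = mann_whitney_u([1, 2, 3], [7, 8, 9])
        assert r.method == "exact"
        assert r.p_two_sided == pytest.approx(2 / 20)

    def test_identical_samples_exact_p_is_one(self):
        r = mann_whitney_u([1.0, 2.5, 7.0], [1.0, 2.5, 7.0])
        assert r.method == "exact"
        assert r.p_two_sided == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mann_whitney_u([], [1.0])

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_u_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 9, size=2)
        x = rng.integers(0, 6, n1).astype(float)  # small support forces ties
        y = rng.integers(0, 6, n2).astype(float)
        r = mann_whitney_u(x, y)
        assert r.u_statistic == brute_force_u(x, y)
        assert r.u_statistic + brute_force_u(y, x) == pytest.approx(n1 * n2)
        assert 0.0 <= r.p_two_sided <= 1.0

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_u_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 6)
        y = rng.normal(0, 1, 5)
        base = mann_whitney_u(x, y).u_statistic
        for f in (lambda v: 3 * v + 2, np.exp, lambda v: v**3):
            assert mann_whitney_u(f(x), f(y)).u_statistic == base

    def test_exact_p_matches_full_enumeration_with_ties(self):
        x, y = [1.0, 2.0, 2.0], [2.0, 3.0]
        r = mann_whitney_u(x, y)
        pooled = x + y
        mu = len(x) * len(y) / 2
        obs = abs(brute_force_u(x, y) - mu)
        hits = total = 0
        for combo in itertools.combinations(range(5), 3):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(5) if i not in combo]
            hits += abs(brute_force_u(xs, ys) - mu) >= obs - 1e-9
            total += 1
        assert r.p_two_sided == pytest.approx(hits / total)

    def test_large_samples_use_corrected_normal_approximation(self):
        rng = np.random.default_rng(7)
        x = np.round(rng.normal(0, 1, 30), 1)  # rounding introduces ties
        y = np.round(rng.normal(0.7, 1, 25), 1)
        r = mann_whitney_u(x, y)
        assert r.method == "normal_approximation"
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic")
        # scipy reports U for the first sample with the same tie handling
        assert r.u_statistic == pytest.approx(ref.statistic)
        assert r.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)


class TestCompareGroups:
    def make_separated(self, seed=5):
        rng = np.random.default_rng(seed)
        near = synthesize_tracks(
            6, start_region=((0, 0), (30, 30)), drift=(0, 0), step_sd=0.5,
            seed=rng, id_prefix="near",
        )
        far = synthesize_tracks(
            6, start_region=((150, 150), (220, 220)), drift=(2.0, 0), step_sd=0.5,
            seed=rng, id_prefix="far",
        )
        return near + far

    def test_complete_separation_maximizes_u(self):
        tracks = self.make_separated()
        r = compare_groups(tracks, centre=(15, 15), threshold_um=50,
                           response="velocity")
        # far cells drift fast, near cells jitter: far wins every pairing
        assert r.u_statistic == 0.0
        assert r.p_two_sided < 0.01

    def test_identical_groups_p_one(self):
        # same multiset of responses on both sides of the split
        near = [track([(0, 0), (0, v)], tid=f"n{v}") for v in (1, 2, 3)]
        far = [track([(100, 0), (100, v)], tid=f"f{v}") for v in (1, 2, 3)]
        r = compare_groups(near + far, centre=(0, 0), threshold_um=50)
        assert r.method == "exact"
        assert r.p_two_sided == pytest.approx(1.0)

    def test_relabelling_tracks_changes_nothing(self):
        tracks = self.make_separated()
        renamed = [
            CellTrack(f"cell-{i}", t.positions, t.interval_min, t.cell_type)
            for i, t in enumerate(tracks)
        ]
        a = compare_groups(tracks, centre=(15, 15))
        b = compare_groups(renamed, centre=(15, 15))
        assert (a.u_statistic, a.p_two_sided) == (b.u_statistic, b.p_two_sided)

    def test_empty_side_named_in_error(self):
        tracks = self.make_separated()
        with pytest.raises(InvalidArgumentError, match="near"):
            compare_groups(tracks, centre=(-1000, -1000), threshold_um=50)


class TestAttachEvidence:
    def test_verdict_wording(self):
        from gsnfit.stats import UTestResult

        g = create_graph("behaviour is representative")
        calm = UTestResult(10.0, 5, 5, 0.4, "exact")
        uid = attach_evidence(g, g.root, calm, "velocity near/far")
        assert "no significant difference" in g.nodes[uid].statement
        hot = UTestResult(25.0, 5, 5, 0.01, "exact")
        uid2 = attach_evidence(g, g.root, hot, "displacement near/far",
                               link="https://example.org/analysis")
        stmt = g.nodes[uid2].statement
        assert "significant difference" in stmt and "no significant" not in stmt
        assert g.nodes[uid2].links == ["https://example.org/analysis"]
        assert validate(g) == []

    def test_non_goal_target_rejected(self):
        from gsnfit.stats import UTestResult

        g = create_graph("claim")
        s = g.add_child(g.root, NodeKind.STRATEGY, "argue")
        with pytest.raises(EdgeTypingError):
            attach_evidence(g, s, UTestResult(1.0, 2, 2, 0.5, "exact"), "d")


class TestSynthesizeTracks:
    def test_seed_reproducibility(self):
        a = synthesize_tracks(4, seed=42)
        b = synthesize_tracks(4, seed=42)
        for ta, tb in zip(a, b):
            assert ta.track_id == tb.track_id
            np.testing.assert_array_equal(ta.positions, tb.positions)

    def test_pure_drift_is_analytic(self):
        (t,) = synthesize_tracks(1, drift=(1.0, 0.0), step_sd=0.0,
                                 n_steps=10, seed=0)
        s = summarize(t)
        assert s.displacement == pytest.approx(10.0)
        assert s.velocity == pytest.approx(1.0)

    def test_no_motion_zero_velocity(self):
        (t,) = synthesize_tracks(1, drift=(0.0, 0.0), step_sd=0.0, seed=0)
        assert summarize(t).velocity == 0.0

    def test_diffusive_displacement_grows_sublinearly(self):
        # mean displacement of a driftless walk ~ sqrt(steps), well below
        # the ballistic bound; averaged over many tracks
        short = synthesize_tracks(200, drift=(0, 0), step_sd=2.0, n_steps=16,
                                  seed=9)
        long = synthesize_tracks(200, drift=(0, 0), step_sd=2.0, n_steps=64,
                                 seed=10)
        mean = lambda ts: np.mean([summarize(t).displacement for t in ts])
        ratio = mean(long) / mean(short)
        assert ratio < 4 / 1.5  # far from the 4x ballistic scaling

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synthesize_tracks(0)
        with pytest.raises(InvalidArgumentError):
            synthesize_tracks(1, n_steps=0)
        with pytest.raises(InvalidArgumentError):
            synthesize_tracks(1, step_sd=-1.0)


class TestTrackCsv:
    def test_round_trip(self):
        tracks = synthesize_tracks(3, seed=3, cell_type="LTi")
        buf = io.StringIO()
        write_tracks_csv(tracks, buf)
        buf.seek(0)
        back = read_tracks_csv(buf)
        assert [t.track_id for t in back] == [t.track_id for t in tracks]
        for a, b in zip(tracks, back):
            np.testing.assert_allclose(a.positions, b.positions)
            assert b.interval_min == a.interval_min
            assert b.cell_type == "LTi"

    def test_missing_column_rejected(self):
        with pytest.raises(InvalidArgumentError, match="x_um"):
            read_tracks_csv(io.StringIO("track_id,t_min,y_um\na,0,1\na,1,2\n"))

    def test_nonuniform_sampling_rejected(self):
        csv = "track_id,t_min,x_um,y_um\na,0,0,0\na,1,1,0\na,5,2,0\n"
        with pytest.raises(InvalidArgumentError, match="uniform"):
            read_tracks_csv(io.StringIO(csv))
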