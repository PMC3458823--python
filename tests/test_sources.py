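"""Track linking, locus cleaning/smoothing/area, classification, conservation."""

import warnings

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from fibmap import (
    SourceTrack,
    classify_rotor,
    conservation_metric,
    count_concurrent_sources,
    detect_focal_sources,
    link_singularities,
    locus_area,
    predicted_wavelength,
    remove_outlier_points,
    smooth_locus,
)
from fibmap.errors import InvalidArgumentError
from fibmap.phase import PhaseSingularityEvent
from fibmap.sources import LocusCurve
from tests.conftest import dominant_track, nearest_truth_distance


def _events(positions_by_time, charge=1):
    evs = []
    for t, pts in positions_by_time:
        for p in np.atleast_2d(pts):
            evs.append(PhaseSingularityEvent(t_ms=float(t), u_cm=float(p[0]),
                                             v_cm=float(p[1]), charge=charge))
    return evs


# ---------------------------------------------------------------------------
# linking


def test_single_stationary_vortex_yields_one_track():
    evs = _events([(t, [(2.0, 2.0)]) for t in np.arange(0.0, 700.0, 10.0)])
    tracks = link_singularities(evs, sample_interval_ms=35.0, include_boundary=True)
    assert len(tracks) == 1
    assert tracks[0].n_samples == 20
    assert tracks[0].chirality == 1


def test_two_distant_vortices_never_merge():
    evs = []
    for t in np.arange(0.0, 400.0, 10.0):
        evs += _events([(t, [(0.5, 0.5)])], charge=1)
        evs += _events([(t, [(3.5, 3.5)])], charge=-1)
    tracks = link_singularities(evs, sample_interval_ms=35.0, max_jump_cm=1.0,
                                include_boundary=True)
    assert len(tracks) == 2
    for tr in tracks:
        spread = np.linalg.norm(tr.points - tr.points[0], axis=1).max()
        assert spread < 0.1


def test_opposite_chirality_never_linked():
    evs = _events([(0.0, [(1.0, 1.0)])], charge=1) + \
        _events([(40.0, [(1.0, 1.0)])], charge=-1)
    tracks = link_singularities(evs, sample_interval_ms=35.0, include_boundary=True)
    assert len(tracks) == 2


def test_greedy_linking_matches_optimal_assignment_when_unambiguous():
    """With emitters separated by > 2x max_jump, greedy linking equals the
    Hungarian per-slab assignment (computed independently)."""
    rng = np.random.default_rng(17)
    max_jump = 0.5
    centres = np.array([[1.0, 1.0], [3.0, 1.0], [2.0, 3.3]])  # > 2x max_jump apart
    n_slabs = 12
    slab = 35.0
    evs = []
    truth_pos = {k: [] for k in range(len(centres))}
    for s in range(n_slabs):
        t = s * slab + 10.0  # aligned to the slab grid
        for k, c in enumerate(centres):
            p = c + rng.uniform(-0.1, 0.1, 2)  # jitter << max_jump
            truth_pos[k].append(p)
            evs.append(PhaseSingularityEvent(t_ms=float(t), u_cm=p[0], v_cm=p[1], charge=1))
    tracks = link_singularities(evs, sample_interval_ms=slab, max_jump_cm=max_jump,
                                include_boundary=True)
    assert len(tracks) == 3
    # oracle: per-slab optimal assignment of track ends to events
    for tr in tracks:
        k = int(np.argmin(np.linalg.norm(centres - tr.points[0], axis=1)))
        np.testing.assert_allclose(tr.points, truth_pos[k], atol=1e-9)
    # independent Hungarian check on one slab pair: assignment is identity
    for s in range(n_slabs - 1):
        a = np.array([truth_pos[k][s] for k in range(3)])
        b = np.array([truth_pos[k][s + 1] for k in range(3)])
        cost = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        rows, cols = linear_sum_assignment(cost)
        np.testing.assert_array_equal(cols, np.arange(3))


def test_track_closed_after_max_gap():
    evs = _events([(t, [(2.0, 2.0)]) for t in [0.0, 35.0, 300.0, 335.0]])
    tracks = link_singularities(evs, sample_interval_ms=35.0, max_gap_ms=105.0,
                                include_boundary=True)
    assert len(tracks) == 2


# ---------------------------------------------------------------------------
# outlier removal


def _circle_track(n=24, r=0.5, centre=(2.0, 2.0)):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([centre[0] + r * np.cos(ang), centre[1] + r * np.sin(ang)])
    return SourceTrack(kind="rotor", times_ms=np.arange(n) * 35.0, points=pts, chirality=1)


def test_extreme_outlier_removed():
    tr = _circle_track()
    pts = tr.points.copy()
    pts[10] = [7.0, 7.0]  # ten radii away
    bad = SourceTrack(kind="rotor", times_ms=tr.times_ms, points=pts, chirality=1)
    out = remove_outlier_points(bad)
    assert out.n_samples == 23
    assert not np.any(np.all(out.points == [7.0, 7.0], axis=1))


def test_tight_cluster_unchanged():
    tr = _circle_track(r=0.1)
    out = remove_outlier_points(tr)
    np.testing.assert_array_equal(out.points, tr.points)


def test_outlier_rule_matches_brute_force_audit():
    """Seeded contaminated tracks: removal set equals an independent
    re-implementation of the running-median MAD rule."""
    rng = np.random.default_rng(23)
    for _ in range(50):
        n = int(rng.integers(8, 40))
        pts = np.cumsum(rng.normal(0, 0.05, size=(n, 2)), axis=0) + [2.0, 2.0]
        n_bad = int(rng.integers(0, max(1, n // 10)))
        bad_idx = rng.choice(n, size=n_bad, replace=False)
        pts[bad_idx] += rng.choice([-1, 1], size=(n_bad, 2)) * rng.uniform(3, 6, (n_bad, 2))
        tr = SourceTrack(kind="rotor", times_ms=np.arange(n) * 35.0, points=pts, chirality=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = remove_outlier_points(tr, k=5.0, window=11)
        # independent audit
        med = np.array([np.median(pts[max(0, i - 5):min(n, i + 6)], axis=0)
                        for i in range(n)])
        d = np.linalg.norm(pts - med, axis=1)
        scale = np.median(d)
        if scale == 0.0:
            expect = pts
        else:
            drop = d > 5.0 * scale
            expect = pts if (drop.sum() > 0.2 * n or drop.sum() == 0) else pts[~drop]
        np.testing.assert_array_equal(out.points, expect)


def test_short_track_returned_unchanged_with_warning():
    tr = SourceTrack(kind="rotor", times_ms=[0.0, 35.0], points=[[0, 0], [1, 1]],
                     chirality=1)
    with pytest.warns(UserWarning):
        out = remove_outlier_points(tr)
    assert out.n_samples == 2


# ---------------------------------------------------------------------------
# locus smoothing


def test_collinear_points_give_straight_curve():
    pts = np.column_stack([np.linspace(0, 2, 9), np.linspace(0, 1, 9)])
    curve = smooth_locus(pts)
    s = np.linspace(0, curve.total_length, 200)
    xy = curve(s)
    # deviation from the chord
    chord = pts[-1] - pts[0]
    t = (xy - pts[0]) @ chord / (chord @ chord)
    proj = pts[0] + t[:, None] * chord
    assert np.abs(xy - proj).max() < 1e-9


def test_two_points_give_segment():
    curve = smooth_locus(np.array([[0.0, 0.0], [1.0, 1.0]]))
    np.testing.assert_allclose(curve(curve.total_length / 2), [0.5, 0.5])


def test_duplicate_consecutive_points_collapsed():
    curve = smooth_locus(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [1.0, 1.0]]))
    assert len(curve.knot_points) == 3


def test_curve_is_c2_at_interior_knots():
    """Finite-difference audit: first/second derivative jumps at knots are
    at round-off scale relative to the curve."""
    rng = np.random.default_rng(31)
    for _ in range(10):
        n = int(rng.integers(4, 12))
        pts = rng.uniform(0, 3, size=(n, 2))
        curve = smooth_locus(pts)
        scale = max(curve.total_length, 1.0)
        eps = 1e-9  # straddle the knot at machine scale
        for s in curve.knots_s[1:-1]:
            for order in (1, 2):
                left = curve.derivative(np.array([s - eps]), order)[0]
                right = curve.derivative(np.array([s + eps]), order)[0]
                assert np.linalg.norm(right - left) / scale < 1e-6


def test_curve_interpolates_every_knot():
    rng = np.random.default_rng(2)
    pts = rng.uniform(0, 4, size=(7, 2))
    curve = smooth_locus(pts)
    np.testing.assert_allclose(curve(curve.knots_s), curve.knot_points, atol=1e-9)


# ---------------------------------------------------------------------------
# locus area


def _brute_force_hull_area(pts):
    """O(n^3) convex-hull area: find hull edges by the all-points-on-one-side
    test, then shoelace on the ordered hull."""
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    hull_pts = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            cross = d[0] * (pts[:, 1] - pts[i, 1]) - d[1] * (pts[:, 0] - pts[i, 0])
            if np.all(cross <= 1e-12) or np.all(cross >= -1e-12):
                hull_pts.append(pts[i])
                break
    if len(hull_pts) < 3:
        return 0.0
    hull_pts = np.unique(np.asarray(hull_pts), axis=0)
    c = hull_pts.mean(axis=0)
    ang = np.arctan2(hull_pts[:, 1] - c[1], hull_pts[:, 0] - c[0])
    ordered = hull_pts[np.argsort(ang)]
    x, y = ordered[:, 0], ordered[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def test_dense_circle_area_close_to_pi():
    ang = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    pts = np.column_stack([np.cos(ang), np.sin(ang)])
    assert abs(locus_area(pts) - np.pi) / np.pi < 0.01


def test_collinear_points_zero_area():
    pts = np.column_stack([np.arange(5.0), 2.0 * np.arange(5.0)])
    assert locus_area(pts) == 0.0


def test_hull_area_matches_brute_force_oracle():
    rng = np.random.default_rng(13)
    for _ in range(100):
        n = int(rng.integers(3, 40))
        pts = rng.uniform(-2, 2, size=(n, 2))
        assert abs(locus_area(pts) - _brute_force_hull_area(pts)) < 1e-9


def test_area_rigid_motion_invariant():
    rng = np.random.default_rng(19)
    pts = rng.uniform(0, 2, size=(30, 2))
    a = locus_area(pts)
    th = 0.83
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    moved = pts @ R.T + [5.0, -3.0]
    assert abs(locus_area(moved) - a) < 1e-9


# ---------------------------------------------------------------------------
# classification on simulated fixtures


def test_spiral_dominant_track_is_rotor_with_expected_turns(spiral_chain):
    tr = dominant_track(spiral_chain["tracks"])
    is_rotor, count = classify_rotor(tr, spiral_chain["pm"])
    assert is_rotor
    truth = spiral_chain["episode"].truth
    expected_turns = (tr.times_ms[-1] - tr.times_ms[0]) / truth.period_ms
    assert count >= 4
    assert abs(count - expected_turns) / expected_turns < 0.25


def test_truncated_track_is_not_a_rotor(spiral_chain):
    tr = dominant_track(spiral_chain["tracks"])
    truth = spiral_chain["episode"].truth
    half_rotation_ms = truth.period_ms / 2
    keep = tr.times_ms <= tr.times_ms[0] + half_rotation_ms
    assert keep.sum() >= 2
    short = SourceTrack(kind="rotor", times_ms=tr.times_ms[keep],
                        points=tr.points[keep], chirality=tr.chirality)
    is_rotor, count = classify_rotor(short, spiral_chain["pm"])
    assert not is_rotor
    assert count < 2


def test_classification_exclusivity_on_fixtures(spiral_chain, focal_chain, plane_chain):
    """Spirals yield rotors only; focal episodes focal only; plane waves none."""
    assert len(spiral_chain["rotors"]) >= 1
    assert spiral_chain["focal"] == []
    assert focal_chain["rotors"] == []
    assert len(focal_chain["focal"]) == 1
    assert plane_chain["rotors"] == []
    assert plane_chain["focal"] == []


def test_focal_origin_recovered_within_electrode_pitch(focal_chain):
    tr = focal_chain["focal"][0]
    origin = np.array(focal_chain["episode"].truth.origin)
    pitch = focal_chain["episode"].grid.median_pitch()
    assert np.linalg.norm(tr.centroid - origin) <= pitch
    assert tr.n_beats >= 2


def test_meander_locus_recovers_truth_hull(meander_episode, spiral_chain):
    """Meandering rotor: measured hull contains >= 80% of truth tip points
    and its area is within a factor of 2 of the truth tip hull."""
    from shapely.geometry import MultiPoint, Point

    from tests.conftest import _chain

    chain = _chain(meander_episode)
    tr = dominant_track(chain["tracks"])
    tr = remove_outlier_points(tr)
    curve = smooth_locus(tr)
    hull = MultiPoint(curve.sample(512)).convex_hull
    truth_pts = meander_episode.truth.tip_positions
    inside = np.mean([hull.buffer(0.05).contains(Point(*p)) for p in truth_pts])
    assert inside >= 0.8
    truth_area = MultiPoint(truth_pts).convex_hull.area
    assert 0.5 * truth_area <= max(hull.area, 1e-12) <= 2.0 * truth_area


# ---------------------------------------------------------------------------
# counting, conservation, wavelength


def test_count_concurrent_sources_by_overlap():
    rotor = SourceTrack(kind="rotor", times_ms=[0.0, 900.0], points=[[1, 1], [1, 1]],
                        chirality=1)
    focal = SourceTrack(kind="focal", times_ms=[400.0, 600.0], points=[[3, 3], [3, 3]])
    late = SourceTrack(kind="focal", times_ms=[2000.0, 2100.0], points=[[2, 2], [2, 2]])
    assert count_concurrent_sources([rotor], (0.0, 1000.0)) == 1
    assert count_concurrent_sources([rotor, focal], (0.0, 1000.0)) == 2
    assert count_concurrent_sources([rotor, focal, late], (0.0, 1000.0)) == 2


def test_conservation_identical_tracks():
    tr = _circle_track()
    rep = conservation_metric(tr, tr)
    assert rep.centroid_distance_cm == 0.0
    assert abs(rep.hull_overlap - 1.0) < 1e-12


def test_conservation_disjoint_hulls():
    a = _circle_track(centre=(0.0, 0.0))
    b = _circle_track(centre=(10.0, 0.0))
    rep = conservation_metric(a, b)
    assert rep.hull_overlap == 0.0
    assert abs(rep.centroid_distance_cm - 10.0) < 1e-9


def test_conservation_offset_squares_third():
    def square(offset):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]) + [offset, 0.0]
        return SourceTrack(kind="rotor", times_ms=np.arange(4.0), points=pts, chirality=1)

    rep = conservation_metric(square(0.0), square(0.5))
    assert abs(rep.hull_overlap - 1.0 / 3.0) < 1e-9


def test_conservation_degenerate_hulls_buffered():
    a = SourceTrack(kind="focal", times_ms=[0.0, 1.0], points=[[1, 1], [1, 1.0001]])
    b = SourceTrack(kind="focal", times_ms=[0.0, 1.0], points=[[1, 1], [1, 1.0001]])
    rep = conservation_metric(a, b)
    assert rep.degenerate
    assert rep.hull_overlap > 0.9


def test_predicted_wavelength_values_and_linearity():
    assert predicted_wavelength(100.0, 40.0) == pytest.approx(40.0)
    assert predicted_wavelength(110.0, 40.0) == pytest.approx(44.0)
    assert predicted_wavelength(0.001, 40.0) == pytest.approx(4e-4)
    for r in (50.0, 100.0, 200.0):
        for cv in (20.0, 40.0, 80.0):
            assert predicted_wavelength(r, cv) == pytest.approx(r * cv / 100.0)
    with pytest.raises(InvalidArgumentError):
        predicted_wavelength(-1.0, 40.0)
    with pytest.raises(InvalidArgumentError):
        predicted_wavelength(100.0, 0.0)


def test_track_times_must_increase():
    with pytest.raises(InvalidArgumentError):
        SourceTrack(kind="rotor", times_ms=[0.0, 0.0], points=[[0, 0], [1, 1]],
                    chirality=1)
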