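"""Source tracking and characterization: rotors, focal beats, loci.

Phase-singularity events are linked through time into candidate rotor
tracks; focal sources are found as recurring interior early-activation
origins in per-cycle isochronal maps.  Each retained track is cleaned
of isolated outlying points (interpolation artifacts), its migration
locus is smoothed with a C2 piecewise-cubic curve, and the locus area
(convex hull of the smoothed path) quantifies how spatially constrained
the source is.  Temporal conservation between two maps of the same
chamber is reported as centroid distance plus fractional hull overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from shapely.geometry import MultiPoint, Point

from .errors import InvalidArgumentError
from .geometry import ElectrodeGrid
from .isochrone import IsochroneMap
from .phase import PhaseMap, PhaseSingularityEvent

__all__ = [
    "SourceTrack",
    "ConservationReport",
    "LocusCurve",
    "link_singularities",
    "remove_outlier_points",
    "smooth_locus",
    "locus_area",
    "classify_rotor",
    "detect_focal_sources",
    "suppress_rotor_coincident_focal",
    "count_concurrent_sources",
    "conservation_metric",
    "predicted_wavelength",
]


@dataclass
class SourceTrack:
    """A tracked rotor or focal source."""

    kind: str  # "rotor" | "focal"
    times_ms: np.ndarray
    points: np.ndarray  # (n, 2) cm
    chirality: int | None = None  # +1 / -1 for rotors, None for focal
    locus_area_cm2: float | None = None
    n_rotations: float | None = None
    n_beats: int | None = None
    smoothed: "LocusCurve | None" = None

    def __post_init__(self):
        t = np.asarray(self.times_ms, dtype=float)
        p = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(t) != len(p):
            raise InvalidArgumentError("times and points must have equal length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("track sample times must strictly increase")
        self.times_ms = t
        self.points = p

    @property
    def n_samples(self) -> int:
        return len(self.times_ms)

    @property
    def time_span(self) -> tuple:
        return (float(self.times_ms[0]), float(self.times_ms[-1])) if len(self.times_ms) else (np.nan, np.nan)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "chirality": self.chirality,
            "times_ms": self.times_ms.tolist(),
            "points": self.points.tolist(),
            "time_span": list(self.time_span),
        }
        if self.locus_area_cm2 is not None:
            d["locus_area_cm2"] = float(self.locus_area_cm2)
        if self.n_rotations is not None:
            d["n_rotations"] = float(self.n_rotations)
        if self.n_beats is not None:
            d["n_beats"] = int(self.n_beats)
        return d


@dataclass(frozen=True)
class ConservationReport:
    """Spatial agreement between two source loci mapped at different times."""

    centroid_distance_cm: float
    hull_overlap: float  # area(A and B) / area(A or B), in [0, 1]
    elapsed_min: float = float("nan")
    degenerate: bool = False

    def __post_init__(self):
        if not -1e-9 <= self.hull_overlap <= 1 + 1e-9:
            raise InvalidArgumentError("overlap must be in [0, 1]")


class LocusCurve:
    """C2 piecewise-cubic interpolating curve through locus points.

    Parameterized by chord length; passes through every retained sample
    point, with continuous first and second derivatives at interior
    knots (the stated continuity of third-order curve fitting forces
    exactly this class).  Two points degenerate to a straight segment.
    """

    def __init__(self, points: np.ndarray):
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        # collapse consecutive duplicates before fitting
        if len(pts) > 1:
            keep = np.ones(len(pts), dtype=bool)
            keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
            pts = pts[keep]
        if len(pts) < 2:
            raise InvalidArgumentError("need at least 2 distinct points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        self.knots_s = s
        self.knot_points = pts
        if len(pts) == 2:
            self._spline = None
        else:
            self._spline = CubicSpline(s, pts, axis=0, bc_type="natural")

    @property
    def total_length(self) -> float:
        return float(self.knots_s[-1])

    def __call__(self, s):
        s = np.asarray(s, dtype=float)
        if self._spline is None:
            frac = np.clip(s / max(self.total_length, 1e-300), 0.0, 1.0)
            p0, p1 = self.knot_points
            return p0 + frac[..., None] * (p1 - p0)
        return self._spline(s)

    def derivative(self, s, order: int = 1):
        if self._spline is None:
            d = (self.knot_points[1] - self.knot_points[0]) / max(self.total_length, 1e-300)
            s = np.asarray(s, dtype=float)
            if order == 1:
                return np.broadcast_to(d, s.shape + (2,)).copy()
            return np.zeros(s.shape + (2,))
        return self._spline(s, nu=order)

    def sample(self, n: int = 256) -> np.ndarray:
        return self(np.linspace(0.0, self.total_length, n))


# ---------------------------------------------------------------------------
# linking


def _cluster_slab_events(events, radius: float):
    """Merge same-charge events closer than ``radius`` into centroids."""
    out = []  # (point, charge, any_boundary)
    for charge in (+1, -1):
        pts = np.array([[e.u_cm, e.v_cm] for e in events if np.sign(e.charge) == charge])
        flags = [e.boundary for e in events if np.sign(e.charge) == charge]
        used = np.zeros(len(pts), dtype=bool)
        for i in range(len(pts)):
            if used[i]:
                continue
            member = [i]
            used[i] = True
            for j in range(i + 1, len(pts)):
                if not used[j] and np.linalg.norm(pts[j] - pts[i]) <= radius:
                    member.append(j)
                    used[j] = True
            centroid = pts[member].mean(axis=0)
            out.append((centroid, charge, all(flags[m] for m in member)))
    return out


def link_singularities(
    events,
    sample_interval_ms: float = 35.0,
    max_jump_cm: float = 1.0,
    max_gap_ms: float = 105.0,
    include_boundary: bool = False,
) -> list:
    """Link singularity events into provisional rotor tracks.

    Events are binned into time slabs of ``sample_interval_ms`` (the
    rotational centre is assigned periodically, every 25-45 ms by
    default).  Within each slab, events of equal chirality are merged
    into cluster centroids; tracks then claim the nearest same-chirality
    candidate within ``max_jump_cm`` (greedy nearest-neighbour, oldest
    track first).  Unclaimed candidates open new tracks; a track with no
    match for more than ``max_gap_ms`` is closed.  Purely boundary-
    flagged clusters are ignored unless ``include_boundary`` is set.
    """
    if not 0 < sample_interval_ms:
        raise InvalidArgumentError("sample_interval_ms must be positive")
    events = sorted(events, key=lambda e: e.t_ms)
    if not events:
        return []
    t0 = events[0].t_ms
    slabs: dict = {}
    for e in events:
        slabs.setdefault(int((e.t_ms - t0) // sample_interval_ms), []).append(e)

    open_tracks: list = []  # dicts: times, points, chirality, last_t
    closed: list = []
    for si in sorted(slabs):
        t_slab = t0 + (si + 0.5) * sample_interval_ms
        cands = _cluster_slab_events(slabs[si], radius=0.5 * max_jump_cm)
        if not include_boundary:
            cands = [c for c in cands if not c[2]]
        # close stale tracks
        still = []
        for tr in open_tracks:
            if t_slab - tr["last_t"] > max_gap_ms:
                closed.append(tr)
            else:
                still.append(tr)
        open_tracks = still
        # greedy claim: oldest track first takes its nearest candidate
        unclaimed = list(range(len(cands)))
        for tr in open_tracks:
            best, best_d = None, np.inf
            for ci in unclaimed:
                pt, charge, _ = cands[ci]
                if charge != tr["chirality"]:
                    continue
                d = float(np.linalg.norm(pt - tr["points"][-1]))
                if d < best_d:
                    best, best_d = ci, d
            if best is not None and best_d <= max_jump_cm:
                pt, charge, _ = cands[best]
                tr["times"].append(t_slab)
                tr["points"].append(pt)
                tr["last_t"] = t_slab
                unclaimed.remove(best)
        for ci in unclaimed:
            pt, charge, _ = cands[ci]
            open_tracks.append(
                {"times": [t_slab], "points": [pt], "chirality": charge, "last_t": t_slab}
            )
    closed.extend(open_tracks)
    closed.sort(key=lambda tr: tr["times"][0])
    return [
        SourceTrack(
            kind="rotor",
            times_ms=np.asarray(tr["times"]),
            points=np.asarray(tr["points"]),
            chirality=tr["chirality"],
        )
        for tr in closed
    ]


# ---------------------------------------------------------------------------
# locus cleaning, smoothing, area


def remove_outlier_points(track: SourceTrack, k: float = 5.0, window: int = 11,
                          max_fraction: float = 0.2) -> SourceTrack:
    """Drop isolated extreme outlying samples (interpolation errors).

    A sample is an outlier when its distance to the track's running
    median position (centred window) exceeds ``k`` times the median
    absolute deviation of positions about that running median (i.e. the
    median of those distances).  At most ``max_fraction`` of
    samples may be dropped; if the rule would drop more, the track is
    returned unchanged with a warning.  Tracks with fewer than 4
    samples are returned unchanged.
    """
    n = track.n_samples
    if n < 4:
        warnings.warn("track too short for outlier removal; returned unchanged")
        return track
    med = np.empty_like(track.points)
    half = window // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        med[i] = np.median(track.points[lo:hi], axis=0)
    d = np.linalg.norm(track.points - med, axis=1)
    scale = float(np.median(d))
    if scale == 0.0:
        return track
    drop = d > k * scale
    if drop.sum() == 0:
        return track
    if drop.sum() > max_fraction * n:
        warnings.warn("outlier rule would drop >20% of samples; keeping all")
        return track
    keep = ~drop
    return replace(track, times_ms=track.times_ms[keep], points=track.points[keep],
                   smoothed=None, locus_area_cm2=None)


def smooth_locus(track_or_points) -> LocusCurve:
    """Fit the C2 piecewise-cubic migration-locus curve through samples."""
    pts = track_or_points.points if isinstance(track_or_points, SourceTrack) else track_or_points
    return LocusCurve(pts)


def locus_area(obj, n_samples: int = 512) -> float:
    """Convex-hull area (cm^2) of a locus.

    Accepts a SourceTrack, a LocusCurve, or an (n, 2) point array; a
    curve is sampled densely first.  Degenerate loci (fewer than 3
    distinct points, or collinear) have zero area.
    """
    if isinstance(obj, SourceTrack):
        pts = obj.points
    elif isinstance(obj, LocusCurve):
        pts = obj.sample(n_samples)
    else:
        pts = np.asarray(obj, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        return 0.0
    hull = MultiPoint(pts).convex_hull
    return float(hull.area)  # 0 for points/lines


# ---------------------------------------------------------------------------
# classification


def classify_rotor(
    track: SourceTrack,
    pm: PhaseMap,
    min_rotations: float = 2.0,
    max_gap_ms: float = 105.0,
    ring_radius_cm: tuple = (0.3, 0.7),
    min_winding_fraction: float = 0.8,
):
    """Decide whether a track is a sustained rotor.

    Two conditions must hold.  First, the phase must actually rotate
    *about* the track: at each track sample the spatial winding number
    of the phase around a ring centred on the sample point must be
    nonzero with the track's chirality, for at least
    ``min_winding_fraction`` of samples (this is what separates a pivot
    from ordinary through-going wavefronts, where every site sweeps
    2*pi per cycle in time but the spatial winding is zero).  Second,
    the rotation count — the mean temporal unwrapped phase progression
    at ring-distance nodes over the track's span, divided by 2*pi —
    must reach ``min_rotations``, with no inter-sample gap exceeding
    ``max_gap_ms``.

    Returns ``(is_rotor, rotation_count)``.
    """
    if track.n_samples < 2:
        return False, 0.0
    gaps_ok = np.all(np.diff(track.times_ms) <= max_gap_ms)
    f0 = pm.frame_index(track.times_ms[0])
    f1 = pm.frame_index(track.times_ms[-1])
    if f1 <= f0:
        return False, 0.0

    # spatial winding about each track sample
    r_ring = 0.5 * (ring_radius_cm[0] + ring_radius_cm[1])
    angles = np.linspace(0.0, 2.0 * np.pi, 17)[:-1]
    ring_offsets = r_ring * np.column_stack([np.cos(angles), np.sin(angles)])
    g = pm.grid
    windings = []
    for t, p in zip(track.times_ms, track.points):
        fr = pm.frame_index(t)
        phi_ring = []
        for off in ring_offsets:
            i = int(round((p[0] + off[0] - g.origin[0]) / g.du))
            j = int(round((p[1] + off[1] - g.origin[1]) / g.dv))
            if not (0 <= i < g.nu and 0 <= j < g.nv):
                phi_ring = []
                break
            phi_ring.append(pm.phases[fr, j, i])
        if not phi_ring or not np.all(np.isfinite(phi_ring)):
            continue
        phi_ring = np.asarray(phi_ring)
        diffs = np.angle(np.exp(1j * np.diff(np.concatenate([phi_ring, phi_ring[:1]]))))
        windings.append(int(np.round(np.sum(diffs) / (2.0 * np.pi))))
    if not windings:
        return False, 0.0
    sign = track.chirality if track.chirality in (-1, 1) else int(np.sign(np.median(windings)) or 1)
    frac = float(np.mean([w == sign for w in windings]))

    # temporal rotation count at ring nodes around the centroid
    cen = track.centroid
    U, V = pm.grid.node_coords()
    dist = np.hypot(U - cen[0], V - cen[1])
    ring = (dist >= ring_radius_cm[0]) & (dist <= ring_radius_cm[1])
    series = pm.phases[f0 : f1 + 1, ring]  # (T, n_ring)
    good = np.all(np.isfinite(series), axis=0)
    if not np.any(good):
        return False, 0.0
    unwrapped = np.unwrap(series[:, good], axis=0)
    progression = np.abs(unwrapped[-1] - unwrapped[0])
    count = float(np.mean(progression) / (2.0 * np.pi))
    is_rotor = bool(gaps_ok and frac >= min_winding_fraction and count >= min_rotations)
    return is_rotor, count


def detect_focal_sources(
    maps,
    grid: ElectrodeGrid,
    min_repeats: int = 2,
    max_jump_cm: float = 1.0,
    ray_spacings: float = 2.0,
    min_rays: int = 7,
) -> list:
    """Find repetitive focal sources in per-cycle isochronal maps.

    A candidate origin in one cycle is an interior raster node that is a
    local minimum of activation time and from which time increases
    monotonically along at least ``min_rays`` of the 8 grid rays for
    ``ray_spacings`` electrode pitches (tolerating one aberrant sector,
    e.g. a poorly timed electrode; non-radiating patterns fail several
    rays at once).  Origins recurring within ``max_jump_cm`` over at
    least ``min_repeats`` consecutive cycles form a focal track.
    """
    maps = list(maps)
    if len(maps) < min_repeats:
        return []
    pitch = grid.median_pitch()
    origins = []  # (cycle_index, t0, point) one candidate per cycle (earliest wins)
    for ci, iso in enumerate(maps):
        cands = _focal_candidates(iso, ray_length_cm=ray_spacings * pitch,
                                  min_rays=min_rays)
        for pt, t_act in cands:
            origins.append((ci, iso.cycle_window[0], pt, t_act))

    # group across consecutive cycles
    tracks = []
    used = [False] * len(origins)
    for i in range(len(origins)):
        if used[i]:
            continue
        chain = [origins[i]]
        used[i] = True
        for j in range(i + 1, len(origins)):
            if used[j]:
                continue
            prev = chain[-1]
            if origins[j][0] == prev[0]:
                continue
            if origins[j][0] - prev[0] > 1:
                break
            if np.linalg.norm(origins[j][2] - prev[2]) <= max_jump_cm:
                chain.append(origins[j])
                used[j] = True
        if len(chain) >= min_repeats:
            times = np.asarray([c[1] for c in chain], dtype=float)
            pts = np.asarray([c[2] for c in chain])
            order = np.argsort(times)
            tracks.append(
                SourceTrack(
                    kind="focal",
                    times_ms=times[order],
                    points=pts[order],
                    chirality=None,
                    n_beats=len(chain),
                )
            )
    return tracks


def _focal_candidates(iso: IsochroneMap, ray_length_cm: float, tol_ms: float = 15.0,
                      min_rays: int = 7, min_rise_ms: float = 20.0):
    """Interior local minima with monotone centrifugal activation.

    Monotonicity along rays is judged with a tolerance of ``tol_ms``:
    interpolated maps carry local texture from per-electrode detection
    jitter (up to roughly one smoothing length of the map), while
    genuine non-radiating patterns violate monotonicity by large
    fractions of the cycle length.
    """
    T = iso.times
    nv, nu = T.shape
    finite = np.isfinite(T)
    cands = []
    n_u = max(2, int(round(ray_length_cm / iso.grid.du)))
    n_v = max(2, int(round(ray_length_cm / iso.grid.dv)))
    dirs = [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)]
    # local minima among finite interior nodes
    for j in range(1, nv - 1):
        for i in range(1, nu - 1):
            if not finite[j, i]:
                continue
            patch = T[j - 1 : j + 2, i - 1 : i + 2]
            if not np.all(np.isfinite(patch)):
                continue
            if T[j, i] != patch.min():
                continue
            good_rays = 0
            for dj, di in dirs:
                if dj != 0 and di != 0:  # diagonal step is h*sqrt(2) long
                    steps = max(2, int(round(n_v / np.sqrt(2.0))))
                else:
                    steps = n_v if dj != 0 else n_u
                prev = T[j, i]
                ok = True
                for s in range(1, steps + 1):
                    jj, ii = j + dj * s, i + di * s
                    if not (0 <= jj < nv and 0 <= ii < nu) or not finite[jj, ii]:
                        ok = False
                        break
                    if T[jj, ii] < prev - tol_ms:
                        ok = False
                        break
                    prev = max(prev, T[jj, ii])
                # radiation must actually progress outward: rays that stay
                # nearly flat run along a wavefront, not away from a source
                if ok and prev - T[j, i] < min_rise_ms:
                    ok = False
                good_rays += int(ok)
            if good_rays >= min_rays:
                cands.append((np.array([iso.grid.origin[0] + i * iso.grid.du,
                                        iso.grid.origin[1] + j * iso.grid.dv]),
                              float(T[j, i])))
    if not cands:
        return []
    # keep the earliest-activating candidate cluster per cycle
    cands.sort(key=lambda c: c[1])
    best_t = cands[0][1]
    close = [c for c in cands if c[1] <= best_t + 5.0]
    pts = np.array([c[0] for c in close])
    return [(pts.mean(axis=0), best_t)]


def suppress_rotor_coincident_focal(focal_tracks, rotor_tracks,
                                    radius_cm: float = 1.0) -> list:
    """Drop focal tracks whose origin sits on a classified rotor locus.

    A single-cycle isochronal map of a rotor also shows activation
    radiating from near the core, so the focal detector can fire there;
    the rotational interpretation, established from the phase field,
    takes precedence (the two source kinds are mutually exclusive
    readings of the same region).
    """
    kept = []
    for f in focal_tracks:
        near = False
        for r in rotor_tracks:
            d = np.linalg.norm(r.points - f.centroid, axis=1).min()
            if d <= radius_cm:
                near = True
                break
        if not near:
            kept.append(f)
    return kept


def count_concurrent_sources(tracks, window: tuple) -> int:
    """Number of tracks whose time span overlaps the window."""
    t0, t1 = window
    n = 0
    for tr in tracks:
        a, b = tr.time_span
        if np.isfinite(a) and a <= t1 and b >= t0:
            n += 1
    return n


def conservation_metric(track_a: SourceTrack, track_b: SourceTrack,
                        elapsed_min: float = float("nan"),
                        buffer_cm: float = 0.1) -> ConservationReport:
    """Spatial conservation of a source between two mapping sessions.

    Centroid distance between loci plus fractional hull overlap
    (intersection over union).  Degenerate hulls (zero area) are
    buffered by 1 mm and the report flagged.
    """
    if track_a.n_samples == 0 or track_b.n_samples == 0:
        raise InvalidArgumentError("both tracks must be non-empty")
    ca, cb = track_a.centroid, track_b.centroid
    dist = float(np.linalg.norm(ca - cb))
    ha = MultiPoint(track_a.points).convex_hull
    hb = MultiPoint(track_b.points).convex_hull
    degenerate = ha.area == 0 or hb.area == 0
    if degenerate:
        ha = ha.buffer(buffer_cm)
        hb = hb.buffer(buffer_cm)
    union = ha.union(hb).area
    overlap = float(ha.intersection(hb).area / union) if union > 0 else 0.0
    return ConservationReport(
        centroid_distance_cm=dist,
        hull_overlap=overlap,
        elapsed_min=elapsed_min,
        degenerate=degenerate,
    )


def predicted_wavelength(repolarization_ms: float, cv_cm_s: float) -> float:
    """Minimum reentrant wavelength in mm: repolarization time x CV.

    The clinical resolution argument: the shortest path that can sustain
    re-entry is the recovery time times the slowest conduction velocity,
    e.g. 100 ms x 40 cm/s = 40 mm.
    """
    if repolarization_ms <= 0 or cv_cm_s <= 0:
        raise InvalidArgumentError("repolarization and CV must be positive")
    return repolarization_ms * cv_cm_s / 100.0


def tracks_to_json_dict(tracks) -> dict:
    """Serializable summary of a track list."""
    return {"tracks": [t.to_dict() for t in tracks]}


def tracks_to_frame(tracks) -> pd.DataFrame:
    rows = []
    for t in tracks:
        rows.append(
            {
                "kind": t.kind,
                "chirality": t.chirality if t.chirality is not None else 0,
                "n_samples": t.n_samples,
                "t_start_ms": t.time_span[0],
                "t_end_ms": t.time_span[1],
                "locus_area_cm2": t.locus_area_cm2,
                "n_rotations": t.n_rotations,
                "n_beats": t.n_beats,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["kind", "chirality", "n_samples", "t_start_ms", "t_end_ms",
                 "locus_area_cm2", "n_rotations", "n_beats"],
    )
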