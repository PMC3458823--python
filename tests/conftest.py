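"""Shared fixtures: simulated episodes and processed mapping chains.

Episodes are simulated once per session on a 0.03 cm tissue grid (the
production default is 0.02 cm); all downstream tests share them.  Every
random element is seeded so the suite is fully deterministic.
"""

import numpy as np
import pytest

from fibmap import (
    AnalysisGrid,
    RestitutionCurve,
    TissueParams,
    bandpass,
    build_isochrone_map,
    detect_activations,
    detect_focal_sources,
    instantaneous_phase,
    link_singularities,
    make_episode,
    phase_field,
    restitution_filter,
    segment_cycles,
)
from fibmap.errors import InsufficientDataError
from fibmap.phase import detect_singularity_events
from fibmap.sources import classify_rotor, suppress_rotor_coincident_focal

TEST_PARAMS = TissueParams(h_cm=0.03, dt_ms=0.2)


@pytest.fixture(scope="session")
def test_params():
    return TEST_PARAMS


@pytest.fixture(scope="session")
def spiral_episode():
    return make_episode("spiral", params=TEST_PARAMS, duration_ms=1500.0, seed=0)


@pytest.fixture(scope="session")
def meander_episode():
    return make_episode("spiral", params=TEST_PARAMS, duration_ms=1500.0, seed=0,
                        meander_level=0.3)


@pytest.fixture(scope="session")
def focal_episode():
    return make_episode("focal", params=TEST_PARAMS, duration_ms=1250.0, seed=1,
                        cycle_length_ms=250.0)


@pytest.fixture(scope="session")
def plane_episode():
    return make_episode("planewave", params=TEST_PARAMS, duration_ms=1400.0, seed=2,
                        cycle_length_ms=400.0)


def _chain(episode, ps_stride_ms=5.0):
    """Run the standard mapping chain on an episode."""
    rec = bandpass(episode.recording, 0.05, episode.recording.fs / 2.0)
    series = restitution_filter(detect_activations(rec), RestitutionCurve.flat(100.0))
    target = AnalysisGrid.from_electrodes(episode.grid, spacing=0.1)
    maps = []
    try:
        windows = segment_cycles(series)
    except InsufficientDataError:
        windows = []
    for w in windows:
        try:
            maps.append(build_isochrone_map(series, episode.grid, w, target))
        except InsufficientDataError:
            continue
    phases, _ = instantaneous_phase(rec)
    pm = phase_field(phases, episode.grid, target, times_ms=rec.times_ms, fs=rec.fs)
    events = detect_singularity_events(pm, stride_ms=ps_stride_ms)
    nonboundary = [e for e in events if not e.boundary]
    tracks = link_singularities(nonboundary, sample_interval_ms=35.0, max_jump_cm=1.0)
    rotors = []
    for tr in tracks:
        is_rotor, count = classify_rotor(tr, pm)
        if is_rotor:
            tr.n_rotations = count
            rotors.append(tr)
    focal = suppress_rotor_coincident_focal(
        detect_focal_sources(maps, episode.grid), rotors)
    return {
        "episode": episode,
        "rec": rec,
        "series": series,
        "target": target,
        "maps": maps,
        "pm": pm,
        "events": events,
        "nonboundary": nonboundary,
        "tracks": tracks,
        "rotors": rotors,
        "focal": focal,
    }


@pytest.fixture(scope="session")
def spiral_chain(spiral_episode):
    return _chain(spiral_episode)


@pytest.fixture(scope="session")
def focal_chain(focal_episode):
    return _chain(focal_episode)


@pytest.fixture(scope="session")
def plane_chain(plane_episode):
    return _chain(plane_episode)


@pytest.fixture(scope="session")
def spiral_reports():
    """Two identical scaled pipeline runs (determinism + rotor content)."""
    from fibmap.pipeline import run_pipeline, validate_config

    cfg = validate_config({"tissue_h_cm": 0.03, "tissue_dt_ms": 0.2,
                           "kind": "spiral", "duration_ms": 1200.0, "seed": 3})
    r1, art1 = run_pipeline(cfg)
    r2, _ = run_pipeline(cfg)
    return r1, r2, art1


def dominant_track(tracks):
    """The track with the most samples (ties: earliest start)."""
    return max(tracks, key=lambda t: (t.n_samples, -t.times_ms[0]))


def nearest_truth_distance(track, truth):
    """Per-sample distance from track points to the time-nearest truth tip."""
    out = []
    for t, p in zip(track.times_ms, track.points):
        i = int(np.argmin(np.abs(truth.tip_times_ms - t)))
        out.append(float(np.linalg.norm(truth.tip_positions[i] - p)))
    return np.asarray(out)
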