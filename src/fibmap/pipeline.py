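"""End-to-end pipeline: simulate/ingest -> activations -> maps -> phase -> tracks.

The run configuration is a flat key-value document with strict
validation: unknown keys and out-of-range values are errors, so a run
report always echoes the exact, complete parameter set that produced
it.  All randomness derives from the single ``seed`` (per-stage
substreams are offsets of it), making reports byte-identical across
repeated runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .activation import (
    RestitutionCurve,
    bandpass,
    cycle_length_stats,
    detect_activations,
    restitution_filter,
)
from .errors import ConfigError, InsufficientDataError
from .geometry import AnalysisGrid, make_basket_geometry
from .isochrone import build_isochrone_map, segment_cycles
from .phase import detect_singularity_events, events_to_frame, instantaneous_phase, phase_field
from .simulate import TissueParams, make_episode
from .sources import (
    classify_rotor,
    detect_focal_sources,
    link_singularities,
    locus_area,
    remove_outlier_points,
    smooth_locus,
    suppress_rotor_coincident_focal,
    tracks_to_frame,
    tracks_to_json_dict,
)

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline", "DEFAULTS"]

# key -> (default, type, (lo, hi) or tuple of choices)
_SCHEMA = {
    "kind": ("spiral", str, ("spiral", "focal", "planewave")),
    "duration_ms": (1500.0, float, (400.0, 20000.0)),
    "seed": (0, int, (0, 2**31 - 1)),
    "noise_sd": (0.0, float, (0.0, 1.0)),
    "meander_level": (0.0, float, (0.0, 0.5)),
    "cycle_length_ms": (200.0, float, (120.0, 500.0)),
    "focal_origin_u": (2.0, float, (0.0, 10.0)),
    "focal_origin_v": (2.0, float, (0.0, 10.0)),
    "sample_interval_ms": (35.0, float, (25.0, 45.0)),
    "min_apd_ms": (100.0, float, (100.0, 110.0)),
    "min_rotations": (2.0, float, (0.5, 10.0)),
    "detrend": ("moving_mean", str, ("moving_mean", "mean", "none")),
    "spline_count": (8, int, (1, 26)),
    "electrodes_per_spline": (8, int, (1, 64)),
    "sheet_extent_cm": (4.0, float, (2.0, 10.0)),
    "analysis_spacing_cm": (0.1, float, (0.05, 0.5)),
    "max_jump_cm": (1.0, float, (0.2, 2.0)),
    "lockout_ms": (50.0, float, (10.0, 200.0)),
    "ps_stride_ms": (5.0, float, (1.0, 45.0)),
    "tissue_h_cm": (0.02, float, (0.005, 0.1)),
    "tissue_dt_ms": (0.25, float, (0.01, 2.0)),
}

DEFAULTS = {k: v[0] for k, v in _SCHEMA.items()}


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (see ``DEFAULTS`` for keys)."""

    values: dict

    def __getattr__(self, key):
        try:
            return self.values[key]
        except KeyError as exc:  # pragma: no cover - guarded by schema
            raise AttributeError(key) from exc

    def to_dict(self) -> dict:
        return dict(sorted(self.values.items()))


def validate_config(raw: dict | None = None, force: bool = False) -> RunConfig:
    """Validate a flat key-value document against the schema.

    Unknown keys are errors (naming the key); values are coerced to the
    declared type and range-checked.  ``force=True`` skips range checks
    (types and known-key checks still apply).  An empty document yields
    the full default configuration.
    """
    raw = dict(raw or {})
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    out = {}
    for key, (default, typ, bounds) in _SCHEMA.items():
        val = raw.get(key, default)
        try:
            val = typ(val)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"key {key!r}: cannot coerce {val!r} to {typ.__name__}") from exc
        if not force:
            if isinstance(bounds, tuple) and bounds and isinstance(bounds[0], str):
                if val not in bounds:
                    raise ConfigError(f"key {key!r}: {val!r} not in {bounds}")
            else:
                lo, hi = bounds
                if not lo <= val <= hi:
                    raise ConfigError(f"key {key!r}: {val} outside [{lo}, {hi}]")
        out[key] = val
    return RunConfig(values=out)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass
class RunReport:
    """Per-run parameter echo plus per-episode source summary."""

    config: dict
    version: str
    truth: dict
    cycle_length: dict
    n_sources: int
    sources: list
    n_singularity_events: int = 0
    n_cycles_mapped: int = 0

    def to_json(self) -> str:
        return json.dumps(_jsonable(asdict(self)), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def run_pipeline(config: RunConfig, out_dir=None, keep_movie: bool = False):
    """Execute the full mapping chain on one simulated episode.

    Returns ``(report, artifacts)`` where ``artifacts`` is a dict of the
    intermediate objects (episode, activation series, maps, phase map,
    events, tracks).  When ``out_dir`` is given, intermediates are
    written there (activations.csv, events.csv, tracks.json,
    report.json).
    """
    c = config
    extent = (c.sheet_extent_cm, c.sheet_extent_cm)
    params = TissueParams(size_cm=extent, h_cm=c.tissue_h_cm, dt_ms=c.tissue_dt_ms)
    grid = make_basket_geometry(
        c.spline_count, c.electrodes_per_spline, sheet_extent=extent, jitter_seed=c.seed
    )
    episode = make_episode(
        c.kind,
        params=params,
        grid=grid,
        duration_ms=c.duration_ms,
        seed=c.seed,
        noise_sd=c.noise_sd,
        meander_level=c.meander_level,
        cycle_length_ms=c.cycle_length_ms,
        focal_origin=(c.focal_origin_u, c.focal_origin_v),
        keep_movie=keep_movie,
    )
    rec = bandpass(episode.recording, 0.05, episode.recording.fs / 2.0)
    series = detect_activations(rec, lockout_ms=c.lockout_ms)
    series = restitution_filter(series, RestitutionCurve.flat(c.min_apd_ms))

    target = AnalysisGrid.from_electrodes(grid, spacing=c.analysis_spacing_cm)
    maps = []
    try:
        windows = segment_cycles(series)
    except InsufficientDataError:
        windows = []
    for w in windows:
        try:
            maps.append(build_isochrone_map(series, grid, w, target))
        except InsufficientDataError:
            continue

    phases, _ = instantaneous_phase(rec, detrend=c.detrend)
    pm = phase_field(phases, grid, target, times_ms=rec.times_ms, fs=rec.fs)
    events = detect_singularity_events(pm, stride_ms=c.ps_stride_ms)

    raw_tracks = link_singularities(
        events, sample_interval_ms=c.sample_interval_ms, max_jump_cm=c.max_jump_cm
    )
    rotor_tracks = []
    for tr in raw_tracks:
        tr = remove_outlier_points(tr)
        is_rotor, count = classify_rotor(tr, pm, min_rotations=c.min_rotations)
        if is_rotor:
            tr.n_rotations = count
            if tr.n_samples >= 2:
                tr.smoothed = smooth_locus(tr)
                tr.locus_area_cm2 = locus_area(tr.smoothed)
            else:
                tr.locus_area_cm2 = 0.0
            rotor_tracks.append(tr)
    focal_tracks = detect_focal_sources(maps, grid, max_jump_cm=c.max_jump_cm)
    focal_tracks = suppress_rotor_coincident_focal(focal_tracks, rotor_tracks)
    for tr in focal_tracks:
        tr.locus_area_cm2 = locus_area(tr.points)
    tracks = rotor_tracks + focal_tracks

    cl = cycle_length_stats(series)
    cl.pop("undefined_channels", None)
    report = RunReport(
        config=c.to_dict(),
        version=__version__,
        truth=episode.truth.to_dict() if c.kind != "spiral" else {
            "episode_kind": "spiral", "period_ms": episode.truth.period_ms,
            "n_tip_samples": int(len(episode.truth.tip_times_ms)),
        },
        cycle_length=cl,
        n_sources=len(tracks),
        sources=[
            {
                "kind": t.kind,
                "chirality": t.chirality,
                "time_span_ms": list(t.time_span),
                "n_samples": t.n_samples,
                "locus_area_cm2": t.locus_area_cm2,
                "n_rotations": t.n_rotations,
                "n_beats": t.n_beats,
            }
            for t in tracks
        ],
        n_singularity_events=len(events),
        n_cycles_mapped=len(maps),
    )

    artifacts = {
        "episode": episode,
        "series": series,
        "maps": maps,
        "phase_map": pm,
        "events": events,
        "tracks": tracks,
    }
    if out_dir is not None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        series.to_csv(d / "activations.csv")
        events_to_frame(events).to_csv(d / "events.csv", index=False)
        (d / "tracks.json").write_text(json.dumps(_jsonable(tracks_to_json_dict(tracks)),
                                                  indent=1, sort_keys=True))
        tracks_to_frame(tracks).to_csv(d / "tracks_summary.csv", index=False)
        (d / "report.json").write_text(report.to_json())
    return report, artifacts
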