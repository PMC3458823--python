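"""Episode bundles and tabular exports.

An episode bundle is one HDF5 file with groups ``/recording`` (channels
x samples float32 mV, ``fs`` attribute), ``/geometry`` (coordinate
table) and ``/truth`` (ground-truth scalars and arrays).  A plain-text
alternative (recording CSV + geometry CSV + truth JSON) covers
environments without HDF5 tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .activation import EgmRecording
from .geometry import ElectrodeGrid, grid_from_csv, grid_to_csv
from .simulate import GroundTruth, SimulatedEpisode

__all__ = ["write_episode_h5", "read_episode_h5", "write_episode_text", "read_episode_text"]


def write_episode_h5(episode: SimulatedEpisode, path) -> None:
    with h5py.File(path, "w") as f:
        rec = f.create_group("recording")
        rec.create_dataset("samples", data=episode.recording.samples.astype(np.float32))
        rec.attrs["fs"] = episode.recording.fs
        rec.create_dataset(
            "channel_ids",
            data=np.array([c.encode() for c in episode.recording.channel_ids]),
        )
        geo = f.create_group("geometry")
        geo.create_dataset("coords", data=episode.grid.coords)
        geo.create_dataset(
            "channel_ids", data=np.array([c.encode() for c in episode.grid.channel_ids])
        )
        geo.attrs["atrium_label"] = episode.grid.atrium_label
        geo.attrs["spline_count"] = episode.grid.spline_count
        geo.attrs["electrodes_per_spline"] = episode.grid.electrodes_per_spline
        tr = f.create_group("truth")
        tr.attrs["episode_kind"] = episode.truth.episode_kind
        tr.attrs["period_ms"] = episode.truth.period_ms
        tr.attrs["capture_warning"] = episode.truth.capture_warning
        tr.attrs["seed"] = episode.seed
        if episode.truth.tip_times_ms is not None:
            tr.create_dataset("tip_times_ms", data=np.asarray(episode.truth.tip_times_ms))
            tr.create_dataset("tip_positions", data=np.asarray(episode.truth.tip_positions))
        if episode.truth.origin is not None:
            tr.attrs["origin_u"] = episode.truth.origin[0]
            tr.attrs["origin_v"] = episode.truth.origin[1]
        if episode.truth.cycle_length_ms is not None:
            tr.attrs["cycle_length_ms"] = episode.truth.cycle_length_ms
        if episode.truth.speed_cm_s is not None:
            tr.attrs["speed_cm_s"] = episode.truth.speed_cm_s
            tr.create_dataset("direction", data=np.asarray(episode.truth.direction))


def read_episode_h5(path) -> SimulatedEpisode:
    with h5py.File(path, "r") as f:
        rec = EgmRecording(
            samples=f["recording/samples"][()],
            fs=float(f["recording"].attrs["fs"]),
            channel_ids=tuple(c.decode() for c in f["recording/channel_ids"][()]),
        )
        geo = f["geometry"]
        grid = ElectrodeGrid(
            coords=geo["coords"][()],
            channel_ids=tuple(c.decode() for c in geo["channel_ids"][()]),
            atrium_label=str(geo.attrs["atrium_label"]),
            spline_count=int(geo.attrs["spline_count"]),
            electrodes_per_spline=int(geo.attrs["electrodes_per_spline"]),
        )
        tr = f["truth"]
        truth = GroundTruth(
            episode_kind=str(tr.attrs["episode_kind"]),
            period_ms=float(tr.attrs["period_ms"]),
            capture_warning=bool(tr.attrs["capture_warning"]),
        )
        if "tip_times_ms" in tr:
            truth.tip_times_ms = tr["tip_times_ms"][()]
            truth.tip_positions = tr["tip_positions"][()]
        if "origin_u" in tr.attrs:
            truth.origin = (float(tr.attrs["origin_u"]), float(tr.attrs["origin_v"]))
        if "cycle_length_ms" in tr.attrs:
            truth.cycle_length_ms = float(tr.attrs["cycle_length_ms"])
        if "speed_cm_s" in tr.attrs:
            truth.speed_cm_s = float(tr.attrs["speed_cm_s"])
            truth.direction = tuple(tr["direction"][()])
        seed = int(tr.attrs["seed"])
    return SimulatedEpisode(recording=rec, grid=grid, truth=truth, seed=seed)


def write_episode_text(episode: SimulatedEpisode, directory) -> None:
    """Plain-text bundle: recording.csv + geometry.csv + truth.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(episode.recording.samples.T, columns=list(episode.recording.channel_ids))
    df.insert(0, "t_ms", episode.recording.times_ms)
    df.to_csv(d / "recording.csv", index=False)
    grid_to_csv(episode.grid, d / "geometry.csv")
    truth = episode.truth.to_dict()
    truth["fs"] = episode.recording.fs
    truth["seed"] = episode.seed
    (d / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def read_episode_text(directory) -> SimulatedEpisode:
    d = Path(directory)
    df = pd.read_csv(d / "recording.csv")
    truth_doc = json.loads((d / "truth.json").read_text())
    channel_ids = [c for c in df.columns if c != "t_ms"]
    rec = EgmRecording(
        samples=df[channel_ids].to_numpy(float).T,
        fs=float(truth_doc["fs"]),
        channel_ids=tuple(channel_ids),
    )
    grid = grid_from_csv(d / "geometry.csv")
    truth = GroundTruth(
        episode_kind=truth_doc["episode_kind"],
        period_ms=float(truth_doc["period_ms"]),
        capture_warning=bool(truth_doc.get("capture_warning", False)),
    )
    if "tip_times_ms" in truth_doc:
        truth.tip_times_ms = np.asarray(truth_doc["tip_times_ms"])
        truth.tip_positions = np.asarray(truth_doc["tip_positions"])
    if "origin" in truth_doc:
        truth.origin = tuple(truth_doc["origin"])
    if "cycle_length_ms" in truth_doc:
        truth.cycle_length_ms = float(truth_doc["cycle_length_ms"])
    if "speed_cm_s" in truth_doc:
        truth.speed_cm_s = float(truth_doc["speed_cm_s"])
        truth.direction = tuple(truth_doc["direction"])
    return SimulatedEpisode(recording=rec, grid=grid, truth=truth, seed=int(truth_doc["seed"]))
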