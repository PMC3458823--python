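"""Hilbert-transform phase mapping and phase-singularity detection.

Each electrogram is assigned an instantaneous phase — the angle of its
analytic signal — so one fibrillatory cycle sweeps the phase through
2*pi.  Phases are interpolated to the analysis raster on the unit
circle (via cos/sin, never raw angles, so the +/-pi wrap is handled
correctly).  A phase singularity is a point where all phases converge:
the line integral of the phase gradient around it is +/-2*pi rather
than zero.  On the raster this integral is evaluated on every 2x2 node
plaquette as the sum of the four wrapped phase differences around the
loop; the topological charge is that sum divided by 2*pi.  A rotor's
pivot carries charge +/-1 (the sign is its chirality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert

from .activation import EgmRecording
from .errors import InvalidArgumentError
from .geometry import AnalysisGrid, ElectrodeGrid, interpolate_to_grid

__all__ = [
    "PhaseMap",
    "PhaseSingularityEvent",
    "instantaneous_phase",
    "phase_field",
    "detect_phase_singularities",
    "winding_number_oracle",
    "events_to_frame",
]

TWO_PI = 2.0 * np.pi


def _wrap(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - x, TWO_PI)


@dataclass(frozen=True)
class PhaseMap:
    """Instantaneous phase field on the raster over time.

    ``phases`` has shape (n_times, nv, nu), values in (-pi, pi], NaN
    outside the electrode hull.
    """

    grid: AnalysisGrid
    phases: np.ndarray
    times_ms: np.ndarray
    fs: float

    def __post_init__(self):
        p = np.asarray(self.phases, dtype=float)
        object.__setattr__(self, "phases", p)
        object.__setattr__(self, "times_ms", np.asarray(self.times_ms, dtype=float))
        if p.ndim != 3 or p.shape[1:] != (self.grid.nv, self.grid.nu):
            raise InvalidArgumentError("phases must be (n_times, nv, nu)")
        if p.shape[0] != len(self.times_ms):
            raise InvalidArgumentError("times_ms length must match phases")
        finite = p[np.isfinite(p)]
        if finite.size and (finite.min() <= -np.pi - 1e-9 or finite.max() > np.pi + 1e-9):
            raise InvalidArgumentError("phases must lie in (-pi, pi]")

    def frame_index(self, t_ms: float) -> int:
        return int(np.argmin(np.abs(self.times_ms - t_ms)))


@dataclass(frozen=True)
class PhaseSingularityEvent:
    """A detected phase singularity at one time sample."""

    t_ms: float
    u_cm: float
    v_cm: float
    charge: int
    boundary: bool = False

    def __post_init__(self):
        if abs(self.charge) < 1:
            raise InvalidArgumentError("charge magnitude must be >= 1")


def dominant_frequency(x: np.ndarray, fs: float, band=(1.0, 20.0)) -> float:
    """Dominant frequency (Hz) of a channel within the AF-relevant band."""
    x = x - np.mean(x)
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(max(8 * n, 1024))))  # pad for fine resolution
    spec = np.abs(np.fft.rfft(x, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel) or np.allclose(spec[sel], 0):
        return float("nan")
    return float(freqs[sel][np.argmax(spec[sel])])


def instantaneous_phase(rec: EgmRecording, detrend: str = "moving_mean"):
    """Per-channel instantaneous phase via the Hilbert transform.

    ``detrend`` selects the pre-processing ahead of the transform:

    - ``"moving_mean"`` (default): subtract the moving mean over one
      dominant cycle length, the minimal stabilization against the
      baseline drift that survives a 0.05 Hz high-pass;
    - ``"mean"``: subtract the global mean only;
    - ``"none"``: use the raw signal.

    Returns ``(phases, valid)``: phases is (n_channels, n_samples) in
    (-pi, pi]; ``valid`` flags channels with nonzero variance after
    detrending (others carry NaN phase — the undefined-phase flag).
    """
    if detrend not in ("moving_mean", "mean", "none"):
        raise InvalidArgumentError(f"unknown detrend mode {detrend!r}")
    x = rec.samples.astype(float)
    if detrend == "moving_mean":
        out = np.empty_like(x)
        for i in range(x.shape[0]):
            f = dominant_frequency(x[i], rec.fs)
            win = int(round(rec.fs / f)) if np.isfinite(f) and f > 0 else x.shape[1]
            win = max(3, min(win, x.shape[1]))
            out[i] = x[i] - uniform_filter1d(x[i], size=win, mode="nearest")
        x = out
    elif detrend == "mean":
        x = x - x.mean(axis=1, keepdims=True)

    valid = x.std(axis=1) > 0
    phases = np.full(x.shape, np.nan)
    if np.any(valid):
        analytic = hilbert(x[valid], axis=1)
        phases[valid] = _wrap(np.angle(analytic))
    return phases, valid


def phase_field(
    channel_phases: np.ndarray,
    grid: ElectrodeGrid,
    target: AnalysisGrid,
    times_ms: np.ndarray | None = None,
    fs: float = 1000.0,
) -> PhaseMap:
    """Interpolate channel phases to the raster on the unit circle.

    cos and sin of the phase are interpolated separately and recombined
    by ``atan2``, which is exact at electrode locations, respects the
    +/-pi wrap, and is equivariant under global phase rotation.
    ``channel_phases`` is (n_channels, n_times); channels that are NaN
    at a time sample are excluded from that sample's interpolation.
    """
    ph = np.atleast_2d(np.asarray(channel_phases, dtype=float))
    if ph.shape[0] != grid.n_channels:
        raise InvalidArgumentError("one phase row per channel required")
    n_t = ph.shape[1]
    if times_ms is None:
        times_ms = np.arange(n_t) / fs * 1000.0

    cos_f = np.empty((n_t, target.nv, target.nu))
    sin_f = np.empty((n_t, target.nv, target.nu))
    valid_all = np.all(np.isfinite(ph), axis=1)
    if np.all(valid_all):
        # fast path: one triangulation, vector-valued interpolation
        from scipy.interpolate import LinearNDInterpolator
        from scipy.spatial import Delaunay, QhullError

        from .errors import DegenerateGeometryError

        try:
            tri = Delaunay(grid.coords)
        except QhullError as exc:
            raise DegenerateGeometryError(str(exc)) from exc
        U, V = target.node_coords()
        nodes = np.column_stack([U.ravel(), V.ravel()])
        vals = np.concatenate([np.cos(ph), np.sin(ph)], axis=1)  # (n_ch, 2*n_t)
        interp = LinearNDInterpolator(tri, vals)
        out = interp(nodes)  # (n_nodes, 2*n_t)
        cos_f = out[:, :n_t].T.reshape(n_t, target.nv, target.nu)
        sin_f = out[:, n_t:].T.reshape(n_t, target.nv, target.nu)
    else:
        for ti in range(n_t):
            cos_f[ti] = interpolate_to_grid(np.cos(ph[:, ti]), grid, target)
            sin_f[ti] = interpolate_to_grid(np.sin(ph[:, ti]), grid, target)

    with np.errstate(invalid="ignore"):
        field = np.arctan2(sin_f, cos_f)
        field[~(np.isfinite(cos_f) & np.isfinite(sin_f))] = np.nan
    field = _wrap(field)
    return PhaseMap(grid=target, phases=field, times_ms=np.asarray(times_ms, float), fs=fs)


def _plaquette_sums(phi: np.ndarray) -> np.ndarray:
    """Wrapped loop sums over all 2x2 plaquettes of one phase frame.

    The loop runs counterclockwise in (u, v):
    (j,i) -> (j,i+1) -> (j+1,i+1) -> (j+1,i) -> (j,i).
    """
    d1 = _wrap(phi[:-1, 1:] - phi[:-1, :-1])
    d2 = _wrap(phi[1:, 1:] - phi[:-1, 1:])
    d3 = _wrap(phi[1:, :-1] - phi[1:, 1:])
    d4 = _wrap(phi[:-1, :-1] - phi[1:, :-1])
    return d1 + d2 + d3 + d4


def detect_phase_singularities(
    pm: PhaseMap,
    t_ms: float | None = None,
    frame: int | None = None,
    include_boundary: bool = True,
) -> list:
    """Topological-charge phase-singularity detection on one frame.

    Every 2x2 plaquette whose wrapped loop sum exceeds pi in magnitude
    emits an event with charge ``round(sum / 2*pi)`` at the plaquette
    centre.  Plaquettes adjacent to missing (NaN) nodes or to the raster
    edge are flagged ``boundary=True`` — these are the dominant source
    of interpolation artifacts and are excluded from tracking by
    default downstream.  Set ``include_boundary=False`` to drop them
    here.
    """
    if frame is None:
        if t_ms is None:
            raise InvalidArgumentError("give t_ms or frame")
        frame = pm.frame_index(t_ms)
    phi = pm.phases[frame]
    sums = _plaquette_sums(phi)
    finite = (
        np.isfinite(phi[:-1, :-1])
        & np.isfinite(phi[:-1, 1:])
        & np.isfinite(phi[1:, :-1])
        & np.isfinite(phi[1:, 1:])
    )
    hits = finite & (np.abs(sums) > np.pi)
    if not np.any(hits):
        return []

    # a plaquette is 'boundary' if any node within one ring is missing or off-grid
    nv, nu = phi.shape
    pad = np.pad(np.isfinite(phi), 1, constant_values=False)
    events = []
    t = float(pm.times_ms[frame])
    g = pm.grid
    for j, i in zip(*np.nonzero(hits)):
        charge = int(np.round(sums[j, i] / TWO_PI))
        if charge == 0:
            continue
        # ring of nodes around the plaquette in padded coords
        ring = pad[j : j + 4, i : i + 4]
        boundary = not np.all(ring)
        if boundary and not include_boundary:
            continue
        events.append(
            PhaseSingularityEvent(
                t_ms=t,
                u_cm=float(g.origin[0] + (i + 0.5) * g.du),
                v_cm=float(g.origin[1] + (j + 0.5) * g.dv),
                charge=charge,
                boundary=boundary,
            )
        )
    return events


def detect_singularity_events(pm: PhaseMap, stride_ms: float = 1.0, include_boundary: bool = True) -> list:
    """Run plaquette detection over the whole map at the given stride."""
    step = max(1, int(round(stride_ms / (1000.0 / pm.fs))))
    events = []
    for f in range(0, pm.phases.shape[0], step):
        events.extend(detect_phase_singularities(pm, frame=f, include_boundary=include_boundary))
    return events


def winding_number_oracle(pm: PhaseMap, path, frame: int = 0) -> int:
    """Reference winding number: wrapped phase-difference sum on a loop.

    ``path`` is a sequence of (j, i) node indices forming a closed loop
    (first == last, or it is closed implicitly); all nodes must carry
    defined phase.  Returns the loop integral of the phase gradient
    divided by 2*pi, rounded to the nearest integer.
    """
    path = [tuple(p) for p in path]
    if len(path) < 3:
        raise InvalidArgumentError("path must have at least 3 nodes")
    if path[0] != path[-1]:
        raise InvalidArgumentError("path must be closed (first node == last node)")
    phi = pm.phases[frame]
    total = 0.0
    for (j0, i0), (j1, i1) in zip(path[:-1], path[1:]):
        a, b = phi[j0, i0], phi[j1, i1]
        if not (np.isfinite(a) and np.isfinite(b)):
            raise InvalidArgumentError("path crosses undefined nodes")
        total += float(_wrap(b - a))
    return int(np.round(total / TWO_PI))


def rectangle_path(j0: int, j1: int, i0: int, i1: int) -> list:
    """Closed counterclockwise boundary path of a node rectangle."""
    path = []
    for i in range(i0, i1):
        path.append((j0, i))
    for j in range(j0, j1):
        path.append((j, i1))
    for i in range(i1, i0, -1):
        path.append((j1, i))
    for j in range(j1, j0, -1):
        path.append((j, i0))
    path.append((j0, i0))
    return path


def events_to_frame(events) -> pd.DataFrame:
    """Events as a DataFrame: t_ms,u_cm,v_cm,charge,boundary."""
    return pd.DataFrame(
        [
            {"t_ms": e.t_ms, "u_cm": e.u_cm, "v_cm": e.v_cm,
             "charge": e.charge, "boundary": e.boundary}
            for e in events
        ],
        columns=["t_ms", "u_cm", "v_cm", "charge", "boundary"],
    )
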