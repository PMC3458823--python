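"""Synthetic episode generator: spiral, focal, and plane-wave activity.

The stand-in for clinical recordings is a two-variable
excitation/recovery (Aliev-Panfilov-type) monodomain sheet:

    du/dt = D lap(u) + [ k u (1 - u)(u - a) - u w ] / tau
    dw/dt = [ (eps0 + mu1 w / (u + mu2)) (-w - k u (u - b - 1)) ] / tau

with ``u`` the dimensionless transmembrane variable, ``w`` the recovery
variable, ``D`` the diffusion coefficient (cm^2/ms) and ``tau`` (ms) the
kinetic time scale.  Default parameters produce a stable spiral with a
period near 180 ms — inside the 150-250 ms human AF cycle-length band —
and a wavelength of roughly 2.4 cm on the 4 x 4 cm sheet (a desk-scale
reduction of the clinical 4-5 cm reentrant wavelength that preserves the
clinical ratio of wavelength to electrode pitch, about 4).

Episodes are sampled at basket electrodes as pseudo-unipolar
electrograms: a distance-weighted sum of -du/dt over all tissue nodes
(dipole-layer 1/r^2 kernel by default) plus white noise, resampled to
the clinical 1 kHz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import MultiLineString
from skimage import measure

from .activation import EgmRecording
from .errors import InvalidArgumentError, SimulationFailureError
from .geometry import ElectrodeGrid

__all__ = [
    "TissueParams",
    "StateMovie",
    "GroundTruth",
    "SimulatedEpisode",
    "simulate_spiral",
    "simulate_focal",
    "simulate_planewave",
    "true_tip_trajectory",
    "sample_electrograms",
    "make_episode",
]


@dataclass(frozen=True)
class TissueParams:
    """Monodomain sheet parameters (physical units: cm, ms).

    Defaults: 4 x 4 cm sheet at 0.02 cm node spacing (201 x 201 nodes),
    explicit Euler at dt = 0.15 ms, kinetics k=8, a=0.1, b=0.15,
    eps0=0.002, mu1=0.2, mu2=0.3 with tau = 7 ms.
    """

    size_cm: tuple = (4.0, 4.0)
    h_cm: float = 0.02
    diffusion: float = 6.6e-4  # cm^2/ms
    tau_ms: float = 7.0
    dt_ms: float = 0.15
    k: float = 8.0
    a: float = 0.1
    b: float = 0.15
    eps0: float = 0.002
    mu1: float = 0.2
    mu2: float = 0.3

    def __post_init__(self):
        for name in ("h_cm", "diffusion", "tau_ms", "dt_ms", "k", "mu2"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.size_cm[0] <= 0 or self.size_cm[1] <= 0:
            raise InvalidArgumentError("size_cm must be positive")
        cfl = self.h_cm**2 / (4.0 * self.diffusion)
        if self.dt_ms > cfl:
            raise InvalidArgumentError(
                f"dt={self.dt_ms} ms violates diffusion stability limit h^2/(4D)={cfl:.3g} ms"
            )

    @property
    def shape(self) -> tuple:
        """(ny, nx) node counts; index order is (v, u)."""
        nx = int(round(self.size_cm[0] / self.h_cm)) + 1
        ny = int(round(self.size_cm[1] / self.h_cm)) + 1
        return ny, nx


@dataclass
class StateMovie:
    """Stored frames of the transmembrane variable ``u``.

    ``frames`` has shape (n_frames, ny, nx); axis 1 is ``v``, axis 2 is
    ``u`` (so ``frames[t, j, i]`` sits at ``(u, v) = (i*h, j*h)``).
    """

    frames: np.ndarray
    times_ms: np.ndarray
    params: TissueParams

    @property
    def frame_interval_ms(self) -> float:
        return float(self.times_ms[1] - self.times_ms[0]) if len(self.times_ms) > 1 else 1.0

    def node_positions(self):
        ny, nx = self.frames.shape[1:]
        u = np.arange(nx) * self.params.h_cm
        v = np.arange(ny) * self.params.h_cm
        return np.meshgrid(u, v)


@dataclass
class GroundTruth:
    """Known truth of a simulated episode, used as oracle in validation."""

    episode_kind: str  # spiral | focal | planewave
    period_ms: float = float("nan")
    tip_times_ms: np.ndarray | None = None  # spiral
    tip_positions: np.ndarray | None = None  # (n, 2) cm, aligned with tip_times_ms
    origin: tuple | None = None  # focal
    cycle_length_ms: float | None = None  # focal / planewave pacing period
    speed_cm_s: float | None = None  # planewave
    direction: tuple | None = None  # planewave unit vector
    capture_warning: bool = False

    def to_dict(self) -> dict:
        d = {"episode_kind": self.episode_kind, "period_ms": self.period_ms,
             "capture_warning": self.capture_warning}
        if self.tip_times_ms is not None:
            d["tip_times_ms"] = np.asarray(self.tip_times_ms).tolist()
            d["tip_positions"] = np.asarray(self.tip_positions).tolist()
        if self.origin is not None:
            d["origin"] = list(self.origin)
        if self.cycle_length_ms is not None:
            d["cycle_length_ms"] = self.cycle_length_ms
        if self.speed_cm_s is not None:
            d["speed_cm_s"] = self.speed_cm_s
            d["direction"] = list(self.direction)
        return d


@dataclass
class SimulatedEpisode:
    recording: EgmRecording
    grid: ElectrodeGrid
    truth: GroundTruth
    seed: int
    movie: StateMovie | None = None

    def __post_init__(self):
        if tuple(self.recording.channel_ids) != tuple(self.grid.channel_ids):
            raise InvalidArgumentError("recording channel order must match grid channel order")


# ---------------------------------------------------------------------------
# core stepper


def _laplacian(f: np.ndarray, h: float) -> np.ndarray:
    out = -4.0 * f
    out[1:, :] += f[:-1, :]
    out[:-1, :] += f[1:, :]
    out[:, 1:] += f[:, :-1]
    out[:, :-1] += f[:, 1:]
    # no-flux (Neumann) boundaries
    out[0, :] += f[0, :]
    out[-1, :] += f[-1, :]
    out[:, 0] += f[:, 0]
    out[:, -1] += f[:, -1]
    return out / (h * h)


class _Stepper:
    """Explicit Euler integrator with optional excitability modulation."""

    def __init__(self, params: TissueParams, u0: np.ndarray, w0: np.ndarray):
        self.p = params
        self.u = u0.astype(float)
        self.w = w0.astype(float)
        self.t_ms = 0.0
        self.step_count = 0

    def advance(self, duration_ms: float, a_of_t=None, stim=None):
        p = self.p
        n = int(round(duration_ms / p.dt_ms))
        for _ in range(n):
            a = p.a if a_of_t is None else a_of_t(self.t_ms)
            u, w = self.u, self.w
            du = p.diffusion * _laplacian(u, p.h_cm) + (
                p.k * u * (1.0 - u) * (u - a) - u * w
            ) / p.tau_ms
            dw = ((p.eps0 + p.mu1 * w / (u + p.mu2)) * (-w - p.k * u * (u - p.b - 1.0))) / p.tau_ms
            u += p.dt_ms * du
            w += p.dt_ms * dw
            self.t_ms += p.dt_ms
            self.step_count += 1
            if stim is not None:
                stim(self)
            if self.step_count % 200 == 0 and not np.isfinite(u).all():
                raise SimulationFailureError(self.step_count)
        if not np.isfinite(self.u).all():
            raise SimulationFailureError(self.step_count)


def _record(stepper: _Stepper, duration_ms: float, frame_interval_ms: float,
            a_of_t=None, stim=None):
    frames = []
    times = []
    n_frames = int(round(duration_ms / frame_interval_ms))
    for _ in range(n_frames):
        stepper.advance(frame_interval_ms, a_of_t=a_of_t, stim=stim)
        frames.append(stepper.u.astype(np.float32).copy())
        times.append(stepper.t_ms)
    return np.asarray(frames), np.asarray(times)


def _measure_period(movie: StateMovie, threshold: float = 0.5) -> float:
    """Dominant period from threshold upcrossings at several probe nodes."""
    ny, nx = movie.frames.shape[1:]
    probes = [(ny // 4, nx // 4), (ny // 4, 3 * nx // 4),
              (3 * ny // 4, nx // 4), (3 * ny // 4, 3 * nx // 4)]
    periods = []
    for j, i in probes:
        x = movie.frames[:, j, i]
        ups = np.where((x[:-1] < threshold) & (x[1:] >= threshold))[0]
        if len(ups) >= 2:
            periods.extend(np.diff(movie.times_ms[ups]))
    return float(np.median(periods)) if periods else float("nan")


def _periodic_stimulus(region: np.ndarray, cycle_length_ms: float,
                       current_per_ms: float = 0.4, pulse_ms: float = 3.0):
    """Periodic soft stimulus: depolarizing current in ``region``.

    Current injection over a few milliseconds (rather than an
    instantaneous reset) mirrors real pacing and keeps the stimulus
    far-field in sampled electrograms small compared with local
    wavefront deflections.
    """
    state = {"next_stim_ms": 0.0, "until_ms": -1.0}

    def stim(stepper: _Stepper):
        if stepper.t_ms >= state["next_stim_ms"]:
            state["until_ms"] = state["next_stim_ms"] + pulse_ms
            state["next_stim_ms"] += cycle_length_ms
        if stepper.t_ms <= state["until_ms"]:
            stepper.u[region] = np.minimum(
                stepper.u[region] + stepper.p.dt_ms * current_per_ms, 1.0
            )

    return stim


# ---------------------------------------------------------------------------
# episode kinds


def simulate_spiral(
    params: TissueParams = TissueParams(),
    duration_ms: float = 1500.0,
    meander_level: float = 0.0,
    seed: int = 0,
    frame_interval_ms: float = 1.0,
    burn_in_ms: float = 600.0,
    meander_period_ms: float = 450.0,
    tip_stride: int = 5,
):
    """Simulate a (possibly meandering) spiral wave.

    A cross-field initial condition (excited left half, refractory lower
    half, with a small seeded perturbation) breaks into a single spiral
    whose core sits near the sheet centre.  ``meander_level`` modulates
    the excitability parameter ``a`` sinusoidally in time with period
    ``meander_period_ms``, which drives bounded core drift — the
    "migration locus" phenomenology.  The true tip path is computed per
    stored frame pair (every ``tip_stride`` frames) by the isoline-
    intersection tip definition, and the dominant period is measured
    from probe-node upcrossings.

    Returns ``(movie, truth)``; the movie covers the post-burn-in window
    starting at t = 0.
    """
    if duration_ms < 3 * 180.0:
        warnings.warn("duration below ~3 dominant periods; tracking statistics will be weak")
    ny, nx = params.shape
    rng = np.random.default_rng(seed)
    u0 = np.zeros((ny, nx))
    w0 = np.zeros((ny, nx))
    u0[:, : nx // 2] = 1.0
    w0[: ny // 2, :] = 1.5
    u0 += 0.01 * rng.standard_normal((ny, nx))
    np.clip(u0, 0.0, 1.0, out=u0)

    a_of_t = None
    if meander_level != 0.0:
        base_a, lvl, per = params.a, meander_level, meander_period_ms

        def a_of_t(t, base_a=base_a, lvl=lvl, per=per):
            return base_a * (1.0 + lvl * np.sin(2.0 * np.pi * t / per))

    stepper = _Stepper(params, u0, w0)
    stepper.advance(burn_in_ms, a_of_t=a_of_t)
    stepper.t_ms = 0.0  # movie clock starts after burn-in
    frames, times = _record(stepper, duration_ms, frame_interval_ms, a_of_t=a_of_t)
    movie = StateMovie(frames=frames, times_ms=times, params=params)

    tips = true_tip_trajectory(movie, stride=tip_stride)
    truth = GroundTruth(
        episode_kind="spiral",
        period_ms=_measure_period(movie),
        tip_times_ms=tips[:, 0] if len(tips) else np.array([]),
        tip_positions=tips[:, 1:] if len(tips) else np.empty((0, 2)),
    )
    return movie, truth


def simulate_focal(
    params: TissueParams = TissueParams(),
    origin: tuple = (2.0, 2.0),
    cycle_length_ms: float = 200.0,
    duration_ms: float = 1000.0,
    seed: int = 0,
    frame_interval_ms: float = 1.0,
    stim_radius_cm: float = 0.12,
):
    """Simulate centrifugal (target-wave) activity from a periodic focus.

    A disc of radius ``stim_radius_cm`` at ``origin`` is forced excited
    every ``cycle_length_ms``, starting at t = 0.  If the pacing period
    is below local refractoriness so that some stimuli fail to propagate
    (2:1 capture), ``truth.capture_warning`` is set.
    """
    ny, nx = params.shape
    h = params.h_cm
    if not (0 <= origin[0] <= params.size_cm[0] and 0 <= origin[1] <= params.size_cm[1]):
        raise InvalidArgumentError("origin must lie inside the tissue domain")
    if cycle_length_ms <= 0:
        raise InvalidArgumentError("cycle_length_ms must be positive")
    U, V = np.meshgrid(np.arange(nx) * h, np.arange(ny) * h)
    disc = (U - origin[0]) ** 2 + (V - origin[1]) ** 2 <= stim_radius_cm**2
    stim = _periodic_stimulus(disc, cycle_length_ms)

    u0 = np.zeros((ny, nx))
    # mild pre-conditioning of recovery: tissue behaves as if already in
    # rhythm, so the first paced beat has a steady-state APD and every
    # stimulus at a physiological cycle length captures 1:1
    w0 = np.full((ny, nx), 0.3)
    stepper = _Stepper(params, u0, w0)
    frames, times = _record(stepper, duration_ms, frame_interval_ms, stim=stim)
    movie = StateMovie(frames=frames, times_ms=times, params=params)

    # capture check: count upstrokes at a probe 1 cm from the origin
    du_probe = 1.0 if origin[0] + 1.0 <= params.size_cm[0] else -1.0
    i = int(round((origin[0] + du_probe) / h))
    j = int(round(origin[1] / h))
    x = movie.frames[:, min(max(j, 0), ny - 1), min(max(i, 0), nx - 1)]
    n_up = int(np.sum((x[:-1] < 0.5) & (x[1:] >= 0.5)))
    expected = int(np.floor((duration_ms - 1) / cycle_length_ms)) + 1
    capture_warning = n_up < expected - 1  # allow the last front not to arrive yet

    truth = GroundTruth(
        episode_kind="focal",
        period_ms=cycle_length_ms,
        origin=(float(origin[0]), float(origin[1])),
        cycle_length_ms=float(cycle_length_ms),
        capture_warning=capture_warning,
    )
    return movie, truth


def simulate_planewave(
    params: TissueParams = TissueParams(),
    cycle_length_ms: float = 400.0,
    duration_ms: float = 800.0,
    seed: int = 0,
    frame_interval_ms: float = 1.0,
):
    """Simulate periodic plane waves travelling along +u.

    A strip at the left edge is forced excited every ``cycle_length_ms``.
    The true propagation speed is measured from upstroke times along the
    mid-row of the sheet (line fit of activation time vs distance).
    """
    ny, nx = params.shape
    strip = int(max(2, round(0.06 / params.h_cm)))
    region = np.zeros((ny, nx), dtype=bool)
    region[:, :strip] = True
    stim = _periodic_stimulus(region, cycle_length_ms)

    stepper = _Stepper(params, np.zeros((ny, nx)), np.zeros((ny, nx)))
    frames, times = _record(stepper, duration_ms, frame_interval_ms, stim=stim)
    movie = StateMovie(frames=frames, times_ms=times, params=params)

    speed = measure_plane_speed(movie)
    truth = GroundTruth(
        episode_kind="planewave",
        period_ms=cycle_length_ms,
        cycle_length_ms=float(cycle_length_ms),
        speed_cm_s=speed,
        direction=(1.0, 0.0),
    )
    return movie, truth


def measure_plane_speed(movie: StateMovie, threshold: float = 0.5) -> float:
    """Plane-wave speed (cm/s) from first-upstroke times along the mid-row."""
    ny, nx = movie.frames.shape[1:]
    row = movie.frames[:, ny // 2, :]  # (T, nx)
    act = np.full(nx, np.nan)
    up = (row[:-1] < threshold) & (row[1:] >= threshold)
    for i in range(nx):
        idx = np.where(up[:, i])[0]
        if len(idx):
            act[i] = movie.times_ms[idx[0] + 1]
    sel = np.isfinite(act)
    x = np.arange(nx)[sel] * movie.params.h_cm
    t = act[sel]
    if sel.sum() < 10:
        return float("nan")
    # drop edges influenced by the stimulus strip / boundary
    k = max(2, sel.sum() // 10)
    slope = np.polyfit(x[k:-k], t[k:-k], 1)[0]  # ms/cm
    return float(1000.0 / slope) if slope != 0 else float("inf")


# ---------------------------------------------------------------------------
# tip tracking and electrode sampling


def _contour_multiline(f: np.ndarray, level: float, h: float):
    cs = measure.find_contours(f, level)
    lines = [c[:, ::-1] * h for c in cs if len(c) >= 2]  # (row, col) -> (u, v) cm
    return MultiLineString(lines) if lines else None


def true_tip_trajectory(movie: StateMovie, v_iso: float = 0.5, stride: int = 1) -> np.ndarray:
    """Spiral-tip positions by the isoline-intersection definition.

    The tip at frame ``t`` is the intersection of the ``u = v_iso``
    contour at ``t`` with the same contour at ``t + stride`` frames: the
    point where the excitation front pivots instead of advancing.
    Returns an (n, 3) array of ``(t_ms, u_cm, v_cm)`` rows; frames with
    no tip contribute nothing (e.g. plane waves and target waves).
    """
    if movie.frames.shape[0] < 2:
        raise InvalidArgumentError("movie must have at least 2 frames")
    h = movie.params.h_cm
    rows = []
    for f0 in range(0, movie.frames.shape[0] - stride, stride):
        c0 = _contour_multiline(movie.frames[f0], v_iso, h)
        c1 = _contour_multiline(movie.frames[f0 + stride], v_iso, h)
        if c0 is None or c1 is None:
            continue
        inter = c0.intersection(c1)
        if inter.is_empty:
            continue
        geoms = [inter] if inter.geom_type == "Point" else list(getattr(inter, "geoms", []))
        for g in geoms:
            if g.geom_type == "Point":
                rows.append((movie.times_ms[f0 + stride], g.x, g.y))
    return np.asarray(rows) if rows else np.empty((0, 3))


def sample_electrograms(
    movie: StateMovie,
    grid: ElectrodeGrid,
    noise_sd: float = 0.0,
    farfield_gain: float = 1.0,
    seed: int = 0,
    fs_out: float = 1000.0,
    kernel_power: float = 2.0,
) -> EgmRecording:
    """Sample pseudo-unipolar electrograms at basket electrodes.

    Per channel the signal is the distance-weighted sum of ``-du/dt``
    over all tissue nodes with kernel ``1/r**kernel_power`` (r floored
    at one node spacing), scaled to millivolt-order amplitudes, plus
    white Gaussian noise of the stated SD.  The default power of 2
    matches the far-field decay of a transmembrane current dipole layer
    seen by a contact electrode on a thin sheet, keeping local
    wavefront deflections dominant over distant coherent activity;
    power 1 gives a heavier far-field mix.  ``farfield_gain``
    additionally scales the contribution of nodes farther than one
    median electrode pitch (1.0 = plain kernel).  Output is resampled
    to ``fs_out`` (clinical 1 kHz).
    """
    h = movie.params.h_cm
    wu, wv = movie.params.size_cm
    if np.any(grid.coords[:, 0] < -1e-9) or np.any(grid.coords[:, 0] > wu + 1e-9) or \
       np.any(grid.coords[:, 1] < -1e-9) or np.any(grid.coords[:, 1] > wv + 1e-9):
        raise InvalidArgumentError("electrode outside tissue domain")

    U, V = movie.node_positions()
    nodes = np.column_stack([U.ravel(), V.ravel()])  # (n_nodes, 2)
    r = np.linalg.norm(grid.coords[:, None, :] - nodes[None, :, :], axis=-1)
    np.maximum(r, h, out=r)
    weights = (h * h) / r**kernel_power  # area element x kernel
    pitch = grid.median_pitch()
    if farfield_gain != 1.0 and pitch > 0:
        weights[r > pitch] *= farfield_gain

    dt = movie.frame_interval_ms
    dvdt = np.diff(movie.frames.astype(np.float64), axis=0) / dt  # (T-1, ny, nx)
    flat = dvdt.reshape(dvdt.shape[0], -1)  # (T-1, n_nodes)
    sig = -(weights @ flat.T)  # (n_channels, T-1)
    sig *= 1.0  # scale factor keeping deflections at mV order

    t_in = movie.times_ms[1:]
    if abs(dt - 1000.0 / fs_out) > 1e-9:
        t_out = np.arange(t_in[0], t_in[-1] + 1e-9, 1000.0 / fs_out)
        sig = np.vstack([np.interp(t_out, t_in, s) for s in sig])

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(sig.shape) * noise_sd
    return EgmRecording(samples=sig + noise, fs=fs_out, channel_ids=grid.channel_ids)


def make_episode(
    kind: str,
    params: TissueParams = TissueParams(),
    grid: ElectrodeGrid | None = None,
    duration_ms: float = 1500.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    meander_level: float = 0.0,
    cycle_length_ms: float = 200.0,
    focal_origin: tuple = (2.0, 2.0),
    keep_movie: bool = True,
) -> SimulatedEpisode:
    """Simulate an episode of the given kind and sample it at a basket.

    ``kind`` is "spiral", "focal" or "planewave".  All randomness (initial
    perturbation, electrode noise) derives from ``seed``.
    """
    from .geometry import make_basket_geometry

    if grid is None:
        grid = make_basket_geometry(sheet_extent=params.size_cm, jitter_seed=seed)
    if kind == "spiral":
        movie, truth = simulate_spiral(
            params, duration_ms=duration_ms, meander_level=meander_level, seed=seed
        )
    elif kind == "focal":
        movie, truth = simulate_focal(
            params, origin=focal_origin, cycle_length_ms=cycle_length_ms,
            duration_ms=duration_ms, seed=seed
        )
    elif kind == "planewave":
        # pace slowly enough that one sweep occupies the sheet alone
        movie, truth = simulate_planewave(
            params, cycle_length_ms=max(cycle_length_ms, 400.0), duration_ms=duration_ms, seed=seed
        )
    else:
        raise InvalidArgumentError(f"unknown episode kind {kind!r}")
    rec = sample_electrograms(movie, grid, noise_sd=noise_sd, seed=seed + 1)
    return SimulatedEpisode(
        recording=rec, grid=grid, truth=truth, seed=seed,
        movie=movie if keep_movie else None,
    )
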