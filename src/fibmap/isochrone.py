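"""Per-cycle isochronal maps, propagation direction, and CV estimation.

An isochronal map colors the sheet by local activation time within one
cycle.  The propagation direction at a node is the normalized gradient
of activation time (the wave moves from earlier- to later-activating
tissue), and the local speed is the reciprocal gradient magnitude.
Cycle-to-cycle direction recurrence (mean cosine between consecutive
cycles' direction vectors) quantifies how repeatable the activation
sequence is — high recurrence is the signature of a stable driver,
near-zero recurrence of disorganized conduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activation import ActivationSeries
from .errors import InsufficientDataError, InvalidArgumentError
from .geometry import AnalysisGrid, ElectrodeGrid, interpolate_to_grid

__all__ = [
    "IsochroneMap",
    "DirectionField",
    "build_isochrone_map",
    "propagation_field",
    "estimate_cv_planewave",
    "direction_recurrence",
    "segment_cycles",
]


@dataclass(frozen=True)
class IsochroneMap:
    """Activation-time field (ms) on the analysis raster; NaN = diastole."""

    grid: AnalysisGrid
    times: np.ndarray  # (nv, nu), ms; NaN where not activated
    cycle_window: tuple

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.shape != (self.grid.nv, self.grid.nu):
            raise InvalidArgumentError("times shape does not match grid")
        t0, t1 = self.cycle_window
        if not t1 > t0:
            raise InvalidArgumentError("cycle window must have t1 > t0")
        defined = t[np.isfinite(t)]
        if defined.size and (defined.min() < t0 - 1e-9 or defined.max() > t1 + 1e-9):
            raise InvalidArgumentError("activation times fall outside the cycle window")

    def to_frame(self) -> pd.DataFrame:
        U, V = self.grid.node_coords()
        return pd.DataFrame(
            {"u_cm": U.ravel(), "v_cm": V.ravel(), "t_ms": self.times.ravel()}
        )


@dataclass(frozen=True)
class DirectionField:
    """Unit propagation-direction vectors and speeds on the raster."""

    grid: AnalysisGrid
    du: np.ndarray  # (nv, nu) unit-vector components; NaN undefined
    dv: np.ndarray
    speed_cm_s: np.ndarray

    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.du) & np.isfinite(self.dv)

    def to_frame(self) -> pd.DataFrame:
        U, V = self.grid.node_coords()
        return pd.DataFrame(
            {
                "u_cm": U.ravel(),
                "v_cm": V.ravel(),
                "du": self.du.ravel(),
                "dv": self.dv.ravel(),
                "speed_cm_s": self.speed_cm_s.ravel(),
            }
        )


def build_isochrone_map(
    series: ActivationSeries,
    grid: ElectrodeGrid,
    window: tuple,
    target: AnalysisGrid,
    method: str = "linear",
) -> IsochroneMap:
    """Interpolate each channel's first activation in ``window`` to the raster.

    Raises :class:`InsufficientDataError` when fewer than 3 channels
    activate inside the window.  Nodes outside the hull of active
    channels are NaN (non-activated / diastole).
    """
    t0, t1 = window
    if not t1 > t0:
        raise InvalidArgumentError("window must have t1 > t0")
    values = np.full(grid.n_channels, np.nan)
    for i, cid in enumerate(grid.channel_ids):
        t = series.times.get(cid, np.array([]))
        inside = t[(t >= t0) & (t < t1)]
        if len(inside):
            values[i] = inside[0]
    n_active = int(np.isfinite(values).sum())
    if n_active < 3:
        raise InsufficientDataError(f"only {n_active} channels active in window {window}")
    field = interpolate_to_grid(values, grid, target, method=method)
    return IsochroneMap(grid=target, times=field, cycle_window=(float(t0), float(t1)))


def propagation_field(iso: IsochroneMap, grad_tol_ms_per_cm: float = 1e-6) -> DirectionField:
    """Direction and speed of propagation from the activation-time gradient.

    Central finite differences with missing-data masking; a node is
    undefined where any neighbour needed for the difference is missing
    or where the gradient magnitude is below tolerance (no propagation
    direction at a flat map).  Speed is ``1/|grad T|`` in cm/s.
    """
    T = iso.times
    gv, gu = np.gradient(T, iso.grid.dv, iso.grid.du)  # ms/cm
    mag = np.hypot(gu, gv)
    with np.errstate(invalid="ignore", divide="ignore"):
        du = np.where(mag > grad_tol_ms_per_cm, gu / mag, np.nan)
        dv = np.where(mag > grad_tol_ms_per_cm, gv / mag, np.nan)
        speed = np.where(mag > grad_tol_ms_per_cm, 1000.0 / mag, np.nan)
    return DirectionField(grid=iso.grid, du=du, dv=dv, speed_cm_s=speed)


def estimate_cv_planewave(iso: IsochroneMap, residual_tol_ms: float = 5.0):
    """Conduction velocity from a least-squares plane fit of the map.

    Fits ``T = a u + b v + c`` over defined nodes and returns
    ``(speed_cm_s, rms_residual_ms)`` with speed ``1/sqrt(a^2+b^2)``
    converted to cm/s.  A residual above ``residual_tol_ms`` triggers a
    not-planar warning (the estimate is still returned).
    """
    U, V = iso.grid.node_coords()
    mask = np.isfinite(iso.times)
    if mask.sum() < 3:
        raise InsufficientDataError("fewer than 3 defined nodes")
    A = np.column_stack([U[mask], V[mask], np.ones(mask.sum())])
    coef, *_ = np.linalg.lstsq(A, iso.times[mask], rcond=None)
    a, b, _ = coef
    resid = iso.times[mask] - A @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    if rms > residual_tol_ms:
        warnings.warn(f"isochrone map is not planar (rms residual {rms:.1f} ms)")
    slope = float(np.hypot(a, b))  # ms/cm
    speed = 1000.0 / slope if slope > 0 else float("inf")
    return speed, rms


def direction_recurrence(fields) -> np.ndarray:
    """Per-node direction recurrence score across consecutive cycles.

    For each raster node, the mean cosine of the angle between the
    direction vectors of consecutive cycle pairs where both are
    defined; in [-1, 1].  Nodes defined in fewer than 2 cycles are NaN.
    """
    fields = list(fields)
    if len(fields) < 2:
        raise InvalidArgumentError("need at least 2 cycles")
    g = fields[0].grid
    acc = np.zeros((g.nv, g.nu))
    cnt = np.zeros((g.nv, g.nu), dtype=int)
    for f0, f1 in zip(fields[:-1], fields[1:]):
        if f0.grid != g or f1.grid != g:
            raise InvalidArgumentError("all fields must share one grid")
        both = f0.defined_mask() & f1.defined_mask()
        cos = f0.du * f1.du + f0.dv * f1.dv
        acc[both] += cos[both]
        cnt[both] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return out


def segment_cycles(
    series: ActivationSeries,
    reference_channel: str | None = None,
    max_cycles: int | None = None,
):
    """Split a recording into per-cycle windows.

    Windows are anchored on the activations of a reference channel; each
    window runs from one reference activation (minus a small lead
    margin) over one cycle.  The default reference is chosen so that a
    travelling wavefront is captured whole inside each window: channel
    activation times are reduced modulo the dominant cycle length, the
    largest empty arc on that circle (the diastolic gap between the end
    of one wavefront's sweep and the birth of the next) is located, and
    the channel activating immediately after the gap — the wavefront's
    site of earliest activation — anchors the windows.  Only regular
    channels (interval variance within 1.5x the minimum, >= 3 events)
    are considered.  Returns a list of ``(t0, t1)``.
    """
    if reference_channel is None:
        variances = {
            cid: float(np.var(np.diff(t)))
            for cid, t in series.times.items()
            if len(t) >= 3
        }
        if not variances:
            raise InsufficientDataError("no channel has >= 3 activations")
        vmin = min(variances.values())
        regular = [cid for cid, v in variances.items() if v <= 1.5 * vmin + 1e-9]
        base = min(regular, key=lambda cid: variances[cid])
        cl0 = float(np.median(np.diff(series.times[base])))
        anchor = series.times[base][0]
        # circular mean activation offset of each regular channel
        offsets = {}
        for cid in regular:
            phases = 2.0 * np.pi * (((series.times[cid] - anchor) % cl0) / cl0)
            mean = np.angle(np.mean(np.exp(1j * phases)))
            offsets[cid] = float((mean / (2.0 * np.pi) * cl0) % cl0)
        # largest empty arc on the offset circle = the diastolic gap;
        # the channel just after it activates earliest in the sweep
        ordered = sorted(offsets.items(), key=lambda kv: kv[1])
        vals = [v for _, v in ordered]
        gaps = [vals[(k + 1) % len(vals)] - vals[k] for k in range(len(vals))]
        gaps[-1] += cl0  # wrap-around arc
        after_gap = (int(np.argmax(gaps)) + 1) % len(ordered)
        reference_channel = ordered[after_gap][0]
    t = series.times[reference_channel]
    if len(t) < 2:
        raise InsufficientDataError(f"reference channel {reference_channel} has < 2 events")
    lead = 10.0  # ms; tolerate activation-timing jitter just before the anchor
    windows = [(float(a) - lead, float(b) - lead) for a, b in zip(t[:-1], t[1:])]
    if max_cycles is not None:
        windows = windows[:max_cycles]
    return windows
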