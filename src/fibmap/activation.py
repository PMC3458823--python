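"""Electrogram conditioning, activation detection, and restitution filtering.

Activation at an electrode is marked at local maxima of the negative
voltage slope (-dV/dt), the standard criterion for unipolar electrograms.
Detected event trains are then passed through a physiological filter:
successive activation intervals shorter than the recovery time implied by
action-potential-duration (APD) restitution are discarded, because tissue
cannot re-excite before it has repolarized.  The minimum human atrial
repolarization time is 100-110 ms, which bounds the recovery time from
below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InvalidArgumentError

__all__ = [
    "EgmRecording",
    "RestitutionCurve",
    "ActivationSeries",
    "bandpass",
    "detect_activations",
    "restitution_filter",
    "cycle_length_stats",
]


@dataclass(frozen=True)
class EgmRecording:
    """Multichannel unipolar electrogram recording.

    ``samples`` is a (n_channels, n_samples) voltage matrix in mV at
    sampling rate ``fs`` Hz (clinical systems digitize at 1 kHz).
    """

    samples: np.ndarray
    fs: float
    channel_ids: tuple
    filter_band: tuple | None = None

    def __post_init__(self):
        samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channel_ids", tuple(self.channel_ids))
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        if samples.shape[0] != len(self.channel_ids):
            raise InvalidArgumentError(
                f"{samples.shape[0]} rows but {len(self.channel_ids)} channel ids"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise InvalidArgumentError("channel_ids must be unique")
        if not np.all(np.isfinite(samples)):
            raise InvalidArgumentError("samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs * 1000.0


@dataclass(frozen=True)
class RestitutionCurve:
    """APD restitution: recovery time as a function of diastolic interval.

    ``points`` is an optional sequence of ``(di_ms, apd_ms)`` pairs with
    strictly increasing DI and non-decreasing APD.  When ``points`` is
    None the curve is flat and the recovery time is ``min_apd_ms``
    everywhere — the default mode, used when no per-patient monophasic
    action potential (MAP) restitution data are available.
    """

    points: tuple | None = None
    min_apd_ms: float = 100.0

    def __post_init__(self):
        if not 0 < self.min_apd_ms:
            raise InvalidArgumentError("min_apd_ms must be positive")
        if self.points is not None:
            pts = tuple((float(d), float(a)) for d, a in self.points)
            if len(pts) == 0:
                raise InvalidArgumentError("restitution curve has no points; pass None for flat mode")
            dis = np.array([p[0] for p in pts])
            apds = np.array([p[1] for p in pts])
            if np.any(np.diff(dis) <= 0):
                raise InvalidArgumentError("diastolic intervals must be strictly increasing")
            if np.any(np.diff(apds) < 0):
                raise InvalidArgumentError("APD must be non-decreasing in DI")
            object.__setattr__(self, "points", pts)

    @classmethod
    def flat(cls, min_apd_ms: float = 100.0) -> "RestitutionCurve":
        return cls(points=None, min_apd_ms=min_apd_ms)

    def recovery_time(self, di_ms: float) -> float:
        """Recovery time (ms) at the given diastolic interval, floored at min_apd."""
        if self.points is None:
            return self.min_apd_ms
        dis = [p[0] for p in self.points]
        apds = [p[1] for p in self.points]
        apd = float(np.interp(di_ms, dis, apds))
        return max(self.min_apd_ms, apd)


@dataclass(frozen=True)
class ActivationSeries:
    """Per-channel strictly increasing activation times in ms."""

    times: dict  # channel_id -> np.ndarray of ms

    def __post_init__(self):
        clean = {}
        for cid, t in self.times.items():
            t = np.asarray(t, dtype=float)
            if t.ndim != 1:
                raise InvalidArgumentError(f"channel {cid}: times must be 1-D")
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise InvalidArgumentError(f"channel {cid}: times must strictly increase")
            clean[cid] = t
        object.__setattr__(self, "times", clean)

    @property
    def channel_ids(self) -> tuple:
        return tuple(self.times.keys())

    def n_events(self) -> int:
        return int(sum(len(t) for t in self.times.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [(cid, t) for cid, ts in self.times.items() for t in ts]
        return pd.DataFrame(rows, columns=["channel_id", "time_ms"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ActivationSeries":
        df = pd.read_csv(path)
        times = {
            str(cid): np.sort(g["time_ms"].to_numpy(float))
            for cid, g in df.groupby("channel_id", sort=False)
        }
        return cls(times=times)


def bandpass(rec: EgmRecording, lo: float = 0.05, hi: float = 500.0, order: int = 4) -> EgmRecording:
    """Zero-phase band-limit a recording to (lo, hi) Hz.

    The filter is a forward-backward (zero-phase) Butterworth, so
    activation timing is not skewed by group delay.  ``hi`` equal to the
    Nyquist frequency degenerates to a pure high-pass; ``hi`` above
    Nyquist is rejected.
    """
    nyq = rec.fs / 2.0
    if not 0 <= lo < hi:
        raise InvalidArgumentError("need 0 <= lo < hi")
    if hi > nyq:
        raise InvalidArgumentError(f"hi={hi} Hz exceeds Nyquist ({nyq} Hz)")
    if lo == 0 and hi >= nyq:
        return replace(rec, filter_band=(lo, hi))
    if hi >= nyq:
        sos = sps.butter(order, lo, btype="highpass", fs=rec.fs, output="sos")
    elif lo == 0:
        sos = sps.butter(order, hi, btype="lowpass", fs=rec.fs, output="sos")
    else:
        sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=out, filter_band=(lo, hi))


def _robust_sd(x: np.ndarray) -> float:
    """1.4826 x median absolute deviation — robust to sparse spikes."""
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def detect_activations(
    rec: EgmRecording,
    slope_threshold: float | None = None,
    lockout_ms: float = 50.0,
    threshold_factor: float = 3.0,
    peak_fraction: float = 0.5,
) -> ActivationSeries:
    """Mark activations at local maxima of -dV/dt.

    Per channel, activation times are the peaks of the negative slope
    exceeding ``slope_threshold`` (mV/ms) and separated by at least
    ``lockout_ms``.  When ``slope_threshold`` is None an adaptive
    per-channel threshold is used: the larger of ``threshold_factor``
    times the robust noise SD of -dV/dt and ``peak_fraction`` of its
    99.9th percentile (true depolarization downslopes are an order of
    magnitude steeper than far-field and repolarization deflections, so
    the relative floor rejects those even in noiseless recordings).  A
    flat channel yields an empty train.
    """
    if lockout_ms <= 0:
        raise InvalidArgumentError("lockout_ms must be positive")
    dt_ms = 1000.0 / rec.fs
    distance = max(1, int(round(lockout_ms / dt_ms)))
    times = {}
    for i, cid in enumerate(rec.channel_ids):
        neg_slope = -np.gradient(rec.samples[i]) / dt_ms  # mV/ms
        if np.allclose(neg_slope, 0.0):
            times[cid] = np.array([])
            continue
        thr = slope_threshold
        if thr is None:
            sd = _robust_sd(neg_slope)
            if sd == 0:
                sd = float(np.std(neg_slope))
            thr = max(threshold_factor * sd,
                      peak_fraction * float(np.percentile(neg_slope, 99.9)))
        peaks, _ = sps.find_peaks(neg_slope, height=thr, distance=distance)
        times[cid] = peaks * dt_ms
    return ActivationSeries(times=times)


def restitution_filter(series: ActivationSeries, curve: RestitutionCurve) -> ActivationSeries:
    """Discard activation intervals shorter than the restitution recovery time.

    Forward scan per channel, always keeping the earlier event of a
    too-close pair: an event whose interval from the last *accepted*
    event is below the recovery time is dropped, and subsequent events
    are re-evaluated against the last accepted one.  The recovery time
    is the curve's APD at the preceding diastolic interval (preceding
    accepted interval minus the recovery time used at the previous
    acceptance), floored at ``min_apd_ms``.  Idempotent.
    """
    if not isinstance(curve, RestitutionCurve):
        raise InvalidArgumentError("curve must be a RestitutionCurve")
    out = {}
    for cid, t in series.times.items():
        if len(t) == 0:
            out[cid] = t
            continue
        accepted = [float(t[0])]
        prev_recovery = curve.min_apd_ms  # no history before the first event
        prev_interval = None
        for ti in t[1:]:
            interval = ti - accepted[-1]
            if prev_interval is None:
                recovery = curve.min_apd_ms
            else:
                di = max(0.0, prev_interval - prev_recovery)
                recovery = curve.recovery_time(di)
            if interval >= recovery:
                accepted.append(float(ti))
                prev_interval = interval
                prev_recovery = recovery
        out[cid] = np.asarray(accepted)
    return ActivationSeries(times=out)


def cycle_length_stats(
    series: ActivationSeries,
    channels=None,
    epoch: tuple | None = None,
) -> dict:
    """Pooled cycle-length statistics over the given channels and epoch.

    Returns mean and median cycle length (ms) and the per-channel event
    counts.  Channels with fewer than 2 events inside the epoch are
    flagged in ``undefined_channels`` and excluded from pooling.
    """
    if channels is None:
        channels = series.channel_ids
    intervals = []
    undefined = []
    for cid in channels:
        t = series.times[cid]
        if epoch is not None:
            t = t[(t >= epoch[0]) & (t < epoch[1])]
        if len(t) < 2:
            undefined.append(cid)
            continue
        intervals.append(np.diff(t))
    if intervals:
        pooled = np.concatenate(intervals)
        mean_cl = float(np.mean(pooled))
        median_cl = float(np.median(pooled))
        n = int(len(pooled))
    else:
        mean_cl = median_cl = float("nan")
        n = 0
    return {
        "mean_cl_ms": mean_cl,
        "median_cl_ms": median_cl,
        "n_intervals": n,
        "undefined_channels": undefined,
    }


def cycle_length_change(
    series: ActivationSeries,
    epoch_before: tuple,
    epoch_after: tuple,
    channels=None,
) -> float:
    """Percent change in mean cycle length between two epochs.

    ``100 * (CL_after - CL_before) / CL_before`` — positive values mean
    the rhythm slowed (intervals lengthened).
    """
    before = cycle_length_stats(series, channels=channels, epoch=epoch_before)
    after = cycle_length_stats(series, channels=channels, epoch=epoch_after)
    return 100.0 * (after["mean_cl_ms"] - before["mean_cl_ms"]) / before["mean_cl_ms"]
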