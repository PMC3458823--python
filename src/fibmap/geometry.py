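"""Electrode layouts on the unwrapped atrial sheet and rasterization.

The mapping chain works in a flat 2-D coordinate system: each atrium is
treated as a sheet obtained by unwrapping the chamber, and every basket
electrode is assigned a continuous ``(u, v)`` position in centimetres on
that sheet.  Scattered per-electrode scalars (activation times, phases)
are interpolated onto a regular :class:`AnalysisGrid` raster for map
construction; nodes outside the electrode convex hull carry no data and
are flagged as missing (NaN).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import Delaunay, QhullError

from .errors import DegenerateGeometryError, InvalidArgumentError

__all__ = [
    "ElectrodeGrid",
    "AnalysisGrid",
    "make_basket_geometry",
    "interpolate_to_grid",
    "grid_from_csv",
    "grid_to_csv",
]

# Clinical basket pitch: 4-6 mm along a spline, 4-10 mm between splines.
INTRA_SPLINE_SPACING_CM = (0.4, 0.6)
INTER_SPLINE_SPACING_CM = (0.4, 1.0)


@dataclass(frozen=True)
class ElectrodeGrid:
    """Channel-to-coordinate map of a multielectrode basket.

    Parameters
    ----------
    coords : (n_channels, 2) float array
        Per-channel ``(u, v)`` position in cm on the unwrapped sheet.
    channel_ids : tuple of str
        Ordered labels, spline letter + electrode index (``"A1"`` ...).
    atrium_label : {"LA", "RA"}
    spline_count, electrodes_per_spline : int
    """

    coords: np.ndarray
    channel_ids: tuple
    atrium_label: str = "LA"
    spline_count: int = 8
    electrodes_per_spline: int = 8

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "channel_ids", tuple(self.channel_ids))
        if self.atrium_label not in ("LA", "RA"):
            raise InvalidArgumentError(f"atrium_label must be LA or RA, got {self.atrium_label!r}")
        n = len(self.channel_ids)
        if coords.shape != (n, 2):
            raise InvalidArgumentError(f"coords shape {coords.shape} does not match {n} channels")
        if n != self.spline_count * self.electrodes_per_spline:
            raise InvalidArgumentError(
                f"{n} channels != {self.spline_count} splines x {self.electrodes_per_spline} electrodes"
            )
        if len(set(self.channel_ids)) != n:
            raise InvalidArgumentError("channel_ids must be unique")
        if not np.all(np.isfinite(coords)):
            raise InvalidArgumentError("electrode coordinates must be finite")
        if n > 1:
            d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            if d2.min() <= 0.0:
                raise InvalidArgumentError("two channels coincide")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def median_pitch(self) -> float:
        """Median nearest-neighbour electrode spacing in cm."""
        if self.n_channels < 2:
            return 0.0
        d2 = np.sum((self.coords[:, None, :] - self.coords[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        return float(np.median(np.sqrt(d2.min(axis=1))))

    def intra_spline_spacings(self) -> np.ndarray:
        """Distances between successive electrodes along each spline."""
        out = []
        eps = self.electrodes_per_spline
        for s in range(self.spline_count):
            block = self.coords[s * eps : (s + 1) * eps]
            if len(block) > 1:
                out.extend(np.hypot(*np.diff(block, axis=0).T))
        return np.asarray(out)


@dataclass(frozen=True)
class AnalysisGrid:
    """Regular raster on which isochrone and phase fields are evaluated."""

    origin: tuple = (0.0, 0.0)
    du: float = 0.1
    dv: float = 0.1
    nu: int = 41
    nv: int = 41

    def __post_init__(self):
        if self.du <= 0 or self.dv <= 0:
            raise InvalidArgumentError("grid spacing must be positive")
        if self.nu < 2 or self.nv < 2:
            raise InvalidArgumentError("grid must have at least 2 nodes per axis")

    @property
    def u_axis(self) -> np.ndarray:
        return self.origin[0] + self.du * np.arange(self.nu)

    @property
    def v_axis(self) -> np.ndarray:
        return self.origin[1] + self.dv * np.arange(self.nv)

    def node_coords(self):
        """Meshgrid ``(U, V)`` arrays of shape (nv, nu)."""
        return np.meshgrid(self.u_axis, self.v_axis)

    def to_dict(self) -> dict:
        return {
            "origin": [float(self.origin[0]), float(self.origin[1])],
            "du": self.du,
            "dv": self.dv,
            "nu": self.nu,
            "nv": self.nv,
        }

    @classmethod
    def from_electrodes(cls, grid: ElectrodeGrid, spacing: float = 0.1) -> "AnalysisGrid":
        """Raster covering the electrode bounding box at the given spacing (cm).

        The default 0.1 cm (1 mm) is far below the 4-10 mm electrode pitch,
        so raster error is negligible relative to map resolution.
        """
        lo = grid.coords.min(axis=0)
        hi = grid.coords.max(axis=0)
        nu = int(np.ceil((hi[0] - lo[0]) / spacing)) + 1
        nv = int(np.ceil((hi[1] - lo[1]) / spacing)) + 1
        return cls(origin=(float(lo[0]), float(lo[1])), du=spacing, dv=spacing, nu=max(nu, 2), nv=max(nv, 2))


def make_basket_geometry(
    spline_count: int = 8,
    electrodes_per_spline: int = 8,
    sheet_extent=(4.0, 4.0),
    jitter_seed: int = 0,
    jitter_cm: float = 0.01,
    atrium_label: str = "LA",
) -> ElectrodeGrid:
    """Build a basket electrode layout on the unwrapped sheet.

    Splines are vertical lines spaced evenly across ``u``; electrodes are
    spaced evenly along ``v``.  A small deterministic positional jitter
    (default 0.01 cm) emulates imperfect deployment without violating the
    clinical spacing envelope (0.4-0.6 cm along splines, 0.4-1.0 cm
    between splines for the default 8x8 basket on a 4x4 cm sheet).

    Channel labels follow spline letter + electrode number: A1..A8, B1..B8, ...
    Bit-reproducible for a fixed ``jitter_seed``.
    """
    if spline_count < 1 or electrodes_per_spline < 1:
        raise InvalidArgumentError("spline_count and electrodes_per_spline must be >= 1")
    wu, wv = float(sheet_extent[0]), float(sheet_extent[1])
    if wu <= 0 or wv <= 0:
        raise InvalidArgumentError("sheet_extent must be positive")
    if jitter_cm < 0:
        raise InvalidArgumentError("jitter_cm must be >= 0")

    # inset by the jitter amplitude so jittered electrodes stay on the sheet
    us = (
        np.linspace(jitter_cm, wu - jitter_cm, spline_count)
        if spline_count > 1
        else np.array([wu / 2.0])
    )
    vs = (
        np.linspace(jitter_cm, wv - jitter_cm, electrodes_per_spline)
        if electrodes_per_spline > 1
        else np.array([wv / 2.0])
    )
    U, V = np.meshgrid(us, vs, indexing="ij")  # row s = spline s
    coords = np.column_stack([U.ravel(), V.ravel()])
    if len(coords) > 1:  # the degenerate single channel stays at the sheet centre
        rng = np.random.default_rng(jitter_seed)
        coords = coords + rng.uniform(-jitter_cm, jitter_cm, size=coords.shape)

    letters = string.ascii_uppercase
    ids = []
    for s in range(spline_count):
        letter = letters[s % 26] * (s // 26 + 1)
        for e in range(electrodes_per_spline):
            ids.append(f"{letter}{e + 1}")
    return ElectrodeGrid(
        coords=coords,
        channel_ids=tuple(ids),
        atrium_label=atrium_label,
        spline_count=spline_count,
        electrodes_per_spline=electrodes_per_spline,
    )


def interpolate_to_grid(
    values,
    grid: ElectrodeGrid,
    target: AnalysisGrid,
    method: str = "linear",
) -> np.ndarray:
    """Interpolate per-channel scalars onto the analysis raster.

    Returns an array of shape ``(nv, nu)``; nodes outside the convex hull
    of channels carrying finite values are NaN.  ``method`` is "linear"
    (barycentric on a Delaunay triangulation, the default) or "nearest"
    (hull-masked nearest neighbour).

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 non-collinear channels carry values.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_channels,):
        raise InvalidArgumentError(
            f"expected one value per channel ({grid.n_channels}), got shape {values.shape}"
        )
    ok = np.isfinite(values)
    pts = grid.coords[ok]
    vals = values[ok]
    if len(pts) < 3:
        raise DegenerateGeometryError(f"only {len(pts)} channels carry values; need >= 3")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate electrode layout: {exc}") from exc

    U, V = target.node_coords()
    nodes = np.column_stack([U.ravel(), V.ravel()])
    if method == "linear":
        interp = LinearNDInterpolator(tri, vals)
        out = interp(nodes)
    elif method == "nearest":
        interp = NearestNDInterpolator(pts, vals)
        out = interp(nodes)
        out[tri.find_simplex(nodes) < 0] = np.nan  # mask outside hull
    else:
        raise InvalidArgumentError(f"unknown interpolation method {method!r}")
    return out.reshape(target.nv, target.nu)


def grid_to_csv(grid: ElectrodeGrid, path) -> None:
    """Write geometry as CSV: channel_id,atrium,spline,electrode,u_cm,v_cm."""
    eps = grid.electrodes_per_spline
    rows = []
    for i, cid in enumerate(grid.channel_ids):
        rows.append(
            {
                "channel_id": cid,
                "atrium": grid.atrium_label,
                "spline": i // eps,
                "electrode": i % eps + 1,
                "u_cm": grid.coords[i, 0],
                "v_cm": grid.coords[i, 1],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def grid_from_csv(path) -> ElectrodeGrid:
    """Read geometry written by :func:`grid_to_csv`."""
    df = pd.read_csv(path)
    required = {"channel_id", "atrium", "spline", "electrode", "u_cm", "v_cm"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"geometry CSV missing columns: {sorted(missing)}")
    df = df.sort_values(["spline", "electrode"], kind="stable")
    spline_count = df["spline"].nunique()
    eps = len(df) // spline_count
    return ElectrodeGrid(
        coords=df[["u_cm", "v_cm"]].to_numpy(float),
        channel_ids=tuple(df["channel_id"].astype(str)),
        atrium_label=str(df["atrium"].iloc[0]),
        spline_count=spline_count,
        electrodes_per_spline=eps,
    )
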