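"""Hilbert phase, circular interpolation, and singularity detection.

The plaquette detector is validated against the brute-force winding-
number oracle on seeded band-limited random phase screens, including
the charge-conservation identity (plaquette charges inside a rectangle
sum to the boundary winding number).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibmap import (
    AnalysisGrid,
    EgmRecording,
    ElectrodeGrid,
    PhaseMap,
    detect_phase_singularities,
    instantaneous_phase,
    phase_field,
    winding_number_oracle,
)
from fibmap.errors import InvalidArgumentError
from fibmap.phase import _wrap, rectangle_path

# ---------------------------------------------------------------------------
# helpers


def random_phase_screen(rng, n=20, n_vortices=2, smooth_scale=4.0):
    """Band-limited random phase screen with embedded vortices.

    Sum of a smooth random harmonic background and a few point
    vortices; the resulting field is smooth away from vortex cores, so
    plaquette sums are well defined everywhere.
    """
    x = np.arange(n)
    U, V = np.meshgrid(x, x)
    phi = np.zeros((n, n))
    for _ in range(3):  # smooth background
        kx, ky = rng.uniform(-1.0, 1.0, 2) / smooth_scale
        phi += rng.uniform(0.3, 0.9) * np.sin(kx * U + ky * V + rng.uniform(0, 2 * np.pi))
    for _ in range(rng.integers(0, n_vortices + 1)):
        cx, cy = rng.uniform(2, n - 3, 2) + 0.5
        phi += rng.choice([-1.0, 1.0]) * np.arctan2(V - cy, U - cx)
    return _wrap(phi)


def phase_map_from(phi, du=0.1):
    n = phi.shape[0]
    grid = AnalysisGrid(origin=(0.0, 0.0), du=du, dv=du, nu=phi.shape[1], nv=n)
    return PhaseMap(grid=grid, phases=phi[None], times_ms=np.array([0.0]), fs=1000.0)


def vortex_screen(n=21, c=(1.05, 1.05), du=0.1, sign=1.0):
    x = np.arange(n) * du
    U, V = np.meshgrid(x, x)
    return _wrap(sign * np.arctan2(V - c[1], U - c[0]))


# ---------------------------------------------------------------------------
# instantaneous phase


def test_sinusoid_phase_slope_within_one_percent():
    fs = 1000.0
    t = np.arange(3000) / fs
    x = np.sin(2 * np.pi * 5.0 * t)
    rec = EgmRecording(samples=x[None], fs=fs, channel_ids=("C0",))
    phases, valid = instantaneous_phase(rec, detrend="mean")
    assert valid[0]
    core = slice(300, 2700)  # interior 80%
    slope = np.polyfit(t[core], np.unwrap(phases[0])[core], 1)[0]
    assert abs(slope - 2 * np.pi * 5.0) / (2 * np.pi * 5.0) < 0.01


def test_constant_channel_gets_undefined_phase_flag():
    rec = EgmRecording(samples=np.vstack([np.ones(500), np.sin(np.arange(500) / 10)]),
                       fs=1000.0, channel_ids=("flat", "osc"))
    phases, valid = instantaneous_phase(rec, detrend="mean")
    assert not valid[0] and valid[1]
    assert np.all(np.isnan(phases[0])) and np.all(np.isfinite(phases[1]))


def test_spiral_phase_progression_matches_truth(spiral_chain):
    """Mean phase progression rate ~ 2*pi / rotor period, within 5%."""
    rec = spiral_chain["rec"]
    phases, valid = instantaneous_phase(rec)
    assert valid.all()
    expected = 2 * np.pi / spiral_chain["episode"].truth.period_ms
    n = phases.shape[1]
    lo, hi = int(0.1 * n), int(0.9 * n)  # interior 80%: avoid edge transients
    span_ms = (hi - lo) / rec.fs * 1000.0
    rates = []
    for p in phases:
        up = np.unwrap(p)
        rates.append(abs(up[hi] - up[lo]) / span_ms)
    assert abs(np.median(rates) - expected) / expected < 0.05


def test_invalid_detrend_mode():
    rec = EgmRecording(samples=np.zeros((1, 100)), fs=1000.0, channel_ids=("a",))
    with pytest.raises(InvalidArgumentError):
        instantaneous_phase(rec, detrend="bogus")


# ---------------------------------------------------------------------------
# circular interpolation


@pytest.fixture
def lattice():
    u, v = np.meshgrid(np.arange(5) * 0.5, np.arange(5) * 0.5, indexing="ij")
    coords = np.column_stack([u.ravel(), v.ravel()])
    ids = tuple(f"E{k}" for k in range(25))
    return ElectrodeGrid(coords=coords, channel_ids=ids, spline_count=5,
                         electrodes_per_spline=5)


def test_uniform_phase_interpolates_to_constant(lattice):
    target = AnalysisGrid(origin=(0.0, 0.0), du=0.1, dv=0.1, nu=21, nv=21)
    pm = phase_field(np.full((25, 1), 2.2), lattice, target)
    defined = pm.phases[0][np.isfinite(pm.phases[0])]
    np.testing.assert_allclose(defined, 2.2, atol=1e-9)


def test_interpolation_respects_pi_wrap(lattice):
    """Channels at +/-(pi - 0.01): interpolants stay near pi, never near 0."""
    rng = np.random.default_rng(0)
    ph = np.where(rng.random(25) < 0.5, np.pi - 0.01, -np.pi + 0.01)[:, None]
    target = AnalysisGrid(origin=(0.0, 0.0), du=0.1, dv=0.1, nu=21, nv=21)
    pm = phase_field(ph, lattice, target)
    defined = np.abs(pm.phases[0][np.isfinite(pm.phases[0])])
    assert defined.min() > 3.0


def test_interpolation_exact_at_electrodes(lattice):
    rng = np.random.default_rng(4)
    base = rng.uniform(-np.pi, np.pi)
    # smooth screen: phases vary gently across the lattice
    ph = _wrap(base + 0.3 * lattice.coords[:, 0] + 0.2 * lattice.coords[:, 1])[:, None]
    target = AnalysisGrid(origin=(0.0, 0.0), du=0.1, dv=0.1, nu=21, nv=21)
    pm = phase_field(ph, lattice, target)
    for k, (u, v) in enumerate(lattice.coords):
        i, j = int(round(u / 0.1)), int(round(v / 0.1))
        assert abs(_wrap(pm.phases[0, j, i] - ph[k, 0])) < 1e-9


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.floats(-10.0, 10.0))
def test_global_phase_rotation_equivariance(shift):
    """Adding a constant to all channel phases shifts the field (mod 2*pi)
    and leaves every plaquette charge unchanged."""
    u, v = np.meshgrid(np.arange(4) * 0.5, np.arange(4) * 0.5, indexing="ij")
    grid = ElectrodeGrid(coords=np.column_stack([u.ravel(), v.ravel()]),
                         channel_ids=tuple(f"E{k}" for k in range(16)),
                         spline_count=4, electrodes_per_spline=4)
    rng = np.random.default_rng(8)
    ph = rng.uniform(-np.pi, np.pi, size=(16, 1))
    target = AnalysisGrid(origin=(0.0, 0.0), du=0.1, dv=0.1, nu=16, nv=16)
    pm0 = phase_field(ph, grid, target)
    pm1 = phase_field(_wrap(ph + shift), grid, target)
    d = _wrap(pm1.phases - pm0.phases - shift)
    assert np.nanmax(np.abs(d)) < 1e-6
    ev0 = detect_phase_singularities(pm0, frame=0)
    ev1 = detect_phase_singularities(pm1, frame=0)
    assert [(e.u_cm, e.v_cm, e.charge) for e in ev0] == \
           [(e.u_cm, e.v_cm, e.charge) for e in ev1]


# ---------------------------------------------------------------------------
# singularity detection vs oracle


def test_canonical_vortex_detected_once():
    # core at a plaquette centre (a core exactly on a node has undefined
    # phase there and the loop integral is ill-posed)
    phi = vortex_screen(n=21, c=(1.05, 1.05))
    pm = phase_map_from(phi)
    events = [e for e in detect_phase_singularities(pm, frame=0)]
    assert len(events) == 1
    e = events[0]
    assert e.charge == 1
    assert abs(e.u_cm - 1.05) <= 0.1 and abs(e.v_cm - 1.05) <= 0.1
    assert not e.boundary


def test_uniform_phase_has_no_singularities():
    pm = phase_map_from(np.full((15, 15), 0.4))
    assert detect_phase_singularities(pm, frame=0) == []


def test_oracle_loop_values():
    phi = vortex_screen(n=21, c=(1.05, 1.05))
    pm = phase_map_from(phi)
    assert winding_number_oracle(pm, rectangle_path(5, 15, 5, 15)) == 1
    assert winding_number_oracle(pm, rectangle_path(15, 19, 15, 19)) == 0
    # +1 and -1 vortex together: enclosing both cancels
    phi2 = _wrap(vortex_screen(n=21, c=(0.7, 1.0)) + vortex_screen(n=21, c=(1.3, 1.0), sign=-1.0))
    pm2 = phase_map_from(phi2)
    assert winding_number_oracle(pm2, rectangle_path(2, 18, 2, 18)) == 0


def test_oracle_rejects_open_path():
    pm = phase_map_from(np.zeros((5, 5)))
    with pytest.raises(InvalidArgumentError):
        winding_number_oracle(pm, [(0, 0), (0, 1), (1, 1)])


@pytest.mark.parametrize("n_screens,seed", [(60, 0)])
def test_plaquette_detection_equals_oracle_on_random_screens(n_screens, seed):
    """Plaquette events match the winding oracle on every elementary loop,
    and regional charge sums equal boundary winding numbers."""
    rng = np.random.default_rng(seed)
    n = 20
    for _ in range(n_screens):
        phi = random_phase_screen(rng, n=n)
        pm = phase_map_from(phi)
        events = detect_phase_singularities(pm, frame=0)
        found = {(round(e.v_cm / 0.1 - 0.5), round(e.u_cm / 0.1 - 0.5)): e.charge
                 for e in events}
        for j in range(n - 1):
            for i in range(n - 1):
                w = winding_number_oracle(pm, [(j, i), (j, i + 1), (j + 1, i + 1),
                                               (j + 1, i), (j, i)])
                assert found.get((j, i), 0) == w
        # charge conservation on random rectangles
        for _ in range(5):
            j0, i0 = rng.integers(0, n - 3, 2)
            j1 = rng.integers(j0 + 2, n)
            i1 = rng.integers(i0 + 2, n)
            inner = sum(c for (j, i), c in found.items()
                        if j0 <= j < j1 and i0 <= i < i1)
            assert inner == winding_number_oracle(pm, rectangle_path(j0, j1, i0, i1))


def test_boundary_plaquettes_flagged():
    phi = vortex_screen(n=15, c=(0.05, 0.75))  # core inside an edge plaquette
    pm = phase_map_from(phi)
    events = detect_phase_singularities(pm, frame=0)
    assert any(e.boundary for e in events)
    assert detect_phase_singularities(pm, frame=0, include_boundary=False) == [
        e for e in events if not e.boundary
    ]
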