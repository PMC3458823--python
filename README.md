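# fibmap

Panoramic mapping of the electrical sources that sustain atrial
fibrillation (AF), from multichannel unipolar electrograms recorded by
basket catheters, together with an excitable-medium simulator that
provides ground truth for validating every stage of the chain.

## Who this is for

Cardiac electrophysiology researchers and methods developers who want a
transparent, fully tested reference implementation of the classic
panoramic AF-mapping chain: activation-time isochronal maps,
Hilbert-transform phase maps, topological phase-singularity detection,
rotor-tip tracking with migration-locus measurement, and repetitive
focal-source detection — all operating on a 2-D "unwrapped atrium"
sheet sampled by an 8 x 8 (64-pole) basket electrode grid.

## The model and the method

**Phase mapping.** Each unipolar electrogram `V_k(t)` is assigned an
instantaneous phase via the analytic signal,

    phi_k(t) = arg( V_k(t) + i * H[V_k](t) ),

with `H` the Hilbert transform, so one fibrillatory cycle sweeps `phi`
through 2*pi. Channel phases are interpolated to a regular raster on
the unit circle (cos/sin, never raw angles). A **phase singularity** —
the pivot of a rotor — is a point where the line integral of the phase
gradient around it is non-zero:

    (1 / 2*pi) * closed-integral( grad(phi) . dl ) = n != 0,

with topological charge `n = +/-1` (the sign is the rotor's chirality).
On the raster this integral is evaluated on every 2 x 2 plaquette as
the sum of four wrapped phase differences, and verified in the tests
against a brute-force winding-number oracle on arbitrary loops.

**Activation mapping.** Activation at an electrode is marked at local
maxima of `-dV/dt`; intervals shorter than the restitution-derived
recovery time (floored at the 100–110 ms minimum atrial repolarization
time) are discarded as physiologically impossible. Per-cycle
activation-time fields yield isochrones, propagation-direction vector
fields `grad(T)/|grad(T)|`, conduction velocity `1/|grad(T)|`, and
cycle-to-cycle direction-recurrence scores.

**Sources.** Singularity events are linked through time (every 25–45
ms) into tracks; a track is a rotor when the phase field actually winds
around it and completes at least two full rotations. The migration
locus is a C2 piecewise-cubic curve through the (outlier-cleaned) tip
samples, and its convex-hull area in cm^2 quantifies spatial stability.
Focal sources are interior activation-time minima radiating in (nearly)
all directions across consecutive cycles. The classic resolution
argument — minimum reentrant wavelength = repolarization time x slowest
conduction velocity, e.g. 100 ms x 40 cm/s = 40 mm, comfortably above
the 4–10 mm electrode pitch — is available as
`fibmap.predicted_wavelength`.

**Simulator.** A two-variable excitation/recovery (Aliev–Panfilov-type)
monodomain sheet generates stable or meandering spiral waves, periodic
focal target waves, and plane-wave controls, each with exact ground
truth (isoline-intersection tip paths, focal origin, pacing period,
measured wave speed). Episodes are sampled at the basket electrodes as
pseudo-unipolar electrograms (distance-weighted `-dV/dt` sums plus
white noise) at the clinical 1 kHz.

## Worked example

Run the full chain on a simulated stable spiral (rotor) episode:

```python
from fibmap.pipeline import run_pipeline, validate_config

config = validate_config({
    "kind": "spiral",          # episode type
    "duration_ms": 1500.0,     # mapped segment length
    "seed": 0,                 # all randomness derives from this
    "tissue_h_cm": 0.03,       # validation-scale tissue grid
    "tissue_dt_ms": 0.2,
})
report, artifacts = run_pipeline(config)
print(report.n_sources, report.sources[0])
```

This prints one detected source:

```
1 {'kind': 'rotor', 'chirality': 1, 'time_span_ms': [17.5, 1487.5],
   'n_samples': 43, 'locus_area_cm2': 0.162, 'n_rotations': 8.33, 'n_beats': None}
```

Read: the pipeline found exactly one source, a counterclockwise rotor
(`chirality +1`) tracked across the whole 1.5 s episode (43 samples at
the 35 ms assignment interval), completing 8.3 rotations — consistent
with the episode's true period of 178 ms — and migrating within a
0.16 cm^2 locus, i.e. a spatially stable driver. The report also
carries the measured cycle length (`mean_cl_ms` 177.1 over 472
intervals, matching the truth period to 0.5%) and the parameter echo
needed to reproduce the run byte-for-byte.

The same chain is available from the shell:

```bash
fibmap simulate --kind spiral --duration-ms 1500 --seed 0 --out episode.h5
fibmap activations --in episode.h5 --min-apd 100 --out act.csv
fibmap phase --in episode.h5 --out ps.csv
fibmap track --ps ps.csv --out tracks.json
fibmap run --seed 0 --out run_dir/        # everything end to end
```

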