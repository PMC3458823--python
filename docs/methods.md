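# Methods

This note documents the models, algorithms, parameter choices, and
numerical decisions behind `fibmap`, and what the simulator-based
validation does and does not establish about clinical recordings.

## Coordinate system and electrode geometry

All mapping operates on a flat 2-D sheet in centimetres — each atrium
treated as if unwrapped, with no 3-D chamber registration. The sheet is
non-periodic: the seam created by unwrapping is an ordinary boundary.
The default electrode layout emulates a 64-pole basket: 8 splines of 8
electrodes on a 4 x 4 cm sheet, consecutive electrodes 0.55–0.59 cm
apart along a spline and adjacent splines 0.4–1.0 cm apart, with a
deterministic 0.01 cm deployment jitter. Scattered per-electrode
scalars are rasterized by barycentric linear interpolation on a
Delaunay triangulation (nearest-neighbour available for robustness
checks) onto a 1 mm analysis grid — far below the electrode pitch, so
raster error is negligible; nodes outside the electrode hull are
missing (NaN).

## Tissue model

The simulator integrates a two-variable cubic excitation/recovery
(Aliev–Panfilov-type) monodomain model,

    du/dt = D lap(u) + [ k u (1 - u)(u - a) - u w ] / tau
    dw/dt = [ (eps0 + mu1 w / (u + mu2)) (-w - k u (u - b - 1)) ] / tau

by explicit Euler with a five-point Laplacian and no-flux boundaries.
Defaults (all tunable through `TissueParams`):

| parameter | default | meaning |
|---|---|---|
| sheet | 4 x 4 cm | unwrapped-atrium patch |
| h | 0.02 cm | node spacing (201 x 201 nodes) |
| D | 6.6e-4 cm^2/ms | diffusion coefficient |
| tau | 7 ms | kinetic time scale |
| dt | 0.15 ms | Euler step (must satisfy dt <= h^2/(4D)) |
| k, a, b | 8, 0.1, 0.15 | cubic excitation kinetics |
| eps0, mu1, mu2 | 0.002, 0.2, 0.3 | recovery kinetics |

These values put the spiral period at ~178 ms — inside the 150–250 ms
human AF cycle-length band — with a plane-wave speed of ~15 cm/s and a
wavelength of ~2.6 cm. This is a deliberate desk-scale reduction: the
real atrial wavelength (~4–5 cm) and conduction velocity (~40–70 cm/s)
will not fit a 4 cm patch, so the model preserves the *ratios* that
matter for mapping — wavelength to electrode pitch ~4.5 (clinical: 4–10)
and wavelength to domain size ~0.65 — rather than the absolute speeds.
Consequences: absolute conduction velocities and locus areas from the
simulator are not clinically scaled quantities; fractions, counts,
periods, and agreement statistics are the meaningful outputs.

Episode kinds:

- **spiral** — cross-field initiation (excited left half against a
  refractory lower half, with a seeded 1% perturbation), 600 ms
  burn-in, then recording. Meander is driven by sinusoidal modulation
  of the excitability parameter `a` (level x sin(2 pi t / 450 ms)).
  The true tip path is the intersection of the u = 0.5 isoline at
  frame t with the same isoline one stride later (the point where the
  front pivots rather than advances), computed with sub-node precision
  from contour geometry. The dominant period is measured from
  threshold upcrossings at four probe nodes.
- **focal** — a 0.12 cm disc receives a soft depolarizing current
  (0.4/ms for 3 ms) every cycle length. The recovery variable starts
  mildly elevated (w = 0.3) so the first paced beat already has its
  steady-state duration and every stimulus at a physiological cycle
  length captures 1:1; a dropped-beat check records a 2:1 warning in
  the ground truth. Default pacing 250 ms: at the model's conduction
  velocity one wavefront then occupies the sheet alone (corner transit
  ~195 ms), which is also why plane-wave control episodes pace at
  >= 400 ms.
- **planewave** — a 2-node strip at the left edge is paced the same
  way; the true speed is measured from first-upstroke times along the
  mid-row.

## Electrogram forward model

A channel's pseudo-unipolar signal is the distance-weighted sum of
`-du/dt` over all tissue nodes with kernel `h^2 / max(r, h)^p`, `p = 2`
by default — the far-field decay of a transmembrane current dipole
layer seen by a contact electrode. A 1/r kernel (`p = 1`) is available
but not default: in a 2-D sheet its long tail lets any spatially
coherent distant event (pacing artifact, synchronized repolarization)
dominate the local deflection at every electrode, which is not how
contact electrograms behave. Signals are resampled to 1 kHz and white
Gaussian noise of configurable SD (mV) is added from the episode seed.
What the model omits: ventricular far-field (QRS/T contamination),
electrode contact variability, fractionation from microstructure, and
3-D volume-conductor effects. Validation passing on these clean
signals therefore bounds algorithmic error, not robustness to every
clinical artifact; the noise and meander knobs probe the first-order
versions of those stresses.

## Signal conditioning and activation detection

Filtering is a zero-phase (forward-backward) Butterworth, order 4,
passband 0.05–500 Hz by default; at 1 kHz sampling the upper corner
coincides with Nyquist and the filter degenerates to the 0.05 Hz
high-pass alone. Zero-phase filtering is chosen so group delay cannot
bias activation times.

Activation is the local maximum of `-dV/dt` (the standard unipolar
criterion) above an adaptive per-channel threshold: the larger of 3x
the robust (MAD-based) noise SD of the slope and 0.5x its 99.9th
percentile, with a 50 ms lockout. The relative floor was calibrated
against simulator ground truth: across labelled episodes, spurious
deflections (repolarization, stimulus far-field) reach at most 0.44 of
the median true-activation slope, while a 0.5 floor loses only 0.6% of
true beats (weak stimulus-adjacent first beats) — so 0.5 separates the
two populations with margin on both sides. Detected trains then pass
the restitution filter: scanning forward, an event whose interval from
the last accepted event is below the recovery time is discarded (the
earlier event of a too-close pair is always kept, matching refractory
physiology). The recovery time is the APD-restitution curve evaluated
at the preceding diastolic interval, floored at the 100 ms minimum
atrial repolarization time; with no patient curve available the flat
floor is the default. The filter is idempotent and only ever removes
events.

## Isochronal maps, conduction velocity, recurrence

Per-cycle windows are anchored on a reference channel chosen by
circular statistics: activation offsets are reduced modulo the dominant
cycle length, and the channel activating immediately after the largest
empty arc (the diastolic gap) — the wavefront's earliest site — anchors
the windows, which start 10 ms before the anchor to absorb timing
jitter. This rule captures a travelling wavefront whole; a naive
"earliest event" rule breaks when a first beat is lost in the filter
transient. Each channel contributes its first activation inside the
window; maps with fewer than 3 active channels are rejected.

The propagation direction is `grad(T)/|grad(T)|` by central differences
with missing-data masking (undefined below a 1e-6 ms/cm gradient
tolerance); speed is `1/|grad(T)|` in cm/s. Plane-wave conduction
velocity is a least-squares plane fit with an rms-residual warning
above 5 ms. Direction recurrence between cycles is the per-node mean
cosine between consecutive cycles' unit directions — chosen over the
unspecified alternatives because it is bounded in [-1, 1], invariant
under global rotation, and reduces to the intuitive 1 / -1 for
identical / reversed maps; consecutive (not all) cycle pairs are used.

## Phase mapping and singularity detection

Before the Hilbert transform each channel is detrended by subtracting
its moving mean over one dominant cycle length (dominant frequency from
a zero-padded FFT in the 1–20 Hz band). This is the minimal
stabilization against the baseline drift that survives a 0.05 Hz
high-pass; `"mean"` and `"none"` modes are available and the choice is
echoed in every run report. Phase is the analytic-signal angle, wrapped
to (-pi, pi]; zero-variance channels carry an undefined-phase flag.

Interpolation to the raster happens on the unit circle: cos and sin
are interpolated separately and recombined by atan2. This is exact at
electrodes, correct across the +/-pi wrap, and equivariant under global
phase rotation (all verified by tests).

Singularity detection evaluates every 2 x 2 plaquette's wrapped loop
sum; |sum| > pi flags a singularity with charge round(sum / 2 pi) at
the plaquette centre (discrete wrapped sums are exact multiples of
2 pi only in ideal fields, hence the half-turn threshold). Plaquettes
within one node ring of missing data or the raster edge are flagged
`boundary` and excluded from tracking by default — edge plaquettes are
the dominant interpolation-artifact source. The detector is validated
against a brute-force winding-number oracle on every elementary loop of
500 random band-limited phase screens, including the charge-conservation
identity (plaquette charges in any rectangle sum to the boundary
winding number).

## Source tracking and characterization

Events are binned into 35 ms slabs (configurable 25–45 ms); within a
slab, same-chirality events closer than half the jump limit merge into
cluster centroids, and existing tracks greedily claim the nearest
same-chirality candidate within 1 cm (oldest track first). Unclaimed
candidates open tracks; a track idle for more than 105 ms closes.
Greedy linking matches the optimal per-slab assignment whenever
emitters are separated by more than twice the jump limit (tested
against a Hungarian-algorithm oracle); it is preferred for its
order-stability and because the periodic assignment it implements is
the natural reading of tip sampling every few tens of ms.

A track is a **rotor** only if (i) the spatial winding number of the
phase on a ring (0.3–0.7 cm) around the track samples is non-zero with
the track's chirality in at least 80% of samples — the condition that
separates a pivot from through-going wavefronts, at which every site
also sweeps 2 pi per cycle in *time* — and (ii) the temporal rotation
count (mean unwrapped phase progression at ring nodes over the track
span, / 2 pi) reaches 2 with no inter-sample gap above 105 ms. The
two-rotation minimum is a documented, configurable reading of
"sustained rotation"; no numeric criterion exists in the clinical
definition.

Isolated outliers (interpolation errors) are removed when a sample's
distance to the track's running median position (11-sample window)
exceeds 5x the median of those distances; at most 20% of samples may
be dropped, else the track is kept whole with a warning. The migration
locus is a chord-length-parameterized C2 cubic spline through the
retained samples (the stated first- and second-derivative continuity of
third-order curve fitting forces exactly this class; two points
degenerate to a segment), and the locus area is the convex hull of the
densely sampled curve — the reproducible, rigid-motion-invariant choice
among unspecified alternatives (an outline or density contour would
need extra parameters).

**Focal sources** are interior raster nodes that are local activation
minima radiating outward: time must increase monotonically (15 ms
tolerance, about the map's interpolation texture) along at least 7 of
8 rays over two electrode pitches, each passing ray rising by at least
20 ms (a flat ray runs along a wavefront, not away from a source).
Origins recurring within 1 cm over >= 2 consecutive cycles form a
track. Because a rotor's single-cycle isochrone also radiates from
near its core, focal tracks whose origin lies within 1 cm of a
classified rotor locus are suppressed — the phase-derived rotational
reading takes precedence, mirroring the mutually exclusive source
definitions. Conservation between two mapping sessions is reported as
locus-centroid distance plus hull intersection-over-union (degenerate
hulls are buffered by 1 mm and flagged).

## Pipeline and reproducibility

`run_pipeline` composes simulate -> band-limit -> detect ->
restitution-filter -> segment -> isochrones -> phase -> singularities
-> tracks -> report. The configuration is a flat, strictly validated
key-value document (unknown keys are errors; the 25–45 ms singularity
assignment interval and the 100–110 ms minimum APD are range-enforced
unless forced); every random element derives from the single config
seed, and reports serialize with sorted keys and no timestamps, so
identical config + seed gives byte-identical reports.

## Validation scales and what the tests show

The test suite and the acceptance script run the tissue model at
h = 0.03 cm (134 x 134 nodes, dt = 0.2 ms) with episodes of 1.2–1.5 s —
the package's validation scale, chosen so the full chain (including two
complete pipeline runs for the determinism check) completes in a few
minutes; the production default is h = 0.02 cm. A dt-refinement check
(halving dt changes the final state by < 1% rms) guards the
discretization. Multi-seed sweeps during development showed the rotor
tip-capture fraction >= 0.95 and exactly one recovered focal source
with origin error <= 0.3 cm across ten seeds, and zero sources on
plane-wave controls.

Passing these tests establishes that the mapping chain recovers known
synthetic sources through the full electrode-sampling bottleneck (64
channels, 0.55 cm pitch, 1 kHz). It does not establish performance on
clinical recordings, whose far-field contamination, fractionation, and
contact artifacts the forward model deliberately omits.

## Known limitations

- Single-sheet mapping; no bi-atrial joint fields, no 3-D geometry.
- The excitation model is phenomenological; restitution and CV are not
  fit to human atrial measurements beyond the cycle-length band.
- Focal detection assumes one wavefront per cycle window on the sheet;
  at pacing periods below the sheet transit time, window edges mix
  consecutive sweeps.
- The rotor/focal exclusivity rule resolves the core ambiguity in
  favour of rotors; a genuinely co-located focal source under a rotor
  would be suppressed.
- Epicardial/endocardial breakthrough disambiguation and ablation
  planning are out of scope.
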