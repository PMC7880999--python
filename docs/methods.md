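# Methods

This note records the models, conventions and numerical choices behind
`parmotion`, what the simulator does and does not emulate, and the design
decisions taken where the problem left them open.

## Geometry and units

All angles are degrees at interfaces and radians internally.  A parallel
view at angle θ integrates along `d̂(θ) = (−sin θ, cos θ)` over lines offset
by `s` along `n̂(θ) = (cos θ, sin θ)`; at θ = 0 rays run along +y and s along
+x.  A fan ray at view angle β, channel angle γ is the parallel ray
`θ = β + γ`, `s = R sin γ` (R = source-to-isocenter distance, default
600 mm).  Image arrays map index `(i, j)` to `(x, y) = origin +
(j·Δ, i·Δ)` with the origin at the lower-left pixel center and the isocenter
at the grid center.  CT numbers convert to attenuation by
`μ = μ_water (1 + HU/1000)` with `μ_water = 0.019 /mm` (≈ 70 keV,
configurable); projections are monochromatic line integrals in μ·mm.

Parallel view angles are kept monotone in acquisition order (they may run
past 360° in multi-rotation scans) so that each view keeps a well-defined
acquisition time; view time is that of the central contributing fan view.

## The moving-phantom simulator

The `copd_like` preset emulates a lung-simulating quality phantom: a
100 mm water-equivalent body disk, an 88 mm lung-foam core (−856 HU), and 24
internal structures — 12 air columns (−1000 HU, radii 1.5–6 mm) and 12
polycarbonate airway tubes (+100 HU walls of 0.5–3 mm around air lumens) —
spread quasi-uniformly over three rings.  The commercial phantom's exact
layout is proprietary and its tubes are angulated in 3D; this preset is an
in-plane emulation, not a replica.  The uniform spread is deliberate:
the artifact metrics are computed in ROI boxes fixed in scanner coordinates
while the phantom oscillates by up to ±21 mm, so the structure mix inside
the boxes must be insensitive to the pose at the target time.  With sparse
clustered structures the normalized positivity of even a perfectly
reconstructed frozen pose varied by a factor of ~3 with pose; with the
spread layout it varies by ≈ ±10%, which is what lets pose-independent
quantities like "NP of the corrected image vs. NP of the static scan" be
meaningful at all.

Motion is a rigid periodic in-plane oscillation: both axes driven by one
scalar phase, `d(t) = A·wave(2π·rpm·t/60 + φ₀)`, with half-stroke
`A = (20, 7.5) mm` matching the actuator's ±20 mm vertical and ±7.5 mm
lateral stroke settings.  The waveform is sinusoidal by default (the
actuator's true waveform is unspecified; a triangle wave is available), and
the mean travel per rotation,
`2·|2A|·rpm·T/60`, is waveform-independent — 3.6 / 7.1 / 10.7 mm per 0.5 s
rotation at 5 / 10 / 15 rpm for the combined 42.7 mm stroke.  Motion is
frozen within a view (a view lasts ~0.7 ms; intra-view blur is negligible).

Forward projection is exact: chord lengths of disks/annuli times the
attenuation step of each primitive over its surroundings.  This additive
decomposition assumes nested overlap (each primitive sits on a uniform
region of the stack below it, probed at one interior point), which holds for
the presets; the background must be air so the exterior contributes nothing.
Optional Poisson noise on the line integrals is available but off by
default — every effect studied here is motion-driven, and determinism makes
runs exactly reproducible.

What the simulator does **not** emulate: polychromatic spectra, scatter,
detector apertures and bowtie filtration, helical/cone geometry, z-motion,
elastic (non-rigid) phantom deformation, and scanner noise texture.
Passing tests therefore demonstrate the internal consistency of the
pipeline and its behavior under rigid in-plane motion — not performance on
clinical raw data, where deformation is elastic and contrast is lower.

## Reconstruction

Rebinning interpolates bilinearly in (β, γ) onto a uniform (θ, s) grid and
requires ≥ 180° + fan of fan coverage.  The ramp filter is the band-limited
Ram–Lak kernel assembled in the spatial domain (Kak–Slaney form) and applied
by FFT with ≥ 2× zero-padding; Shepp–Logan and Hann apodizations are
available.  Backprojection is pixel-driven with linear interpolation along
s, scaled by `π / (views per 180°)`, so a half scan of parallel views
reconstructs μ exactly; parallel half-scans are complete without redundancy
(Parker) weighting.  Final images use the plain Ram–Lak filter ("standard
kernel" behavior); PAR images default to Hann, which stabilizes
registration.

PAR segments are centered at `θ_c ∓ 90°` with width equal to the fan angle
(50°) by default, the heuristic segment length for heart-rate-scale motion.
PARs are kept as raw partial sums (not rescaled to full-reconstruction
units): the registration is made scale-invariant instead (below).  Because
every partial reconstruction shares the per-view weighting and the filter is
per-view, partial images over a disjoint partition of views sum *exactly* to
the reconstruction over the union — the identity is asserted to 1e−10 in the
tests.  Note the PAR windows extend L/2 beyond the half-scan range on either
side, so the partition identity is stated over the enclosing
`[θ_c−90−L/2, θ_c+90+L/2)` range.

Band-pass is a difference of Gaussians, σ_fine = 1 px and σ_coarse = 8 px by
default: small enough to keep vessel/airway-scale edges, large enough to
remove limited-angle shading lobes.  Neither cutoff is dictated by the
problem; both are configuration.

## Motion estimation

The deformation model is a uniform cubic B-spline lattice (free-form
deformation) with at least one control interval of margin around the image.
Registration minimizes

    SSD(fixed, moving∘(id+D)) / (n·range²)  +  λ · bend(C) / (n_c·spacing²)

by steepest descent with Armijo backtracking (step capped at 0.4 control
spacings initially, grown ×1.8 after accepted steps), coarse-to-fine over
control spacings 24 → 12 mm with image pre-smoothing σ = spacing/4.  Level
transitions re-fit the finer lattice to the current dense field by separable
least squares (exact for nested spacings).  Everything is deterministic —
identical inputs give bit-identical fields.  Normalizing the data term by
the squared dynamic range makes the estimate invariant to a common rescaling
of the PAR pair, which is why the arbitrary PAR normalization is harmless.
NCC is selectable.  λ defaults to 0.01; the bending term is normalized so
this is a dimensionless trade-off.  Repeated line-search failure is treated
as convergence (a backtracking descent never accepts a cost increase);
only a non-finite cost is an error.

**Motion-detectability gate.**  The estimated field is accepted only if it
explains at least half of the initial PAR mismatch (`min_explained = 0.5`).
Conjugate PARs of a static object differ only by rebinning/filtering
residue, of which a smooth FFD can explain a measured ~1.5%; genuine motion
within capture range is explained > 99%.  The gate therefore returns the
exact zero field for static data — making "no motion in, no correction out"
an exact property rather than an approximate one — while sitting two orders
of magnitude away from both measured regimes.

**Conventions.**  The MVF is the forward displacement of material points
from the BEFORE-PAR state to the AFTER-PAR state, indexed at target-frame
positions; the target time sits midway, so the linear factor is
`α(θ) = wrap(θ − θ_c)/180` with α = ∓0.5 at the PAR centers.  Whether the
original formulation registers before→after or both→target symmetrically is
not stated anywhere; the midpoint interpretation is this package's recorded
choice.  An intrinsic limitation worth knowing: a PAR from views near angle
θ resolves structure sharply along n̂(θ) but poorly along the ray direction,
so the component of motion along the rays of the PAR segments is estimated
less accurately than the transverse component.

## Motion-compensated reconstruction

MCR warps the backprojection, not the image: pixel X samples the filtered
view at the radial position of `X + α(θ)·D(X)`.  This is exact for per-view
rigid motion, shares its code path with plain FBP (zero field → bit-identical
output), and avoids resampling artifacts of warp-then-sum alternatives.  α
is computed from the view's angle rather than its timestamp (affinely
related in an axial scan; the angle avoids rebinning time-interpolation
noise).  D is evaluated at the target-frame position (one-step explicit
warp); the inverse-map error is O(‖D‖²‖∇D‖), negligible for the smooth
few-mm fields here.

## Metrics

P(h) is a Gaussian-kernel density evaluated on a uniform 1-HU grid and
normalized to unit *mass*; entropy is the discrete `−Σ P ln P` in nats.  The
grid step enters the discrete entropy additively, constant across compared
conditions, so relative comparisons are unaffected; whether the original
measure used masses or density values is ambiguous, and masses are the
default here.  The kernel bandwidth is nowhere specified; the default is
Silverman's rule per ROI floored at 5 HU, and the bandwidth used is recorded
in every result row.  One mathematical fact worth noting: KDE entropy is
monotonically non-decreasing in the bandwidth (larger-bandwidth estimates
are convolutions of smaller-bandwidth ones), so entropy comparisons are only
meaningful at matched bandwidths — another reason to record them.

The automatic threshold is the lowest grid point attaining the density
maximum (ties resolve downward).  Positivity sums `(f − T)²` over pixels at
or below T; normalized positivity divides by the ROI pixel count.  ROIs are
axis-aligned mm rectangles converted to pixel masks by center inclusion; a
warning fires below 25 pixels (KDE stability).  The paired t-test is the
standard two-sided test on per-slice differences; identical samples have an
undefined t and raise.

## The experiment harness

`run_phantom_experiment` mirrors the moving-phantom study design: actuator
rates {0, 5, 10, 15} rpm (equivalently 0/3.6/7.1/10.7 mm per rotation — the
conditions are reported by travel, which is the waveform-independent
quantity), half-scan FBP and MCR per condition, five 40×40 mm ROI boxes plus
their union, per-condition percent changes, paired t-tests across slices,
and deviation of each MCR condition from the 0-rpm FBP ground truth.  The
physical study's 17 slices are emulated as repeated realizations of the
single simulated slice at evenly spaced actuator phase offsets (with noise
enabled they also differ in noise); at 0 rpm with noise off all realizations
are identical, so the 0-rpm paired test is degenerate there and reported as
such.  Desk-scale defaults are a 256² grid over a 360 mm field of view, 720
views/rotation, 400 channels over a 50° fan; the acceptance script runs 4
conditions × 5 phase realizations at these sizes, and the trend test in the
suite uses 3 realizations.  Full runs are byte-reproducible with noise off.

## Known limitations

- 2D axial only; no helical pitch handling, no z-motion, no cone beam.
- Rigid simulated motion; elastic deformation is estimated by the same
  machinery but is not exercised by the phantom experiment.
- The absolute NP/entropy magnitudes depend on the phantom layout, the KDE
  bandwidth and the reconstruction noise floor; only relative comparisons
  (between methods and against the static scan) are meaningful.
- The FFD optimizer is first-order; very large displacements (≫ control
  spacing) would need more levels or larger smoothing than the defaults.
- Ray-direction motion components in the PAR pair are intrinsically less
  observable than transverse ones (see above).
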