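# parmotion

Motion-compensated CT reconstruction from conjugate partial-angle images,
with motion-artifact metrics and a moving-phantom simulator.

## The problem

Even under breath-hold, routine axial or helical chest CT suffers from
cardiac-transmitted motion of lung parenchyma, vessels and airways (reported
at roughly 1–4 mm).  The resulting artifacts — doubled edges, shading,
CT-value bias — can mimic bronchiectasis, cysts, emphysema or ground-glass
nodules and corrupt quantitative lung measurements.  Gated acquisition is not
an option for routine scans, so the correction has to come from the raw data
of an ordinary scan.

`parmotion` implements such a correction pipeline for 2D axial scans,
together with the quantitative artifact measures used to evaluate it, and an
analytic moving-phantom simulator (a lung-simulating phantom of air columns
and polycarbonate airway tubes on a periodic motion actuator) that stands in
for the scanner.

## The method

1. **Rebinning.** Fan-beam raw data `(β, γ)` is rebinned to parallel
   geometry via `θ = β + γ`, `s = R sin γ`.
2. **Conjugate PAR pair.** For target angle `θ_c` (whose acquisition time is
   the middle of the half-scan data), two partial-angle reconstructions
   (PARs) are made from short segments (width = the fan angle by default)
   centered at `θ_c − 90°` and `θ_c + 90°`.  They sample the same ray lines
   half a rotation apart: identical for a static object, displaced by the
   motion for a moving one.
3. **Band-pass + non-rigid registration.** Both PARs are
   difference-of-Gaussians filtered to remove limited-angle shading, then
   registered with a cubic B-spline free-form deformation (SSD + bending
   energy, deterministic gradient descent, coarse-to-fine).  No segmentation
   is involved, so motion of every edge — parenchyma, vessels, airways — is
   estimated.  The result is a motion vector field (MVF) `D(X)` spanning the
   before→after half-rotation interval.
4. **Motion-compensated FBP.** Assuming motion linear in time, the view at
   angle `θ` gets `α(θ) = wrap(θ − θ_c)/180°` of the field.  Each
   ramp-filtered view is backprojected with pixel `X` sampled at
   `s = (X + α(θ)·D(X)) · n̂(θ)` — the pixel's material position at that
   view's time.  With a zero field this is exactly half-scan FBP.

Artifacts are quantified per ROI `Ω` by

- `Entropy = −Σ_h P(h) ln P(h)` with `P(h)` a Gaussian-kernel (Parzen)
  density of the CT values on a 1-HU grid, and
- `Normalized positivity (NP) = (1/n(Ω)) Σ_{X∈Ω, f(X)≤T} (f(X) − T)²`, with
  the threshold `T = argmax_h P(h)` chosen automatically — the power of the
  below-mode shading that motion artifacts produce,

plus paired t-tests across slices and percent-change summaries.

## Worked example

Simulate the lung phantom moving at 10 rpm (7.1 mm of travel per 0.5 s
rotation), reconstruct with and without compensation, and score the ROIs:

```python
import numpy as np
from parmotion import (ExperimentConfig, MotionTrajectory, build_phantom,
                       forward_project_fan, rebin_fan_to_parallel, fbp_half,
                       reconstruct_par_pair, bandpass, register_ffd,
                       MCRConfig, motion_compensated_fbp, evaluate_roi,
                       union_roi, path_per_rotation)
from parmotion.pipeline import default_rois

cfg = ExperimentConfig()
phantom = build_phantom("copd_like")
traj = MotionTrajectory(kind="periodic_1d", amplitude=(20.0, 7.5), rpm=10.0)
print(f"travel per rotation: {path_per_rotation(traj, 0.5):.1f} mm")

geom, grid = cfg.scan_geometry(), cfg.recon_grid()
sino = rebin_fan_to_parallel(forward_project_fan(phantom, geom, traj))
fbp = fbp_half(sino, grid, theta_c=90.0)

pair = reconstruct_par_pair(sino, grid, theta_c=90.0, segment_length=50.0)
mvf = register_ffd(bandpass(pair.before), bandpass(pair.after))
mcr = motion_compensated_fbp(sino, grid, MCRConfig(theta_c=90.0, mvf=mvf))

roi = union_roi(default_rois(), grid)
for name, img in [("FBP", fbp), ("MCR", mcr)]:
    m = evaluate_roi(img.values[roi.raster(grid)], "union")
    print(f"{name}: NP = {m.normalized_positivity:6.1f} HU^2, "
          f"entropy = {m.entropy:.3f} nats (T = {m.threshold:.0f} HU)")
```

Output:

```
travel per rotation: 7.1 mm
FBP: NP = 1217.2 HU^2, entropy = 5.618 nats (T = -858 HU)
MCR: NP =  776.7 HU^2, entropy = 4.985 nats (T = -856 HU)
```

The uncorrected half-scan image shows strong below-threshold shading power
(NP 1217 HU²) and a smeared CT-value distribution; compensation brings both
measures back toward their static-scan values (the static NP of this phantom
and ROI set is ≈ 827 HU²).  The same pipeline over several actuator rates at
once, with paired statistics, is `run_phantom_experiment(ExperimentConfig())`
or, from the shell, `parmotion run --config experiment.yaml --out results/`.

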