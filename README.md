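# microflow

Quantitative analysis of intravital microcirculation videos: blood
velocity from kymograph spectra and vessel diameter from transverse
intensity profiles, with the preprocessing (motion correction, vessel
segmentation, robust PCA) needed to get there, and the group-statistics
layer used in longitudinal small-animal studies.

## Who this is for

Labs imaging skin or dorsal-window microcirculation with a calibrated
color camera (pixel size on the order of 0.64 µm, frame rates of tens
to hundreds of Hz) who want per-vessel red-blood-cell flow speed and
vessel diameter over time — for example to follow sepsis models and
their treatment. No in-vivo data ships with the package; a synthetic
video generator with exact ground truth stands in for every stage's
validation.

## The method

Given a calibrated video `I(t, y, x)`:

1. **Motion correction.** Each frame is aligned to the first by the
   integer translation maximizing normalized cross-correlation of a
   template region (the whole frame by default).
2. **Vessel extraction.** Multiscale Hessian vesselness (Frangi-type,
   dark tubular structures in the green channel, where hemoglobin
   absorption gives the strongest contrast) is thresholded and cleaned;
   the mask is thinned to a one-pixel skeleton and traced into
   branch-free centerlines. A `VesselPredictor` interface accepts any
   patch-probability model (e.g. a trained U-net) as a drop-in
   replacement, using the same overlap-averaged patch protocol.
3. **RBC isolation.** The registered green-channel video, one flattened
   frame per column of a matrix `D`, is split by principal component
   pursuit — minimize `‖L‖* + λ‖S‖₁` subject to `D = L + S` — into a
   low-rank background `L` (tissue, vessel walls) and a sparse
   component `S` carrying the moving red blood cells
   (λ = 1/√max(m, n) by default; inexact augmented-Lagrangian solver).
4. **Velocity.** Sampling `|S|` along a centerline section, frame by
   frame, gives a kymograph whose oblique streaks are RBC tracks. The
   2-D Fourier magnitude spectrum concentrates on a line through the
   origin orthogonal to the streaks; with θ′ the angle between that
   dominant line and the temporal-frequency axis,

       v  =  cot θ′  [px/frame]  =  cot θ′ · pixel_size / frame_interval.

   About 150 frames give a stable spectrum.
5. **Diameter.** Along normals to the centerline at regular intervals,
   the green-channel profile shows a dip; the full width at half
   maximum — measured from the dip minimum to the midpoint of the
   highest shoulder on each side, crossings interpolated to subpixel —
   is the diameter. Vessels classify as capillary (< 20 µm),
   arteriole/vein (20–100 µm) or out of range.
6. **Statistics.** Per-group per-timepoint mean ± SD, range
   normalization with mean centering for cross-quantity trend
   comparison, and paired Student t-tests of each timepoint against the
   pre-intervention baseline at α = 0.1.

## Worked example

```python
import numpy as np
from microflow.synth import SceneSpec, VesselSpec, render_scene
from microflow.io import RunConfig
from microflow.pipeline import run_pipeline

spec = SceneSpec(
    height_px=72, width_px=180,
    vessels=[VesselSpec(polyline_points=[(8, 24), (170, 44)],
                        width_um=14.0, velocity_um_s=150.0, rbc_rate=20.0)],
    noise_sd=0.01, jitter_px=2, specular_blobs=1, n_frames=100, seed=11)
seq, truth = render_scene(spec)

config = RunConfig(pixel_size_um=0.64, frame_interval_s=0.01,
                   search_radius_px=3, rpca_window=100, kymo_n_frames=100,
                   min_diameter_um=5.0, profile_half_length_px=30)
report = run_pipeline(config, seq, out_dir="out")
v = report.vessels[0]
print(f"diameter {v['diameter_um']:.1f} um ({v['vessel_class']}), "
      f"velocity {v['velocity_um_s']:.0f} um/s")
```

prints

```
diameter 15.1 um (capillary), velocity 154 um/s
```

for a vessel rendered at 14 µm and 150 µm/s: the diameter comes back
within about a micron and the velocity within a few percent. `out/results.csv`
holds the same numbers as tidy records and `out/report.json` the full
per-stage provenance.

The same stages are available from the shell:

```bash
microflow simulate --config scene.yaml --out sim/
microflow register sim/video.tif reg.tif --pixel-size-um 0.64 --frame-interval-s 0.01
microflow segment reg.tif seg/ --pixel-size-um 0.64 --frame-interval-s 0.01
microflow run sim/video.tif out/ --config run.yaml
```

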