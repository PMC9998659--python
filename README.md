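# spindlekit

3D reconstruction and tracking of the mitotic spindle and cell cortex from
sparse z-stack time-lapse microscopy.

Live imaging of dividing cells typically yields only a handful of z-slices
(three slices, 2 µm apart is common) every few minutes — far too sparse for
conventional volumetric analysis, yet spindle *movements* in 3D (tumbling,
rolling, rotation, and displacement toward or along the cortex) are exactly
what many mitosis experiments need to measure. spindlekit is for cell
biologists and image analysts who have per-frame segmentation masks of the
spindle and the cell boundary (from any source: the built-in classical
pipelines, a neural segmenter, or manual annotation) and want quantitative,
identity-consistent 3D spindle kinematics.

## What it computes

- **Cortex model.** Mask boundary pixels from each z-slice are lifted to
  their physical plane and enclosed with a minimum-volume enclosing
  ellipsoid (MVEE), solved by Wolfe–Atwood coordinate ascent on the dual
  determinant-maximization program.
- **Spindle model.** The spindle mask is burned onto the raw fluorescence
  image; the top 30 % brightest masked pixels acquire axial offsets by
  inverting the PSF's axial Gaussian, ẑ = z_c + σ·√(−log I), and the cloud is
  enclosed with an MVEE. Poles are refined onto the mask boundary along the
  pole-to-pole axis (`refine_poles`), compensating the ellipsoid fit's
  over/undershoot.
- **Pole–cortex distances.** The pole axis is intersected with the cortex
  ellipsoid analytically: in the principal frame the line substituted into
  the ellipsoid equation gives χt² + γt + ζ = 0, classified by discriminant.
- **Six-point tracking.** The three principal-axis endpoint pairs are
  matched frame-to-frame with per-axis 2×2 distance matrices; label swaps
  are corrected, flagged, and propagated.
- **Kinematics.** Frame-to-frame rotation R = A_t A_{t−1}ᵀ decomposed into
  ZYX Euler angles (α tumbling, β rolling, γ rotation), and displacement
  decomposed into longitudinal/equatorial/axial components with fractions
  f_lg² + f_eq² + f_ax² = 1.
- **Classical annotation** (Otsu chromosome plates, adaptive-threshold +
  convex-hull spindles, outward active-contour spindles), Stage-3 candidate
  filtering and centroid tracking, IoU / average-precision / mask-correlation
  metrics, and a fully scripted **synthetic movie generator** with exact
  ground truth for every stage.

## Worked example

Simulate the default acquisition regime (21 frames every 3 min, three
z-slices 2 µm apart, 0.06887 µm pixels) with a spindle rotating 5° per frame
in-plane, then reconstruct and track it:

```python
import numpy as np
from spindlekit import GaussianPSFModel
from spindlekit.simulate import SimulationParams, generate_movie
from spindlekit.pipeline import reconstruct_and_track
from spindlekit.kinematics import summarize_track
from spindlekit.io import write_tracks

params = SimulationParams(euler_increments_deg=(0, 0, 5.0), seed=7)
movie, truth = generate_movie(params)
psf = GaussianPSFModel(amplitude=1.0, xy_center=(0, 0), z_center=0.0,
                       sigma_x=1.3, sigma_y=1.3, sigma_z=0.30)
track = reconstruct_and_track(movie, truth.spindle_masks, truth.cortex_masks, psf)
table = write_tracks(track, "track.csv")
s = summarize_track(track)
print(f"frames accepted: {track.n_accepted}/{movie.n_frames}")
print(f"median |alpha|, |beta|, |gamma| (deg/3 min): "
      f"{s['median_abs_alpha_deg']:.2f}, {s['median_abs_beta_deg']:.2f}, {s['median_abs_gamma_deg']:.2f}")
```

prints

```
frames accepted: 21/21
median |alpha|, |beta|, |gamma| (deg/3 min): 0.07, 0.06, 5.02
```

The recovered median rotation of 5.02°/frame matches the scripted 5°/frame
to 0.02°; the out-of-plane angles are ~0.1°, as scripted. The per-frame CSV
holds endpoint coordinates (µm), pole-cortex distances, Euler angles,
displacement components and the identity-correction flag — e.g. the first
rows of this run:

```
 time_min  pole1_cortex_dist_um  gamma_deg
      0.0              5.007299   0.000000
      3.0              5.052961   4.982629
      6.0              5.038460   5.354716
      9.0              4.964512   4.987173
```

(true pole-cortex distance in this scene: 4.51–5.05 µm as the rotating
spindle samples the slightly elliptic cortex).

A CLI mirrors the library: `spindlekit simulate | annotate | psf-fit |
track | evaluate` (see `spindlekit --help`).

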