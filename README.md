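# aprep — Adaptive Particle Representation of fluorescence microscopy images

Modern light-sheet and confocal microscopes produce 3D image stacks faster
than they can be stored, moved, or processed as pixel grids. Most of those
pixels are background or smooth foreground: the information content of a
fluorescence image is far smaller than its pixel count. `aprep` implements
the **Adaptive Particle Representation (APR)**: it resamples a pixel image
into a set of *particles* placed at the centers of content-adapted
*Particle Cells* — an octree-style powers-of-two partition that is fine
near edges and coarse in flat regions — with a mathematical guarantee on
the reconstruction error. The representation can be stored, filtered,
projected and reconstructed without ever returning to the full pixel grid.

It is aimed at people building image-analysis pipelines for large
fluorescence datasets and at anyone who wants a compact, well-tested
reference implementation of resolution-bound adaptive sampling in Python.

## The model

Given an image `I(y)`, a user error bound `E` and a Local Intensity Scale
`σ(y)` (a smooth estimate of the local dynamic range, providing gain
control across bright and dim objects), the APR guarantees the
**Reconstruction Condition**

```
|I(y) − Î(y)| ≤ E σ(y)      for every pixel y,
```

for any reconstruction `Î` formed as a non-negative weighted average of the
particles within the local resolution radius. The pipeline:

1. `|∇I|` — gradient magnitude from a smoothing cubic B-spline fit
   (parameter `λ`);
2. `σ(y)` — windowed local dynamic range on the 2× downsampled image,
   clamped below by `σ_min`;
3. `L(y) = E σ(y) / |∇I(y)|` — the Local Resolution Estimate, the largest
   admissible sampling radius at `y`;
4. the **Pulling Scheme** — a linear-time level sweep that converts the
   cell-quantised `L` (the Local Particle Cell set) into the unique
   coarsest valid tiling of the image, the Optimal Valid Particle Cell set
   `V`;
5. one particle per cell at `y_p = (|Ω|/2^l)(i + 0.5)`, with intensity
   copied from the pixel (finest cells) or block-averaged (coarser cells).

The APR is the pair `{V, P}` (cells + particle intensities); particle
positions are implied by the cells. Quality is measured by the observed
relative error `E* = max |I − Î|/σ` (always ≤ E on noise-free input), PSNR,
and the Computational Ratio `CR = N / N_p` (pixels per particle).

## Worked example

```python
import numpy as np
from aprep import (gaussian_1d_example, build_apr, PipelineParams,
                   reconstruct_constant, observed_error, psnr,
                   generate_sphere_scene, render_ground_truth,
                   corrupt_with_noise, noise_gain_for_peak_snr)

# 1D didactic example: shifted Gaussian, E = 0.1, constant unit scale
img = gaussian_1d_example(256)
apr = build_apr(img, PipelineParams(E=0.1, lambda_smoothing=0.0, constant_scale=1.0))
rec = reconstruct_constant(apr)
print(f"N = {img.size}, N_p = {apr.n_particles}, "
      f"CR = {img.size/apr.n_particles:.1f}, "
      f"E* = {observed_error(img, rec, np.ones_like(img)):.4f}")

# 3D synthetic benchmark: six blurred spheres, medium-quality noise
scene = generate_sphere_scene((64, 64, 64), 6, (1, 10), (4, 10),
                              psf_sigma=2.0, noise_gain=1.0, seed=7)
gt = render_ground_truth(scene)
gain = noise_gain_for_peak_snr(gt, 20.0)
noisy = corrupt_with_noise(gt, gain, seed=7)
apr = build_apr(noisy, PipelineParams(E=0.1, lambda_smoothing=3.0, scale_window=2))
print(f"N = {noisy.size}, N_p = {apr.n_particles}, CR = {noisy.size/apr.n_particles:.1f}")
print(f"PSNR noisy input   vs truth = {psnr(gt, noisy):.2f} dB")
print(f"PSNR reconstruction vs truth = {psnr(gt, reconstruct_constant(apr)):.2f} dB")
```

prints

```
N = 256, N_p = 27, CR = 9.5, E* = 0.0221
N = 262144, N_p = 69154, CR = 3.8
PSNR noisy input   vs truth = 36.20 dB
PSNR reconstruction vs truth = 37.78 dB
```

The 1D Gaussian needs 27 particles instead of 256 pixels while keeping the
observed relative error (0.022) well inside the requested bound E = 0.1.
On the noisy 3D scene the APR uses 3.8× fewer samples than pixels *and* is
1.6 dB closer to the ground truth than the input — coarse cells average
away noise in smooth regions (the representation's inherent denoising).

There is also a CLI:

```sh
aprep synth --objects 6 --shape 64,64,64 --seed 42 gt.tif noisy.tif
aprep convert --E 0.1 --lambda 3 noisy.tif img.h5
aprep stats img.h5
aprep reconstruct --mode constant img.h5 rec.tif
aprep project --axis 0 img.h5 mip.tif
aprep selftest
```

APR files are HDF5 (one group per level, run-length encoded cell
coordinates, flat intensity dataset; optional deflate compression) and
round-trip bit-exactly.

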