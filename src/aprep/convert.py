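"""End-to-end conversion of a pixel image to its APR.

The procedure: (1) estimate the intensity-gradient magnitude with a
smoothing cubic B-spline, (2) estimate the Local Intensity Scale, (3) form
the Local Resolution Estimate ``L = E sigma / |grad I|``, (4) quantise it
into the Local Particle Cell set, (5) run the Pulling Scheme to obtain the
Optimal Valid Particle Cell set, (6) place one particle per cell and sample
intensities from the image.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .cells import APRDomain, build_lpc_set
from .pipeline import (
    PipelineParams,
    compute_gradient_magnitude,
    compute_local_intensity_scale,
    compute_local_resolution_estimate,
)
from .pulling import classify_cell_types, pulling_scheme, reduce_lpc
from .sampling import APR, sample_intensities, uniform_cell_set

__all__ = ["build_apr", "apr_from_fields", "lossless_apr", "pipeline_fields"]


def pipeline_fields(image: np.ndarray, params: PipelineParams):
    """The three pixel-resolution fields: gradient magnitude, intensity
    scale, resolution estimate."""
    img = np.asarray(image, dtype=float)
    domain = APRDomain(img.shape)
    grad = compute_gradient_magnitude(img, params.lambda_smoothing)
    if params.constant_scale is not None:
        sigma = np.full(img.shape, float(params.constant_scale))
    else:
        sigma_min = params.sigma_min
        if sigma_min is None:
            dynamic = float(img.max() - img.min())
            sigma_min = 0.05 * dynamic if dynamic > 0 else 1.0
        sigma = compute_local_intensity_scale(img, params.scale_window, sigma_min)
    L = compute_local_resolution_estimate(grad, sigma, params.E, domain.omega)
    return grad, sigma, L


def apr_from_fields(
    image: np.ndarray,
    gradient: np.ndarray,
    sigma: np.ndarray,
    params: PipelineParams,
    use_equivalence_optimization: bool = True,
) -> APR:
    """Build an APR from precomputed gradient/scale fields.

    The two fields do not depend on ``E``, so sweeps over the error bound
    can reuse them and only redo the resolution estimate onward.
    """
    img = np.asarray(image, dtype=float)
    domain = APRDomain(img.shape)
    L = compute_local_resolution_estimate(gradient, sigma, params.E, domain.omega)
    lpc = build_lpc_set(L, domain)
    V = pulling_scheme(lpc, domain, use_equivalence_optimization)
    V = classify_cell_types(V, reduce_lpc(lpc), domain)
    particles = sample_intensities(img, V, domain)
    return APR(domain=domain, cells=V, particles=particles, params=params)


def build_apr(
    image: np.ndarray,
    params: Optional[PipelineParams] = None,
    use_equivalence_optimization: bool = True,
) -> APR:
    """Transform a pixel image into its Adaptive Particle Representation."""
    params = params or PipelineParams()
    img = np.asarray(image, dtype=float)
    grad, sigma, _ = pipeline_fields(img, params)
    return apr_from_fields(img, grad, sigma, params, use_equivalence_optimization)


def lossless_apr(image: np.ndarray) -> APR:
    """APR with one particle per pixel; reconstructs the input exactly."""
    img = np.asarray(image, dtype=float)
    domain = APRDomain(img.shape)
    V = uniform_cell_set(domain)
    particles = sample_intensities(img, V, domain)
    return APR(domain=domain, cells=V, particles=particles, params=None)
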