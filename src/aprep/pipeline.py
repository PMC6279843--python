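"""Pixel-resolution fields feeding the Pulling Scheme.

Three fields are computed from the input image at full pixel resolution:

* the gradient magnitude ``|grad I|``, estimated from a smoothing cubic
  B-spline fit of the image (robust against shot noise),
* the Local Intensity Scale ``sigma(y)``, a smooth estimate of the local
  dynamic range that makes the error bound relative rather than absolute
  (the analogue of gain control in the visual system),
* the Local Resolution Estimate ``L(y) = E * sigma(y) / |grad I(y)|``, the
  largest locally admissible sampling radius.

Smoothing B-spline fit
----------------------
Along each axis the spline coefficients ``c`` minimise

    || B c - I ||^2  +  lambda * || D2 c ||^2

where ``B`` is the cubic B-spline sampling operator (taps ``[1, 4, 1]/6``)
and ``D2`` the second difference of the coefficient sequence (the discrete
curvature of the spline), both taken under mirror (whole-sample reflect)
extension at the borders.  The normal equations ``(B'B + lambda D2'D2) c =
B'I`` are symmetric positive definite by construction; one Cholesky
factorisation per (line length, lambda) is cached and reused across all
image lines.  ``lambda = 0`` reduces to the interpolating cubic spline.
The derivative of the spline at the grid points is the centred difference
of the coefficients, ``s'(j) = (c[j+1] - c[j-1]) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "PipelineParams",
    "compute_gradient_magnitude",
    "compute_local_intensity_scale",
    "compute_local_resolution_estimate",
]

# Cubic B-spline sampling taps, coefficient second difference, derivative taps.
_B3 = np.array([1.0, 4.0, 1.0]) / 6.0
_D2 = np.array([1.0, -2.0, 1.0])
_DERIV = np.array([-0.5, 0.0, 0.5])


@dataclass
class PipelineParams:
    """User parameters of the APR pipeline.

    E
        Relative error bound in (0, 1]; the guaranteed bound on
        ``|I - Ihat| / sigma``.
    lambda_smoothing
        Curvature penalty of the B-spline gradient fit, in squared intensity
        units per pixel^3.  0 interpolates; raise for noisier images.
    scale_window
        Window (in downsampled pixels) of the local dynamic-range estimate;
        roughly the PSF half width at half maximum.
    sigma_min
        Floor of the Local Intensity Scale, preventing adaptation to
        background noise.  ``None`` defaults to 5% of the image dynamic
        range at run time.
    constant_scale
        If set, overrides sigma with this constant everywhere (e.g. 1 for
        the didactic 1D example).
    """

    E: float = 0.1
    lambda_smoothing: float = 3.0
    scale_window: int = 2
    sigma_min: Optional[float] = None
    constant_scale: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.E <= 1:
            raise ValueError(f"E must be in (0, 1], got {self.E}")
        if self.lambda_smoothing < 0:
            raise ValueError("lambda_smoothing must be >= 0")
        if self.scale_window < 1:
            raise ValueError("scale_window must be >= 1")
        if self.sigma_min is not None and not self.sigma_min > 0:
            raise ValueError("sigma_min must be positive")


def _mirror_fold_operator(kernel: np.ndarray, n: int) -> np.ndarray:
    """Dense matrix of a convolution under whole-sample mirror extension,
    out-of-range taps folded back across the borders."""
    half = len(kernel) // 2
    dense = np.zeros((n, n))
    for i in range(n):
        for m in range(-half, half + 1):
            j = i + m
            if j < 0:
                j = -j
            elif j >= n:
                j = 2 * n - 2 - j
            dense[i, j] += kernel[m + half]
    return dense


@lru_cache(maxsize=16)
def _spline_system(n: int, lam: float):
    """Cached Cholesky factor of ``B'B + lambda D2'D2`` and the operator B."""
    B = _mirror_fold_operator(_B3, n)
    M = B.T @ B
    if lam > 0:
        D2 = _mirror_fold_operator(_D2, n)
        M = M + lam * (D2.T @ D2)
    return cho_factor(M, lower=True), B


def _spline_coefficients_1d(data: np.ndarray, lam: float, axis: int) -> np.ndarray:
    """Smoothing-spline coefficient prefilter along one axis (mirror BC)."""
    n = data.shape[axis]
    factor, B = _spline_system(n, float(lam))
    moved = np.moveaxis(data, axis, 0).reshape(n, -1)
    coef = cho_solve(factor, B.T @ moved)
    out_shape = (n,) + data.shape[:axis] + data.shape[axis + 1 :]
    return np.moveaxis(coef.reshape(out_shape), 0, axis)


def compute_gradient_magnitude(image: np.ndarray, lambda_smoothing: float) -> np.ndarray:
    """Euclidean norm of the partial derivatives of the smoothing-spline fit.

    The coefficient prefilter is applied separably along every axis (a
    tensor-product spline); each partial derivative is then the coefficient
    centred difference along its axis combined with B-spline evaluation taps
    along the others.  Mirror extension at the borders makes the derivative
    vanish there, avoiding spurious edge gradients.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if lambda_smoothing < 0:
        raise ValueError("lambda_smoothing must be >= 0")
    if any(n < 4 for n in img.shape):
        raise ValueError("cubic spline gradient needs >= 4 samples per axis")
    coef = img
    for axis in range(img.ndim):
        coef = _spline_coefficients_1d(coef, lambda_smoothing, axis)
    sq = np.zeros_like(img)
    for axis in range(img.ndim):
        d = ndimage.correlate1d(coef, _DERIV, axis=axis, mode="mirror")
        for other in range(img.ndim):
            if other != axis:
                d = ndimage.correlate1d(d, _B3, axis=other, mode="mirror")
        sq += d * d
    return np.sqrt(sq)


def _block_mean_downsample_2(image: np.ndarray) -> np.ndarray:
    """Downsample by two per axis with block means (partial edge blocks use
    the pixels they actually contain)."""
    sums = image.astype(float)
    counts = np.ones_like(sums)
    for axis in range(image.ndim):
        def reduce(a: np.ndarray) -> np.ndarray:
            n = a.shape[axis]
            if n % 2:
                pad = [(0, 0)] * a.ndim
                pad[axis] = (0, 1)
                a = np.pad(a, pad, constant_values=0.0)
            shape = list(a.shape)
            shape[axis] //= 2
            shape.insert(axis + 1, 2)
            return a.reshape(shape).sum(axis=axis + 1)
        sums = reduce(sums)
        counts = reduce(counts)
    return sums / counts


def _upsample_2_nearest(coarse: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    out = coarse
    for axis in range(out.ndim):
        out = np.repeat(out, 2, axis=axis)
    return out[tuple(slice(0, n) for n in shape)]


def compute_local_intensity_scale(
    image: np.ndarray, scale_window: int, sigma_min: float
) -> np.ndarray:
    """Smooth estimate of the local dynamic range of the image.

    Computed on the image downsampled by two (which also guarantees the
    required smoothness of the scale): windowed local maximum minus windowed
    local minimum, box-smoothed with the same window, then upsampled back to
    full resolution and clamped below at ``sigma_min``.
    """
    if not sigma_min > 0:
        raise ValueError(f"sigma_min must be positive, got {sigma_min}")
    if scale_window < 1:
        raise ValueError("scale_window must be >= 1")
    img = np.asarray(image, dtype=float)
    down = _block_mean_downsample_2(img)
    w = int(scale_window)
    hi = ndimage.maximum_filter(down, size=w, mode="reflect")
    lo = ndimage.minimum_filter(down, size=w, mode="reflect")
    rng = ndimage.uniform_filter(hi - lo, size=w, mode="reflect")
    sigma = _upsample_2_nearest(rng, img.shape)
    return np.maximum(sigma, sigma_min)


def compute_local_resolution_estimate(
    gradient: np.ndarray, scale: np.ndarray, E: float, omega: int
) -> np.ndarray:
    """Local Resolution Estimate ``L = E * sigma / |grad I|``.

    Where the gradient vanishes no resolution is needed and ``L`` is clamped
    to the domain edge length ``omega``.
    """
    if gradient.shape != scale.shape:
        raise ValueError("gradient and scale shapes differ")
    if not E > 0:
        raise ValueError("E must be positive")
    L = np.full(gradient.shape, float(omega))
    nz = gradient > 0
    L[nz] = E * scale[nz] / gradient[nz]
    return L
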