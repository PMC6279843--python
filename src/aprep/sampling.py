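"""Particle placement and intensity sampling.

One particle is placed at the center of every Optimal Valid Particle Cell,
``y_p = (omega / 2**l) * (i + 0.5)`` per axis, so positions never need to be
stored: they are implied by the cell set.  Particle intensities come from
the pixel image: cells at single-pixel resolution copy their pixel value
verbatim, coarser cells take the arithmetic mean of all image pixels they
contain.  The means are computed by recursive 2**d block reduction of a
sum/count pyramid (one linear pass), which keeps partially-out-of-image
boundary cells exact: they average only the pixels actually present.

Particles follow the canonical order: ascending level, then lexicographic
cell location within each level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .cells import APRDomain, ParticleCellSet
from .errors import InternalInconsistencyError

__all__ = ["ParticleSet", "APR", "place_particles", "sample_intensities", "uniform_cell_set"]


@dataclass
class ParticleSet:
    """Per-particle arrays aligned with the canonical cell order."""

    levels: np.ndarray  # (N_p,) int16
    cell_coords: np.ndarray  # (N_p, d) int64
    positions: np.ndarray  # (N_p, d) float64, pixel units
    intensities: np.ndarray  # (N_p,) float64

    def __len__(self) -> int:
        return len(self.intensities)


@dataclass
class APR:
    """The Adaptive Particle Representation: domain + cell set + particles.

    The cell set tiles the image; particles are bijective with cells.  When
    every cell sits at single-pixel resolution the representation is
    lossless and reconstructs the input exactly.
    """

    domain: APRDomain
    cells: ParticleCellSet
    particles: ParticleSet
    params: Optional[object] = None

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    @property
    def n_pixels(self) -> int:
        return int(np.prod(self.domain.image_shape))


def place_particles(V: ParticleCellSet, domain: APRDomain) -> ParticleSet:
    """Positions (cell centers) for every cell of ``V``, canonical order.

    Intensities are left NaN; :func:`sample_intensities` fills them.
    """
    levels, coords, positions = [], [], []
    for l in V.levels():
        a = V.cells(l)
        side = domain.side(l)
        levels.append(np.full(len(a), l, dtype=np.int16))
        coords.append(a)
        positions.append((a + 0.5) * side)
    if levels:
        lev = np.concatenate(levels)
        crd = np.concatenate(coords)
        pos = np.concatenate(positions)
    else:
        lev = np.empty(0, dtype=np.int16)
        crd = np.empty((0, domain.ndim), dtype=np.int64)
        pos = np.empty((0, domain.ndim))
    return ParticleSet(lev, crd, pos, np.full(len(lev), np.nan))


def _sum_count_pyramids(
    image: np.ndarray, domain: APRDomain
) -> Tuple[Dict[int, np.ndarray], Dict[int, np.ndarray]]:
    sums = {domain.l_max: np.asarray(image, dtype=np.float64)}
    counts = {domain.l_max: np.ones(image.shape, dtype=np.float64)}
    for l in range(domain.l_max - 1, domain.l_min - 1, -1):
        s, c = sums[l + 1], counts[l + 1]
        for axis in range(image.ndim):
            n = s.shape[axis]
            if n % 2:
                pad = [(0, 0)] * s.ndim
                pad[axis] = (0, 1)
                s = np.pad(s, pad, constant_values=0.0)
                c = np.pad(c, pad, constant_values=0.0)
            shape = list(s.shape)
            shape[axis] //= 2
            shape.insert(axis + 1, 2)
            s = s.reshape(shape).sum(axis=axis + 1)
            c = c.reshape(shape).sum(axis=axis + 1)
        sums[l], counts[l] = s, c
    return sums, counts


def sample_intensities(
    image: np.ndarray, V: ParticleCellSet, domain: APRDomain
) -> ParticleSet:
    """Particle intensities for the cells of ``V`` from the pixel image.

    Single-pixel cells copy the pixel value exactly; coarser cells take the
    mean over their interior pixels (pyramid block reduction).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.shape != domain.image_shape:
        raise ValueError(f"image shape {img.shape} != domain {domain.image_shape}")
    ps = place_particles(V, domain)
    needs_pyramid = any(l < domain.l_max for l in V.levels())
    if needs_pyramid:
        sums, counts = _sum_count_pyramids(img, domain)
    out = ps.intensities
    for l in V.levels():
        sel = ps.levels == l
        a = ps.cell_coords[sel]
        if l == domain.l_max:
            out[sel] = img[tuple(a.T)]
        else:
            c = counts[l][tuple(a.T)]
            if np.any(c == 0):
                raise InternalInconsistencyError(
                    "cell with no interior pixels survived to sampling"
                )
            out[sel] = sums[l][tuple(a.T)] / c
    return ps


def uniform_cell_set(domain: APRDomain, level: Optional[int] = None) -> ParticleCellSet:
    """Tiling with every cell at one level (default: single-pixel cells).

    The ``l_max`` case is the lossless mode: one particle per pixel.
    """
    l = domain.l_max if level is None else int(level)
    if not domain.l_min <= l <= domain.l_max:
        raise ValueError(f"level {l} outside domain levels")
    V = ParticleCellSet(domain.ndim, role="ovpc")
    V.add_cells(l, np.argwhere(np.ones(domain.level_shape(l), dtype=bool)))
    return V
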