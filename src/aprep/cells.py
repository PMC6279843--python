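"""Particle Cells: the powers-of-two spatial decomposition underlying the APR.

A Particle Cell ``c_{i,l}`` is an axis-aligned box at level ``l`` and integer
location ``i`` (one integer per image axis).  The cell has side length
``omega / 2**l`` pixels, where ``omega`` is the image edge length rounded up
to the nearest power of two (the image itself is never padded).  Level
``l_min = 1`` corresponds to cells of half the domain edge; at ``l_max``
cells are single pixels.

This module provides cell arithmetic (locating the cell of a pixel, choosing
the level that realises a requested local resolution), tree relations
(parent / children / face neighbors / descendant index ranges), construction
of the Local Particle Cell (LPC) set from a resolution-estimate field, the
validity predicate used as the correctness oracle for the Pulling Scheme, and
the Implied Resolution Function of a cell tiling.

Conventions: pixel indices are 0-based, cells are half-open boxes, and all
cell arithmetic is integer shift arithmetic so that results are bit-exact.
A cell at level ``l`` is "image-intersecting" iff every component of its
location is below ``ceil(shape / 2**(l_max - l))``; cells entirely outside
the image are never stored and carry no particles.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .errors import NonTilingError

__all__ = [
    "APRDomain",
    "adjacent_neighbors",
    "CellType",
    "ParticleCellSet",
    "level_for_resolution",
    "cell_of",
    "cells_of",
    "build_lpc_set",
    "tree_relations",
    "is_tiling",
    "is_valid_set",
    "has_descendant_in",
    "implied_resolution_at",
    "level_map",
]


class CellType(enum.IntEnum):
    """Structural role of a cell in an OVPC set."""

    NONE = 0
    SEED = 1
    BOUNDARY = 2
    FILLER = 3


@dataclass(frozen=True)
class APRDomain:
    """Geometry of the powers-of-two decomposition for a given image shape.

    ``omega`` is the smallest power of two that is >= the largest image
    dimension; levels run from ``l_min = 1`` (cells of side ``omega/2``) to
    ``l_max = log2(omega)`` (single-pixel cells).
    """

    image_shape: Tuple[int, ...]

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.image_shape)
        if len(shape) not in (1, 2, 3):
            raise ValueError(f"dimension must be 1, 2 or 3, got {len(shape)}")
        if any(n < 1 for n in shape):
            raise ValueError(f"image shape must be positive, got {shape}")
        object.__setattr__(self, "image_shape", shape)

    @property
    def ndim(self) -> int:
        return len(self.image_shape)

    @property
    def omega(self) -> int:
        n = max(max(self.image_shape), 2)
        return 1 << (n - 1).bit_length()

    @property
    def l_min(self) -> int:
        return 1

    @property
    def l_max(self) -> int:
        return self.omega.bit_length() - 1

    def side(self, level: int) -> int:
        """Cell side length (pixels) at ``level``."""
        return self.omega >> level

    def level_shape(self, level: int) -> Tuple[int, ...]:
        """Number of image-intersecting cells per axis at ``level``."""
        s = self.l_max - level
        return tuple(-(-n >> s) if s else n for n in self.image_shape)

    def levels(self) -> range:
        return range(self.l_min, self.l_max + 1)


def _as_coord_array(coords: Sequence[Sequence[int]], ndim: int) -> np.ndarray:
    a = np.atleast_2d(np.asarray(coords, dtype=np.int64))
    if a.size == 0:
        return a.reshape(0, ndim)
    if a.shape[1] != ndim:
        raise ValueError(f"coordinates must have {ndim} components")
    return a


def _canonical(a: np.ndarray) -> np.ndarray:
    """Sort rows lexicographically (C order) and drop duplicates."""
    if len(a) == 0:
        return a
    order = np.lexsort(a.T[::-1])
    a = a[order]
    keep = np.ones(len(a), dtype=bool)
    keep[1:] = np.any(a[1:] != a[:-1], axis=1)
    return a[keep]


class ParticleCellSet:
    """Sparse per-level collection of particle-cell locations.

    Cells are stored per level as lexicographically sorted, duplicate-free
    integer coordinate arrays of shape ``(n, ndim)``.  Concrete roles: the
    Local Particle Cell set built from the resolution-estimate field, and the
    Optimal Valid Particle Cell set returned by the Pulling Scheme.  An
    optional per-level ``types`` array carries the SEED/BOUNDARY/FILLER
    classification.
    """

    def __init__(self, ndim: int, role: str = "generic"):
        self.ndim = int(ndim)
        self.role = role
        self._levels: Dict[int, np.ndarray] = {}
        self.types: Dict[int, np.ndarray] = {}

    def add_cells(self, level: int, coords: Sequence[Sequence[int]]) -> None:
        a = _as_coord_array(coords, self.ndim)
        if len(a) == 0:
            return
        if level in self._levels:
            a = np.concatenate([self._levels[level], a])
        self._levels[level] = _canonical(a)

    def cells(self, level: int) -> np.ndarray:
        return self._levels.get(level, np.empty((0, self.ndim), dtype=np.int64))

    def levels(self) -> List[int]:
        return sorted(l for l, a in self._levels.items() if len(a))

    def contains(self, level: int, coord: Sequence[int]) -> bool:
        a = self.cells(level)
        if len(a) == 0:
            return False
        c = np.asarray(coord, dtype=np.int64)
        idx = _row_searchsorted(a, c[None, :])[0]
        return idx < len(a) and bool(np.all(a[idx] == c))

    def iter_cells(self) -> Iterator[Tuple[int, Tuple[int, ...]]]:
        for l in self.levels():
            for row in self.cells(l):
                yield l, tuple(int(v) for v in row)

    def __len__(self) -> int:
        return sum(len(a) for a in self._levels.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParticleCellSet):
            return NotImplemented
        if self.ndim != other.ndim or self.levels() != other.levels():
            return False
        return all(np.array_equal(self.cells(l), other.cells(l)) for l in self.levels())

    def copy(self) -> "ParticleCellSet":
        out = ParticleCellSet(self.ndim, self.role)
        for l, a in self._levels.items():
            out._levels[l] = a.copy()
        for l, t in self.types.items():
            out.types[l] = t.copy()
        return out

    def __repr__(self) -> str:
        per = {l: len(self.cells(l)) for l in self.levels()}
        return f"ParticleCellSet(ndim={self.ndim}, role={self.role!r}, cells={per})"


def _row_searchsorted(sorted_rows: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Lexicographic searchsorted for integer coordinate rows.

    Rows are packed into scalar keys; coordinates must be non-negative and
    fit 21 bits per axis (ample for any supported domain).
    """
    return np.searchsorted(_pack_rows(sorted_rows), _pack_rows(query))


def _pack_rows(rows: np.ndarray) -> np.ndarray:
    key = np.zeros(len(rows), dtype=np.int64)
    for k in range(rows.shape[1]):
        key = (key << 21) | rows[:, k].astype(np.int64)
    return key


def rows_membership(sorted_rows: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Boolean membership of ``query`` rows in lexicographically sorted rows."""
    if len(sorted_rows) == 0 or len(query) == 0:
        return np.zeros(len(query), dtype=bool)
    keys = _pack_rows(sorted_rows)
    q = _pack_rows(query)
    idx = np.clip(np.searchsorted(keys, q), 0, len(keys) - 1)
    return keys[idx] == q


def level_for_resolution(L_value: float, domain: APRDomain) -> int:
    """Smallest level whose cell side does not exceed the requested resolution.

    Implements ``l = ceil(log2(omega / L))`` clamped to ``[l_min, l_max]``,
    evaluated through exact integer comparisons ``omega >> l <= L`` so that
    values on a power-of-two boundary never drift across it.
    """
    if not L_value > 0:
        raise ValueError(f"resolution value must be positive, got {L_value}")
    for l in range(0, domain.l_max + 1):
        if (domain.omega >> l) <= L_value:
            return max(l, domain.l_min)
    return domain.l_max


def cell_of(pixel_index: Sequence[int], level: int, domain: APRDomain) -> Tuple[int, ...]:
    """Location of the level-``level`` cell containing a pixel: ``i = y >> (l_max - l)``."""
    y = np.asarray(pixel_index, dtype=np.int64).reshape(-1)
    if y.shape[0] != domain.ndim:
        raise ValueError("pixel index has wrong dimension")
    if np.any(y < 0) or np.any(y >= np.asarray(domain.image_shape)):
        raise ValueError(f"pixel index {tuple(y)} outside image {domain.image_shape}")
    if not domain.l_min <= level <= domain.l_max:
        raise ValueError(f"level {level} outside [{domain.l_min}, {domain.l_max}]")
    shift = domain.l_max - level
    return tuple(int(v) for v in (y >> shift))


def cells_of(pixel_indices: np.ndarray, level: int, domain: APRDomain) -> np.ndarray:
    """Vectorised :func:`cell_of` for an ``(n, ndim)`` pixel index array."""
    return np.asarray(pixel_indices, dtype=np.int64) >> (domain.l_max - level)


def build_lpc_set(L_field: np.ndarray, domain: APRDomain) -> ParticleCellSet:
    """Quantise the Local Resolution Estimate into the LPC set.

    Every pixel contributes the cell containing it at the level required by
    its resolution estimate; duplicates collapse.  The per-pixel level is the
    smallest ``l`` with ``omega >> l <= L(y)``, clamped to the domain levels,
    matching :func:`level_for_resolution` exactly.
    """
    L = np.asarray(L_field, dtype=float)
    if L.shape != domain.image_shape:
        raise ValueError(f"field shape {L.shape} != image shape {domain.image_shape}")
    if not np.all(L > 0):
        raise ValueError("resolution estimate must be strictly positive")
    lev = np.full(L.shape, domain.l_max, dtype=np.int16)
    for l in range(domain.l_max - 1, domain.l_min - 1, -1):
        lev[(domain.omega >> l) <= L] = l
    out = ParticleCellSet(domain.ndim, role="lpc")
    for l in range(domain.l_min, domain.l_max + 1):
        mask = lev == l
        if not mask.any():
            continue
        pix = np.argwhere(mask)
        out.add_cells(l, cells_of(pix, l, domain))
    return out


def tree_relations(cell: Tuple[int, Sequence[int]], domain: APRDomain) -> dict:
    """Parent, children, face neighbors and descendant ranges of a cell.

    Children and face neighbors are restricted to image-intersecting cells.
    Descendants are returned as half-open per-axis index ranges for each finer
    level (never enumerated): at level ``lq`` the descendants of location
    ``i`` occupy ``[i << (lq-l), (i+1) << (lq-l))`` per axis.
    """
    level, coord = cell
    if not domain.l_min <= level <= domain.l_max:
        raise ValueError(f"level {level} outside [{domain.l_min}, {domain.l_max}]")
    c = np.asarray(coord, dtype=np.int64)
    shape = np.asarray(domain.level_shape(level), dtype=np.int64)
    if np.any(c < 0) or np.any(c >= shape):
        raise ValueError(f"cell {tuple(c)} not image-intersecting at level {level}")

    parent = None
    if level > domain.l_min:
        parent = (level - 1, tuple(int(v) for v in (c >> 1)))

    children: List[Tuple[int, Tuple[int, ...]]] = []
    if level < domain.l_max:
        child_shape = np.asarray(domain.level_shape(level + 1), dtype=np.int64)
        for offs in np.ndindex(*(2,) * domain.ndim):
            ch = 2 * c + np.asarray(offs)
            if np.all(ch < child_shape):
                children.append((level + 1, tuple(int(v) for v in ch)))

    face_neighbors: List[Tuple[int, Tuple[int, ...]]] = []
    for axis in range(domain.ndim):
        for sign in (-1, 1):
            nb = c.copy()
            nb[axis] += sign
            if 0 <= nb[axis] < shape[axis]:
                face_neighbors.append((level, tuple(int(v) for v in nb)))

    descendants_range = {}
    for lq in range(level + 1, domain.l_max + 1):
        s = lq - level
        descendants_range[lq] = tuple(
            (int(v) << s, (int(v) + 1) << s) for v in c
        )

    return {
        "parent": parent,
        "children": children,
        "face_neighbors": face_neighbors,
        "descendants_range": descendants_range,
    }


def adjacent_neighbors(
    cell: Tuple[int, Sequence[int]], domain: APRDomain
) -> List[Tuple[int, Tuple[int, ...]]]:
    """All same-level cells sharing any boundary point with ``cell`` (up to
    ``3**d - 1``), restricted to the image-intersecting grid.

    This is the neighborhood of the validity predicate: the resolution-bound
    neighborhood around a pixel is isotropic, so diagonal cells constrain the
    admissible resolution just as face-adjacent ones do.
    """
    level, coord = cell
    c = np.asarray(coord, dtype=np.int64)
    shape = np.asarray(domain.level_shape(level), dtype=np.int64)
    out: List[Tuple[int, Tuple[int, ...]]] = []
    for offs in np.ndindex(*(3,) * domain.ndim):
        d = np.asarray(offs) - 1
        if not d.any():
            continue
        nb = c + d
        if np.all(nb >= 0) and np.all(nb < shape):
            out.append((level, tuple(int(v) for v in nb)))
    return out


def has_descendant_in(
    cells: ParticleCellSet, level: int, coord: Sequence[int], domain: APRDomain
) -> bool:
    """True iff any cell of ``cells`` at a finer level lies inside ``(level, coord)``.

    The test is a per-level interval query: a cell at level ``lq > level`` is
    a descendant iff shifting its location right by ``lq - level`` recovers
    ``coord``.
    """
    c = np.asarray(coord, dtype=np.int64)
    for lq in cells.levels():
        if lq <= level:
            continue
        a = cells.cells(lq)
        if len(a) and bool(np.any(np.all((a >> (lq - level)) == c, axis=1))):
            return True
    return False


def _paint_counts(V: ParticleCellSet, domain: APRDomain) -> np.ndarray:
    """Per-pixel count of covering cells (1 everywhere iff V tiles the image)."""
    counts = np.zeros(domain.image_shape, dtype=np.int32)
    for l in V.levels():
        shape_l = domain.level_shape(l)
        a = V.cells(l)
        if np.any(a < 0) or np.any(a >= np.asarray(shape_l)):
            raise ValueError(f"cell outside image-intersecting grid at level {l}")
        grid = np.zeros(shape_l, dtype=np.int32)
        grid[tuple(a.T)] = 1
        s = domain.l_max - l
        for axis in range(domain.ndim):
            grid = np.repeat(grid, 1 << s, axis=axis)
        counts += grid[tuple(slice(0, n) for n in domain.image_shape)]
    return counts


def is_tiling(V: ParticleCellSet, domain: APRDomain) -> bool:
    """True iff ``V`` covers every image pixel exactly once."""
    try:
        return bool(np.all(_paint_counts(V, domain) == 1))
    except ValueError:
        return False


def is_valid_set(V: ParticleCellSet, L: ParticleCellSet, domain: APRDomain) -> bool:
    """Validity oracle: no cell of ``V`` may have a descendant of itself or of
    any of its neighbors (all adjacent same-level cells) in the LPC set ``L``.

    ``V`` must tile the image (a :class:`NonTilingError` is raised otherwise,
    distinct from returning ``False`` for an invalid tiling).
    """
    if not is_tiling(V, domain):
        raise NonTilingError("V does not tile the image domain")
    for level, coord in V.iter_cells():
        probes = [(level, coord)] + adjacent_neighbors((level, coord), domain)
        for _, pc in probes:
            if has_descendant_in(L, level, pc, domain):
                return False
    return True


def implied_resolution_at(
    V: ParticleCellSet, y: Sequence[int], domain: APRDomain
) -> float:
    """Side length of the unique cell of the tiling ``V`` containing pixel ``y``.

    This is the Implied Resolution Function evaluated at ``y``: the piecewise
    constant resolution defined by the upper edges of the chosen cells.
    """
    yv = np.asarray(y, dtype=np.int64).reshape(-1)
    if np.any(yv < 0) or np.any(yv >= np.asarray(domain.image_shape)):
        raise ValueError(f"position {tuple(yv)} outside image {domain.image_shape}")
    for l in V.levels():
        coord = tuple(int(v) for v in (yv >> (domain.l_max - l)))
        if V.contains(l, coord):
            return float(domain.side(l))
    raise NonTilingError(f"no cell of V contains pixel {tuple(yv)}")


def level_map(V: ParticleCellSet, domain: APRDomain) -> np.ndarray:
    """Dense per-pixel map of the covering cell's level (requires a tiling)."""
    out = np.zeros(domain.image_shape, dtype=np.int16)
    for l in V.levels():
        shape_l = domain.level_shape(l)
        grid = np.zeros(shape_l, dtype=np.int16)
        a = V.cells(l)
        grid[tuple(a.T)] = l
        s = domain.l_max - l
        for axis in range(domain.ndim):
            grid = np.repeat(grid, 1 << s, axis=axis)
        grid = grid[tuple(slice(0, n) for n in domain.image_shape)]
        np.maximum(out, grid, out=out)
    if np.any(out == 0):
        raise NonTilingError("V does not cover the image")
    return out
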