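"""The Pulling Scheme: from Local Particle Cells to the Optimal Valid set.

Given the LPC set (the cell-quantised resolution-estimate field), the
Optimal Valid Particle Cell (OVPC) set is the unique coarsest tiling of the
image such that no cell has a descendant of itself or of any of its
adjacent cells in the LPC set.  A single LPC cell "pulls" the resolution down around it,
forcing progressively finer cells.

The implementation here runs on a dense image pyramid, one status array per
level, in a single fine-to-coarse pass followed by a coarse-to-fine emission
pass:

1.  Fine-to-coarse, compute per level the mask ``D_l`` of cells that have a
    strict descendant in the LPC set (an OR-reduction of the level below).
2.  Per level, dilate ``D_l`` by one cell in every direction (the validity
    neighborhood is isotropic, so diagonal adjacency counts) to obtain the
    mask ``F_l`` of cells that cannot be members of a valid tiling at that
    level.
3.  Coarse-to-fine, emit every still-active cell with ``F_l`` clear as an
    OVPC member and activate the children of the rest.

Every pass is a constant number of whole-array operations per level, so the
total work is linear in the pyramid size.  With the equivalence optimization
enabled, no dense array is ever allocated at the single-pixel level
``l_max``: its contribution to the reduction is scattered directly from the
LPC coordinate lists and the finest cells are emitted from the coordinates
of their split parents, shrinking the bookkeeping grid by a factor of
``2**d`` while returning the identical set.

A greedy top-down :func:`brute_force_ovpc` oracle (guarded to small domains)
serves as the independent correctness check.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

from .cells import (
    APRDomain,
    CellType,
    ParticleCellSet,
    adjacent_neighbors,
    has_descendant_in,
    rows_membership,
    tree_relations,
)
from .errors import ResourceGuardError

__all__ = [
    "reduce_lpc",
    "pulling_scheme",
    "brute_force_ovpc",
    "classify_cell_types",
    "random_lpc_set",
]

#: total-cell guard for the brute-force oracle
_BRUTE_FORCE_MAX_CELLS = 200_000


def reduce_lpc(L: ParticleCellSet) -> ParticleCellSet:
    """Drop every LPC cell that has a descendant in the LPC set.

    Descendants impose equal or tighter resolution constraints than their
    ancestors, so removing such redundant cells leaves the OVPC set
    unchanged.
    """
    out = ParticleCellSet(L.ndim, role="lpc")
    levels = L.levels()
    for idx, l in enumerate(levels):
        a = L.cells(l)
        keep = np.ones(len(a), dtype=bool)
        for lq in levels[idx + 1 :]:
            b = L.cells(lq) >> (lq - l)
            keep &= ~rows_membership(np.unique(b, axis=0), a)
        if keep.any():
            out.add_cells(l, a[keep])
    return out


def _scatter(coords: np.ndarray, shape) -> np.ndarray:
    grid = np.zeros(shape, dtype=bool)
    if len(coords):
        grid[tuple(coords.T)] = True
    return grid


def _or_reduce_children(fine: np.ndarray, coarse_shape) -> np.ndarray:
    """OR-reduce 2**d sibling blocks of ``fine`` onto the coarser grid."""
    a = fine
    for axis in range(a.ndim):
        n = a.shape[axis]
        if n % 2:
            pad = [(0, 0)] * a.ndim
            pad[axis] = (0, 1)
            a = np.pad(a, pad, constant_values=False)
        shape = list(a.shape)
        shape[axis] //= 2
        shape.insert(axis + 1, 2)
        a = a.reshape(shape).any(axis=axis + 1)
    assert a.shape == tuple(coarse_shape)
    return a


def _box_dilate(mask: np.ndarray) -> np.ndarray:
    """Dilate by one cell in every direction, diagonals included; the
    validity neighborhood is isotropic."""
    struct = np.ones((3,) * mask.ndim, dtype=bool)
    return ndimage.binary_dilation(mask, structure=struct)


def _expand_to_children(mask: np.ndarray, child_shape) -> np.ndarray:
    out = mask
    for axis in range(out.ndim):
        out = np.repeat(out, 2, axis=axis)
    return out[tuple(slice(0, n) for n in child_shape)]


def pulling_scheme(
    L: ParticleCellSet,
    domain: APRDomain,
    use_equivalence_optimization: bool = False,
) -> ParticleCellSet:
    """Compute the OVPC set from an LPC set in one level sweep.

    Returns the unique tiling that is valid (no member has a descendant of
    itself or of an adjacent cell in ``L``) and optimal (merging any sibling
    group into its parent breaks validity).  ``use_equivalence_optimization``
    runs the bookkeeping on a ``2**d``-coarser grid and must return the
    identical set.
    """
    if np.prod(domain.image_shape) == 0:
        raise ValueError("empty image domain")
    l_min, l_max = domain.l_min, domain.l_max
    for l in L.levels():
        if not l_min <= l <= l_max:
            raise ValueError(f"LPC level {l} outside domain levels")

    # Fine-to-coarse: D_l = "has a strict descendant in L".
    D: dict[int, np.ndarray] = {}
    below: Optional[np.ndarray] = None  # M_{l+1} | D_{l+1}
    for l in range(l_max - 1, l_min - 1, -1):
        shape_l = domain.level_shape(l)
        if l == l_max - 1:
            if use_equivalence_optimization:
                # Scatter parents of finest LPC cells directly; no dense
                # array at l_max is ever built.
                D[l] = _scatter(L.cells(l_max) >> 1, shape_l)
            else:
                fine = _scatter(L.cells(l_max), domain.level_shape(l_max))
                D[l] = _or_reduce_children(fine, shape_l)
        else:
            D[l] = _or_reduce_children(below, shape_l)
        below = D[l] | _scatter(L.cells(l), domain.level_shape(l))

    V = ParticleCellSet(domain.ndim, role="ovpc")
    active = np.ones(domain.level_shape(l_min), dtype=bool)
    for l in range(l_min, l_max + 1):
        if l < l_max:
            forbidden = _box_dilate(D[l])
            tiles = active & ~forbidden
            split = active & forbidden
        else:
            tiles = active
            split = None
        if tiles.any():
            V.add_cells(l, np.argwhere(tiles))
        if l == l_max:
            break
        child_shape = domain.level_shape(l + 1)
        if l == l_max - 1 and use_equivalence_optimization:
            # Emit finest cells straight from split-parent coordinates.
            parents = np.argwhere(split)
            if len(parents):
                kids = []
                for offs in np.ndindex(*(2,) * domain.ndim):
                    ch = 2 * parents + np.asarray(offs)
                    inside = np.all(ch < np.asarray(child_shape), axis=1)
                    kids.append(ch[inside])
                V.add_cells(l_max, np.concatenate(kids))
            break
        active = _expand_to_children(split, child_shape)
    return V


def brute_force_ovpc(L: ParticleCellSet, domain: APRDomain) -> ParticleCellSet:
    """Greedy top-down refinement oracle for the OVPC set.

    Starts from the coarsest tiling and recursively splits every cell whose
    own or neighbors' descendants intersect ``L``, using the validity
    predicate directly.  Exponential-size safe only on small domains; refuses
    larger ones.
    """
    total = sum(
        int(np.prod(domain.level_shape(l))) for l in range(domain.l_min, domain.l_max + 1)
    )
    if total > _BRUTE_FORCE_MAX_CELLS:
        raise ResourceGuardError(
            f"domain too large for brute-force oracle ({total} cells)"
        )
    V = ParticleCellSet(domain.ndim, role="ovpc")
    frontier = [
        (domain.l_min, tuple(c)) for c in np.ndindex(*domain.level_shape(domain.l_min))
    ]
    while frontier:
        level, coord = frontier.pop()
        probes = [(level, coord)] + adjacent_neighbors((level, coord), domain)
        invalid = any(
            has_descendant_in(L, level, pc, domain) for _, pc in probes
        )
        if invalid and level < domain.l_max:
            frontier.extend(tree_relations((level, coord), domain)["children"])
        else:
            V.add_cells(level, [coord])
    return V


def classify_cell_types(
    V: ParticleCellSet, L_reduced: ParticleCellSet, domain: APRDomain
) -> ParticleCellSet:
    """Label OVPC cells by the image structure they encode.

    SEED cells are members of the reduced LPC set (they carry the local
    resolution constraint), BOUNDARY cells have a same-level SEED face
    neighbor, and the remaining space-filling cells are FILLER.  Returns a
    copy of ``V`` with per-level ``types`` arrays set.
    """
    out = V.copy()
    seeds: dict[int, np.ndarray] = {}
    for l in out.levels():
        a = out.cells(l)
        seed_mask = rows_membership(L_reduced.cells(l), a)
        seeds[l] = seed_mask
    for l in out.levels():
        a = out.cells(l)
        types = np.full(len(a), int(CellType.FILLER), dtype=np.uint8)
        types[seeds[l]] = int(CellType.SEED)
        seed_cells = a[seeds[l]]
        if len(seed_cells):
            shape_l = np.asarray(domain.level_shape(l))
            near_seed = np.zeros(len(a), dtype=bool)
            for axis in range(out.ndim):
                for sign in (-1, 1):
                    nb = a.copy()
                    nb[:, axis] += sign
                    ok = (nb[:, axis] >= 0) & (nb[:, axis] < shape_l[axis])
                    hit = np.zeros(len(a), dtype=bool)
                    hit[ok] = rows_membership(seed_cells, nb[ok])
                    near_seed |= hit
            types[near_seed & ~seeds[l]] = int(CellType.BOUNDARY)
        out.types[l] = types
    return out


def random_lpc_set(
    domain: APRDomain, n_cells: int, rng: np.random.Generator
) -> ParticleCellSet:
    """Sample an LPC set of ``n_cells`` cells uniform over levels and locations."""
    L = ParticleCellSet(domain.ndim, role="lpc")
    for _ in range(int(n_cells)):
        l = int(rng.integers(domain.l_min, domain.l_max + 1))
        shape_l = domain.level_shape(l)
        coord = [int(rng.integers(0, n)) for n in shape_l]
        L.add_cells(l, [coord])
    return L
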