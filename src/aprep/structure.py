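"""Sparse random-access data structure over the APR and its particle graph.

Particles are indexed contiguously ``0 .. N_p - 1`` in canonical order
(ascending level, lexicographic cell location within each level, last axis
fastest).  Per level only sorted coordinate arrays are kept; random access
is binary search on packed coordinate keys, and the on-disk layout encodes
just the fastest-varying coordinate explicitly as run-length intervals (see
:mod:`aprep.io`).

The particle graph links particles whose cells share a face in the tiling.
A coarse face can abut up to ``2**(d-1)`` finer cells, and neighbor levels
differ by at most one in any Pulling-Scheme tiling, so the adjacency is
assembled from two vectorised probes per level/axis/direction: same-level
cells, and the parent of the would-be same-level neighbor (every
coarse-fine edge is discovered from its fine side).  Edges carry the axis
and direction, which the adaptive gradient filter needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .cells import APRDomain, ParticleCellSet, _pack_rows
from .sampling import APR

__all__ = ["SparseAPR", "build_sparse_structure", "find_graph_neighbors"]


@dataclass
class _LevelBlock:
    coords: np.ndarray  # (n, d) sorted lexicographically
    keys: np.ndarray  # packed scalar keys, sorted
    offset: int  # global index of first particle at this level


@dataclass
class Edges:
    """Directed particle-graph edges with face metadata."""

    src: np.ndarray
    dst: np.ndarray
    axis: np.ndarray
    sign: np.ndarray  # direction from src to dst along axis (+1 / -1)


class SparseAPR:
    """Random-access view of an APR's cells and particles."""

    def __init__(self, apr: APR):
        self.apr = apr
        self.domain = apr.domain
        self._levels: Dict[int, _LevelBlock] = {}
        offset = 0
        for l in apr.cells.levels():
            coords = apr.cells.cells(l)
            self._levels[l] = _LevelBlock(coords, _pack_rows(coords), offset)
            offset += len(coords)
        self.n_particles = offset
        self._edges: Optional[Edges] = None
        self._csr: Optional[Tuple[np.ndarray, np.ndarray]] = None

    def __len__(self) -> int:
        return self.n_particles

    def levels(self) -> List[int]:
        return sorted(self._levels)

    def level_of(self, particle_index: int) -> int:
        self._check_index(particle_index)
        for l, blk in self._levels.items():
            if blk.offset <= particle_index < blk.offset + len(blk.coords):
                return l
        raise AssertionError("unreachable")

    def cell_of_particle(self, particle_index: int) -> Tuple[int, Tuple[int, ...]]:
        l = self.level_of(particle_index)
        blk = self._levels[l]
        row = blk.coords[particle_index - blk.offset]
        return l, tuple(int(v) for v in row)

    def particle_index(self, level: int, coord) -> int:
        """Random access: global index of the particle in cell ``(level, coord)``."""
        blk = self._levels.get(level)
        if blk is None:
            raise KeyError(f"no cells at level {level}")
        key = _pack_rows(np.asarray(coord, dtype=np.int64)[None, :])[0]
        i = int(np.searchsorted(blk.keys, key))
        if i >= len(blk.keys) or blk.keys[i] != key:
            raise KeyError(f"cell {tuple(coord)} not present at level {level}")
        return blk.offset + i

    def _check_index(self, k: int) -> None:
        if not 0 <= k < self.n_particles:
            raise ValueError(f"particle index {k} out of range [0, {self.n_particles})")

    # -- particle graph ----------------------------------------------------

    def _match(
        self, level: int, cand: np.ndarray, src_idx: np.ndarray
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Match candidate coords into a level's sorted keys; return pairs."""
        blk = self._levels.get(level)
        if blk is None or len(cand) == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        keys = _pack_rows(cand)
        pos = np.searchsorted(blk.keys, keys)
        pos_c = np.clip(pos, 0, len(blk.keys) - 1)
        hit = blk.keys[pos_c] == keys
        return src_idx[hit], blk.offset + pos_c[hit]

    def edges(self) -> Edges:
        """Directed face-adjacency edges (both orientations of every link)."""
        if self._edges is not None:
            return self._edges
        d = self.domain.ndim
        srcs, dsts, axes, signs = [], [], [], []

        def add(s, t, a, g):
            srcs.append(s)
            dsts.append(t)
            axes.append(np.full(len(s), a, dtype=np.int8))
            signs.append(np.full(len(s), g, dtype=np.int8))

        for l in self.levels():
            blk = self._levels[l]
            coords = blk.coords
            idx = blk.offset + np.arange(len(coords))
            shape_l = np.asarray(self.domain.level_shape(l))
            for a in range(d):
                # same level, + direction only (symmetry adds the reverse)
                cand = coords.copy()
                cand[:, a] += 1
                ok = cand[:, a] < shape_l[a]
                s, t = self._match(l, cand[ok], idx[ok])
                add(s, t, a, +1)
                add(t, s, a, -1)
                # coarser neighbor, probed from the fine side, both directions
                if l - 1 in self._levels:
                    for g in (+1, -1):
                        cand = coords.copy()
                        cand[:, a] += g
                        ok = (cand[:, a] >= 0) & (cand[:, a] < shape_l[a])
                        s, t = self._match(l - 1, cand[ok] >> 1, idx[ok])
                        add(s, t, a, g)
                        add(t, s, a, -g)

        if srcs:
            e = Edges(
                np.concatenate(srcs),
                np.concatenate(dsts),
                np.concatenate(axes),
                np.concatenate(signs),
            )
        else:
            z = np.empty(0, np.int64)
            e = Edges(z, z, z.astype(np.int8), z.astype(np.int8))
        self._edges = e
        return e

    def _adjacency(self) -> Tuple[np.ndarray, np.ndarray]:
        """CSR arrays (indptr, neighbor indices) of the undirected graph."""
        if self._csr is None:
            e = self.edges()
            order = np.argsort(e.src, kind="stable")
            dst = e.dst[order]
            counts = np.bincount(e.src, minlength=self.n_particles)
            indptr = np.concatenate([[0], np.cumsum(counts)])
            self._csr = (indptr, dst)
        return self._csr

    def neighbors(self, particle_index: int) -> np.ndarray:
        self._check_index(particle_index)
        indptr, dst = self._adjacency()
        return np.sort(dst[indptr[particle_index] : indptr[particle_index + 1]])


def build_sparse_structure(apr: APR) -> SparseAPR:
    """Build the sparse random-access structure over an APR."""
    return SparseAPR(apr)


def find_graph_neighbors(s: SparseAPR, particle_index: int) -> List[int]:
    """Indices of particles whose cells share a face with the query cell."""
    return [int(v) for v in s.neighbors(particle_index)]
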