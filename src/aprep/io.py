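"""Lossless APR persistence (HDF5) and TIFF pixel-image I/O.

On-disk layout (this package's normative format, version ``aprep-1``): one
HDF5 group per level holding the cell coordinates in run-length form —
``lead`` stores the leading ``d - 1`` coordinates of each run, ``y_begin``
and ``y_count`` the contiguous interval of the fastest-varying coordinate —
plus an optional ``types`` byte per cell, and a single flat ``intensity``
dataset over all particles in canonical order.  Root attributes carry the
domain geometry, pipeline parameters, and the format version.

Compression (``compress=True``) uses the container's built-in deflate
filter with byte shuffling; it changes file size only, never content.
"""

from __future__ import annotations

import os
from typing import Optional

import h5py
import numpy as np

from .cells import APRDomain, ParticleCellSet
from .errors import UnsupportedVersionError
from .pipeline import PipelineParams
from .sampling import APR, sample_intensities, place_particles

__all__ = ["write_apr", "read_apr", "FORMAT_VERSION", "read_tiff", "write_tiff"]

FORMAT_VERSION = "aprep-1"


def _run_length(coords: np.ndarray):
    """Split sorted cell coords into runs of contiguous fastest coordinates."""
    n, d = coords.shape
    if n == 0:
        return (
            np.empty((0, max(d - 1, 0)), np.int64),
            np.empty(0, np.int64),
            np.empty(0, np.int64),
        )
    lead = coords[:, :-1]
    y = coords[:, -1]
    new_run = np.ones(n, dtype=bool)
    if n > 1:
        same_lead = np.all(lead[1:] == lead[:-1], axis=1) if d > 1 else np.ones(n - 1, bool)
        contiguous = y[1:] == y[:-1] + 1
        new_run[1:] = ~(same_lead & contiguous)
    starts = np.flatnonzero(new_run)
    counts = np.diff(np.append(starts, n))
    return lead[starts], y[starts], counts


def _expand_runs(lead: np.ndarray, y_begin: np.ndarray, y_count: np.ndarray, d: int):
    total = int(y_count.sum())
    out = np.empty((total, d), dtype=np.int64)
    pos = 0
    for k in range(len(y_begin)):
        c = int(y_count[k])
        if d > 1:
            out[pos : pos + c, :-1] = lead[k]
        out[pos : pos + c, -1] = y_begin[k] + np.arange(c)
        pos += c
    return out


#: datasets below this byte size are stored contiguously even when
#: compression is requested: chunked-storage overhead would dominate
_COMPRESS_THRESHOLD_BYTES = 4096


def write_apr(apr: APR, path: str, compress: bool = False) -> None:
    """Write an APR to ``path``; the round trip is bit-exact."""

    def kwargs_for(data: np.ndarray) -> dict:
        if compress and data.nbytes >= _COMPRESS_THRESHOLD_BYTES:
            return {"compression": "gzip", "shuffle": True}
        return {}
    p: Optional[PipelineParams] = apr.params if isinstance(apr.params, PipelineParams) else None
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["image_shape"] = np.asarray(apr.domain.image_shape, np.int64)
        f.attrs["omega"] = apr.domain.omega
        f.attrs["l_min"] = apr.domain.l_min
        f.attrs["l_max"] = apr.domain.l_max
        if p is not None:
            f.attrs["E"] = p.E
            f.attrs["lambda_smoothing"] = p.lambda_smoothing
            f.attrs["scale_window"] = p.scale_window
            f.attrs["sigma_min"] = -1.0 if p.sigma_min is None else p.sigma_min
            f.attrs["constant_scale"] = (
                np.nan if p.constant_scale is None else p.constant_scale
            )
        for l in apr.cells.levels():
            g = f.create_group(f"level_{l}")
            lead, y_begin, y_count = _run_length(apr.cells.cells(l))
            g.create_dataset("lead", data=lead, **kwargs_for(lead))
            g.create_dataset("y_begin", data=y_begin, **kwargs_for(y_begin))
            g.create_dataset("y_count", data=y_count, **kwargs_for(y_count))
            if l in apr.cells.types:
                t = apr.cells.types[l]
                g.create_dataset("types", data=t, **kwargs_for(t))
        intens = apr.particles.intensities
        f.create_dataset("intensity", data=intens, **kwargs_for(intens))


def read_apr(path: str) -> APR:
    """Read an APR written by :func:`write_apr`."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise UnsupportedVersionError(
                f"unsupported APR file version {version!r} (expected {FORMAT_VERSION!r})"
            )
        shape = tuple(int(v) for v in f.attrs["image_shape"])
        domain = APRDomain(shape)
        V = ParticleCellSet(domain.ndim, role="ovpc")
        params = None
        if "E" in f.attrs:
            sm = float(f.attrs["sigma_min"])
            cs = float(f.attrs["constant_scale"])
            params = PipelineParams(
                E=float(f.attrs["E"]),
                lambda_smoothing=float(f.attrs["lambda_smoothing"]),
                scale_window=int(f.attrs["scale_window"]),
                sigma_min=None if sm < 0 else sm,
                constant_scale=None if np.isnan(cs) else cs,
            )
        for name in sorted(k for k in f.keys() if k.startswith("level_")):
            l = int(name.split("_")[1])
            g = f[name]
            coords = _expand_runs(
                np.asarray(g["lead"]),
                np.asarray(g["y_begin"]),
                np.asarray(g["y_count"]),
                domain.ndim,
            )
            V.add_cells(l, coords)
            if "types" in g:
                V.types[l] = np.asarray(g["types"])
        intensities = np.asarray(f["intensity"])
    ps = place_particles(V, domain)
    ps.intensities[:] = intensities
    return APR(domain=domain, cells=V, particles=ps, params=params)


def read_tiff(path: str) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path))


def write_tiff(path: str, image: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(image))
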