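"""APR-native operators and their pixel-oracle equivalences."""

import numpy as np
import pytest
from scipy import ndimage

from aprep.cells import APRDomain, ParticleCellSet
from aprep.convert import lossless_apr
from aprep.processing import (
    adaptive_blur,
    adaptive_gradient,
    max_projection,
    neighbor_average,
    separable_filter,
)
from aprep.pulling import pulling_scheme, random_lpc_set
from aprep.reconstruct import reconstruct_constant
from aprep.sampling import APR, sample_intensities
from aprep.structure import build_sparse_structure


def pixel_neighbor_average(img):
    sums = np.zeros_like(img)
    counts = np.zeros_like(img)
    for ax in range(img.ndim):
        for sh in (1, -1):
            rolled = np.roll(img, sh, axis=ax)
            valid = np.ones_like(img, dtype=bool)
            edge = [slice(None)] * img.ndim
            edge[ax] = 0 if sh == 1 else -1
            valid[tuple(edge)] = False
            sums += np.where(valid, rolled, 0.0)
            counts += valid
    return sums / counts


class TestNeighborAverage:
    def test_constant_field_unchanged(self, rng):
        apr = lossless_apr(rng.random((6, 6)))
        s = build_sparse_structure(apr)
        out = neighbor_average(s, np.full(apr.n_particles, 4.0))
        assert np.allclose(out, 4.0)

    def test_uniform_1d_middle_particle(self):
        apr = lossless_apr(np.array([1.0, 2.0, 3.0]))
        s = build_sparse_structure(apr)
        out = neighbor_average(s, apr.particles.intensities)
        assert out[1] == pytest.approx(2.0)

    def test_matches_pixel_oracle_on_uniform_apr(self, rng):
        img = rng.random((7, 9, 11))
        apr = lossless_apr(img)
        s = build_sparse_structure(apr)
        out = neighbor_average(s, apr.particles.intensities)
        rebuilt = np.empty_like(img)
        rebuilt[tuple(apr.particles.cell_coords.T)] = out
        assert np.abs(rebuilt - pixel_neighbor_average(img)).max() <= 1e-9

    def test_misaligned_field_rejected(self, rng):
        s = build_sparse_structure(lossless_apr(rng.random((4, 4))))
        with pytest.raises(ValueError):
            neighbor_average(s, np.zeros(3))


class TestSeparableFilter:
    def test_delta_stencil_is_identity(self, rng):
        apr = lossless_apr(rng.random((8, 8)))
        v = apr.particles.intensities.copy()
        out = separable_filter(apr, v, np.array([0.0, 1.0, 0.0]))
        assert np.allclose(out, v)

    def test_normalized_stencil_preserves_constant(self, rng):
        dom = APRDomain((16, 16))
        V = pulling_scheme(random_lpc_set(dom, 4, rng), dom)
        apr = APR(dom, V, sample_intensities(np.full(dom.image_shape, 2.0), V, dom))
        w = np.array([0.25, 0.5, 0.25])
        out = separable_filter(apr, apr.particles.intensities, w)
        assert np.allclose(out, 2.0)

    def test_gaussian_matches_pixel_convolution_on_uniform_apr(self, rng):
        img = rng.random((10, 12, 14))
        apr = lossless_apr(img)
        x = np.arange(-3, 4, dtype=float)
        w = np.exp(-0.5 * x * x)
        w /= w.sum()
        out = separable_filter(apr, apr.particles.intensities, w)
        oracle = img.copy()
        for ax in range(3):
            oracle = ndimage.correlate1d(oracle, w, axis=ax, mode="mirror")
        rebuilt = np.empty_like(img)
        rebuilt[tuple(apr.particles.cell_coords.T)] = out
        assert np.abs(rebuilt - oracle).max() <= 1e-9

    def test_even_stencil_rejected(self, rng):
        apr = lossless_apr(rng.random((6, 6)))
        with pytest.raises(ValueError):
            separable_filter(apr, apr.particles.intensities, np.array([0.5, 0.5]))


class TestAdaptiveFilters:
    def test_blur_weight_zero_is_identity(self, rng):
        apr = lossless_apr(rng.random((6, 6)))
        s = build_sparse_structure(apr)
        v = apr.particles.intensities
        assert np.array_equal(adaptive_blur(s, v, 0.0), v)

    def test_blur_weight_one_is_neighbor_average(self, rng):
        apr = lossless_apr(rng.random((6, 6)))
        s = build_sparse_structure(apr)
        v = apr.particles.intensities
        assert np.array_equal(adaptive_blur(s, v, 1.0), neighbor_average(s, v))

    def test_blur_constant_field_fixed_point(self, rng):
        dom = APRDomain((16, 16))
        V = pulling_scheme(random_lpc_set(dom, 4, rng), dom)
        apr = APR(dom, V, sample_intensities(np.full(dom.image_shape, 1.5), V, dom))
        s = build_sparse_structure(apr)
        out = adaptive_blur(s, apr.particles.intensities, 0.7)
        assert np.allclose(out, 1.5)

    def test_blur_weight_out_of_range_rejected(self, rng):
        apr = lossless_apr(rng.random((4, 4)))
        s = build_sparse_structure(apr)
        with pytest.raises(ValueError):
            adaptive_blur(s, apr.particles.intensities, 1.5)

    def test_gradient_zero_on_constant_field(self, rng):
        dom = APRDomain((16, 16))
        V = pulling_scheme(random_lpc_set(dom, 4, rng), dom)
        apr = APR(dom, V, sample_intensities(np.full(dom.image_shape, 2.0), V, dom))
        s = build_sparse_structure(apr)
        assert np.allclose(adaptive_gradient(s, apr, apr.particles.intensities), 0.0)

    def test_gradient_exact_on_uniform_ramp(self):
        img = np.outer(np.arange(8, dtype=float) * 1.5, np.ones(8))
        apr = lossless_apr(img)
        s = build_sparse_structure(apr)
        g = adaptive_gradient(s, apr, apr.particles.intensities)
        rebuilt = np.empty(img.shape)
        rebuilt[tuple(apr.particles.cell_coords.T)] = g
        assert np.allclose(rebuilt[1:-1, :], 1.5, atol=1e-9)

    def test_gradient_exact_across_level_interface(self, domain_1d8):
        # cells {0..3 at level 3, 2..3 at level 2}; field linear in position
        L = ParticleCellSet(1)
        L.add_cells(3, [[0]])
        V = pulling_scheme(L, domain_1d8)
        a = 2.0
        img = a * np.arange(8, dtype=float)
        apr = APR(domain_1d8, V, sample_intensities(img, V, domain_1d8))
        s = build_sparse_structure(apr)
        # block means of a linear field are linear in the cell centers
        g = adaptive_gradient(s, apr, apr.particles.intensities)
        assert np.allclose(g, a, atol=1e-9)


class TestMaxProjection:
    def test_constant_apr_constant_projection(self, rng):
        dom = APRDomain((16, 16, 16))
        V = pulling_scheme(random_lpc_set(dom, 3, rng), dom)
        apr = APR(dom, V, sample_intensities(np.full(dom.image_shape, 3.0), V, dom))
        for axis in range(3):
            assert np.allclose(max_projection(apr, axis), 3.0)

    def test_single_bright_particle_square_footprint(self):
        dom = APRDomain((8, 8))
        V = ParticleCellSet(2)
        V.add_cells(2, [[i, j] for i in range(4) for j in range(4)])
        img = np.full(dom.image_shape, 1.0)
        apr = APR(dom, V, sample_intensities(img, V, dom))
        k = 2 * 4 + 1  # cell (2, 1) at level 2, side 2
        apr.particles.intensities[k] = 9.0
        proj = max_projection(apr, 0)
        assert proj.tolist() == [1.0, 1.0, 9.0, 9.0, 1.0, 1.0, 1.0, 1.0]

    def test_matches_reconstruction_mip_on_random_aprs(self, rng):
        for shape in [(16, 16), (12, 16, 8)]:
            dom = APRDomain(shape)
            V = pulling_scheme(random_lpc_set(dom, 6, rng), dom)
            apr = APR(dom, V, sample_intensities(rng.random(shape), V, dom))
            full = reconstruct_constant(apr)
            for axis in range(len(shape)):
                assert np.abs(max_projection(apr, axis) - full.max(axis=axis)).max() == 0.0

    def test_invalid_axis_rejected(self, rng):
        apr = lossless_apr(rng.random((4, 4)))
        with pytest.raises(ValueError):
            max_projection(apr, 2)
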