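"""Pulling Scheme: oracle equivalence, validity, optimality, structure."""

import numpy as np
import pytest

from aprep.cells import (
    APRDomain,
    CellType,
    ParticleCellSet,
    is_valid_set,
    is_tiling,
    level_map,
)
from aprep.errors import ResourceGuardError
from aprep.pulling import (
    brute_force_ovpc,
    classify_cell_types,
    pulling_scheme,
    random_lpc_set,
    reduce_lpc,
)


def lpc_1d(cells):
    L = ParticleCellSet(1, "lpc")
    for l, i in cells:
        L.add_cells(l, [[i]])
    return L


class TestReduceLpc:
    def test_ancestor_of_member_removed(self):
        L = lpc_1d([(1, 0), (3, 0)])
        R = reduce_lpc(L)
        assert R.levels() == [3]
        assert R.cells(3).ravel().tolist() == [0]

    def test_single_level_unchanged(self):
        L = lpc_1d([(2, 0), (2, 3)])
        assert reduce_lpc(L) == L

    def test_empty_stays_empty(self):
        assert len(reduce_lpc(ParticleCellSet(1))) == 0

    def test_reduction_preserves_ovpc(self, domain_1d8, rng):
        for _ in range(20):
            dom = APRDomain((16,))
            L = random_lpc_set(dom, int(rng.integers(1, 8)), rng)
            assert pulling_scheme(L, dom) == pulling_scheme(reduce_lpc(L), dom)


class TestHandDerivedCases:
    def test_empty_lpc_gives_coarsest_tiling(self, domain_1d8):
        V = pulling_scheme(ParticleCellSet(1), domain_1d8)
        assert V.levels() == [1]
        assert V.cells(1).ravel().tolist() == [0, 1]

    def test_single_seed_case(self, domain_1d8):
        V = pulling_scheme(lpc_1d([(3, 0)]), domain_1d8)
        assert V.cells(3).ravel().tolist() == [0, 1, 2, 3]
        assert V.cells(2).ravel().tolist() == [2, 3]
        assert V.levels() == [2, 3]

    def test_two_opposite_seeds_force_finest(self, domain_1d8):
        V = pulling_scheme(lpc_1d([(3, 0), (3, 7)]), domain_1d8)
        assert V.levels() == [3]
        assert len(V.cells(3)) == 8

    def test_separability_min_combination(self, domain_1d8):
        a = pulling_scheme(lpc_1d([(3, 0)]), domain_1d8)
        b = pulling_scheme(lpc_1d([(3, 7)]), domain_1d8)
        ab = pulling_scheme(lpc_1d([(3, 0), (3, 7)]), domain_1d8)
        combined = np.maximum(level_map(a, domain_1d8), level_map(b, domain_1d8))
        assert np.array_equal(level_map(ab, domain_1d8), combined)

    def test_all_finest_lpc_gives_finest_tiling(self, domain_1d8):
        L = ParticleCellSet(1)
        L.add_cells(3, [[k] for k in range(8)])
        V = brute_force_ovpc(L, domain_1d8)
        assert V.levels() == [3] and len(V) == 8


class TestOracleEquivalence:
    @pytest.mark.parametrize("shape,n_trials", [((16,), 40), ((8, 8), 40)])
    def test_random_lpc_sets(self, shape, n_trials, rng):
        dom = APRDomain(shape)
        for _ in range(n_trials):
            L = random_lpc_set(dom, int(rng.integers(0, 7)), rng)
            V = pulling_scheme(L, dom)
            assert V == brute_force_ovpc(L, dom)
            assert is_valid_set(V, L, dom)

    def test_3d_hand_built_cases(self, rng):
        dom = APRDomain((8, 8, 8))
        cases = [
            ParticleCellSet(3),
            lpc := ParticleCellSet(3),
        ]
        lpc.add_cells(3, [[0, 0, 0], [7, 7, 7]])
        mid = ParticleCellSet(3)
        mid.add_cells(2, [[1, 2, 3]])
        cases.append(mid)
        for L in cases:
            V = pulling_scheme(L, dom)
            assert V == brute_force_ovpc(L, dom)
            assert is_valid_set(V, L, dom)

    def test_equivalence_optimization_changes_nothing(self, rng):
        for shape in [(16,), (8, 8), (8, 8, 8), (13,), (6, 9)]:
            dom = APRDomain(shape)
            for _ in range(10):
                L = random_lpc_set(dom, int(rng.integers(0, 6)), rng)
                assert pulling_scheme(L, dom, False) == pulling_scheme(L, dom, True)

    def test_brute_force_refuses_large_domains(self):
        with pytest.raises(ResourceGuardError):
            brute_force_ovpc(ParticleCellSet(3), APRDomain((256, 256, 256)))


def _sibling_groups(V, domain):
    """All complete groups of cells in V sharing one parent."""
    for l in V.levels():
        if l == domain.l_min:
            continue
        cells = V.cells(l)
        parents = {}
        for row in cells:
            parents.setdefault(tuple(row >> 1), []).append(tuple(row))
        child_shape = np.asarray(domain.level_shape(l))
        for par, members in parents.items():
            expected = [
                tuple(2 * np.asarray(par) + np.asarray(o))
                for o in np.ndindex(*(2,) * domain.ndim)
            ]
            expected = [c for c in expected if all(np.asarray(c) < child_shape)]
            if sorted(members) == sorted(expected):
                yield l, par, members


class TestStructuralProperties:
    def test_tiling_validity_optimality(self, rng):
        dom = APRDomain((16, 16))
        for _ in range(10):
            L = random_lpc_set(dom, int(rng.integers(1, 6)), rng)
            V = pulling_scheme(L, dom)
            assert is_tiling(V, dom)
            assert is_valid_set(V, L, dom)
            # optimality: merging any complete sibling group breaks validity
            for l, par, members in _sibling_groups(V, dom):
                merged = V.copy()
                keep = ~np.array(
                    [tuple(r) in set(members) for r in merged.cells(l)]
                )
                merged._levels[l] = merged.cells(l)[keep]
                merged.add_cells(l - 1, [list(par)])
                assert not is_valid_set(merged, L, dom)

    def test_neighbor_levels_differ_by_at_most_one(self, rng):
        dom = APRDomain((16, 16))
        for _ in range(10):
            L = random_lpc_set(dom, int(rng.integers(1, 8)), rng)
            lm = level_map(pulling_scheme(L, dom), dom)
            for axis in range(2):
                d = np.abs(np.diff(lm, axis=axis))
                assert d.max(initial=0) <= 1

    def test_refinement_monotonicity(self, rng):
        dom = APRDomain((16,))
        for _ in range(15):
            L = random_lpc_set(dom, int(rng.integers(1, 5)), rng)
            extra = random_lpc_set(dom, 2, rng)
            L2 = L.copy()
            for l in extra.levels():
                L2.add_cells(l, extra.cells(l))
            lm1 = level_map(pulling_scheme(L, dom), dom)
            lm2 = level_map(pulling_scheme(L2, dom), dom)
            assert np.all(lm2 >= lm1)


class TestCellTypes:
    def test_empty_lpc_all_filler(self, domain_1d8):
        V = pulling_scheme(ParticleCellSet(1), domain_1d8)
        typed = classify_cell_types(V, reduce_lpc(ParticleCellSet(1)), domain_1d8)
        assert all(
            t == int(CellType.FILLER) for arr in typed.types.values() for t in arr
        )

    def test_single_seed_classification(self, domain_1d8):
        L = lpc_1d([(3, 0)])
        V = pulling_scheme(L, domain_1d8)
        typed = classify_cell_types(V, reduce_lpc(L), domain_1d8)
        t3 = dict(zip(map(tuple, typed.cells(3)), typed.types[3]))
        assert t3[(0,)] == int(CellType.SEED)
        assert t3[(1,)] == int(CellType.BOUNDARY)
        assert t3[(2,)] == int(CellType.FILLER)
        assert all(t == int(CellType.FILLER) for t in typed.types[2])

    def test_seed_levels_match_lpc(self, rng):
        dom = APRDomain((16, 16))
        L = random_lpc_set(dom, 5, rng)
        R = reduce_lpc(L)
        typed = classify_cell_types(pulling_scheme(L, dom), R, dom)
        for l in typed.levels():
            seeds = typed.cells(l)[typed.types[l] == int(CellType.SEED)]
            for row in seeds:
                assert R.contains(l, tuple(row))
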