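"""Generalized 2D correlation maps and their invariants."""

import numpy as np
import pytest

from leafnir.spectra import SpectrumKind
from leafnir.twod import (
    PerturbationSeries,
    asynchronous,
    hilbert_noda_matrix,
    make_series,
    split_nir_regions,
    synchronous,
    twod_hotspots,
)

from conftest import make_meta, make_set


def series_from(dynamic, levels=None, grid=None, analyte="casein"):
    dynamic = np.asarray(dynamic, dtype=float)
    if levels is None:
        levels = np.arange(dynamic.shape[0], dtype=float)
    if grid is None:
        grid = 4000.0 + 6.0 * np.arange(dynamic.shape[1])
    return PerturbationSeries(
        grid=grid,
        dynamic=dynamic - dynamic.mean(axis=0),
        levels=np.asarray(levels, dtype=float),
        reference=dynamic.mean(axis=0),
        analyte=analyte,
    )


def sync_oracle(a, b):
    """Dense triple-loop synchronous map."""
    m = a.shape[0]
    out = np.zeros((a.shape[1], b.shape[1]))
    for i in range(a.shape[1]):
        for j in range(b.shape[1]):
            for k in range(m):
                out[i, j] += a[k, i] * b[k, j]
    return out / (m - 1)


def async_oracle(a, b):
    """Dense triple-loop asynchronous map via the explicit Noda matrix."""
    m = a.shape[0]
    noda = np.zeros((m, m))
    for j in range(m):
        for k in range(m):
            if j != k:
                noda[j, k] = 1.0 / (np.pi * (k - j))
    out = np.zeros((a.shape[1], b.shape[1]))
    for i in range(a.shape[1]):
        for j in range(b.shape[1]):
            for p in range(m):
                for q in range(m):
                    out[i, j] += a[p, i] * noda[p, q] * b[q, j]
    return out / (m - 1)


class TestMakeSeries:
    def _level_set(self, matrix, concs):
        metas = [
            make_meta(i, level=i + 1, rep=1, cas=c) for i, c in enumerate(concs)
        ]
        return make_set(matrix, metas=metas, kind=SpectrumKind.SECOND_DERIVATIVE)

    def test_dynamic_columns_are_centered(self, rng):
        s = self._level_set(rng.normal(size=(9, 40)), np.linspace(0.2, 1.0, 9))
        ser = make_series(s, "casein")
        assert np.max(np.abs(ser.dynamic.mean(axis=0))) < 1e-12 * max(
            1.0, np.abs(ser.dynamic).max()
        )
        np.testing.assert_allclose(ser.reference, s.matrix.mean(axis=0), rtol=1e-14)

    def test_levels_sorted_by_concentration(self, rng):
        concs = [0.9, 0.1, 0.5]
        s = self._level_set(rng.normal(size=(3, 10)), concs)
        ser = make_series(s, "casein")
        np.testing.assert_array_equal(ser.levels, sorted(concs))

    def test_identical_spectra_give_zero_dynamic(self):
        s = self._level_set(np.ones((2, 10)), [0.1, 0.2])
        assert np.all(make_series(s, "casein").dynamic == 0)

    def test_duplicate_levels_rejected(self, rng):
        metas = [make_meta(0, level=1, rep=1), make_meta(1, level=1, rep=2)]
        s = make_set(rng.normal(size=(2, 5)), metas=metas,
                     kind=SpectrumKind.SECOND_DERIVATIVE)
        with pytest.raises(ValueError, match="duplicate"):
            make_series(s, "casein")


class TestSynchronous:
    def test_two_level_hand_computation(self):
        a = series_from(np.array([[1.0], [-1.0]]))
        b = series_from(np.array([[2.0], [-2.0]]))
        assert synchronous(a, b)[0, 0] == pytest.approx(4.0)

    def test_homo_spectral_diagonal_is_variance(self, rng):
        a = series_from(rng.normal(size=(9, 25)))
        phi = synchronous(a, a)
        np.testing.assert_allclose(phi, phi.T, atol=1e-14)
        np.testing.assert_allclose(
            np.diag(phi), a.dynamic.var(axis=0, ddof=1), rtol=1e-12
        )

    def test_matches_triple_loop_oracle(self, rng):
        a = series_from(rng.normal(size=(9, 12)))
        b = series_from(rng.normal(size=(9, 8)))
        np.testing.assert_allclose(
            synchronous(a, b), sync_oracle(a.dynamic, b.dynamic), atol=1e-12
        )

    def test_homo_spectral_map_is_psd(self, rng):
        a = series_from(rng.normal(size=(9, 30)))
        phi = synchronous(a, a)
        eig = np.linalg.eigvalsh(phi)
        assert eig.min() >= -1e-10 * np.abs(phi).max()

    def test_level_mismatch_rejected(self, rng):
        a = series_from(rng.normal(size=(9, 5)))
        b = series_from(rng.normal(size=(8, 5)))
        with pytest.raises(ValueError, match="mismatch"):
            synchronous(a, b)

    def test_misaligned_level_values_rejected(self, rng):
        a = series_from(rng.normal(size=(4, 5)), levels=[1, 2, 3, 4])
        b = series_from(rng.normal(size=(4, 5)), levels=[1, 2, 3.5, 4])
        with pytest.raises(ValueError, match="level 2"):
            synchronous(a, b)


class TestAsynchronous:
    def test_matches_noda_matrix_oracle(self, rng):
        a = series_from(rng.normal(size=(7, 10)))
        b = series_from(rng.normal(size=(7, 6)))
        np.testing.assert_allclose(
            asynchronous(a, b), async_oracle(a.dynamic, b.dynamic), atol=1e-12
        )

    def test_in_phase_series_has_null_async(self, rng):
        # b proportional to a at every wavenumber: no sequential component
        profile = rng.normal(size=20)
        amp = rng.normal(size=9)
        a = series_from(np.outer(amp, profile))
        b = series_from(np.outer(amp, 3.7 * profile))
        psi = asynchronous(a, b)
        phi = synchronous(a, b)
        assert np.abs(psi).max() <= 1e-12 * np.abs(phi).max()

    def test_homo_spectral_antisymmetry_zero_diagonal(self, rng):
        a = series_from(rng.normal(size=(9, 15)))
        psi = asynchronous(a, a)
        np.testing.assert_allclose(psi, -psi.T, atol=1e-14)
        np.testing.assert_allclose(np.diag(psi), 0.0, atol=1e-14)

    def test_hilbert_noda_matrix_entries(self):
        n = hilbert_noda_matrix(4)
        assert n[0, 0] == 0.0
        assert n[0, 1] == pytest.approx(1.0 / np.pi)
        assert n[2, 0] == pytest.approx(-1.0 / (2.0 * np.pi))


class TestBilinearity:
    def test_swapping_series_transposes_maps(self, rng):
        a = series_from(rng.normal(size=(6, 7)))
        b = series_from(rng.normal(size=(6, 9)))
        np.testing.assert_allclose(synchronous(a, b), synchronous(b, a).T, atol=1e-13)
        np.testing.assert_allclose(
            asynchronous(a, b), -asynchronous(b, a).T, atol=1e-13
        )

    def test_constant_offset_leaves_maps_unchanged(self, rng):
        raw = rng.normal(size=(6, 7))
        b = series_from(rng.normal(size=(6, 9)))
        a1 = series_from(raw)
        a2 = series_from(raw + rng.normal(size=7))  # level-independent spectrum
        np.testing.assert_allclose(
            synchronous(a1, b), synchronous(a2, b), atol=1e-12
        )
        np.testing.assert_allclose(
            asynchronous(a1, b), asynchronous(a2, b), atol=1e-12
        )

    def test_bilinear_scaling(self, rng):
        a = series_from(rng.normal(size=(6, 5)))
        b = series_from(rng.normal(size=(6, 4)))
        a2 = series_from(2.0 * (a.dynamic + a.reference))
        np.testing.assert_allclose(
            synchronous(a2, b), 2.0 * synchronous(a, b), atol=1e-12
        )


class TestRegionSplit:
    def test_five_disjoint_regions_cover_working_range(self):
        grid = np.arange(4000.0, 7500.1, 6.0)
        regions = split_nir_regions(grid)
        assert len(regions) == 5
        covered = np.concatenate([np.arange(s, e + 1) for s, e in regions])
        assert covered.size == np.unique(covered).size  # pairwise disjoint
        np.testing.assert_array_equal(np.sort(covered), np.arange(grid.size))

    def test_boundaries_on_grid_points(self):
        grid = np.arange(4000.0, 7501.0, 1.0)
        regions = split_nir_regions(grid)
        # boundary wavenumbers sit at region edges, assigned to the upper region
        tops = [grid[e] for _, e in regions]
        bottoms = [grid[s] for s, _ in regions]
        assert tops == [7500.0, 6889.0, 5552.0, 5141.0, 4438.0]
        assert bottoms == [6890.0, 5553.0, 5142.0, 4439.0, 4000.0]

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            split_nir_regions(np.array([7500.0, 4000.0, 6000.0]))

    def test_non_covering_grid_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            split_nir_regions(np.arange(5000.0, 6000.0, 6.0))


class TestHotspots:
    def test_single_peak_map_selects_only_that_index(self):
        grid1 = np.arange(4000.0, 7500.1, 6.0)
        grid2 = np.arange(900.0, 3900.0, 4.0)
        sync = np.zeros((grid1.size, grid2.size))
        i_star = int(np.argmin(np.abs(grid1 - 6000.0)))
        j_star = int(np.argmin(np.abs(grid2 - 1650.0)))
        sync[i_star, j_star] = 5.0
        # q below the per-region quantile resolution (~1/223): the zero
        # background cannot reach the threshold interpolated to the peak
        hits = twod_hotspots(sync, grid1, [(1500.0, 1700.0)], grid2, q=0.001)
        assert i_star in hits
        # only the peak exceeds the top quantile in its region
        region = next(
            (s, e) for s, e in split_nir_regions(grid1) if s <= i_star <= e
        )
        in_region = [h for h in hits if region[0] <= h <= region[1]]
        assert in_region == [i_star]

    def test_q_one_selects_every_index(self, rng):
        grid1 = np.arange(4000.0, 7500.1, 6.0)
        grid2 = np.arange(1000.0, 1800.0, 4.0)
        sync = rng.normal(size=(grid1.size, grid2.size))
        hits = twod_hotspots(sync, grid1, [(1500.0, 1700.0)], grid2, q=1.0)
        np.testing.assert_array_equal(hits, np.arange(grid1.size))

    def test_empty_mir_bands_rejected(self, rng):
        grid1 = np.arange(4000.0, 7500.1, 6.0)
        grid2 = np.arange(1000.0, 1800.0, 4.0)
        with pytest.raises(ValueError, match="mir_bands"):
            twod_hotspots(np.zeros((grid1.size, grid2.size)), grid1, [], grid2)

    def test_generator_truth_centers_are_hotspots(self, dry_campaign):
        from leafnir.pipeline import PreprocessConfig, preprocess_mir, preprocess_nir
        from leafnir.simulate import generate_mir_set
        from leafnir.spectra import average_replicates
        from leafnir.twod import correlate, make_series

        nir, truth = dry_campaign
        mir, _ = generate_mir_set(truth.design)
        cfg = PreprocessConfig()
        p, mp = preprocess_nir(nir, cfg), preprocess_mir(mir, cfg)
        tm = correlate(
            make_series(average_replicates(p), "casein"),
            make_series(average_replicates(mp), "casein"),
        )
        hits = twod_hotspots(
            tm.sync, tm.axis1, [(1500.0, 1700.0)], tm.axis2, q=0.25
        )
        centers = truth.center_indices(p.grid, "casein")
        assert np.isin(centers, hits).all()
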