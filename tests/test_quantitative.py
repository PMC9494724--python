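"""Threshold-table fingerprints, match counting, and the 80/20 blind test."""

import numpy as np
import pytest

import ramantissue as rt
from ramantissue.errors import GridMismatchError
from ramantissue.quantitative import ReferenceTable
from ramantissue.spectra_io import SpectrumMeta


def _norm_spectrum(grid, vals, **meta):
    return rt.Spectrum(grid, vals, SpectrumMeta(normalized=True, **meta))


def _random_table(rng, grid):
    # levels 0 (unassigned) .. 9, uniformly at random
    return ReferenceTable(grid, rng.integers(0, 10, size=len(grid)))


class TestThresholdFeatures:
    def test_floor_to_tenth_example(self):
        t = rt.extract_threshold_features(
            _norm_spectrum(np.array([100.0, 101, 102, 103]),
                           np.array([0.05, 0.35, 1.0, 0.55])))
        assert t.assignment == pytest.approx({
            0.3: np.array([101.0]), 0.9: np.array([102.0]), 0.5: np.array([103.0])})
        assert t.size == 3  # 100 cm⁻¹ excluded (below 0.1)

    def test_peak_band_assigned_to_level_09(self):
        # trapezoid peak over 1510–1590 whose top (≥0.9) spans 1542–1560
        grid = np.arange(1500.0, 1601.0)
        vals = np.clip(1.0 - np.abs(grid - 1551.0) / 95.0, 0.0, None)
        top = grid[(grid >= 1542) & (grid <= 1560)]
        t = rt.extract_threshold_features(_norm_spectrum(grid, vals))
        assert set(top) <= set(t.assignment[0.9])

    def test_boundary_belongs_to_lower_level(self):
        grid = np.array([100.0, 101.0, 102.0])
        t = rt.extract_threshold_features(_norm_spectrum(grid, np.array([0.3, 0.6, 1.0])))
        assert t.level_tenths.tolist() == [3, 6, 9]  # 1.0 lands in the 0.9 set

    def test_only_max_when_everything_else_below_01(self):
        grid = np.arange(400.0, 410.0)
        vals = np.full(10, 0.05)
        vals[4] = 1.0
        t = rt.extract_threshold_features(_norm_spectrum(grid, vals))
        assert t.size == 1
        assert t.assignment == pytest.approx({0.9: np.array([404.0])})

    def test_partition_property(self):
        rng = np.random.default_rng(2)
        vals = rng.random(100)
        vals[7] = 1.0
        t = rt.extract_threshold_features(_norm_spectrum(400.0 + np.arange(100.0), vals))
        assert t.size == int(np.count_nonzero(vals >= 0.1))
        sizes = sum(len(v) for v in t.assignment.values())
        assert sizes == t.size

    def test_requires_normalised_spectrum(self):
        with pytest.raises(ValueError):
            rt.extract_threshold_features(
                _norm_spectrum(np.array([1.0, 2.0]), np.array([0.1, 0.5])))


class TestCountMatches:
    def test_self_match_equals_table_size(self):
        rng = np.random.default_rng(3)
        t = _random_table(rng, 400.0 + np.arange(50.0))
        assert rt.count_matches(t, t) == t.size

    def test_disjoint_assignments_give_zero(self):
        grid = 400.0 + np.arange(4.0)
        a = ReferenceTable(grid, np.array([1, 2, 3, 4]))
        b = ReferenceTable(grid, np.array([2, 3, 4, 5]))
        assert rt.count_matches(a, b) == 0

    def test_grid_mismatch_rejected(self):
        a = _random_table(np.random.default_rng(0), 400.0 + np.arange(10.0))
        b = _random_table(np.random.default_rng(0), 500.0 + np.arange(10.0))
        with pytest.raises(GridMismatchError):
            rt.count_matches(a, b)

    def test_equals_exhaustive_oracle_and_symmetry(self):
        rng = np.random.default_rng(42)
        grid = 400.0 + np.arange(50.0)
        for _ in range(1000):
            a, b = _random_table(rng, grid), _random_table(rng, grid)
            # brute force: loop over every (level, wavenumber) pair
            expected = 0
            for level in range(1, 10):
                sa = {w for w, l in zip(grid, a.level_tenths) if l == level}
                sb = {w for w, l in zip(grid, b.level_tenths) if l == level}
                expected += len(sa & sb)
            got = rt.count_matches(a, b)
            assert got == expected
            assert got == rt.count_matches(b, a)
            assert got <= rt.count_matches(a, a)


class TestClassify:
    def _refs(self):
        rng = np.random.default_rng(6)
        grid = 400.0 + np.arange(60.0)
        refs = []
        for i, c in enumerate(rt.CLASS_ORDER):
            vals = rng.random(60)
            vals[10 + 10 * i] = 1.0
            refs.append(rt.extract_threshold_features(
                _norm_spectrum(grid, vals, tissue_class=c)))
        return grid, refs

    def test_self_match_dominates(self):
        grid, refs = self._refs()
        rng = np.random.default_rng(6)
        vals = rng.random(60)
        vals[10] = 1.0
        res = rt.classify_qm(_norm_spectrum(grid, vals), refs)
        assert res.predicted_class == rt.TissueClass.TUMOR
        assert not res.tied
        assert res.counts[0] == refs[0].size

    def test_identical_references_tie(self):
        grid = 400.0 + np.arange(20.0)
        vals = np.linspace(0.1, 1.0, 20)
        a = rt.extract_threshold_features(
            _norm_spectrum(grid, vals, tissue_class=rt.TissueClass.MUSCLE))
        b = rt.extract_threshold_features(
            _norm_spectrum(grid, vals, tissue_class=rt.TissueClass.FAT))
        res = rt.classify_qm(_norm_spectrum(grid, vals), [a, b])
        assert res.tied
        # deterministic tie-break follows the fixed class order
        assert res.predicted_class == rt.TissueClass.MUSCLE

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            rt.classify_qm(_norm_spectrum(400.0 + np.arange(3.0),
                                          np.array([0.1, 0.5, 1.0])), [])

    def test_per_class_tallies_match_brute_force_recount(self):
        grid, refs = self._refs()
        rng = np.random.default_rng(31)
        for _ in range(20):
            vals = rng.random(60)
            vals[rng.integers(60)] = 1.0
            unknown = _norm_spectrum(grid, vals)
            res = rt.classify_qm(unknown, refs)
            table = rt.extract_threshold_features(unknown)
            recount = {i: rt.count_matches(table, r) for i, r in enumerate(refs)}
            assert res.counts == recount
            best = max(recount.values())
            assert res.per_class_best[res.predicted_class] == best


class TestReferenceSpectrum:
    def test_single_spectrum_identity(self):
        grid = 400.0 + np.arange(10.0)
        vals = np.linspace(0.1, 1.0, 10)
        s = _norm_spectrum(grid, vals, tissue_class=rt.TissueClass.DERMIS)
        out = rt.build_reference_spectrum([s])
        np.testing.assert_allclose(out.intensities, vals)

    def test_renormalised_to_unit_max(self, dataset_default):
        maps, _ = dataset_default
        m = maps[0]
        prepped = rt.preprocess_qm_batch(m.grid, m.flat_intensities())
        spectra = [rt.Spectrum(m.grid, row, SpectrumMeta(
            tissue_class=m.meta.tissue_class, normalized=True)) for row in prepped[:30]]
        ref = rt.build_reference_spectrum(spectra)
        assert ref.intensities.max() == 1.0

    def test_mixed_classes_rejected(self):
        grid = [400.0, 401.0]
        t = rt.Spectrum(grid, [0, 1], SpectrumMeta(tissue_class=rt.TissueClass.TUMOR))
        f = rt.Spectrum(grid, [1, 0], SpectrumMeta(tissue_class=rt.TissueClass.FAT))
        with pytest.raises(ValueError):
            rt.build_reference_spectrum([t, f])


class TestReferenceTableIO:
    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        grid = 400.0 + np.arange(30.0)
        vals = rng.random(30)
        vals[3] = 1.0
        t = rt.extract_threshold_features(
            _norm_spectrum(grid, vals, tissue_class=rt.TissueClass.FAT,
                           patient_id="P2"))
        p = tmp_path / "ref.csv"
        t.to_csv(p)
        back = ReferenceTable.read_csv(p)
        assert back.tissue_class == rt.TissueClass.FAT
        assert back.patient_id == "P2"
        assert back.size == t.size
        for level, wns in t.assignment.items():
            np.testing.assert_allclose(np.sort(back.assignment[level]), np.sort(wns))


class TestBlindTest:
    def test_same_seed_reproduces_matrix(self, dataset_default):
        maps, _ = dataset_default
        a = rt.qm_blind_test(maps, seed=7)
        b = rt.qm_blind_test(maps, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_perfect_at_zero_noise(self, dataset_quiet):
        maps, _ = dataset_quiet
        assert rt.qm_blind_test(maps, seed=7).accuracy() == 1.0

    def test_matrix_total_equals_number_of_unknowns(self, dataset_default):
        maps, _ = dataset_default
        cm = rt.qm_blind_test(maps, seed=3)
        assert cm.total == len(maps)
        cm2 = rt.qm_blind_test(maps, seed=3, unknown_per="patient_class")
        assert cm2.total == len({(m.meta.patient_id, m.meta.tissue_class) for m in maps})

    def test_accuracy_non_increasing_with_noise(self):
        sigmas = [0.0, 0.02, 0.05, 0.1]
        means = []
        for sigma in sigmas:
            cfg = rt.SimulationConfig(n_rows=10, n_cols=10, seed=5)
            maps, _ = rt.simulate_dataset(n_maps_per_class=3, cfg=cfg,
                                          noise_sigma=sigma)
            accs = [rt.qm_blind_test(maps, seed=s).accuracy() for s in range(1, 6)]
            means.append(float(np.mean(accs)))
        assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))

    def test_unlabelled_maps_rejected(self, dataset_default):
        maps, _ = dataset_default
        bare = rt.SpectralMap(maps[0].grid, maps[0].intensities)
        with pytest.raises(ValueError):
            rt.qm_blind_test([bare], seed=0)
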