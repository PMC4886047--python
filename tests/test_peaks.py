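"""Peak picking, ppm alignment, presence filtering, matrix building."""

import numpy as np
import pytest

from msiclassify.io import PeakMatrix
from msiclassify.peaks import (
    PeakList,
    PeakPickConfig,
    align_peaks,
    average_patient_profile,
    build_peak_matrix,
    estimate_noise_mad,
    filter_peaks,
    match_to_references,
    pick_peaks,
)

from conftest import make_dataset, make_spectrum


class TestMadNoise:
    @pytest.mark.parametrize(
        "intensity, expected",
        [
            ([1, 2, 3, 4, 100], 1.4826),       # median 3, MAD 1
            ([5, 5, 5, 5], 0.0),               # constant
            ([0, 1, 2, 3, 4], 1.4826),         # symmetric, MAD 1
        ],
    )
    def test_direct_formula(self, intensity, expected):
        s = make_spectrum(intensity)
        assert estimate_noise_mad(s, PeakPickConfig()) == pytest.approx(expected)


class TestPickPeaks:
    def test_single_gaussian_apex(self, gaussian_spectrum):
        pl = pick_peaks(gaussian_spectrum, PeakPickConfig())
        assert len(pl) == 1
        assert pl.mz[0] == pytest.approx(9200.0)
        assert pl.intensity[0] == pytest.approx(10.0)

    def test_subthreshold_spectrum_yields_empty_list(self):
        # dense wiggle whose strict maxima all sit below 3x the MAD noise
        intensity = 0.01 * np.sin(0.7 * np.arange(300.0))
        s = make_spectrum(intensity)
        noise = estimate_noise_mad(s, PeakPickConfig())
        assert intensity.max() < 3 * noise
        assert len(pick_peaks(s, PeakPickConfig())) == 0

    def test_snr_threshold_inclusive(self):
        """Planted peaks at S/N 2.5, 3 and 10: only >= 3 survive.

        The floor tiles [1,-1,2,-2,3,-3], whose median is 0 and whose
        absolute deviations {1,2,3} have a robust median of 2, so the
        MAD noise stays exactly 2 after planting three peaks.
        """
        floor = np.tile([1.0, -1.0, 2.0, -2.0, 3.0, -3.0], 333)
        floor[300], floor[600], floor[900] = 5.0, 6.0, 40.0
        s = make_spectrum(floor)
        cfg = PeakPickConfig(mad_scale=1.0, halfwindow_local_max=10)
        assert estimate_noise_mad(s, cfg) == pytest.approx(2.0)
        pl = pick_peaks(s, cfg)
        picked = set(np.rint(pl.mz - 3000).astype(int))
        # 5.0 is a strict local maximum (floor max 3) but S/N 2.5 < 3;
        # 6.0 sits exactly at the inclusive threshold
        assert picked == {600, 900}

    def test_plateau_is_not_a_strict_maximum(self):
        intensity = np.zeros(101)
        intensity[40:43] = 5.0
        pl = pick_peaks(make_spectrum(intensity), PeakPickConfig())
        assert len(pl) == 0


class TestAlignment:
    def brute_force_groups(self, mzs, tol_ppm):
        """Oracle: exhaustive left-to-right gap partition of sorted m/z."""
        mzs = np.sort(mzs)
        groups, current = [], [mzs[0]]
        for v in mzs[1:]:
            if v - current[-1] > tol_ppm * 1e-6 * v:
                groups.append(current)
                current = [v]
            else:
                current.append(v)
        groups.append(current)
        return groups

    def test_within_tolerance_merges(self):
        a = PeakList("a", [10000.0], [1.0])
        b = PeakList("b", [10010.0], [3.0])
        refs, aligned = align_peaks([a, b], 2000.0)
        assert len(refs) == 1
        # intensity-weighted mean
        assert refs.mz[0] == pytest.approx((10000 * 1 + 10010 * 3) / 4)
        assert refs.support[0] == 2
        assert aligned[0].mz[0] == aligned[1].mz[0] == refs.mz[0]

    def test_beyond_tolerance_stays_split(self):
        a = PeakList("a", [10000.0], [1.0])
        b = PeakList("b", [10030.0], [1.0])
        refs, _ = align_peaks([a, b], 2000.0)
        assert len(refs) == 2

    def test_single_list_identity(self):
        pl = PeakList("a", [8000.0, 9000.0, 10000.0], [1.0, 2.0, 3.0])
        refs, aligned = align_peaks([pl], 2000.0)
        np.testing.assert_allclose(refs.mz, pl.mz)
        np.testing.assert_allclose(aligned[0].mz, pl.mz)
        np.testing.assert_allclose(aligned[0].intensity, pl.intensity)

    def test_same_source_never_shares_a_reference(self, rng):
        lists = []
        for sid in "abcd":
            base = np.sort(rng.uniform(9000, 9400, size=8))
            base += np.arange(8) * 50  # enforce intra-list spacing
            lists.append(PeakList(sid, np.sort(base), rng.random(8) + 0.1))
        refs, aligned = align_peaks(lists, 2000.0)
        for pl in aligned:
            assert np.unique(pl.mz).size == len(pl)
        # no two references within tolerance of each other at midpoint
        mid = 0.5 * (refs.mz[1:] + refs.mz[:-1])
        assert np.all(np.diff(refs.mz) > 0)

    def test_matches_bruteforce_grouping_without_conflicts(self, rng):
        """One peak per source: greedy grouping equals the gap oracle."""
        mzs = np.sort(rng.uniform(5000, 20000, size=40))
        lists = [PeakList(f"s{i}", [m], [1.0]) for i, m in enumerate(mzs)]
        refs, _ = align_peaks(lists, 2000.0)
        oracle = self.brute_force_groups(mzs, 2000.0)
        assert len(refs) == len(oracle)
        np.testing.assert_allclose(refs.mz, [np.mean(g) for g in oracle])
        np.testing.assert_array_equal(refs.support, [len(g) for g in oracle])


class TestPresenceFilter:
    def _aligned(self, n_lists, present_in):
        """n_lists sources; one reference carried by the first present_in."""
        lists = [
            PeakList(f"s{i}", [10000.0] if i < present_in else [],
                     [1.0] if i < present_in else [])
            for i in range(n_lists)
        ]
        return align_peaks(lists, 2000.0)

    def test_boundary_is_inclusive(self):
        refs, aligned = self._aligned(100, 25)
        kept, _ = filter_peaks(aligned, refs, 0.25)
        assert len(kept) == 1

    def test_rare_reference_removed(self):
        refs, aligned = self._aligned(100, 1)
        kept, out = filter_peaks(aligned, refs, 0.25)
        assert len(kept) == 0
        assert all(len(pl) == 0 for pl in out)

    def test_full_presence_survives_min_presence_one(self):
        refs, aligned = self._aligned(10, 10)
        kept, _ = filter_peaks(aligned, refs, 1.0)
        assert len(kept) == 1

    def test_retained_set_monotone_in_min_presence(self, rng):
        lists = []
        positions = np.array([8000.0, 12000.0, 16000.0, 20000.0])
        for i in range(12):
            mask = rng.random(4) < 0.6
            lists.append(
                PeakList(f"s{i}", positions[mask], np.ones(mask.sum()))
            )
        refs, aligned = align_peaks([pl for pl in lists if len(pl)], 2000.0)
        sizes = [
            len(filter_peaks(aligned, refs, q)[0])
            for q in (0.01, 0.25, 0.5, 0.75, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestPeakMatrixConstruction:
    def test_all_detected(self):
        lists = [
            PeakList("a", [8000.0, 9000.0], [1.0, 2.0]),
            PeakList("b", [8000.0, 9000.0], [3.0, 4.0]),
        ]
        refs, aligned = align_peaks(lists, 2000.0)
        pm = build_peak_matrix(aligned, refs)
        assert pm.shape == (2, 2)
        np.testing.assert_allclose(pm.values, [[1, 2], [3, 4]])
        assert pm.presence.all()

    def test_missing_cell_zero_without_backfill(self):
        lists = [
            PeakList("a", [8000.0, 9000.0], [1.0, 2.0]),
            PeakList("b", [8000.0], [3.0]),
        ]
        refs, aligned = align_peaks(lists, 2000.0)
        pm = build_peak_matrix(aligned, refs)
        assert pm.values[1, 1] == 0.0
        assert not pm.presence[1, 1]

    def test_backfill_reads_spectrum_window_maximum(self):
        lists = [
            PeakList("a", [8000.0, 9000.0], [1.0, 2.0]),
            PeakList("b", [8000.0], [3.0]),
        ]
        refs, aligned = align_peaks(lists, 2000.0)
        mz = 7900.0 + np.arange(1200.0)
        intens = np.zeros(1200)
        intens[int(9000 - 7900) - 3] = 0.7  # 3 Th left of the reference
        spectra = {
            "a": make_spectrum(np.ones(1200), mz=mz),
            "b": make_spectrum(intens, mz=mz, patient_id="b"),
        }
        pm = build_peak_matrix(aligned, refs, spectra=spectra, backfill=True)
        assert pm.values[1, 1] == pytest.approx(0.7)
        assert not pm.presence[1, 1]

    def test_backfill_without_spectrum_errors(self):
        lists = [PeakList("a", [8000.0], [1.0]), PeakList("b", [], [])]
        refs, aligned = align_peaks(lists, 2000.0)
        with pytest.raises(ValueError, match="no spectrum available"):
            build_peak_matrix(aligned, refs, spectra={"a": None}, backfill=True)


class TestMatchToReferences:
    def test_window_arithmetic(self):
        from msiclassify.peaks import ReferencePeaks

        refs = ReferencePeaks([10000.0], [1])
        near = PeakList("a", [10015.0], [2.0])   # 15 Th < 20 Th window
        far = PeakList("b", [10025.0], [2.0])    # 25 Th > 20 Th window
        assert len(match_to_references(near, refs, 2000.0)) == 1
        assert len(match_to_references(far, refs, 2000.0)) == 0


class TestAverageProfile:
    def test_identical_pixels(self):
        s = make_spectrum([1.0, 2.0, 3.0])
        pixels = [
            make_spectrum([1.0, 2.0, 3.0], x=x, y=1) for x in (1, 2, 3)
        ]
        ds = make_dataset(pixels)
        prof = average_patient_profile(ds, "p1")
        np.testing.assert_allclose(prof.intensity, s.intensity)

    def test_two_pixel_mean(self):
        ds = make_dataset(
            [make_spectrum([0.0, 2.0], x=1), make_spectrum([2.0, 0.0], x=2)]
        )
        prof = average_patient_profile(ds, "p1")
        np.testing.assert_allclose(prof.intensity, [1.0, 1.0])

    def test_matches_summation_oracle(self, rng):
        rows = rng.random((50, 30))
        pixels = [
            make_spectrum(rows[i], x=i % 10 + 1, y=i // 10 + 1)
            for i in range(50)
        ]
        ds = make_dataset(pixels)
        prof = average_patient_profile(ds, "p1")
        oracle = sum(rows[i] for i in range(50)) / 50.0
        np.testing.assert_allclose(prof.intensity, oracle, atol=1e-12)

    def test_unknown_patient_errors(self):
        ds = make_dataset([make_spectrum([1.0, 2.0])])
        with pytest.raises(ValueError, match="no spectra"):
            average_patient_profile(ds, "nobody")
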