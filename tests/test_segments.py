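import math

import numpy as np
import pytest

import segscan as ss
from segscan.segments import (
    GRID_SPACING,
    MissingSegmentError,
    NoDataError,
    UnresolvedPeakError,
)

from conftest import gaussian_spectrum


def brute_force_window_count(mz_min, mz_max, width, overlap):
    """Independent enumeration of the stepping rule."""
    count, start = 0, mz_min
    while True:
        count += 1
        if start + width >= mz_max:
            return count
        start += width - overlap


class TestPlanSegments:
    @pytest.mark.parametrize(
        "mz_min,mz_max,width,overlap",
        [(65, 500, 20, 5), (50, 500, 20, 5), (50, 500, 30, 5),
         (50, 500, 100, 10), (65, 500, 50, 0)],
    )
    def test_window_count_matches_brute_force(self, mz_min, mz_max, width, overlap):
        sched = ss.plan_segments(mz_min, mz_max, width, overlap)
        assert len(sched.windows) == brute_force_window_count(
            mz_min, mz_max, width, overlap
        )

    def test_survey_schedule_has_29_windows(self):
        """20 Da windows overlapping 5 Da over m/z 65-500 -> 29 windows."""
        sched = ss.plan_segments(65, 500, 20, 5)
        assert len(sched.windows) == 29
        assert sched.windows[0].mz_low == 65
        assert sched.windows[0].mz_high == 85
        assert sched.windows[-1].mz_high >= 500

    def test_single_window_covers_all(self):
        sched = ss.plan_segments(50, 500, 450, 0)
        assert len(sched.windows) == 1

    def test_adjacent_overlap_region(self):
        sched = ss.plan_segments(65, 500, 20, 5)
        for a, b in zip(sched.windows, sched.windows[1:]):
            assert b.mz_low == pytest.approx(a.mz_low + 15)
            assert a.mz_high - b.mz_low == pytest.approx(5)

    def test_boundaries_at_overlap_midpoints(self):
        sched = ss.plan_segments(65, 500, 20, 5)
        for bnd, (a, b) in zip(sched.merge_boundaries,
                               zip(sched.windows, sched.windows[1:])):
            assert bnd == pytest.approx((a.mz_high + b.mz_low) / 2)

    def test_width_not_exceeding_overlap_rejected(self):
        with pytest.raises(ValueError):
            ss.plan_segments(50, 500, 5, 5)


class TestMergeSegments:
    def _segment_spectra(self, sched, peak_mz, sigma=0.17, height=1e4):
        out = []
        for w in sched.windows:
            s = gaussian_spectrum([peak_mz], [height], sigma=sigma,
                                  lo=w.mz_low, hi=w.mz_high)
            s.metadata["window"] = (w.mz_low, w.mz_high)
            out.append(s)
        return out

    def test_single_segment_identity(self):
        sched = ss.plan_segments(50, 500, 450, 0)
        s = gaussian_spectrum([200.0], [1e4], lo=50, hi=500)
        s.metadata["window"] = (50.0, 500.0)
        merged = ss.merge_segments([s], sched)
        np.testing.assert_array_equal(merged.mz, s.mz)
        np.testing.assert_array_equal(merged.intensity, s.intensity)

    def test_boundary_peak_appears_once(self):
        """A peak exactly at the merge boundary midpoint survives exactly once."""
        sched = ss.plan_segments(50, 80, 20, 5)
        bnd = sched.merge_boundaries[0]
        spectra = self._segment_spectra(sched, peak_mz=bnd)
        merged = ss.merge_segments(spectra, sched)
        assert np.all(np.diff(merged.mz) > 0)  # no duplicated grid points
        inten = merged.intensity
        interior = (inten[1:-1] > inten[:-2]) & (inten[1:-1] > inten[2:])
        maxima = merged.mz[1:-1][interior]
        near = maxima[np.abs(maxima - bnd) < 1.0]
        assert len(near) == 1

    def test_missing_segment_reports_gap(self):
        sched = ss.plan_segments(50, 80, 20, 5)
        spectra = self._segment_spectra(sched, peak_mz=60.0)[:-1]
        with pytest.raises(MissingSegmentError):
            ss.merge_segments(spectra, sched)

    def test_mismatched_window_metadata_rejected(self):
        sched = ss.plan_segments(50, 80, 20, 5)
        spectra = self._segment_spectra(sched, peak_mz=60.0)
        spectra[0].metadata["window"] = (100.0, 120.0)
        with pytest.raises(MissingSegmentError):
            ss.merge_segments(spectra, sched)

    def test_round_trip_centroids_at_low_charge(self, profile, schedule):
        """Merged simulated run reproduces ground-truth centroids within the grid."""
        settings = ss.AcquisitionSettings(injection_time=5.0, scan_mode="segment",
                                          noise_sd=0.01, baseline_sd=0.5, seed=7)
        merged = ss.merge_segments(
            ss.simulate_segment_run(profile, schedule, settings), schedule
        )
        mzs = np.sort([c.mz for c in profile.compounds])
        for c in profile.compounds:
            if not (55 < c.mz < 495) or c.abundance < 50:
                continue
            neighbours = mzs[(np.abs(mzs - c.mz) > 1e-9)
                             & (np.abs(mzs - c.mz) < 1.0)]
            if neighbours.size:
                continue  # unresolvable at 0.4 Da FWHM; apex is a blend
            p = ss.pick_peak(merged, c.mz)
            assert p.method == "local_max"
            assert abs(p.picked_mz - c.mz) <= GRID_SPACING


class TestPickPeak:
    def test_single_gaussian_apex(self):
        s = gaussian_spectrum([75.0], [1e4])
        p = ss.pick_peak(s, 75.0)
        assert p.method == "local_max"
        assert p.picked_mz == pytest.approx(75.0, abs=GRID_SPACING)
        assert abs(p.picked_mz - p.target_mz) <= 0.3

    def test_monotone_ramp_falls_back_to_mean(self):
        mz = np.arange(50.0, 51.0, 0.05)
        s = ss.Spectrum(mz, np.linspace(0, 100, mz.size))
        p = ss.pick_peak(s, 50.5)
        assert p.method == "window_mean"
        assert p.picked_mz == 50.5
        window = (mz >= 50.2) & (mz <= 50.8)
        assert p.intensity == pytest.approx(s.intensity[window].mean())

    def test_equal_maxima_tie_breaks_to_lower_mz(self):
        """Two equal maxima equidistant from the target -> lower m/z wins,
        checked over permuted constructions."""
        for d in (0.10, 0.15, 0.20):
            mz = np.arange(74.0, 76.01, 0.05)
            inten = np.zeros_like(mz)
            for c in (75.0 - d, 75.0 + d):
                inten[np.argmin(np.abs(mz - c))] = 100.0
            s = ss.Spectrum(mz, inten)
            p = ss.pick_peak(s, 75.0)
            assert p.picked_mz == pytest.approx(75.0 - d, abs=1e-9)

    def test_highest_intensity_wins(self):
        s = gaussian_spectrum([74.8, 75.2], [1e3, 5e3])
        p = ss.pick_peak(s, 75.0)
        assert p.picked_mz == pytest.approx(75.2, abs=GRID_SPACING)

    def test_window_outside_spectrum_raises(self):
        s = gaussian_spectrum([75.0], [1e4])
        with pytest.raises(NoDataError):
            ss.pick_peak(s, 200.0)

    def test_tiny_half_window_degrades_to_nearest_point(self):
        s = gaussian_spectrum([75.0], [1e4])
        p = ss.pick_peak(s, 75.02, half_window=0.02)
        i = np.argmin(np.abs(s.mz - 75.02))
        assert p.intensity == pytest.approx(s.intensity[i])


class TestRelativeIntensity:
    def test_single_peak_takes_all(self):
        s = gaussian_spectrum([75.0], [1e4], baseline=0.0)
        p = ss.pick_peak(s, 75.0)
        assert ss.relative_intensity(p, s) == pytest.approx(1.0, abs=1e-3)

    def test_two_identical_peaks_split_evenly(self):
        s = gaussian_spectrum([65.0, 85.0], [1e4, 1e4])
        for c in (65.0, 85.0):
            p = ss.pick_peak(s, c)
            assert ss.relative_intensity(p, s) == pytest.approx(0.5, abs=1e-3)

    def test_three_to_one_area_ratio(self):
        """Analytic Gaussian areas 3:1 -> relative intensities 0.75 / 0.25."""
        s = gaussian_spectrum([65.0, 85.0], [3e4, 1e4])
        p_big = ss.pick_peak(s, 65.0)
        p_small = ss.pick_peak(s, 85.0)
        assert ss.relative_intensity(p_big, s) == pytest.approx(0.75, abs=1e-3)
        assert ss.relative_intensity(p_small, s) == pytest.approx(0.25, abs=1e-3)

    def test_disjoint_peaks_sum_to_at_most_one(self):
        rng = np.random.default_rng(11)
        centers = np.arange(55.0, 96.0, 5.0)
        heights = rng.uniform(1e3, 1e5, centers.size)
        s = gaussian_spectrum(centers, heights)
        total = sum(
            ss.relative_intensity(ss.pick_peak(s, c), s) for c in centers
        )
        assert total <= 1.0 + 1e-6
        assert total == pytest.approx(1.0, abs=5e-3)  # zero baseline

    def test_zero_total_area_rejected(self):
        s = ss.Spectrum(np.array([50.0, 50.05]), np.array([0.0, 0.0]))
        p = ss.PeakMeasurement(target_mz=50.0, picked_mz=50.0, intensity=0.0,
                               method="window_mean")
        with pytest.raises(ZeroDivisionError):
            ss.relative_intensity(p, s)


class TestEstimateFwhm:
    def test_gaussian_closed_form(self):
        """sigma = 0.17 Da -> FWHM = 2.3548 sigma = 0.400 Da."""
        s = gaussian_spectrum([75.0], [1e4], sigma=0.17)
        p = ss.pick_peak(s, 75.0)
        assert ss.estimate_fwhm(s, p.picked_mz) == pytest.approx(0.40, abs=0.01)

    def test_triangular_peak_geometry(self):
        """Triangle of base 0.8 Da has FWHM 0.4 Da."""
        mz = np.arange(74.0, 76.01, 0.05)
        inten = np.maximum(0.0, 1.0 - np.abs(mz - 75.0) / 0.4) * 1e4
        s = ss.Spectrum(mz, inten)
        assert ss.estimate_fwhm(s, 75.0) == pytest.approx(0.4, abs=0.01)

    def test_space_charge_broadening_monotone(self, full_scan_35, full_scan_60):
        """60 ms overloaded full scan is broader than the clean 35 ms scan."""
        p35 = ss.pick_peak(full_scan_35, 255.23)
        p60 = ss.pick_peak(full_scan_60, 257.0)
        assert ss.estimate_fwhm(full_scan_60, p60.picked_mz) > \
            ss.estimate_fwhm(full_scan_35, p35.picked_mz)

    def test_unresolved_peak_raises(self):
        mz = np.arange(74.0, 76.01, 0.05)
        inten = np.full_like(mz, 100.0)
        inten[20] = 101.0  # 1% bump never crosses half height
        s = ss.Spectrum(mz, inten)
        with pytest.raises(UnresolvedPeakError):
            ss.estimate_fwhm(s, float(mz[20]))


class TestMergeConservation:
    def test_hundred_random_profiles(self):
        """Every ground-truth peak appears exactly once in the merged spectrum."""
        rng = np.random.default_rng(2024)
        sched = ss.plan_segments(50, 500, 20, 5)
        for rep in range(100):
            n = rng.integers(10, 30)
            mzs = np.sort(rng.uniform(55, 495, n))
            mzs = mzs[np.r_[True, np.diff(mzs) > 1.5]]  # resolvable spacing
            prof = ss.GroundTruthProfile(tuple(
                ss.Compound(float(m), float(rng.uniform(100, 5000)))
                for m in mzs
            ))
            settings = ss.AcquisitionSettings(
                injection_time=10.0, scan_mode="segment",
                noise_sd=0.01, baseline_sd=0.1, seed=int(rng.integers(2**31)),
            )
            merged = ss.merge_segments(
                ss.simulate_segment_run(prof, sched, settings), sched
            )
            assert np.all(np.diff(merged.mz) > 0)
            inten = merged.intensity
            interior = (inten[1:-1] > inten[:-2]) & (inten[1:-1] > inten[2:])
            maxima = merged.mz[1:-1][interior][inten[1:-1][interior] > 50.0]
            assert len(maxima) == len(mzs)  # one apex per planted compound
            for m in mzs:
                p = ss.pick_peak(merged, float(m))
                assert p.method == "local_max"
                assert abs(p.picked_mz - m) <= GRID_SPACING
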