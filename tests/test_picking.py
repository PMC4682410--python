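import numpy as np
import pytest

from apvpeaks.io import Spectrum
from apvpeaks.models import PeakParams, mapv_eval
from apvpeaks.picking import (
    Component,
    DetectorConfig,
    EmptyComponentError,
    detect_peaks,
    find_valleys,
    fit_component,
    split_at_valleys,
)


class TestFindValleys:
    def test_monotone_increasing(self):
        assert find_valleys(np.array([1.0, 2, 3, 4])) == []

    def test_single_valley(self):
        assert find_valleys(np.array([0.0, 5, 1, 6, 0])) == [2]

    def test_plateau_midpoint(self):
        assert find_valleys(np.array([0.0, 5, 2, 2, 2, 6, 0])) == [3]

    def test_short_input(self):
        assert find_valleys(np.array([1.0, 2.0])) == []

    def test_tolerance_merges_shallow_valleys(self):
        # two dips separated by a barrier of height 0.5 above the deeper dip
        y = np.array([0.0, 5, 1.0, 1.5, 0.8, 5, 0.0])
        assert find_valleys(y, tolerance=0.0) == [2, 4]
        merged = find_valleys(y, tolerance=1.0)
        assert merged == [4]  # deeper valley kept

    def test_endpoints_never_returned(self, rng):
        for _ in range(50):
            y = rng.uniform(size=rng.integers(3, 30))
            v = find_valleys(y)
            assert all(0 < i < y.size - 1 for i in v)


class TestSplitAtValleys:
    def test_no_valleys_single_component(self):
        mz = np.arange(5, dtype=float)
        comps = split_at_valleys(mz, np.array([0.0, 1, 2, 3, 4]))
        assert len(comps) == 1
        assert (comps[0].start, comps[0].stop) == (0, 5)

    def test_boundary_shared(self):
        mz = np.arange(5, dtype=float)
        comps = split_at_valleys(mz, np.array([0.0, 5, 1, 6, 0]))
        assert len(comps) == 2
        assert comps[0].stop - 1 == comps[1].start == 2  # valley shared

    def test_partition_covers_range(self, rng):
        y = rng.uniform(size=50)
        comps = split_at_valleys(np.arange(50, dtype=float), y)
        assert comps[0].start == 0 and comps[-1].stop == 50
        for a, b in zip(comps[:-1], comps[1:]):
            assert a.stop - 1 == b.start


class TestFitComponent:
    def test_noiseless_recovery(self, fast_hpso):
        theta = PeakParams(100, 500, 2, 4, 0.3, 0.7)
        m = np.linspace(500 - 8 * 2, 500 + 8 * 4, 100)
        y = mapv_eval(m, theta)
        fp = fit_component(Component(0, 100, m, y), fast_hpso,
                           rng=np.random.default_rng(0))
        assert fp.sse < 1e-4 * float(y @ y)
        assert abs(fp.theta.alpha - 500) < (m[1] - m[0])
        assert fp.start_mz <= fp.theta.alpha <= fp.end_mz

    def test_symmetric_gaussian_degeneracy(self, fast_hpso):
        m = np.linspace(-10, 10, 120)
        y = 50 * np.exp(-np.log(2) * (m / 2.0) ** 2)
        fp = fit_component(Component(0, 120, m, y), fast_hpso,
                           rng=np.random.default_rng(1))
        assert fp.mu < 1.1
        assert fp.theta.beta1 < 0.15 and fp.theta.beta2 < 0.15

    def test_insufficient_points(self, fast_hpso):
        m = np.array([0.0, 1.0, 2.0])
        with pytest.raises(EmptyComponentError):
            fit_component(Component(0, 3, m, np.array([0.0, 1.0, 0.0])), fast_hpso)

    def test_all_zero_component(self, fast_hpso):
        m = np.arange(10, dtype=float)
        with pytest.raises(EmptyComponentError):
            fit_component(Component(0, 10, m, np.zeros(10)), fast_hpso)


def _spectrum_from_thetas(thetas, mz, noise_sd=0.0, seed=0, stage="baseline_corrected"):
    y = np.zeros(mz.size)
    for th in thetas:
        y += mapv_eval(mz, th)
    if noise_sd:
        y = np.clip(y + np.random.default_rng(seed).normal(0, noise_sd, mz.size), 0, None)
    return Spectrum(mz, y, metadata={"stage": stage})


class TestDetectPeaks:
    def test_flat_zero_spectrum(self, fast_hpso):
        s = Spectrum(np.linspace(0, 10, 100), np.zeros(100),
                     metadata={"stage": "baseline_corrected"})
        assert len(detect_peaks(s, hpso_cfg=fast_hpso, seed=0)) == 0

    def test_two_separated_peaks_with_noise(self, fast_hpso):
        thetas = [
            PeakParams(100, 120, 2, 3, 0.2, 0.6),
            PeakParams(80, 170, 2, 2.5, 0.5, 0.3),
        ]
        mz = np.linspace(100, 200, 1500)
        s = _spectrum_from_thetas(thetas, mz, noise_sd=1.0, seed=4)
        # area cut well below the true peak areas (~300+) but above noise blobs
        peaks = detect_peaks(s, DetectorConfig(area_threshold=60.0),
                             hpso_cfg=fast_hpso, seed=0)
        assert len(peaks) == 2
        for th, got in zip(thetas, peaks.df.summit_mz):
            assert abs(got - th.alpha) / th.alpha < 0.01

    def test_overlapping_pair_split_by_asymmetry_rule(self, fast_hpso):
        # one maximum with an interior shoulder valley; merged fit is wide and
        # asymmetric, so the mu > 2 rule should split and report 2 peaks
        thetas = [
            PeakParams(100, 150, 1.2, 1.2, 0.1, 0.1),
            PeakParams(55, 154.5, 1.3, 3.8, 0.1, 0.4),
        ]
        mz = np.linspace(130, 180, 1200)
        s = _spectrum_from_thetas(thetas, mz)
        cfg = DetectorConfig(valley_tolerance=0.0)
        peaks = detect_peaks(s, cfg, hpso_cfg=fast_hpso, seed=1)
        assert len(peaks) == 2

    def test_noiseless_multi_peak_counts_and_areas(self, fast_hpso):
        from apvpeaks.models import peak_area

        thetas = [
            PeakParams(100, 120, 2, 2, 0.3, 0.3),
            PeakParams(60, 160, 2.5, 3.0, 0.0, 0.5),
            PeakParams(140, 200, 1.5, 2.0, 0.7, 0.2),
        ]
        mz = np.linspace(100, 230, 2000)
        s = _spectrum_from_thetas(thetas, mz)
        peaks = detect_peaks(s, DetectorConfig(area_threshold=1.0),
                             hpso_cfg=fast_hpso, seed=2)
        assert len(peaks) == 3
        for th, (_, row) in zip(thetas, peaks.df.iterrows()):
            assert abs(row.area - peak_area(th)) / peak_area(th) < 0.05

    def test_determinism(self, fast_hpso):
        thetas = [PeakParams(100, 120, 2, 3, 0.2, 0.6)]
        mz = np.linspace(100, 140, 600)
        s = _spectrum_from_thetas(thetas, mz, noise_sd=1.5, seed=9)
        p1 = detect_peaks(s, hpso_cfg=fast_hpso, seed=7)
        p2 = detect_peaks(s, hpso_cfg=fast_hpso, seed=7)
        assert p1.df.equals(p2.df)

    def test_area_threshold_filters(self, fast_hpso):
        thetas = [PeakParams(100, 120, 2, 2, 0.0, 0.0)]
        mz = np.linspace(100, 140, 600)
        s = _spectrum_from_thetas(thetas, mz)
        peaks = detect_peaks(s, DetectorConfig(area_threshold=1e9),
                             hpso_cfg=fast_hpso, seed=0)
        assert len(peaks) == 0

    def test_unpreprocessed_warning(self, fast_hpso, caplog):
        s = Spectrum(np.linspace(0, 10, 100), np.zeros(100))
        with caplog.at_level("WARNING"):
            detect_peaks(s, hpso_cfg=fast_hpso, seed=0)
        assert any("preprocessed" in r.message for r in caplog.records)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DetectorConfig(asymmetry_threshold=1.0)
        with pytest.raises(ValueError):
            DetectorConfig(max_depth=0)
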