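import math

import numpy as np
import pytest

from chromaquant.baseline_noise import NoiseEstimate, estimate_background_noise
from chromaquant.peak_detection import (
    FWHM_FACTOR,
    DetectedPeak,
    DetectionError,
    DetectionSettings,
    derivative_brackets,
    detect_peaks,
    peaks_to_definitions,
    suggest_calibrants,
)
from chromaquant.synthetic import PeakSpec, SimSpec, simulate_chromatogram
from conftest import gaussian_chromatogram, make_chromatogram

ZERO_NOISE = NoiseEstimate(background=0.0, noise=0.0, window_start=0.0, window_points=10)


def integral(chrom, region=None):
    sub = chrom if region is None else chrom.slice(*region)
    return sub.sampling_interval * float(sub.intensity.sum())


class TestDerivativeBrackets:
    def test_single_gaussian_one_bracket_containing_apex(self):
        chrom = gaussian_chromatogram(10.0, 0.05, 100.0, region=(8.0, 12.0))
        settings = DetectionSettings(region=(8.0, 12.0), cutoff_fraction=0.05)
        brackets = derivative_brackets(chrom, settings)
        assert len(brackets) == 1
        lo, hi = brackets[0]
        assert lo <= 10.0 <= hi

    def test_flat_signal_no_brackets(self, flat_chromatogram):
        settings = DetectionSettings(region=(1.0, 9.0), cutoff_fraction=0.05)
        assert derivative_brackets(flat_chromatogram, settings) == []

    def test_two_separated_gaussians_two_brackets(self):
        chrom = gaussian_chromatogram(
            [10.0, 14.0], [0.05, 0.05], [100.0, 80.0], region=(8.0, 16.0)
        )
        settings = DetectionSettings(region=(8.0, 16.0), cutoff_fraction=0.05)
        brackets = derivative_brackets(chrom, settings)
        assert len(brackets) == 2
        assert brackets[0][0] <= 10.0 <= brackets[0][1]
        assert brackets[1][0] <= 14.0 <= brackets[1][1]

    def test_too_few_points(self):
        chrom = make_chromatogram([0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        with pytest.raises(DetectionError):
            derivative_brackets(
                chrom, DetectionSettings(region=(0.0, 2.0), cutoff_fraction=0.05)
            )


class TestDetectPeaks:
    def test_three_gaussians_recovered(self):
        spec = SimSpec(
            peaks=(
                PeakSpec(5.0, 0.05, 100.0),
                PeakSpec(7.0, 0.05, 50.0),
                PeakSpec(9.0, 0.05, 10.0),
            ),
            region=(3.0, 11.0),
            sampling_interval=0.01,
            noise_sigma=0.5,
            seed=1,
        )
        chrom, truth = simulate_chromatogram(spec)
        noise = estimate_background_noise(chrom, (3.0, 11.0), 100)
        peaks = detect_peaks(
            chrom, DetectionSettings(region=(3.0, 11.0), cutoff_fraction=0.05), noise
        )
        assert len(peaks) == 3
        for found, true in zip(peaks, truth):
            assert abs(found.center - true.center) < 0.01
            assert found.area == pytest.approx(true.area, rel=0.05)

    def test_single_gaussian_high_cutoff_one_peak(self):
        chrom = gaussian_chromatogram(10.0, 0.05, 100.0, region=(8.0, 12.0), noise_sigma=0.2, seed=3)
        noise = estimate_background_noise(chrom, (8.0, 12.0), 100)
        peaks = detect_peaks(
            chrom, DetectionSettings(region=(8.0, 12.0), cutoff_fraction=0.5), noise
        )
        assert len(peaks) == 1

    def test_tailing_peak_resolved_as_multiple_gaussians(self):
        # a strongly tailing peak is split into >= 2 Gaussian components
        spec = SimSpec(
            peaks=(PeakSpec(10.0, 0.05, 100.0, tau=0.15),),
            region=(8.0, 13.0),
            sampling_interval=0.005,
            noise_sigma=0.3,
            seed=2,
        )
        chrom, _ = simulate_chromatogram(spec)
        noise = estimate_background_noise(chrom, (8.0, 13.0), 100)
        peaks = detect_peaks(
            chrom, DetectionSettings(region=(8.0, 13.0), cutoff_fraction=0.05), noise
        )
        assert len(peaks) >= 2

    def test_area_conservation(self):
        spec = SimSpec(
            peaks=(PeakSpec(5.0, 0.06, 120.0), PeakSpec(6.0, 0.08, 60.0)),
            region=(3.0, 8.0),
            sampling_interval=0.005,
            noise_sigma=0.4,
            seed=5,
        )
        chrom, _ = simulate_chromatogram(spec)
        noise = estimate_background_noise(chrom, (3.0, 8.0), 100)
        settings = DetectionSettings(region=(3.0, 8.0), cutoff_fraction=0.05)
        peaks = detect_peaks(chrom, settings, noise)
        sub = chrom.slice(3.0, 8.0)
        residual = sub.intensity.copy()
        for p in peaks:
            residual = residual - p.amplitude * np.exp(
                -((sub.time - p.center) ** 2) / (2 * p.sigma**2)
            )
        t_m = sub.sampling_interval
        total_in = t_m * float(sub.intensity.sum())
        total_out = sum(p.area for p in peaks) + t_m * float(residual.sum())
        assert total_out == pytest.approx(total_in, rel=0.02)

    def test_cutoff_monotonicity(self):
        spec = SimSpec(
            peaks=(
                PeakSpec(5.0, 0.05, 100.0),
                PeakSpec(6.5, 0.05, 30.0),
                PeakSpec(8.0, 0.05, 8.0),
            ),
            region=(3.0, 10.0),
            sampling_interval=0.01,
            noise_sigma=0.3,
            seed=4,
        )
        chrom, _ = simulate_chromatogram(spec)
        noise = estimate_background_noise(chrom, (3.0, 10.0), 100)
        counts = []
        for cutoff in (0.5, 0.2, 0.05, 0.02):
            peaks = detect_peaks(
                chrom,
                DetectionSettings(region=(3.0, 10.0), cutoff_fraction=cutoff),
                noise,
            )
            counts.append(len(peaks))
        assert counts == sorted(counts)

    def test_determinism(self):
        chrom = gaussian_chromatogram(
            [10.0, 11.0], [0.05, 0.05], [100.0, 40.0], region=(8.0, 13.0),
            noise_sigma=0.5, seed=9,
        )
        noise = estimate_background_noise(chrom, (8.0, 13.0), 100)
        settings = DetectionSettings(region=(8.0, 13.0), cutoff_fraction=0.05)
        first = detect_peaks(chrom, settings, noise)
        second = detect_peaks(chrom, settings, noise)
        assert first == second

    def test_flat_region_returns_nothing(self, flat_chromatogram):
        noise = NoiseEstimate(background=5.0, noise=0.1, window_start=0.0, window_points=10)
        peaks = detect_peaks(
            flat_chromatogram,
            DetectionSettings(region=(1.0, 9.0), cutoff_fraction=0.05),
            noise,
        )
        assert peaks == []


class TestPeakProperties:
    def test_fwhm_identity(self):
        p = DetectedPeak(center=10.0, sigma=0.05, amplitude=100.0, bracket=(9.9, 10.1), iteration=1)
        assert p.fwhm == pytest.approx(2 * math.sqrt(2 * math.log(2)) * 0.05)
        assert p.area == pytest.approx(100.0 * 0.05 * math.sqrt(2 * math.pi))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            DetectedPeak(center=1.0, sigma=0.0, amplitude=1.0, bracket=(0, 1), iteration=1)
        with pytest.raises(ValueError):
            DetectedPeak(center=1.0, sigma=0.1, amplitude=-1.0, bracket=(0, 1), iteration=1)


class TestPeaksToDefinitions:
    def test_window_is_half_fwhm(self):
        p = DetectedPeak(center=10.0, sigma=0.05, amplitude=50.0, bracket=(9.9, 10.1), iteration=1)
        (d,) = peaks_to_definitions([p])
        assert d.name == "peak1"
        assert d.tr_expected == pytest.approx(10.0)
        assert d.window == pytest.approx(0.0588705, rel=1e-4)  # FWHM/2 = 2.3548*sigma/2

    def test_names_ordered_by_tr(self):
        peaks = [
            DetectedPeak(center=12.0, sigma=0.05, amplitude=5.0, bracket=(0, 1), iteration=1),
            DetectedPeak(center=10.0, sigma=0.05, amplitude=9.0, bracket=(0, 1), iteration=2),
        ]
        defs = peaks_to_definitions(peaks)
        assert [d.name for d in defs] == ["peak1", "peak2"]
        assert defs[0].tr_expected < defs[1].tr_expected

    def test_empty_raises(self):
        with pytest.raises(DetectionError):
            peaks_to_definitions([])


def _peak(center, amplitude):
    return DetectedPeak(
        center=center, sigma=0.05, amplitude=amplitude, bracket=(center - 0.1, center + 0.1), iteration=1
    )


class TestSuggestCalibrants:
    def test_evenly_spaced_one_per_quartile(self):
        peaks = [_peak(10.0 + j, 50.0) for j in range(8)]
        chosen = suggest_calibrants(peaks, k=4)
        assert len(chosen) == 4
        trs = [c.tr_expected for c in chosen]
        # one pick inside each quarter of the 10..17 span
        for j, tr in enumerate(trs):
            assert 10.0 + j * 1.75 <= tr <= 10.0 + (j + 1) * 1.75

    def test_clustered_peaks_fall_back_to_amplitude(self):
        peaks = [
            _peak(10.00, 5.0),
            _peak(10.01, 9.0),
            _peak(10.02, 7.0),
            _peak(10.03, 3.0),
            _peak(12.00, 10.0),
        ]
        chosen = suggest_calibrants(peaks, k=4)
        amps = {round(c.tr_expected, 2) for c in chosen}
        assert amps == {10.01, 10.02, 10.0, 12.0}  # 4 highest amplitudes overall

    def test_k1_single_tallest(self):
        peaks = [_peak(10.0, 5.0), _peak(11.0, 50.0), _peak(12.0, 20.0)]
        (chosen,) = suggest_calibrants(peaks, k=1)
        assert chosen.tr_expected == pytest.approx(11.0)

    def test_fewer_than_k_returns_all(self):
        peaks = [_peak(10.0, 5.0), _peak(11.0, 50.0)]
        chosen = suggest_calibrants(peaks, k=4)
        assert len(chosen) == 2

    def test_empty_raises(self):
        with pytest.raises(DetectionError):
            suggest_calibrants([])


class TestSettings:
    @pytest.mark.parametrize("cutoff", [0.0, 1.0, -0.1, 1.5])
    def test_cutoff_bounds(self, cutoff):
        with pytest.raises(ValueError):
            DetectionSettings(region=(0.0, 1.0), cutoff_fraction=cutoff)

    def test_bad_region(self):
        with pytest.raises(ValueError):
            DetectionSettings(region=(2.0, 1.0), cutoff_fraction=0.1)
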