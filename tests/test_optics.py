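"""Tests of the Fourier processing and optical-constant extraction."""

import numpy as np
import pytest

from thzwheat import optics
from thzwheat.errors import (
    AxisMismatchError,
    DegenerateAmplitudeError,
    EmptyBandError,
    InvalidGridError,
)
from thzwheat.optics import (
    FrequencySpectrum,
    TimeTrace,
    analysis_grid,
    average_scans,
    extract_alpha,
    extract_n,
    restrict_band,
    to_frequency,
)


def _trace(E, dt=0.02):
    t = dt * np.arange(len(E))
    return TimeTrace(t=t, E=E)


class TestToFrequency:
    def test_cosine_peaks_at_its_frequency(self):
        t = 0.02 * np.arange(2000)  # 40 ps window: integer periods of 1 THz
        trace = TimeTrace(t=t, E=np.cos(2 * np.pi * 1.0 * t))
        spec = to_frequency(trace, pad_factor=1)
        f_peak = spec.freq[np.argmax(spec.amplitude)]
        assert f_peak == pytest.approx(1.0, abs=0.05)

    def test_shift_theorem(self, reference_pulse):
        # delaying a trace by dt adds omega*dt to the phase
        delay = 1.25
        delayed = TimeTrace(
            t=reference_pulse.t,
            E=np.interp(
                reference_pulse.t - delay,
                reference_pulse.t,
                reference_pulse.E,
                left=0.0,
                right=0.0,
            ),
        )
        grid = analysis_grid()
        a = to_frequency(reference_pulse).interp(grid)
        b = to_frequency(delayed).interp(grid)
        expected = 2 * np.pi * grid * delay  # f in THz, delay in ps
        assert np.allclose(b.phase - a.phase, expected, atol=1e-3)

    def test_zero_signal_gives_zero_amplitude(self):
        spec = to_frequency(_trace(np.zeros(500)))
        assert np.all(spec.amplitude == 0)

    def test_nonuniform_axis_rejected(self):
        t = np.array([0.0, 0.02, 0.05, 0.09])
        with pytest.raises(InvalidGridError):
            TimeTrace(t=t, E=np.zeros(4))


class TestAverageScans:
    def test_identical_traces_average_to_themselves(self, reference_pulse):
        avg = average_scans([reference_pulse] * 5)
        assert np.allclose(avg.E, reference_pulse.E)

    def test_opposite_traces_cancel(self, reference_pulse):
        flipped = TimeTrace(t=reference_pulse.t, E=-reference_pulse.E)
        avg = average_scans([reference_pulse, flipped])
        assert np.allclose(avg.E, 0.0)

    def test_noise_reduced_about_fivefold(self, reference_pulse):
        rng = np.random.default_rng(5)
        noisy = [
            TimeTrace(
                t=reference_pulse.t,
                E=reference_pulse.E + rng.normal(0, 0.01, reference_pulse.E.size),
            )
            for _ in range(5)
        ]
        mse_single = np.mean((noisy[0].E - reference_pulse.E) ** 2)
        mse_avg = np.mean((average_scans(noisy).E - reference_pulse.E) ** 2)
        assert 3.5 < mse_single / mse_avg < 7.0

    def test_mismatched_axes_rejected(self, reference_pulse):
        other = TimeTrace(t=reference_pulse.t + 1.0, E=reference_pulse.E)
        with pytest.raises(AxisMismatchError):
            average_scans([reference_pulse, other])


class TestExtraction:
    freq = np.linspace(0.2, 1.6, 50)

    def _pair(self, ratio=1.0, dphi=0.0):
        amp = np.ones_like(self.freq)
        ref = FrequencySpectrum(self.freq, amp, np.zeros_like(self.freq))
        sam = FrequencySpectrum(self.freq, amp * ratio, np.full_like(self.freq, dphi))
        return ref, sam

    def test_equal_amplitudes_give_zero_alpha(self):
        ref, sam = self._pair(ratio=1.0)
        assert np.allclose(extract_alpha(ref, sam, 1.0), 0.0)

    def test_known_attenuation_hand_oracle(self):
        # As = Ar exp(-0.5) through 1 mm: alpha = 0.5 / 0.1 cm = 5 cm^-1
        ref, sam = self._pair(ratio=np.exp(-0.5))
        assert np.allclose(extract_alpha(ref, sam, 1.0), 5.0)

    def test_nonpositive_amplitude_rejected(self):
        ref, sam = self._pair()
        bad = FrequencySpectrum(self.freq, 0.0 * sam.amplitude, sam.phase)
        with pytest.raises(DegenerateAmplitudeError):
            extract_alpha(ref, bad, 1.0)

    def test_equal_phases_give_unit_index(self):
        ref, sam = self._pair()
        assert np.allclose(extract_n(ref, sam, 1.0), 1.0)

    def test_positive_delay_gives_index_above_one(self):
        # phase of a slab with n=1.5, d=1mm: (n-1) omega d / c
        omega = 2 * np.pi * self.freq * 1e12
        dphi_at = 0.5 * omega * 1e-3 / optics.C_LIGHT
        ref = FrequencySpectrum(self.freq, np.ones_like(self.freq),
                                np.zeros_like(self.freq))
        sam = FrequencySpectrum(self.freq, np.ones_like(self.freq), dphi_at)
        assert np.allclose(extract_n(ref, sam, 1.0), 1.5)

    def test_zero_frequency_rejected(self):
        freq = np.linspace(0.0, 1.6, 10)
        spec = FrequencySpectrum(freq, np.ones_like(freq), np.zeros_like(freq))
        with pytest.raises(ZeroDivisionError):
            extract_n(spec, spec, 1.0)

    def test_thickness_halves_error_sensitivity(self):
        # a fixed amplitude/phase perturbation produces exactly half the
        # alpha and (n-1) error through a slab twice as thick
        rng = np.random.default_rng(3)
        damp = rng.normal(0, 0.01, self.freq.size)
        dphi = rng.normal(0, 0.01, self.freq.size)
        ref = FrequencySpectrum(self.freq, np.ones_like(self.freq),
                                np.zeros_like(self.freq))
        sam = FrequencySpectrum(self.freq, np.exp(damp), dphi)
        a1, a2 = extract_alpha(ref, sam, 1.0), extract_alpha(ref, sam, 2.0)
        n1, n2 = extract_n(ref, sam, 1.0), extract_n(ref, sam, 2.0)
        assert np.allclose(a1, 2 * a2)
        assert np.allclose(n1 - 1.0, 2 * (n2 - 1.0))


class TestRestrictBand:
    def _spec(self, lo=0.05, hi=3.5, step=0.01):
        freq = np.round(np.arange(lo, hi + step / 2, step), 10)
        return optics.OpticalSpectrum(
            freq=freq, alpha=np.ones_like(freq), n=np.ones_like(freq),
            thickness_mm=1.0,
        )

    def test_band_restriction_bounds(self):
        out = restrict_band(self._spec(), 0.2, 1.6)
        assert out.freq.min() >= 0.2 and out.freq.max() <= 1.6

    def test_standard_band_has_141_bins(self):
        out = restrict_band(self._spec(), 0.2, 1.6)
        assert out.freq.size == 141  # closed interval, 0.01 THz step

    def test_empty_selection_rejected(self):
        with pytest.raises(EmptyBandError):
            restrict_band(self._spec(step=0.1), 0.201, 0.205)
        with pytest.raises(EmptyBandError):
            restrict_band(self._spec(), 1.6, 0.2)
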