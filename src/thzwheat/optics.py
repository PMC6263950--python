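"""Frequency-domain processing of THz time-domain traces.

A transmission THz-TDS measurement records the electric field of a picosecond
pulse twice: once through free space (reference) and once through the sample
slab.  Fourier transforming both traces gives amplitude and phase on a common
frequency grid, from which the two optical constants follow directly:

    alpha(f) = (1/d) * ln(A_ref / A_sam)          [field absorption, cm^-1]
    n(f)     = 1 + (phi_sam - phi_ref) * c / (omega * d)

with ``d`` the slab thickness, ``c`` the vacuum speed of light and
``omega = 2*pi*f``.  The phase convention is E(omega) = A * exp(-i*phi), so a
slab that delays the pulse produces phi_sam > phi_ref and hence n > 1.

The absorption coefficient is applied to the *field* amplitude (no factor of
two between field and intensity); the forward model in :mod:`thzwheat.synthetic`
uses the same convention, so the two are mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import (
    AxisMismatchError,
    DegenerateAmplitudeError,
    EmptyBandError,
    InvalidGridError,
)

#: vacuum speed of light, m/s
C_LIGHT = 299_792_458.0

#: default analysis band, THz
BAND_LO = 0.2
BAND_HI = 1.6

#: default analysis grid step, THz
GRID_STEP = 0.01

_UNIFORM_RTOL = 1e-6


def _check_uniform(t: np.ndarray) -> float:
    """Return the step of a strictly increasing uniform axis, or raise."""
    if t.ndim != 1 or t.size < 2:
        raise InvalidGridError("time axis must be 1-D with at least 2 points")
    dt = np.diff(t)
    if dt[0] <= 0 or not np.allclose(dt, dt[0], rtol=_UNIFORM_RTOL, atol=0):
        raise InvalidGridError("time axis must be strictly increasing and uniform")
    return float(dt[0])


@dataclass(frozen=True)
class TimeTrace:
    """Sampled electric field of one scan.

    Parameters
    ----------
    t : array
        Time axis in picoseconds, strictly increasing and uniform.
    E : array
        Field samples in arbitrary units, same length as ``t``.
    role : str
        ``"reference"`` or ``"sample"``.
    """

    t: np.ndarray
    E: np.ndarray
    role: str = "sample"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        E = np.asarray(self.E, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "E", E)
        _check_uniform(t)
        if t.shape != E.shape:
            raise InvalidGridError("time axis and field must have equal length")

    @property
    def dt(self) -> float:
        """Sampling step in ps."""
        return float(self.t[1] - self.t[0])

    @property
    def span(self) -> float:
        """Window length in ps."""
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class FrequencySpectrum:
    """One-sided amplitude/phase spectrum of a trace.

    ``phase`` is unwrapped, continuous in frequency, and anchored so that its
    linear extrapolation to DC is within (-pi, pi] — phase offsets of whole
    turns carry no physics and would corrupt the refractive index.
    """

    freq: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray

    def interp(self, freq_new: np.ndarray) -> "FrequencySpectrum":
        """Linear interpolation of amplitude and phase onto a new grid."""
        freq_new = np.asarray(freq_new, dtype=float)
        if freq_new.min() < self.freq[0] or freq_new.max() > self.freq[-1]:
            raise InvalidGridError("requested grid outside the computed spectrum")
        return FrequencySpectrum(
            freq=freq_new,
            amplitude=np.interp(freq_new, self.freq, self.amplitude),
            phase=np.interp(freq_new, self.freq, self.phase),
        )


@dataclass(frozen=True)
class OpticalSpectrum:
    """Absorption coefficient and refractive index of one sample over a band."""

    freq: np.ndarray           # THz
    alpha: np.ndarray          # cm^-1
    n: np.ndarray              # dimensionless
    thickness_mm: float
    label: str | None = None
    sample_id: str | None = None


def _window(n: int, kind: str) -> np.ndarray:
    if kind == "rect":
        return np.ones(n)
    if kind == "hann":
        return np.hanning(n)
    raise ValueError(f"unknown window {kind!r}")


def to_frequency(
    trace: TimeTrace, window: str = "rect", pad_factor: int = 4
) -> FrequencySpectrum:
    """FFT a trace to an amplitude/phase spectrum.

    The trace is zero-padded to the next power of two at least ``pad_factor``
    times its length, which densifies the frequency grid for the later
    interpolation onto the analysis band.  Phase is ``-angle(FFT)`` (so that a
    pure delay adds a positive linear phase), unwrapped upward from the lowest
    non-DC bin, then shifted by a whole number of turns so its straight-line
    extrapolation through the DC gap lands near zero.
    """
    dt = trace.dt
    E = trace.E * _window(trace.E.size, window)
    nfft = 1 << max(int(np.ceil(np.log2(pad_factor * E.size))), 1)
    X = np.fft.rfft(E, nfft)
    freq = np.fft.rfftfreq(nfft, dt)  # t in ps -> f in THz

    amplitude = np.abs(X)
    phase = np.zeros_like(freq)
    # skip the DC bin: its angle is meaningless for a band-limited pulse
    phase[1:] = -np.unwrap(np.angle(X[1:]))
    phase[0] = phase[1]

    # anchor: fit phase vs freq where the spectrum carries energy, remove the
    # 2*pi multiple of the DC intercept
    peak = amplitude.max()
    if peak > 0:
        strong = amplitude > 0.1 * peak
        strong[0] = False
        if strong.sum() >= 2:
            slope, intercept = np.polyfit(freq[strong], phase[strong], 1)
            phase = phase - 2 * np.pi * np.round(intercept / (2 * np.pi))
    return FrequencySpectrum(freq=freq, amplitude=amplitude, phase=phase)


def average_scans(traces: Sequence[TimeTrace]) -> TimeTrace:
    """Pointwise mean of repeated scans sharing one time axis."""
    if len(traces) == 0:
        raise AxisMismatchError("no traces to average")
    t0 = traces[0].t
    for tr in traces[1:]:
        if tr.t.shape != t0.shape or not np.allclose(tr.t, t0, rtol=0, atol=1e-12):
            raise AxisMismatchError("traces do not share a time axis")
    E = np.mean([tr.E for tr in traces], axis=0)
    return TimeTrace(t=t0.copy(), E=E, role=traces[0].role)


def _shared_grid(ref: FrequencySpectrum, sam: FrequencySpectrum) -> np.ndarray:
    if ref.freq.shape != sam.freq.shape or not np.allclose(
        ref.freq, sam.freq, rtol=0, atol=1e-12
    ):
        raise AxisMismatchError("reference and sample spectra on different grids")
    return ref.freq


def extract_alpha(
    ref: FrequencySpectrum, sam: FrequencySpectrum, thickness_mm: float
) -> np.ndarray:
    """Absorption coefficient alpha = (1/d) ln(A_ref/A_sam) in cm^-1."""
    _shared_grid(ref, sam)
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    if np.any(ref.amplitude <= 0) or np.any(sam.amplitude <= 0):
        raise DegenerateAmplitudeError(
            "non-positive amplitude in band; cannot form log ratio"
        )
    d_cm = thickness_mm / 10.0
    return np.log(ref.amplitude / sam.amplitude) / d_cm


def extract_n(
    ref: FrequencySpectrum, sam: FrequencySpectrum, thickness_mm: float
) -> np.ndarray:
    """Refractive index n = 1 + (phi_sam - phi_ref) * c / (omega * d)."""
    freq = _shared_grid(ref, sam)
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    if np.any(freq <= 0):
        raise ZeroDivisionError("refractive index undefined at zero frequency")
    omega = 2 * np.pi * freq * 1e12  # rad/s
    d_m = thickness_mm * 1e-3
    return 1.0 + (sam.phase - ref.phase) * C_LIGHT / (omega * d_m)


def analysis_grid(
    lo: float = BAND_LO, hi: float = BAND_HI, step: float = GRID_STEP
) -> np.ndarray:
    """Uniform frequency grid over [lo, hi] inclusive."""
    nbins = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(nbins)


def extract_optical(
    ref: TimeTrace,
    sam: TimeTrace,
    thickness_mm: float,
    band: tuple[float, float] = (BAND_LO, BAND_HI),
    step: float = GRID_STEP,
    window: str = "rect",
    label: str | None = None,
    sample_id: str | None = None,
) -> OpticalSpectrum:
    """Full extraction: FFT both traces, interpolate to the analysis grid,
    compute alpha and n."""
    grid = analysis_grid(band[0], band[1], step)
    rspec = to_frequency(ref, window=window).interp(grid)
    sspec = to_frequency(sam, window=window).interp(grid)
    return OpticalSpectrum(
        freq=grid,
        alpha=extract_alpha(rspec, sspec, thickness_mm),
        n=extract_n(rspec, sspec, thickness_mm),
        thickness_mm=thickness_mm,
        label=label,
        sample_id=sample_id,
    )


def restrict_band(
    spec: OpticalSpectrum, lo: float, hi: float
) -> OpticalSpectrum:
    """Keep only bins with lo <= f <= hi (closed on both ends)."""
    if lo >= hi:
        raise EmptyBandError("band lower edge must be below upper edge")
    keep = (spec.freq >= lo) & (spec.freq <= hi)
    if not keep.any():
        raise EmptyBandError(f"no bins inside [{lo}, {hi}] THz")
    return replace(
        spec, freq=spec.freq[keep], alpha=spec.alpha[keep], n=spec.n[keep]
    )
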