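"""Class-conditional synthetic THz-TDS data for the wheat-quality pipeline.

No public archive of grain THz spectra exists, so the pipeline is exercised on
simulated measurements built from a physical slab transmission model.  Each
virtual wheat pellet is a homogeneous slab with a frequency-dependent
refractive index and a smooth, featureless absorption curve that rises with
frequency — the shapes reported for milled grain pellets, which show no sharp
resonances in the 0.2–1.6 THz band.  Four quality classes are emulated
(normal, germinated, moldy, worm-eaten) with the class ordering of the
refractive level

    n_worm-eaten < n_moldy < n_germinated < n_normal,   all within 1.50–1.56,

and per-class absorption levels ordered the same way (normal most absorbing).
Sample-to-sample biological variability perturbs each pellet's (n, alpha_base)
around the class mean; each pellet is then "measured" with 5 replicate scans
carrying additive white field noise, mirroring the 5-scan averaging protocol
of a real measurement session.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidGridError, InvalidSpecError, WindowOverflowError
from .optics import BAND_HI, BAND_LO, C_LIGHT, TimeTrace

#: fixed class order used everywhere downstream (confusion matrices, masses)
CLASS_ORDER = ("normal", "germinated", "moldy", "worm-eaten")

#: required ordering of the class refractive levels, weakest to strongest
N_ORDER = ("worm-eaten", "moldy", "germinated", "normal")


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time axis specification for simulated scans.

    Defaults give a 40 ps window at 0.02 ps step: frequency resolution
    1/40 ps = 0.025 THz (below the required 0.05 THz) and a Nyquist frequency
    of 25 THz, far above the 1.6 THz band edge.
    """

    span_ps: float = 40.0
    dt_ps: float = 0.02
    t0_ps: float = 8.0

    def axis(self) -> np.ndarray:
        n = int(round(self.span_ps / self.dt_ps)) + 1
        return self.dt_ps * np.arange(n)


@dataclass(frozen=True)
class SlabMaterial:
    """Homogeneous slab: n and alpha as functions of frequency (THz)."""

    n_of: Callable[[np.ndarray], np.ndarray]
    alpha_of: Callable[[np.ndarray], np.ndarray]  # cm^-1
    thickness_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise InvalidSpecError("slab thickness must be positive")


def constant_material(
    n0: float, alpha0: float, thickness_mm: float = 1.0
) -> SlabMaterial:
    """Slab with frequency-independent optical constants."""
    return SlabMaterial(
        n_of=lambda f: np.full_like(np.asarray(f, dtype=float), n0),
        alpha_of=lambda f: np.full_like(np.asarray(f, dtype=float), alpha0),
        thickness_mm=thickness_mm,
    )


@dataclass(frozen=True)
class ClassSpecification:
    """Distribution of slab parameters for one wheat quality class.

    Parameters
    ----------
    label : str
        One of :data:`CLASS_ORDER`.
    n_mean : float
        Class mean refractive level (dimensionless), inside [1.50, 1.56].
    n_slope : float
        Mild linear decrease of n with frequency (per THz); real pellet
        spectra are near-flat with a slight plateau, so this is small.
    alpha_base, alpha_slope : float
        Absorption curve alpha(f) = alpha_base + alpha_slope * f, in cm^-1
        and cm^-1/THz: smooth, monotone, no resonant peaks.
    noise_sd_n, noise_sd_alpha : float
        Between-sample standard deviations of n_mean and alpha_base.
    noise_sd_alpha_slope, noise_sd_curv, noise_sd_n_slope : float
        Between-sample spread of the absorption slope, of a smooth quadratic
        shape term alpha_curv * (f - f_mid)^2, and of the refractive-index
        slope.  Real pellet spectra vary in shape as well as level (packing
        density, grain size), so several principal components carry
        sample-specific structure rather than pure measurement noise.
    rho_n_alpha : float
        Correlation between a pellet's refractive level and absorption level.
        Sound wheat is compositionally homogeneous (rho ~ 0); degradation
        processes couple density and absorbance — mold growth raises water
        and biomass content together (rho > 0) while insect feeding hollows
        kernels so that residual density and absorbance decouple in the
        opposite sense (rho < 0).  This covariance orientation, not the class
        means, is what distinguishes the two defect classes in the region
        where their level distributions overlap.
    scan_noise_sd : float
        Within-scan additive white field noise, in units of the unit-peak
        reference pulse.
    """

    label: str
    n_mean: float
    alpha_base: float
    alpha_slope: float
    n_slope: float = 0.002
    noise_sd_n: float = 0.004
    noise_sd_alpha: float = 0.3
    noise_sd_alpha_slope: float = 0.2
    noise_sd_curv: float = 0.3
    noise_sd_n_slope: float = 0.002
    rho_n_alpha: float = 0.0
    #: correlation between a pellet's refractive level and the slope of its
    #: index curve: degradation that densifies a kernel also flattens or
    #: steepens its dispersion, with opposite sign for the two defect
    #: mechanisms.  A within-modality orientation cue.
    rho_n_nslope: float = 0.0
    scan_noise_sd: float = 0.002

    def __post_init__(self) -> None:
        if self.label not in CLASS_ORDER:
            raise InvalidSpecError(f"unknown class label {self.label!r}")
        for name in (
            "noise_sd_n",
            "noise_sd_alpha",
            "noise_sd_alpha_slope",
            "noise_sd_curv",
            "noise_sd_n_slope",
            "scan_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")
        for name in ("rho_n_alpha", "rho_n_nslope"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise InvalidSpecError(f"{name} must lie in [-1, 1]")

    def material(
        self, rng: np.random.Generator, thickness_mm: float
    ) -> SlabMaterial:
        """Draw one pellet from the class distribution."""
        z_n, z_a, z_s = rng.normal(0.0, 1.0, 3)
        rho_a, rho_s = self.rho_n_alpha, self.rho_n_nslope
        z_a = rho_a * z_n + np.sqrt(1.0 - rho_a * rho_a) * z_a
        z_s = rho_s * z_n + np.sqrt(1.0 - rho_s * rho_s) * z_s
        n0 = self.n_mean + self.noise_sd_n * z_n
        a0 = self.alpha_base + self.noise_sd_alpha * z_a
        slope_a = self.alpha_slope + rng.normal(0.0, self.noise_sd_alpha_slope)
        curv = rng.normal(0.0, self.noise_sd_curv)
        slope_n = self.n_slope + self.noise_sd_n_slope * z_s
        f_mid = 0.5 * (BAND_LO + BAND_HI)

        def n_of(f: np.ndarray) -> np.ndarray:
            return np.maximum(1.0, n0 - slope_n * (np.asarray(f) - f_mid))

        def alpha_of(f: np.ndarray) -> np.ndarray:
            f = np.asarray(f)
            return np.maximum(
                0.0, a0 + slope_a * f + curv * (f - f_mid) ** 2
            )

        return SlabMaterial(
            n_of=n_of, alpha_of=alpha_of, thickness_mm=thickness_mm
        )


#: default per-class parameters.  Refractive levels span the reported
#: 1.50–1.56 window with the reported class ordering; absorption levels are
#: ordered the same way (normal wheat most absorbing), with band-averaged
#: magnitudes in the mid-teens of cm^-1 typical for 1 mm grain pellets.
#: The two defect classes overlap substantially in both level distributions
#: but differ in the sign of the density-absorbance coupling (rho_n_alpha),
#: and are more variable than sound wheat, reflecting heterogeneous
#: degradation severity.
DEFAULT_CLASS_PARAMS: dict[str, dict[str, float]] = {
    "normal": {
        "n_mean": 1.5500, "alpha_base": 8.5, "alpha_slope": 11.0,
        "noise_sd_n": 0.004, "noise_sd_alpha": 0.30,
    },
    "germinated": {
        "n_mean": 1.5350, "alpha_base": 7.2, "alpha_slope": 10.5,
        "noise_sd_n": 0.0045, "noise_sd_alpha": 0.35,
    },
    "moldy": {
        "n_mean": 1.5210, "alpha_base": 6.1, "alpha_slope": 9.9,
        "noise_sd_n": 0.005, "noise_sd_alpha": 0.65,
        "rho_n_alpha": 0.98, "rho_n_nslope": 0.95, "noise_sd_n_slope": 0.005,
    },
    "worm-eaten": {
        "n_mean": 1.5090, "alpha_base": 6.2, "alpha_slope": 10.1,
        "noise_sd_n": 0.005, "noise_sd_alpha": 0.65,
        "rho_n_alpha": -0.98, "rho_n_nslope": -0.95, "noise_sd_n_slope": 0.005,
    },
}


def default_class_specs(
    overrides: dict[str, dict[str, float]] | None = None,
) -> list[ClassSpecification]:
    """The four default class specifications, optionally overridden per field."""
    specs = []
    for label in CLASS_ORDER:
        params = dict(DEFAULT_CLASS_PARAMS[label])
        if overrides and label in overrides:
            params.update(overrides[label])
        specs.append(ClassSpecification(label=label, **params))
    return specs


def validate_class_ordering(specs: Sequence[ClassSpecification]) -> None:
    """Enforce n_worm-eaten < n_moldy < n_germinated < n_normal."""
    by_label = {s.label: s for s in specs}
    if set(by_label) != set(CLASS_ORDER):
        raise InvalidSpecError(
            f"specs must cover exactly the classes {CLASS_ORDER}"
        )
    levels = [by_label[lbl].n_mean for lbl in N_ORDER]
    if not all(a < b for a, b in zip(levels, levels[1:])):
        raise InvalidSpecError(
            "class refractive levels must be ordered "
            "worm-eaten < moldy < germinated < normal"
        )


# ---------------------------------------------------------------------------
# reference pulse and slab propagation
# ---------------------------------------------------------------------------

#: pulse width parameter, ps.  Peak of the amplitude spectrum of a
#: differentiated Gaussian sits at f = 1/(2*pi*tau) = 0.6 THz, centering the
#: emitted energy in the analysis band.
PULSE_TAU_PS = 1.0 / (2.0 * np.pi * 0.6)


def make_reference_pulse(
    grid: TimeGrid | None = None, tau_ps: float = PULSE_TAU_PS
) -> TimeTrace:
    """Single-cycle reference pulse (differentiated Gaussian), peak amplitude 1.

    The differentiated Gaussian E(t) ∝ -(t-t0) exp(-(t-t0)^2 / (2 tau^2)) is
    the standard far-field model of a photoconductive THz emitter; its
    amplitude spectrum |omega| exp(-omega^2 tau^2 / 2) is smooth and nonzero
    across the whole 0.2–1.6 THz band for the default tau.
    """
    grid = grid or TimeGrid()
    if grid.span_ps <= 0 or grid.dt_ps <= 0:
        raise InvalidGridError("span and step must be positive")
    if 1.0 / grid.span_ps > 0.05:
        raise InvalidGridError(
            "time span too short: frequency resolution exceeds 0.05 THz"
        )
    if 1.0 / (2.0 * grid.dt_ps) < BAND_HI:
        raise InvalidGridError("time step too coarse: Nyquist below band edge")
    if not (5 * tau_ps < grid.t0_ps < grid.span_ps - 5 * tau_ps):
        raise InvalidGridError("pulse center too close to the window edge")
    t = grid.axis()
    x = (t - grid.t0_ps) / tau_ps
    E = -x * np.exp(-0.5 * x * x)
    E /= np.abs(E).max()  # peak sampled amplitude exactly 1
    return TimeTrace(t=t, E=E, role="reference")


def forward_transmit(pulse: TimeTrace, material: SlabMaterial) -> TimeTrace:
    """Propagate a pulse through a slab.

    In the frequency domain the slab multiplies the field by

        H(f) = exp(-alpha(f) * d) * exp(-i * omega * (n(f) - 1) * d / c)

    i.e. field-amplitude attenuation consistent with the extraction formula
    alpha = (1/d) ln(A_ref/A_sam), and a phase delay (n-1) d / c relative to
    the same path in vacuum.  The inverse operation is
    :func:`thzwheat.optics.extract_optical`.
    """
    dt = pulse.dt
    n_samp = pulse.E.size
    freq = np.fft.rfftfreq(n_samp, dt)  # THz
    n_arr = np.asarray(material.n_of(freq), dtype=float)
    a_arr = np.asarray(material.alpha_of(freq), dtype=float)
    if np.any(n_arr < 1.0):
        raise InvalidSpecError("refractive index profile must be >= 1")
    if np.any(a_arr < 0.0):
        raise InvalidSpecError("absorption profile must be >= 0")

    d_cm = material.thickness_mm / 10.0
    d_m = material.thickness_mm * 1e-3
    delay_ps = (n_arr - 1.0) * d_m / C_LIGHT * 1e12
    # overflow check: pulse tail plus slab delay must stay inside the window
    peak = np.abs(pulse.E).max()
    if peak > 0:
        tail_idx = np.nonzero(np.abs(pulse.E) > 1e-6 * peak)[0][-1]
        if pulse.t[tail_idx] + delay_ps.max() > pulse.t[-1]:
            raise WindowOverflowError(
                "slab delay pushes the pulse outside the time window"
            )

    omega = 2 * np.pi * freq * 1e12  # rad/s
    H = np.exp(-a_arr * d_cm) * np.exp(-1j * omega * (n_arr - 1.0) * d_m / C_LIGHT)
    E_out = np.fft.irfft(np.fft.rfft(pulse.E) * H, n_samp)
    return TimeTrace(t=pulse.t.copy(), E=E_out, role="sample")


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleScans:
    """All replicate scans of one pellet: (reference, sample) trace pairs."""

    sample_id: str
    label: str
    scans: tuple[tuple[TimeTrace, TimeTrace], ...]


@dataclass(frozen=True)
class SyntheticDataset:
    samples: tuple[SampleScans, ...]
    seed: int
    grid: TimeGrid
    thickness_mm: float

    def labels(self) -> list[str]:
        return [s.label for s in self.samples]


def generate_dataset(
    specs: Sequence[ClassSpecification] | None = None,
    n_per_class: int = 60,
    seed: int = 0,
    grid: TimeGrid | None = None,
    thickness_mm: float = 1.0,
    n_scans: int = 5,
) -> SyntheticDataset:
    """Generate a full class-balanced dataset of replicate scan pairs.

    Deterministic given ``seed``.  Default sizes mirror the measurement
    campaign the pipeline emulates: 60 pellets per class (240 total), each
    scanned 5 times.
    """
    specs = list(specs) if specs is not None else default_class_specs()
    validate_class_ordering(specs)
    if n_per_class < 1:
        raise InvalidSpecError("n_per_class must be >= 1")
    grid = grid or TimeGrid()
    rng = np.random.default_rng(seed)
    pulse = make_reference_pulse(grid)
    by_label = {s.label: s for s in specs}

    samples: list[SampleScans] = []
    for label in CLASS_ORDER:
        spec = by_label[label]
        for i in range(n_per_class):
            material = spec.material(rng, thickness_mm)
            clean_sam = forward_transmit(pulse, material)
            scans = []
            for _ in range(n_scans):
                ref = TimeTrace(
                    t=pulse.t,
                    E=pulse.E + rng.normal(0, spec.scan_noise_sd, pulse.E.size),
                    role="reference",
                )
                sam = TimeTrace(
                    t=pulse.t,
                    E=clean_sam.E
                    + rng.normal(0, spec.scan_noise_sd, clean_sam.E.size),
                    role="sample",
                )
                scans.append((ref, sam))
            samples.append(
                SampleScans(
                    sample_id=f"{label}-{i:03d}",
                    label=label,
                    scans=tuple(scans),
                )
            )
    return SyntheticDataset(
        samples=tuple(samples),
        seed=seed,
        grid=grid,
        thickness_mm=thickness_mm,
    )


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Write traces as two-column text plus a manifest and metadata JSON."""
    outdir = Path(outdir)
    traces = outdir / "traces"
    traces.mkdir(parents=True, exist_ok=True)
    rows = []
    for samp in dataset.samples:
        for k, (ref, sam) in enumerate(samp.scans):
            ref_path = traces / f"{samp.sample_id}_scan{k}_ref.txt"
            sam_path = traces / f"{samp.sample_id}_scan{k}_sam.txt"
            np.savetxt(ref_path, np.column_stack([ref.t, ref.E]), fmt="%.8g")
            np.savetxt(sam_path, np.column_stack([sam.t, sam.E]), fmt="%.8g")
            rows.append(
                {
                    "sample_id": samp.sample_id,
                    "label": samp.label,
                    "scan": k,
                    "ref_path": str(ref_path.relative_to(outdir)),
                    "sam_path": str(sam_path.relative_to(outdir)),
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    meta = {
        "seed": dataset.seed,
        "thickness_mm": dataset.thickness_mm,
        "grid": {
            "span_ps": dataset.grid.span_ps,
            "dt_ps": dataset.grid.dt_ps,
            "t0_ps": dataset.grid.t0_ps,
        },
        "n_samples": len(dataset.samples),
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2))
    return outdir


def read_dataset(indir: str | Path) -> SyntheticDataset:
    """Reload a dataset written by :func:`write_dataset`."""
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    manifest = pd.read_csv(indir / "manifest.csv")
    grid = TimeGrid(**meta["grid"])
    samples = []
    for sample_id, group in manifest.groupby("sample_id", sort=False):
        scans = []
        for _, row in group.sort_values("scan").iterrows():
            rt = np.loadtxt(indir / row["ref_path"])
            st = np.loadtxt(indir / row["sam_path"])
            scans.append(
                (
                    TimeTrace(t=rt[:, 0], E=rt[:, 1], role="reference"),
                    TimeTrace(t=st[:, 0], E=st[:, 1], role="sample"),
                )
            )
        samples.append(
            SampleScans(
                sample_id=str(sample_id),
                label=str(group["label"].iloc[0]),
                scans=tuple(scans),
            )
        )
    return SyntheticDataset(
        samples=tuple(samples),
        seed=int(meta["seed"]),
        grid=grid,
        thickness_mm=float(meta["thickness_mm"]),
    )
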