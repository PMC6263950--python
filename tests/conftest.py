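import numpy as np
import pytest

from thzwheat import optics, synthetic


@pytest.fixture(scope="session")
def reference_pulse():
    return synthetic.make_reference_pulse()


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny but class-complete dataset: 6 pellets per class, 5 scans each."""
    return synthetic.generate_dataset(n_per_class=6, seed=11)


@pytest.fixture(scope="session")
def small_spectra(small_dataset):
    out = []
    for samp in small_dataset.samples:
        ref = optics.average_scans([p[0] for p in samp.scans])
        sam = optics.average_scans([p[1] for p in samp.scans])
        out.append(
            optics.extract_optical(
                ref, sam, small_dataset.thickness_mm,
                label=samp.label, sample_id=samp.sample_id,
            )
        )
    return out


def random_spectra(n, n_bins=25, seed=0, label=None):
    """Synthetic OpticalSpectrum collection with smooth random variation,
    for feature-module tests that need no physics."""
    rng = np.random.default_rng(seed)
    freq = np.linspace(0.2, 1.6, n_bins)
    out = []
    for i in range(n):
        a0, a1 = rng.normal(12, 1), rng.normal(8, 0.5)
        n0 = rng.normal(1.53, 0.01)
        out.append(
            optics.OpticalSpectrum(
                freq=freq,
                alpha=a0 + a1 * freq + rng.normal(0, 0.05, n_bins),
                n=n0 + rng.normal(0, 0.001, n_bins),
                thickness_mm=1.0,
                label=label,
                sample_id=f"s{i:03d}",
            )
        )
    return out
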