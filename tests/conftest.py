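import numpy as np
import pytest

from chemocart.io import Spectrum
from chemocart.simulate import GeneratorConfig


def make_spectrum(
    spectrum_id: str = "s",
    precursor: float = 500.0,
    peaks=None,
    sample_id: str = "",
    **kwargs,
) -> Spectrum:
    if peaks is None:
        peaks = [[100.0, 1.0], [200.0, 2.0], [300.0, 3.0]]
    return Spectrum(
        spectrum_id=spectrum_id,
        sample_id=sample_id,
        precursor_mz=precursor,
        peaks=np.asarray(peaks, dtype=float),
        **kwargs,
    )


def random_spectrum(rng: np.random.Generator, n_peaks: int = 20, precursor: float | None = None) -> Spectrum:
    """Random spectrum with peaks separated by > 1 Da (no matching conflicts
    at 0.5 Da tolerance)."""
    if precursor is None:
        precursor = float(rng.uniform(400, 1200))
    grid = np.arange(100.0, precursor - 25.0, 2.0)
    n = min(n_peaks, len(grid))
    mz = np.sort(rng.choice(grid, size=n, replace=False)) + rng.uniform(0, 0.4, size=n)
    intensity = rng.lognormal(0, 1, size=n)
    return make_spectrum(f"r{rng.integers(1e9)}", precursor, np.column_stack([mz, intensity]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture
def small_config() -> GeneratorConfig:
    """Desk-scale study conditions: fewer scaffolds for fast unit tests."""
    return GeneratorConfig(n_scaffolds=6, samples_per_site=1, rng_seed=7)


@pytest.fixture
def default_config() -> GeneratorConfig:
    """The default synthetic study conditions (20 scaffolds, Poisson-3 analogs)."""
    return GeneratorConfig(rng_seed=42)
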