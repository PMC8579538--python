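import numpy as np
import pytest

from ftirprint.spectra_io import SampleMeta, SpectralDataset, WavenumberGrid
from ftirprint.synthetic_data import SynthConfig, generate_dataset


@pytest.fixture
def full_grid():
    """4000 -> 400 cm^-1 at 4 cm^-1 spacing (descending)."""
    return WavenumberGrid(np.arange(4000.0, 399.0, -4.0))


@pytest.fixture
def small_dataset():
    """Three labeled spectra on a short descending grid."""
    grid = WavenumberGrid(np.arange(1800.0, 899.0, -4.0))
    rng = np.random.default_rng(42)
    meta = [
        SampleMeta("SRC", 1, "New", "upper", 1),
        SampleMeta("EDB", 2, "Height", "lower", 3),
        SampleMeta("ESA", 3, "Mature", "upper", 10),
    ]
    return SpectralDataset(
        grid=grid,
        absorbance=rng.normal(0.5, 0.1, size=(3, len(grid))),
        meta=meta,
    )


@pytest.fixture(scope="session")
def tiny_design_dataset():
    """Reduced factorial design (faster than 1260 spectra) with no effects."""
    cfg = SynthConfig(replicates_per_side=2, seed=7)
    ds, truth = generate_dataset(cfg)
    return ds, truth
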