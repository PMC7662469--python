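import numpy as np
import pandas as pd
import pytest

from soyspec import SpectraSet, WavelengthGrid, make_study_fixture

FIXTURE_SEED = 1


def make_spectra(n_samples=6, n_wavelengths=40, replicates=1, seed=0,
                 labels=None, lo=1350.0, spacing=8.0):
    """Small random SpectraSet for unit tests."""
    rng = np.random.default_rng(seed)
    grid = WavelengthGrid(lo + spacing * np.arange(n_wavelengths))
    n = n_samples * replicates
    A = rng.normal(0.5, 0.1, (n, n_wavelengths))
    meta = pd.DataFrame({
        "sample_id": np.repeat([f"s{i}" for i in range(n_samples)], replicates),
        "replicate_id": np.tile(np.arange(1, replicates + 1), n_samples),
        "class_label": (np.repeat(labels, replicates)
                        if labels is not None else [None] * n),
    })
    return SpectraSet(grid, A, meta)


@pytest.fixture(scope="session")
def study_fixture():
    """The default emulated study (122 samples x 3 replicate scans)."""
    return make_study_fixture(FIXTURE_SEED)


@pytest.fixture
def small_spectra():
    return make_spectra()
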