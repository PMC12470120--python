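import dataclasses

import numpy as np
import pytest

from salivaraman import SyntheticCohortConfig, analyze_cohort, generate_cohort
from salivaraman.preprocess import PreprocessConfig
from salivaraman.spectra_io import RamanSpectrum


def desk_config(**overrides) -> SyntheticCohortConfig:
    """A small-but-representative generator config for fast tests."""
    defaults = dict(n_osas=12, n_ctr=10, replicates_per_subject=3, seed=7)
    defaults.update(overrides)
    return SyntheticCohortConfig(**defaults)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort under the study's default conditions."""
    return generate_cohort(SyntheticCohortConfig(seed=11))


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    """Full pipeline output on the default cohort (computed once)."""
    return analyze_cohort(default_cohort)


@pytest.fixture
def grid_spectrum():
    """A clean spectrum on the default common grid (resampled stage)."""
    cfg = PreprocessConfig()
    grid = cfg.grid
    y = np.exp(-0.5 * ((grid - 1003.0) / 4.0) ** 2)
    return RamanSpectrum(grid, y, subject_id="S1", stage="resampled")


def make_spectrum(wavenumbers, intensities, **kw):
    return RamanSpectrum(np.asarray(wavenumbers, float),
                         np.asarray(intensities, float), **kw)
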