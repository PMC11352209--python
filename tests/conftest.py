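import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

from sersdx import (
    GridSpec,
    PreprocessConfig,
    SimulationConfig,
    SpectrumDataset,
    preprocess_dataset,
    simulate,
)
from sersdx.simulate import PeakSpec

# Coarse grid used by model-level tests: same spectral range, 5 cm^-1
# spacing, so peaks are still resolved but training is fast.
COARSE_GRID = GridSpec(300.0, 2000.0, 5.0)
COARSE_PREPROCESS = PreprocessConfig()

#: a small CNN architecture for tests (full default is exercised in the
#: acceptance suite on the full cohort)
SMALL_CNN = dict(conv_blocks=[(8, 7), (16, 7)], fc_sizes=[32])


def make_tiny_dataset(n_channels: int = 10, seed: int = 0) -> SpectrumDataset:
    """4 spectra / 2 samples / 2 patients / both classes, deterministic."""
    rng = np.random.default_rng(seed)
    shifts = 300.0 + 10.0 * np.arange(n_channels)
    intensities = rng.uniform(0.5, 2.0, size=(4, n_channels))
    manifest = pd.DataFrame(
        {
            "spectrum_id": ["s0", "s1", "s2", "s3"],
            "sample_id": ["A", "A", "B", "B"],
            "patient_id": ["p0", "p0", "p1", "p1"],
            "class_label": ["benign", "benign", "malignant", "malignant"],
        }
    )
    return SpectrumDataset(shifts, intensities, manifest)


def small_cohort_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Reduced cohort on the coarse grid for fast model tests."""
    params = dict(
        n_patients=8,
        spectra_per_sample=12,
        grid=COARSE_GRID,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def separated_cohort_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Strongly separated regime: large effect, small hierarchical noise."""
    params = dict(
        effect_scale=4.0,
        sigma_patient=0.02,
        sigma_sample=0.02,
        sigma_noise=0.01,
    )
    params.update(overrides)
    return small_cohort_config(seed, **params)


@pytest.fixture(scope="session")
def tiny_dataset() -> SpectrumDataset:
    return make_tiny_dataset()


@pytest.fixture(scope="session")
def small_processed_cohort() -> SpectrumDataset:
    """Preprocessed small default-regime cohort shared across model tests."""
    return preprocess_dataset(simulate(small_cohort_config(seed=42)))


@pytest.fixture(scope="session")
def separated_processed_cohort() -> SpectrumDataset:
    return preprocess_dataset(simulate(separated_cohort_config(seed=7)))
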