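"""Shared synthetic fixtures.

All are generated programmatically with fixed seeds; sizes are scaled down
from the full study design so the suite runs quickly while keeping the
statistical structure (dominant peak, group heterogeneity, retention
shifts) every stage needs.
"""

import numpy as np
import pytest

from chromalink import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def masking_config() -> SynthConfig:
    """Dominant-peak regime, no retention shift: the fixture on which a root
    transform should unmask the group structure."""
    return SynthConfig(
        n_groups=8,
        samples_per_group=6,
        n_points=1200,
        n_peaks=25,
        shift_sd=0.0,
        inter_sd=0.4,
        intra_sd=0.12,
        seed=11,
    )


@pytest.fixture(scope="session")
def masking_set(masking_config):
    return generate_dataset(masking_config)


@pytest.fixture(scope="session")
def shifted_config() -> SynthConfig:
    """Retention shifts large enough that alignment visibly helps."""
    return SynthConfig(
        n_groups=3,
        samples_per_group=4,
        n_points=800,
        n_peaks=15,
        shift_sd=4.0,
        seed=2,
    )


@pytest.fixture(scope="session")
def shifted_set(shifted_config):
    return generate_dataset(shifted_config)


@pytest.fixture(scope="session")
def small_set():
    """Cheap all-purpose labelled set (3 groups × 4 samples, 400 points)."""
    return generate_dataset(
        SynthConfig(
            n_groups=3, samples_per_group=4, n_points=400, n_peaks=12, seed=1
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
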