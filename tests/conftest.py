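import numpy as np
import pytest

from aseqpcr.simulate import SimulationConfig


@pytest.fixture
def noiseless_config() -> SimulationConfig:
    """Perfect-doubling, zero-noise, zero-bias measurement model."""
    return SimulationConfig(
        seed=0, efficiency=1.0, dye_bias=0.0, noise_sd=0.0, baseline_ct=30.0
    )


@pytest.fixture
def assay_info() -> dict:
    return {
        "assay_id": "ASSAY01",
        "gene": "GENE1",
        "risk_allele": "A",
        "fam_allele": "A",
        "vic_allele": "B",
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
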