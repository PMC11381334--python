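from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pals.design import DesignConstraints, assemble_barcodes, enumerate_cores, filter_proline

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

# Mature human erythropoietin (166 aa; UniProt P01588 residues 28-193),
# the secreted carrier protein used for serum-based barcode screens.
HEPO_MATURE = (
    "APPRLICDSRVLERYLLEAKEAENITTGCAEHCSLNENITVPDTKVNFYAWKRMEVGQQAVEVWQGLA"
    "LLSEAVLRGQALLVNSSQPWEPLQLHVDKAVSGLRSLTTLLRALGAQKEAISPPDAASAAPLRTITAD"
    "TFRKLFRVYSNFLRGKLKLYTGEACRTGDR"
)


@pytest.fixture(scope="session")
def hepo_sequence() -> str:
    return HEPO_MATURE


@pytest.fixture(scope="session")
def default_constraints() -> DesignConstraints:
    return DesignConstraints()


@pytest.fixture(scope="session")
def default_candidates(default_constraints):
    """All 50,000 assembled candidates of the default cascade (session-shared)."""
    cores = filter_proline(enumerate_cores(default_constraints), default_constraints)
    return assemble_barcodes(cores, default_constraints)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
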