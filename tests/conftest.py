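import numpy as np
import pytest

from blrkit import BarcodeDesign, SimConfig, simulate_library

#: small library with default (1% barcode, 0.2% insert) error rates
SMALL = SimConfig(
    genome_length=200_000,
    n_chromosomes=2,
    n_droplets=100,
    fragments_per_droplet_mean=2.0,
    barcodes_per_droplet_mean=2.0,
    rng_seed=7,
)

#: same library without sequencing errors
SMALL_CLEAN = SimConfig(
    genome_length=200_000,
    n_chromosomes=2,
    n_droplets=100,
    fragments_per_droplet_mean=2.0,
    barcodes_per_droplet_mean=2.0,
    barcode_error_rate=0.0,
    insert_error_rate=0.0,
    rng_seed=7,
)


@pytest.fixture(scope="session")
def design():
    return BarcodeDesign()


@pytest.fixture(scope="session")
def small_lib():
    return simulate_library(SMALL)


@pytest.fixture(scope="session")
def clean_lib():
    return simulate_library(SMALL_CLEAN)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
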