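import numpy as np
import pandas as pd
import pytest

from oncomap import synthetic
from oncomap.mutsig import CHANNELS, SignatureCatalog


@pytest.fixture(scope="session")
def small_genome():
    return synthetic.GenomeSpec(chrom_lengths={"chr1": 60_000}, bin_size=1_000)


@pytest.fixture(scope="session")
def small_reference(small_genome):
    return synthetic.generate_reference(small_genome, seed=11)


@pytest.fixture(scope="session")
def catalog():
    return synthetic.default_catalog(n_signatures=4, seed=12345)


@pytest.fixture(scope="session")
def orthogonal_catalog():
    """Three signatures with disjoint channel support (exactly orthogonal)."""
    profiles = np.zeros((3, 96))
    profiles[0, 0:32] = 1 / 32
    profiles[1, 32:64] = 1 / 32
    profiles[2, 64:96] = 1 / 32
    return SignatureCatalog(
        profiles=pd.DataFrame(profiles, index=["S1", "S2", "S3"], columns=list(CHANNELS))
    )


@pytest.fixture(scope="session")
def small_cohort(small_genome, small_reference, catalog):
    spec = synthetic.CohortSpec(
        n_samples=20,
        benign_fraction=0.25,
        driver_freqs={"PIK3CA": (0.55, 0.38), "TP53": (0.0, 0.2)},
        signature_weights=(0.7, 0.1, 0.1, 0.1),
        tmb_rate=30,
        seed=7,
    )
    variants, metadata = synthetic.generate_mutation_cohort(
        spec, small_genome, small_reference, catalog
    )
    return spec, variants, metadata
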