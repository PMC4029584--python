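import numpy as np
import pytest

from haplocn import decoder, simulator
from haplocn.emission_models import seed_bank
from haplocn.signal_io import SeedClusters


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-sample, 300-SNP cohort with implanted events."""
    return simulator.simulate_cohort(simulator.SimConfig(n_diploids=20, n_snps=300, seed=1))


@pytest.fixture(scope="session")
def small_result(small_cohort):
    return decoder.run_pipeline(small_cohort.signals, small_cohort.genotypes, small_cohort.seeds)


def make_seeds(L=1, spacing=1.0, sd=0.2):
    """Seed clusters on the unit-per-copy grid with isotropic noise."""
    anchors = np.array([[2 * spacing, 0.0], [spacing, spacing], [0.0, 2 * spacing]])
    cov = sd * sd * np.eye(2)
    return SeedClusters(
        np.broadcast_to(anchors, (L, 3, 2)).copy(),
        np.broadcast_to(cov, (L, 3, 2, 2)).copy(),
    )


@pytest.fixture()
def unit_bank():
    """Model bank of one SNP on the unit-per-copy grid."""
    return seed_bank(make_seeds(1))
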