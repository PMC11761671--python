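import numpy as np
import pytest

from dupliscan.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured simulated cohort shared across tests."""
    cfg = SimConfig(
        n_families=6,
        n_background_genes=60,
        spacer_min=8_000,
        spacer_max=20_000,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(n: int, rng) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
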