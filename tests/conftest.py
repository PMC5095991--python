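import pytest

import seqblup as sb


@pytest.fixture(scope="session")
def two_breed_data():
    """A small two-population dataset reused across modules: one Holstein-like
    population and one diverged population, 600 markers, 8 off-array QTL."""
    breeds = [
        sb.BreedSpec("A", 150, 40, 0.02, 10, holstein_like=True),
        sb.BreedSpec("B", 120, 30, 0.10, 10),
    ]
    config = sb.SimulationConfig(breeds=breeds, n_markers=600, n_qtl=8)
    dataset, arch, phenos = sb.simulate_dataset(config, seed=11)
    return config, dataset, arch, phenos


@pytest.fixture(scope="session")
def two_breed_split(two_breed_data):
    config, dataset, arch, phenos = two_breed_data
    frac = {b.name: b.n_validation / b.n_animals for b in config.breeds}
    return sb.split_train_validation(phenos, frac)
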