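import numpy as np
import pytest

from tpsfam.simulate import FamilySpec, SyntheticGenome, assemble_genome


def small_family_spec(seed: int = 11) -> FamilySpec:
    """A reduced family for fast end-to-end tests: 14 functional + 8 pseudo."""
    return FamilySpec(
        seed=seed,
        subfamily_counts={"tps-a": 6, "tps-b": 4, "tps-c": 1, "tps-ef": 1, "tps-g": 2},
        n_pseudogenes=8,
        cluster_sizes=(3, 2, 2),
        n_unplaced=5,
        n_tandem_paralog_pairs=1,
        n_cross_paralog_pairs=0,
        tissue_specific_counts={"leaf": 2, "flower": 1, "fruit": 1},
        n_high_expression=2,
        n_low_expression=2,
    )


@pytest.fixture(scope="session")
def small_genome() -> SyntheticGenome:
    return assemble_genome(small_family_spec())


@pytest.fixture(scope="session")
def default_genome() -> SyntheticGenome:
    """The full-size default family (the published family shape)."""
    return assemble_genome(FamilySpec(seed=101))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
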