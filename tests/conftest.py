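import numpy as np
import pytest

from huihf import seq_core as sc
from huihf import synthetic_data as sd


@pytest.fixture(scope="session")
def hu_alpha() -> sc.CoreAlignedSequence:
    return sc.CoreAlignedSequence.from_parts(
        "EcHUalpha", sd.HU_ALPHA_ECOLI, organism="Escherichia coli",
        group="HU", clade="HU_ecoA",
    )


@pytest.fixture(scope="session")
def hu_beta() -> sc.CoreAlignedSequence:
    return sc.CoreAlignedSequence.from_parts(
        "EcHUbeta", sd.HU_BETA_ECOLI, organism="Escherichia coli",
        group="HU", clade="HU_ecoB",
    )


@pytest.fixture(scope="session")
def family() -> list[sc.CoreAlignedSequence]:
    """A small seeded clade family without indels."""
    spec = sd.SeqFamilySpec(
        n_sequences=20, identity=0.85, insertion_prob=0.0,
        deletion_prob=0.0, name="HU_test", seed=7,
    )
    return sd.generate_family(spec)


@pytest.fixture(scope="session")
def profile(family) -> sc.CladeProfile:
    return sc.build_profile(family, name="HU_test", group="HU", clade="HU_test")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
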