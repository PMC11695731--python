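import numpy as np
import pytest

from reframekit.coding import CodingModel
from reframekit.dysf import dysf_exon44_model, founder_variant, mutant_model


@pytest.fixture(scope="session")
def dysf_wt() -> CodingModel:
    return dysf_exon44_model()


@pytest.fixture(scope="session")
def dysf_variant(dysf_wt):
    return founder_variant(dysf_wt)


@pytest.fixture(scope="session")
def dysf_mut(dysf_wt) -> CodingModel:
    return mutant_model(dysf_wt)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture()
def toy_model() -> CodingModel:
    # ATG AAA TGA -> "MK"
    return CodingModel("toy", "ATGAAATGA", (("1", 1, 4), ("2", 5, 9)))
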