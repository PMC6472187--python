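import numpy as np
import pytest

from sigrefit import (
    ContextSpec,
    deamination_signature,
    random_mutation_records,
    random_reference,
    random_signature_set,
)


@pytest.fixture
def triplet_spec():
    return ContextSpec(1, 1, False, "shiraishi")


@pytest.fixture
def quintet_strand_spec():
    return ContextSpec(2, 2, True, "shiraishi")


@pytest.fixture
def alexandrov_spec():
    return ContextSpec(1, 1, False, "alexandrov")


@pytest.fixture
def deamination():
    return deamination_signature()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def triplet_set(triplet_spec):
    return random_signature_set(4, triplet_spec, seed=11, min_separation=0.3)


@pytest.fixture
def reference():
    return random_reference({"1": 600, "2": 400}, seed=5)


@pytest.fixture
def records(reference):
    return random_mutation_records(reference, 40, seed=6, samples=("T1", "T2"))
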