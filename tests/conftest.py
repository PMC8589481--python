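import numpy as np
import pytest

from kgmedrec.kg_embedding import Triple
from kgmedrec.synthetic import KGSchema, generate_kg, synthesize_world


@pytest.fixture(scope="session")
def small_schema() -> KGSchema:
    return KGSchema(counts={"disease": 4, "symptom": 6, "drug": 4,
                            "food": 3, "department": 2, "examination": 3})


@pytest.fixture(scope="session")
def small_triples(small_schema) -> list[Triple]:
    return generate_kg(small_schema, density=0.5, seed=1)


@pytest.fixture(scope="session")
def tiny_world(small_schema):
    """A fast-to-train world for smoke-level integration tests."""
    return synthesize_world(schema=small_schema, density=0.5, n_users=20,
                            n_per_user=8, vocab_size=20, doc_len=20,
                            image_size=16, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
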