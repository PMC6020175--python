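import random

import pytest

from phimask.core import DeidConfig
from phimask.corpus import GeneratorConfig, generate_corpus
from phimask.data_model import Document, GoldAnnotation, PhiRecord
from phimask.mutators import MutatorSpec


@pytest.fixture
def phi_meadow() -> PhiRecord:
    return PhiRecord(record_id="r1", address_tokens=["100", "Meadow", "Street"])


@pytest.fixture
def doc_meadow(phi_meadow) -> Document:
    text = "Call 100 Meadow Street now"
    return Document(
        doc_id="d1",
        record_id="r1",
        date="2016-12-01",
        text=text,
        gold=[
            GoldAnnotation(start=5, end=8, token="100", source_index=0),
            GoldAnnotation(start=9, end=15, token="Meadow", source_index=1),
            GoldAnnotation(start=16, end=22, token="Street", source_index=2),
        ],
    )


@pytest.fixture
def default_config() -> DeidConfig:
    return DeidConfig()


@pytest.fixture
def rng() -> random.Random:
    return random.Random(12345)


@pytest.fixture(scope="session")
def small_clean_corpus():
    """120 unmutated documents plus their PHI table (shared, read-only)."""
    cfg = GeneratorConfig(n_docs=120, mutator=MutatorSpec(kind="none"), seed=7)
    return generate_corpus(cfg)
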