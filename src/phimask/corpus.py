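"""Seeded generator of benchmark corpora.

Each benchmark document is one synthetic UK-style address (7-10 tokens,
mean ~8.5) that is mutated by the configured model and then embedded,
space-joined, at a random sentence boundary inside lorem-ipsum filler. The
paired PHI table holds the *clean* address — the premise of structured-PHI
-guided masking is that the queries never see the corrupted surface form.

Gold annotations record the exact character span of every surviving mutated
token (one annotation per original token; under OCR the annotated string may
contain inserted spaces). Everything is a pure function of the config seed.

Address grammar::

    house-number  name-words{1,2}  thoroughfare-type  locality
    region-tokens{1,3}  outward-postcode  inward-postcode

drawn from bundled synthetic wordlists; the postcode pair has UK-like shapes
(e.g. ``SE5 8AF``). Ten of the twenty thoroughfare types have standard
abbreviations, so an address carries on average ~0.5 alias-able tokens.
"""

from __future__ import annotations

import datetime as _dt
import random
import string
from typing import Optional

from pydantic import BaseModel, Field, field_validator

from .data_model import Document, GoldAnnotation, PhiRecord
from .mutators import MutatorSpec, apply_mutator
from .mutators import _read_data  # shared package-data loader

__all__ = [
    "GeneratorConfig",
    "generate_address",
    "generate_filler",
    "build_document",
    "generate_corpus",
]

STREET_NAMES = _read_data("street_names.txt")
STREET_TYPES = _read_data("street_types.txt")
LOCALITIES = _read_data("localities.txt")
LOREM_WORDS = _read_data("lorem_words.txt")

_region_lines = _read_data("regions.txt")
_split = _region_lines.index("--")
REGIONS_SINGLE = _region_lines[:_split]
REGIONS_PAIR = [tuple(r.split()) for r in _region_lines[_split + 1 :]]

_POSTCODE_LETTERS = string.ascii_uppercase
_DIGITS = "0123456789"


class GeneratorConfig(BaseModel):
    """Benchmark corpus conditions.

    Defaults are the benchmark's own: 1000 documents, addresses of 7-10
    tokens (mean ~8.5, i.e. ~8500 PHI tokens per corpus), 3-8 filler
    sentences around each address.
    """

    n_docs: int = Field(default=1000, ge=1)
    tokens_per_address: tuple[int, int] = (7, 10)
    filler_sentences: tuple[int, int] = (3, 8)
    mutator: MutatorSpec = Field(default_factory=MutatorSpec)
    seed: int = 0

    @field_validator("tokens_per_address")
    @classmethod
    def _range_ok(cls, v: tuple[int, int]) -> tuple[int, int]:
        lo, hi = v
        if not (3 <= lo <= hi <= 15):
            raise ValueError("tokens_per_address must satisfy 3 <= lo <= hi <= 15")
        return v

    @field_validator("filler_sentences")
    @classmethod
    def _sent_ok(cls, v: tuple[int, int]) -> tuple[int, int]:
        lo, hi = v
        if not (0 <= lo <= hi):
            raise ValueError("filler_sentences must satisfy 0 <= lo <= hi")
        return v


def _postcode(rng: random.Random) -> tuple[str, str]:
    outward = (
        rng.choice(_POSTCODE_LETTERS)
        + rng.choice(_POSTCODE_LETTERS)
        + "".join(rng.choice(_DIGITS) for _ in range(rng.randint(1, 2)))
    )
    inward = rng.choice(_DIGITS) + rng.choice(_POSTCODE_LETTERS) + rng.choice(_POSTCODE_LETTERS)
    return outward, inward


def generate_address(
    rng: random.Random,
    config: Optional[GeneratorConfig] = None,
    record_id: str = "r0",
) -> PhiRecord:
    """Draw one synthetic address from the grammar.

    The grammar's fixed parts contribute 5 tokens (number, thoroughfare,
    locality, postcode pair); name words (1-2) and region tokens (1-3) are
    chosen uniformly over the combinations compatible with
    ``config.tokens_per_address``.
    """
    config = config or GeneratorConfig()
    lo, hi = config.tokens_per_address
    combos = [
        (nn, rn)
        for nn in (1, 2)
        for rn in (1, 2, 3)
        if lo <= 5 + nn + rn <= hi
    ]
    if not combos:
        raise ValueError(
            f"tokens_per_address={config.tokens_per_address} is incompatible "
            "with the address grammar (totals 7-10 tokens)"
        )
    name_n, region_n = rng.choice(combos)

    tokens = [str(rng.randint(1, 999))]
    if name_n == 2:
        tokens.extend(rng.sample(STREET_NAMES, 2))
    else:
        tokens.append(rng.choice(STREET_NAMES))
    tokens.append(rng.choice(STREET_TYPES))
    tokens.append(rng.choice(LOCALITIES))
    if region_n == 1:
        tokens.append(rng.choice(REGIONS_SINGLE))
    elif region_n == 2:
        tokens.extend(rng.choice(REGIONS_PAIR))
    else:
        tokens.extend(rng.choice(REGIONS_PAIR))
        tokens.append(rng.choice(REGIONS_SINGLE))
    tokens.extend(_postcode(rng))
    return PhiRecord(record_id=record_id, address_tokens=tokens)


def generate_filler(rng: random.Random, n_sentences: int) -> str:
    """Pseudo-Latin sentences of 5-12 words, capitalized and period-ended."""
    if n_sentences < 0:
        raise ValueError("n_sentences must be >= 0")
    sentences = []
    for _ in range(n_sentences):
        words = [rng.choice(LOREM_WORDS) for _ in range(rng.randint(5, 12))]
        sentences.append(words[0].capitalize() + " " + " ".join(words[1:]) + "."
                         if len(words) > 1 else words[0].capitalize() + ".")
    return " ".join(sentences)


def _filler_sentences(rng: random.Random, config: GeneratorConfig) -> list[str]:
    n = rng.randint(*config.filler_sentences)
    return [generate_filler(rng, 1) for _ in range(n)]


def build_document(
    phi: PhiRecord,
    config: Optional[GeneratorConfig] = None,
    rng: Optional[random.Random] = None,
    doc_id: str = "d0",
) -> Document:
    """Mutate the address, wrap it in filler, and record gold spans.

    The document's ``record_id`` links to the ORIGINAL clean record; the
    masker never sees the mutated form. One :class:`GoldAnnotation` is
    written per surviving mutated token, with exact final offsets.
    """
    config = config or GeneratorConfig()
    rng = rng if rng is not None else random.Random(config.seed)

    mutated = apply_mutator(config.mutator, phi.address_tokens, rng)
    sentences = _filler_sentences(rng, config)
    k = rng.randint(0, len(sentences))

    parts: list[str] = []
    cursor = 0
    if k:
        pre = " ".join(sentences[:k])
        parts.append(pre + " ")
        cursor = len(pre) + 1

    gold: list[GoldAnnotation] = []
    for i, tok in enumerate(mutated):
        if i:
            parts.append(" ")
            cursor += 1
        parts.append(tok)
        gold.append(
            GoldAnnotation(start=cursor, end=cursor + len(tok), token=tok, source_index=i)
        )
        cursor += len(tok)
    parts.append(".")
    if k < len(sentences):
        parts.append(" " + " ".join(sentences[k:]))

    date = _dt.date(2016, 1, 1) + _dt.timedelta(days=rng.randint(0, 365))
    return Document(
        doc_id=doc_id,
        record_id=phi.record_id,
        date=date,
        text="".join(parts),
        gold=gold,
    )


def generate_corpus(
    config: Optional[GeneratorConfig] = None,
) -> tuple[list[Document], list[PhiRecord]]:
    """Generate ``n_docs`` documents (one address each) plus the PHI table.

    Fully determined by ``config.seed``; the PHI table holds only clean,
    unmutated addresses.
    """
    config = config or GeneratorConfig()
    rng = random.Random(config.seed)
    docs: list[Document] = []
    phis: list[PhiRecord] = []
    for i in range(config.n_docs):
        phi = generate_address(rng, config, record_id=f"r{i:05d}")
        docs.append(build_document(phi, config, rng, doc_id=f"d{i:05d}"))
        phis.append(phi)
    return docs, phis
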