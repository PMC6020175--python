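"""String-mutation models simulating divergence between structured PHIs and
their surface form in documents.

Four models, each capturing one real-world failure mode of exact matching:

* ``keyboard`` — typographic substitutions drawn from the physical QWERTY
  adjacency of each key (per-character rate; benchmark rates 3/10/20%).
* ``alias`` — full address tokens swapped with common abbreviations and
  vice versa (Road<->Rd, Street<->St, ...), per-token rate (benchmark 100%).
* ``truncate`` — supplemental address lines dropped: the token list is cut
  from the end to a fixed minimum length (benchmark: 3 tokens, rate 100%).
* ``ocr`` — keyboard substitutions plus spurious whitespace inserted inside
  tokens, mimicking poor optical character recognition.

All mutators are driven by an explicit ``random.Random`` so identical
(spec, seed) pairs give identical output.
"""

from __future__ import annotations

import random
from importlib import resources
from typing import Literal, Optional

from pydantic import BaseModel, Field

__all__ = [
    "MutatorSpec",
    "AliasDictionary",
    "qwerty_neighbors",
    "mutate_keyboard",
    "mutate_alias",
    "mutate_truncate",
    "mutate_ocr",
    "apply_mutator",
]


def _read_data(name: str) -> list[str]:
    text = resources.files("phimask.data").joinpath(name).read_text(encoding="utf-8")
    return [ln for ln in (raw.strip() for raw in text.splitlines())
            if ln and not ln.startswith("#")]


def qwerty_neighbors() -> dict[str, str]:
    """Key -> string of physically adjacent keys, loaded from the data file."""
    table: dict[str, str] = {}
    for line in _read_data("qwerty_neighbors.txt"):
        key, _, nbrs = line.partition(" ")
        table[key] = nbrs.strip()
    return table


_QWERTY = qwerty_neighbors()


class AliasDictionary:
    """Involutive bidirectional map between full tokens and abbreviations.

    Lookup is case-insensitive; replacements come out in canonical casing.
    ``map(map(x)) == x`` for every key.
    """

    def __init__(self, pairs: Optional[list[tuple[str, str]]] = None) -> None:
        if pairs is None:
            pairs = [tuple(line.split()) for line in _read_data("alias_pairs.txt")]
        self._map: dict[str, str] = {}
        for full, abbrev in pairs:
            self._map[full.lower()] = abbrev
            self._map[abbrev.lower()] = full

    def lookup(self, token: str) -> Optional[str]:
        return self._map.get(token.lower())

    def __contains__(self, token: str) -> bool:
        return token.lower() in self._map

    def keys(self) -> list[str]:
        return list(self._map)


class MutatorSpec(BaseModel):
    """Which mutation model to apply, with its rates and seed.

    ``char_rate`` drives keyboard/OCR substitution, ``ws_rate`` OCR
    whitespace insertion, ``token_rate`` alias and truncate; ``min_tokens``
    is the truncation floor.
    """

    kind: Literal["keyboard", "alias", "truncate", "ocr", "none"] = "none"
    char_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    ws_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    token_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    min_tokens: int = Field(default=3, ge=1)
    seed: int = 0


def mutate_keyboard(token: str, rate: float, rng: random.Random) -> str:
    """Replace each alphanumeric character, with probability ``rate``, by a
    uniformly drawn QWERTY physical neighbour. Case is preserved; other
    characters are untouched; length is preserved."""
    out = []
    for ch in token:
        if ch.isalnum() and rng.random() < rate:
            nbrs = _QWERTY.get(ch.lower())
            if nbrs:
                repl = rng.choice(nbrs)
                ch = repl.upper() if ch.isupper() else repl
        out.append(ch)
    return "".join(out)


def mutate_alias(
    tokens: list[str],
    dictionary: AliasDictionary,
    token_rate: float,
    rng: random.Random,
) -> list[str]:
    """Swap each token that has a dictionary counterpart with probability
    ``token_rate``; list length is preserved."""
    out = []
    for tok in tokens:
        repl = dictionary.lookup(tok)
        if repl is not None and rng.random() < token_rate:
            tok = repl
        out.append(tok)
    return out


def mutate_truncate(
    tokens: list[str], min_tokens: int, token_rate: float, rng: random.Random
) -> list[str]:
    """With probability ``token_rate``, cut the list from the end to exactly
    ``min(len(tokens), min_tokens)`` tokens."""
    if min_tokens < 1:
        raise ValueError("min_tokens must be >= 1")
    if rng.random() < token_rate:
        return tokens[: min(len(tokens), min_tokens)]
    return list(tokens)


def mutate_ocr(
    token: str, char_rate: float, ws_rate: float, rng: random.Random
) -> str:
    """Keyboard substitution at ``char_rate``, then one space inserted, with
    probability ``ws_rate``, in each gap between consecutive characters.
    Output length >= input length."""
    t = mutate_keyboard(token, char_rate, rng)
    if not t:
        return t
    out = [t[0]]
    for ch in t[1:]:
        if rng.random() < ws_rate:
            out.append(" ")
        out.append(ch)
    return "".join(out)


_ALIAS_DEFAULT = AliasDictionary()


def apply_mutator(
    spec: MutatorSpec,
    tokens: list[str],
    rng: Optional[random.Random] = None,
    dictionary: Optional[AliasDictionary] = None,
) -> list[str]:
    """Apply one mutation model to an address token list.

    Character-level models act on each token independently; token-level
    models act on the list. When ``rng`` is omitted, a generator seeded from
    ``spec.seed`` is used, so identical (input, spec) pairs reproduce.
    """
    rng = rng if rng is not None else random.Random(spec.seed)
    dictionary = dictionary or _ALIAS_DEFAULT
    if spec.kind == "none":
        return list(tokens)
    if spec.kind == "keyboard":
        return [mutate_keyboard(t, spec.char_rate, rng) for t in tokens]
    if spec.kind == "alias":
        return mutate_alias(tokens, dictionary, spec.token_rate, rng)
    if spec.kind == "truncate":
        return mutate_truncate(tokens, spec.min_tokens, spec.token_rate, rng)
    if spec.kind == "ocr":
        return [mutate_ocr(t, spec.char_rate, spec.ws_rate, rng) for t in tokens]
    raise ValueError(f"unknown mutator kind {spec.kind!r}")
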