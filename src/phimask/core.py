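"""Structured-PHI-guided masking via sliding-window Levenshtein matching.

The method: for every PHI token known for the patient (from the structured
record), slide a window over the document text and compute the Levenshtein
edit distance between the token and the window content at **every character
offset**, over a range of window widths around the token length. Windows
whose normalized similarity reaches the threshold are masked in place
(character-for-character, so offsets stay stable). Because the queries are
the *clean* identifiers, the method tolerates misspellings, abbreviation
drift and OCR noise in the document without any trained model or
hand-crafted rules.

Normalization: similarity(a, b) = 1 - d(a, b) / max(len(a), len(b)), so a
threshold ``theta`` masks a window at distance up to ``(1-theta) * max(len)``
— short tokens are held near exact match while long tokens absorb several
edits.

Two scanner implementations exist: a brute-force per-offset dynamic program
(:func:`scan_token_reference`, the semantic reference) and a vectorized
sliding DP (:func:`scan_token`, the production path). They are required to
produce identical spans; the test suite enforces this.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Optional

import datetime as _dt

import numpy as np
from pydantic import BaseModel, Field

from .data_model import Document, PhiRecord

__all__ = [
    "DeidConfig",
    "MatchSpan",
    "MaskedDocument",
    "LinkageError",
    "edit_distance",
    "similarity",
    "scan_token",
    "scan_token_reference",
    "deidentify",
    "version_hash",
]


class LinkageError(ValueError):
    """Document and PHI record do not belong to the same patient."""


class DeidConfig(BaseModel):
    """Tunable parameters of the masker.

    theta:
        Similarity threshold in [0, 1]. A window is masked when
        ``similarity(token, window) >= theta``.
    width_slack_fraction:
        Window widths evaluated for a token of length L are
        ``[max(1, L - ceil(f*L)), L + ceil(f*L)]``. The slack absorbs
        insertions (OCR whitespace) and deletions.
    min_token_length:
        PHI tokens shorter than this are skipped entirely — 1-2 character
        queries would mask indiscriminately.
    mask_char:
        Replacement character; masking is in place and length-preserving.
    case_fold:
        Compare case-insensitively (per-character lowercasing that never
        changes string length).
    """

    theta: float = Field(default=0.75, ge=0.0, le=1.0)
    width_slack_fraction: float = Field(default=0.34, ge=0.0, lt=1.0)
    min_token_length: int = Field(default=3, ge=1)
    mask_char: str = Field(default="X", min_length=1, max_length=1)
    case_fold: bool = True


@dataclass(frozen=True)
class MatchSpan:
    """One above-threshold window: half-open character span plus score."""

    start: int
    end: int
    similarity: float
    token_index: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("MatchSpan must be non-empty")


@dataclass
class MaskedDocument:
    """De-identified text plus the evidence that produced it.

    ``text`` has the same length as the input; every offset in
    ``masked_offsets`` (the union of all span ranges) holds the mask
    character. ``version_hash`` ties the output to the identifier set and
    document date used, for version control of re-processed documents.
    """

    doc_id: str
    text: str
    masked_offsets: frozenset[int]
    spans: list[MatchSpan] = field(default_factory=list)
    version_hash: str = ""

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "text": self.text,
            "masked_offsets": sorted(self.masked_offsets),
            "spans": [
                {"start": s.start, "end": s.end,
                 "similarity": s.similarity, "token_index": s.token_index}
                for s in self.spans
            ],
            "version_hash": self.version_hash,
        }


# ---------------------------------------------------------------------------
# Distance and similarity


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance with unit insert/delete/substitute costs."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) > len(b):  # iterate over the longer string, keep rows short
        a, b = b, a
    prev = list(range(len(a) + 1))
    cur = [0] * (len(a) + 1)
    for i, cb in enumerate(b, start=1):
        cur[0] = i
        for j, ca in enumerate(a, start=1):
            cur[j] = min(
                prev[j - 1] + (ca != cb),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev, cur = cur, prev
    return prev[len(a)]


def similarity(a: str, b: str) -> float:
    """Length-normalized similarity: ``1 - d(a,b)/max(len)``; 1.0 iff equal."""
    m = max(len(a), len(b))
    if m == 0:
        return 1.0
    return 1.0 - edit_distance(a, b) / m


# ---------------------------------------------------------------------------
# Sliding-window scan


def _fold(s: str) -> str:
    """Length-preserving per-character lowercase."""
    out = []
    for c in s:
        low = c.lower()
        out.append(low if len(low) == 1 else c)
    return "".join(out)


def _widths(token_len: int, slack_fraction: float) -> range:
    delta = math.ceil(slack_fraction * token_len)
    return range(max(1, token_len - delta), token_len + delta + 1)


def scan_token_reference(
    text: str, token: str, config: DeidConfig, token_index: int = 0
) -> list[MatchSpan]:
    """Brute-force scanner: the semantic reference implementation.

    For every character offset ``i`` and window width ``w``, evaluates
    ``similarity(token, text[i:i+w])``; windows running past the end of the
    text are truncated by slicing. Duplicate (start, end) pairs produced by
    truncation are emitted once.
    """
    if config.case_fold:
        text, token = _fold(text), _fold(token)
    n, L = len(text), len(token)
    if n == 0 or L == 0:
        return []
    found: dict[tuple[int, int], float] = {}
    for w in _widths(L, config.width_slack_fraction):
        for i in range(n):
            window = text[i : i + w]
            if not window:
                continue
            sim = 1.0 - edit_distance(token, window) / max(L, len(window))
            if sim >= config.theta:
                found.setdefault((i, i + len(window)), sim)
    return [
        MatchSpan(start=s, end=e, similarity=found[(s, e)], token_index=token_index)
        for (s, e) in sorted(found)
    ]


def _scan_codes(
    codes: np.ndarray, token: str, config: DeidConfig, token_index: int
) -> list[MatchSpan]:
    """Vectorized scan of one (already case-folded) token over code points.

    Computes, in a single dynamic program vectorized over all start offsets,
    the distance of the token to every window width simultaneously: the DP
    row for window-prefix length ``i`` holds ``d(token, text[o:o+i])`` for
    every offset ``o``, so each row *is* the result for width ``i``.
    """
    n = codes.shape[0]
    L = len(token)
    if n == 0 or L == 0:
        return []
    widths = _widths(L, config.width_slack_fraction)
    w_min, w_max = widths.start, widths.stop - 1
    q = np.array([ord(c) for c in token], dtype=np.int32)

    # Pad so every offset has w_max characters; padded cells are only read
    # for (o, w) with o + w > n, which are discarded below.
    padded = np.concatenate([codes, np.full(w_max, -1, dtype=np.int32)])
    offsets = np.arange(n)

    prev = np.empty((L + 1, n), dtype=np.int32)
    cur = np.empty_like(prev)
    prev[:] = np.arange(L + 1, dtype=np.int32)[:, None]

    found: dict[tuple[int, int], float] = {}
    for i in range(1, w_max + 1):
        col = padded[i - 1 : i - 1 + n]
        cur[0] = i
        for j in range(1, L + 1):
            np.minimum(prev[j - 1] + (col != q[j - 1]), prev[j] + 1, out=cur[j])
            np.minimum(cur[j], cur[j - 1] + 1, out=cur[j])
        if i >= w_min:
            valid = offsets <= n - i
            sims = 1.0 - cur[L] / max(L, i)
            hits = np.nonzero(valid & (sims >= config.theta))[0]
            for o in hits:
                found.setdefault((int(o), int(o) + i), float(sims[o]))
        prev, cur = cur, prev

    # Tail: windows that the slicing contract truncates below w_min. Those of
    # width >= w_min coincide with full windows already evaluated above.
    text = "".join(map(chr, codes))
    for o in range(max(0, n - w_min + 1), n):
        v = n - o
        sim = 1.0 - edit_distance(token, text[o:]) / max(L, v)
        if sim >= config.theta:
            found.setdefault((o, n), sim)

    return [
        MatchSpan(start=s, end=e, similarity=found[(s, e)], token_index=token_index)
        for (s, e) in sorted(found)
    ]


def scan_token(
    text: str, token: str, config: DeidConfig, token_index: int = 0
) -> list[MatchSpan]:
    """Scan ``text`` for fuzzy occurrences of one PHI token.

    Emits a :class:`MatchSpan` for every (offset, width) whose similarity
    reaches ``config.theta`` (union semantics downstream). Output is
    identical to :func:`scan_token_reference`.
    """
    if config.case_fold:
        text, token = _fold(text), _fold(token)
    codes = np.fromiter(map(ord, text), dtype=np.int32, count=len(text))
    return _scan_codes(codes, token, config, token_index)


# ---------------------------------------------------------------------------
# Whole-document masking


def _phi_tokens(phi: PhiRecord) -> list[str]:
    tokens = list(phi.address_tokens)
    for toks in phi.other_phis.values():
        tokens.extend(toks)
    return tokens


def version_hash(phi: PhiRecord, date: _dt.date) -> str:
    """SHA-256 over record id, canonical address and ISO date.

    Deterministic across runs and platforms; changes whenever the identifier
    set or the document date changes, which is what makes it usable for
    version control of re-processed documents.
    """
    payload = f"{phi.record_id}\n{phi.canonical_address}\n{date.isoformat()}"
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def deidentify(doc: Document, phi: PhiRecord, config: Optional[DeidConfig] = None) -> MaskedDocument:
    """Mask every above-threshold fuzzy occurrence of the record's PHI tokens.

    All address tokens plus all ``other_phis`` tokens of length >=
    ``min_token_length`` are scanned; the union of all qualifying window
    ranges is replaced by ``mask_char``. The output text has exactly the
    input's length.
    """
    config = config or DeidConfig()
    if doc.record_id != phi.record_id:
        raise LinkageError(
            f"document {doc.doc_id!r} links to record {doc.record_id!r}, "
            f"got PHI record {phi.record_id!r}"
        )
    text = doc.text
    folded = _fold(text) if config.case_fold else text
    codes = np.fromiter(map(ord, folded), dtype=np.int32, count=len(folded))

    spans: list[MatchSpan] = []
    for idx, tok in enumerate(_phi_tokens(phi)):
        if len(tok) < config.min_token_length:
            continue
        query = _fold(tok) if config.case_fold else tok
        spans.extend(_scan_codes(codes, query, config, token_index=idx))

    mask = np.zeros(len(text), dtype=bool)
    for s in spans:
        mask[s.start : s.end] = True
    masked_text = "".join(
        config.mask_char if m else c for m, c in zip(mask, text)
    )
    spans.sort(key=lambda s: (s.start, s.end, s.token_index))
    return MaskedDocument(
        doc_id=doc.doc_id,
        text=masked_text,
        masked_offsets=frozenset(int(i) for i in np.nonzero(mask)[0]),
        spans=spans,
        version_hash=version_hash(phi, doc.date),
    )
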