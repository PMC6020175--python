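"""Domain types and readers/writers for documents, PHI records and reports.

The central objects are :class:`PhiRecord` (the clean identifiers held for a
patient in an administrative table — the *queries* of the masker),
:class:`Document` (free text linked to a record, optionally carrying gold
annotations for evaluation) and :class:`EvalResult` (per-token confusion
counts with derived precision/recall).

Conventions
-----------
* Character offsets are 0-based, half-open ``[start, end)`` and count Unicode
  code points.
* Documents travel as JSONL (one object per line); PHI records as CSV
  (``record_id,address``) or JSONL; benchmark reports as CSV or JSON.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import re
from pathlib import Path
from typing import Any, Iterable, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "PhiRecord",
    "GoldAnnotation",
    "Document",
    "EvalResult",
    "DataModelError",
    "ParseError",
    "ValidationError",
    "read_documents",
    "write_documents",
    "read_phi_records",
    "write_phi_records",
    "write_report",
    "read_report",
]


class DataModelError(ValueError):
    """Base class for I/O and validation failures in this module."""


class ParseError(DataModelError):
    """A line or row could not be parsed at all."""


class ValidationError(DataModelError):
    """Parsed content violates a domain invariant."""


class PhiRecord(BaseModel):
    """The structured identifiers known for one patient.

    ``address_tokens`` are the clean, *unmutated* tokens as held in the
    administrative table; they are what the masker searches for.
    ``other_phis`` maps a category name (``first_name``, ``last_name``,
    ``phone``, ``nhs_number``, ``date_of_birth``) to further token lists.
    """

    record_id: str
    address_tokens: list[str]
    other_phis: dict[str, list[str]] = Field(default_factory=dict)

    @field_validator("address_tokens")
    @classmethod
    def _tokens_wellformed(cls, v: list[str]) -> list[str]:
        for tok in v:
            if not tok or any(c.isspace() for c in tok):
                raise ValueError(
                    f"address token {tok!r} is empty or contains whitespace"
                )
        return v

    @field_validator("other_phis")
    @classmethod
    def _other_wellformed(cls, v: dict[str, list[str]]) -> dict[str, list[str]]:
        for cat, toks in v.items():
            for tok in toks:
                if not tok or any(c.isspace() for c in tok):
                    raise ValueError(f"PHI token {tok!r} in {cat!r} is malformed")
        return v

    @property
    def canonical_address(self) -> str:
        """Tokens joined with single spaces; round-trips under ``str.split``."""
        return " ".join(self.address_tokens)


class GoldAnnotation(BaseModel):
    """Span of one embedded (possibly mutated) PHI token in a document.

    ``source_index`` is the position of the originating token in the
    unmutated address. ``token`` may contain internal whitespace only when an
    OCR-style mutation split the surface form.
    """

    start: int = Field(ge=0)
    end: int
    token: str
    source_index: int = Field(ge=0)

    @model_validator(mode="after")
    def _span_nonempty(self) -> "GoldAnnotation":
        if self.end <= self.start:
            raise ValueError(f"empty span [{self.start}, {self.end})")
        return self


class Document(BaseModel):
    """Free text plus its link to a PHI record and optional gold spans."""

    doc_id: str
    record_id: str
    date: _dt.date
    text: str
    gold: list[GoldAnnotation] = Field(default_factory=list)

    @model_validator(mode="after")
    def _gold_consistent(self) -> "Document":
        prev_end = 0
        for ann in self.gold:
            if ann.end > len(self.text):
                raise ValueError(
                    f"doc {self.doc_id!r}: span [{ann.start},{ann.end}) "
                    f"outside text of length {len(self.text)}"
                )
            if self.text[ann.start : ann.end] != ann.token:
                raise ValueError(
                    f"doc {self.doc_id!r}: gold token {ann.token!r} != "
                    f"text slice {self.text[ann.start:ann.end]!r}"
                )
            if ann.start < prev_end:
                raise ValueError(
                    f"doc {self.doc_id!r}: gold spans overlap or are unsorted"
                )
            prev_end = ann.end
        return self


class EvalResult(BaseModel):
    """Per-token confusion counts; precision/recall are derived quantities.

    ``precision`` and ``recall`` return ``None`` (the undefined sentinel)
    when their denominator is zero.
    """

    tp: int = Field(ge=0)
    fp: int = Field(ge=0)
    fn: int = Field(ge=0)

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None


# ---------------------------------------------------------------------------
# Documents: JSONL


def read_documents(path: str | Path) -> list[Document]:
    """Read a JSONL document file, validating gold spans against the text.

    Raises :class:`ParseError` (naming the line number) for malformed JSON
    and :class:`ValidationError` (naming the doc_id) for contract violations.
    """
    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: line {lineno}: invalid JSON: {exc}") from exc
            try:
                docs.append(Document(**obj))
            except Exception as exc:
                doc_id = obj.get("doc_id", f"<line {lineno}>") if isinstance(obj, dict) else f"<line {lineno}>"
                raise ValidationError(f"{path}: document {doc_id!r}: {exc}") from exc
    return docs


def write_documents(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(doc.model_dump(mode="json"), ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# PHI records: CSV or JSONL

_EDGE_PUNCT = re.compile(r"^[^\w]+|[^\w]+$", re.UNICODE)


def tokenize_address(address: str) -> list[str]:
    """Whitespace-tokenize a prose address, stripping edge punctuation.

    ``'100 Meadow Street, Barkingford'`` -> four clean tokens. Tokens that
    are punctuation-only disappear.
    """
    toks = []
    for raw in address.split():
        tok = _EDGE_PUNCT.sub("", raw)
        if tok:
            toks.append(tok)
    return toks


def read_phi_records(path: str | Path) -> list[PhiRecord]:
    """Read PHI records from CSV (``record_id,address``) or JSONL.

    Token order is preserved; a duplicate ``record_id`` or an empty address
    raises :class:`ValidationError`.
    """
    path = Path(path)
    records: list[PhiRecord] = []
    if path.suffix.lower() in {".jsonl", ".json", ".ndjson"}:
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"{path}: line {lineno}: invalid JSON: {exc}") from exc
                try:
                    records.append(PhiRecord(**obj))
                except Exception as exc:
                    raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"record_id", "address"} <= set(reader.fieldnames):
                raise ParseError(f"{path}: expected CSV header record_id,address")
            for rowno, row in enumerate(reader, start=2):
                tokens = tokenize_address(row["address"] or "")
                if not tokens:
                    raise ValidationError(f"{path}: row {rowno}: empty address")
                records.append(PhiRecord(record_id=row["record_id"], address_tokens=tokens))
    seen: set[str] = set()
    for rec in records:
        if rec.record_id in seen:
            raise ValidationError(f"{path}: duplicate record_id {rec.record_id!r}")
        seen.add(rec.record_id)
    return records


def write_phi_records(records: Iterable[PhiRecord], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".jsonl", ".json", ".ndjson"}:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(rec.model_dump(mode="json"), ensure_ascii=False) + "\n")
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["record_id", "address"])
            for rec in records:
                writer.writerow([rec.record_id, rec.canonical_address])


# ---------------------------------------------------------------------------
# Benchmark reports: CSV (human) and JSON (lossless)


def _pct(value: Optional[float]) -> str:
    return "" if value is None else f"{100.0 * value:.1f}"


def write_report(report: Any, path: str | Path) -> None:
    """Serialize a benchmark report.

    ``.json`` paths get the lossless form (counts plus configuration);
    anything else gets the human-facing CSV with columns
    ``condition,tp,fp,fn,precision,recall`` where precision/recall are
    percentages with one decimal and undefined values print as empty cells.
    """
    if not report.entries:
        raise ValidationError("report has no conditions")
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2)
            fh.write("\n")
        return
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["condition", "tp", "fp", "fn", "precision", "recall"])
        for label, _spec, result in report.entries:
            writer.writerow(
                [label, result.tp, result.fp, result.fn,
                 _pct(result.precision), _pct(result.recall)]
            )


def read_report(path: str | Path) -> Any:
    """Read back a JSON benchmark report (the lossless round-trip format)."""
    from .evaluation import BenchmarkReport  # local import: avoids a cycle

    with open(path, encoding="utf-8") as fh:
        return BenchmarkReport.from_dict(json.load(fh))
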