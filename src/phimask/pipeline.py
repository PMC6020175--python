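"""Partitioned, incremental de-identification jobs.

The production-scale pattern — a master process splitting a batch of new
documents into partitions handed to workers, with all-or-nothing job
completion and retry from a high-water mark — reduced to a single process
with identical observable semantics: partition statuses, a job that is
complete iff every partition is, and a date high-water mark that only
advances on full success (so a failed partition's documents are retried by
the next job).
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field

from .core import DeidConfig, deidentify
from .data_model import Document, read_phi_records

logger = logging.getLogger(__name__)

__all__ = ["Partition", "JobState", "partition_job", "run_job"]

Status = Literal["pending", "complete", "failed"]


class Partition(BaseModel):
    start: int
    end: int
    status: Status = "pending"
    error: Optional[str] = None


class JobState(BaseModel):
    """Persistent record of one job: partition statuses plus the high-water
    mark (date of the newest document processed by the last successful job)."""

    job_id: str
    partitions: list[Partition] = Field(default_factory=list)
    high_water_mark: Optional[_dt.date] = None
    status: Status = "pending"

    @property
    def complete(self) -> bool:
        return all(p.status == "complete" for p in self.partitions)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "JobState":
        return cls.model_validate_json(Path(path).read_text(encoding="utf-8"))


def partition_job(n_items: int, n_partitions: int) -> list[tuple[int, int]]:
    """Contiguous half-open ranges covering [0, n_items), sizes within 1.

    An empty job yields zero ranges.
    """
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    if n_items < 0:
        raise ValueError("n_items must be >= 0")
    if n_items == 0:
        return []
    base, extra = divmod(n_items, n_partitions)
    ranges = []
    start = 0
    for k in range(min(n_partitions, n_items)):
        size = base + (1 if k < extra else 0)
        if size == 0:
            break
        ranges.append((start, start + size))
        start += size
    return ranges


def _parse_document(line: str, lineno: int) -> Document:
    try:
        obj = json.loads(line)
    except json.JSONDecodeError as exc:
        raise ValueError(f"line {lineno}: invalid JSON: {exc}") from exc
    return Document(**obj)


def run_job(
    documents_path: str | Path,
    phis_path: str | Path,
    deid_config: Optional[DeidConfig] = None,
    n_partitions: int = 1,
    state_path: str | Path = "job_state.json",
    out_path: str | Path = "masked.jsonl",
    job_id: Optional[str] = None,
) -> JobState:
    """Process all documents newer than the high-water mark, in partitions.

    Each partition is processed independently; a failure (malformed
    document, missing PHI record, ...) marks that partition failed without
    touching the others. Only if every partition completes does the
    high-water mark advance, so a failed job's documents are reprocessed by
    the next run. Successful partitions' masked output is appended to
    ``out_path``.
    """
    deid_config = deid_config or DeidConfig()
    state_path = Path(state_path)
    prior_hwm: Optional[_dt.date] = None
    if state_path.exists():
        prior_hwm = JobState.load(state_path).high_water_mark

    # Lenient read: defer per-document validation to partition processing so
    # one bad line fails its partition, not the whole job.
    raw_lines = [
        (i + 1, line)
        for i, line in enumerate(Path(documents_path).read_text(encoding="utf-8").splitlines())
        if line.strip()
    ]
    selected: list[tuple[int, str]] = []
    for lineno, line in raw_lines:
        try:
            doc = _parse_document(line, lineno)
        except Exception:
            selected.append((lineno, line))  # judged by its partition
            continue
        if prior_hwm is None or doc.date > prior_hwm:
            selected.append((lineno, line))

    phi_by_id = {p.record_id: p for p in read_phi_records(phis_path)}
    ranges = partition_job(len(selected), n_partitions)
    state = JobState(
        job_id=job_id or f"job-{_dt.datetime.now():%Y%m%dT%H%M%S}",
        partitions=[Partition(start=s, end=e) for s, e in ranges],
        high_water_mark=prior_hwm,
    )

    newest: Optional[_dt.date] = None
    outputs: list[str] = []
    for part in state.partitions:
        part_out: list[str] = []
        try:
            for lineno, line in selected[part.start : part.end]:
                doc = _parse_document(line, lineno)
                phi = phi_by_id.get(doc.record_id)
                if phi is None:
                    raise KeyError(f"no PHI record {doc.record_id!r} (doc {doc.doc_id!r})")
                masked = deidentify(doc, phi, deid_config)
                rec = masked.to_dict()
                rec["record_id"] = doc.record_id
                rec["date"] = doc.date.isoformat()
                part_out.append(json.dumps(rec, ensure_ascii=False))
                newest = doc.date if newest is None else max(newest, doc.date)
        except Exception as exc:
            part.status = "failed"
            part.error = str(exc)
            logger.error("partition [%d,%d) failed: %s", part.start, part.end, exc)
        else:
            part.status = "complete"
            outputs.extend(part_out)

    with open(out_path, "a", encoding="utf-8") as fh:
        for line in outputs:
            fh.write(line + "\n")

    if state.complete:
        state.status = "complete"
        if newest is not None:
            state.high_water_mark = (
                newest if prior_hwm is None else max(prior_hwm, newest)
            )
    else:
        state.status = "failed"
    state.save(state_path)
    return state
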