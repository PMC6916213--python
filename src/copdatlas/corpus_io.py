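"""Reading and writing the note corpus and the death-date table.

Notes are stored as JSON lines (one object per line, UTF-8) with fields
``patient_id``, ``date`` (ISO-8601 calendar date), ``note_type`` and ``text``.
Death dates are a two-column CSV with header ``patient_id,death_date``.
Both formats round-trip exactly.  Dates are calendar dates only: the whole
pipeline operates at day resolution, one merged document per patient-day.
"""

from __future__ import annotations

import csv
import datetime
import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import CorpusParseError, ValidationError

NOTE_TYPES = ("pulmonary", "radiology", "cardiology")


@dataclass(frozen=True)
class NoteDocument:
    """One free-text clinical note.

    ``note_type`` must be one of :data:`NOTE_TYPES` — the three note sources
    (pulmonary function notes, chest X-ray radiology reports, abnormal
    electrocardiogram cardiology reports) the pipeline consumes.
    """

    patient_id: str
    date: datetime.date
    note_type: str
    text: str

    def __post_init__(self) -> None:
        if self.note_type not in NOTE_TYPES:
            raise ValidationError(
                f"unknown note_type {self.note_type!r}; expected one of {NOTE_TYPES}"
            )
        if not self.text:
            raise ValidationError("note text must be non-empty")


@dataclass(frozen=True)
class DeathRecord:
    """Death date for one patient; at most one record per patient."""

    patient_id: str
    death_date: datetime.date


def _parse_date(raw: str, where: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(raw)
    except (TypeError, ValueError) as exc:
        raise CorpusParseError(f"{where}: invalid ISO date {raw!r}") from exc


def read_notes(path: str | Path) -> list[NoteDocument]:
    """Parse a JSON-lines note file, preserving file order.

    Raises :class:`CorpusParseError` naming the 1-based line number on a
    malformed line, :class:`ValidationError` on an invalid field value.
    """
    notes: list[NoteDocument] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
            try:
                note = NoteDocument(
                    patient_id=str(obj["patient_id"]),
                    date=_parse_date(obj["date"], f"line {lineno}"),
                    note_type=obj["note_type"],
                    text=obj["text"],
                )
            except KeyError as exc:
                raise CorpusParseError(f"line {lineno}: missing field {exc.args[0]!r}") from exc
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
            notes.append(note)
    return notes


def write_notes(notes: Iterable[NoteDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(
                json.dumps(
                    {
                        "patient_id": note.patient_id,
                        "date": note.date.isoformat(),
                        "note_type": note.note_type,
                        "text": note.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_deaths(path: str | Path) -> list[DeathRecord]:
    """Parse the death-date CSV; duplicate patient ids are rejected."""
    records: list[DeathRecord] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != ["patient_id", "death_date"]:
            raise CorpusParseError(
                f"expected header 'patient_id,death_date', got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            pid = row["patient_id"]
            if pid in seen:
                raise ValidationError(f"line {lineno}: duplicate patient_id {pid!r}")
            seen.add(pid)
            records.append(DeathRecord(pid, _parse_date(row["death_date"], f"line {lineno}")))
    return records


def write_deaths(records: Iterable[DeathRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "death_date"])
        for rec in records:
            writer.writerow([rec.patient_id, rec.death_date.isoformat()])


def death_date_map(records: Sequence[DeathRecord]) -> dict[str, datetime.date]:
    return {rec.patient_id: rec.death_date for rec in records}


def validate_join(notes: Sequence[NoteDocument], records: Sequence[DeathRecord]) -> None:
    """Check cross-file invariants: every note precedes its patient's death.

    Notes dated on or after the recorded death date, and notes whose patient
    has no death record, are both domain violations.
    """
    deaths = death_date_map(records)
    for note in notes:
        death = deaths.get(note.patient_id)
        if death is None:
            raise ValidationError(f"patient {note.patient_id!r} has no death record")
        if note.date >= death:
            raise ValidationError(
                f"patient {note.patient_id!r}: note dated {note.date} is not "
                f"strictly before death date {death}"
            )
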