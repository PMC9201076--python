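"""Note corpora, registry tables and patient assembly.

A corpus is a collection of :class:`ClinicalNote` records, one per free-text
document.  Notes are grouped into per-patient longitudinal
:class:`PatientRecord` objects ordered by date, which is the unit every
downstream extractor operates on: both the rule engine and the ML arm resolve
stage at the *patient* level, not the note level.

Stage values move between components in two tabular schemas sharing the
header ``patient_id,cT,cN,cM,pT,pN``:

* registry / gold tables hold raw categories (``T1``..``T4``, ``N0``/``N1``,
  ``M0``/``M1``); an empty cell means missing;
* prediction tables hold dichotomized categories (``T1-2``, ``T3-4``, ``T2``,
  ``N0``, ``N1``, ``M0``, ``M1``).
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

REGISTRY_COLUMNS = ["patient_id", "cT", "cN", "cM", "pT", "pN"]

#: The five patient-level binary staging tasks.
TASKS = ["cT", "cN", "cM", "pT", "pN"]


class NoteType(str, Enum):
    OPERATIVE = "operative"
    HISTORY_PHYSICAL = "history_physical"
    DISCHARGE_TRANSFER = "discharge_transfer"
    PROGRESS = "progress"
    PATHOLOGY = "pathology"
    RADIOLOGY = "radiology"
    OTHER = "other"

    @classmethod
    def coerce(cls, value: str | "NoteType" | None) -> "NoteType":
        """Map arbitrary strings to a note type; unknown strings become OTHER."""
        if isinstance(value, cls):
            return value
        if value is None:
            return cls.OTHER
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            return cls.OTHER


class StageKind(str, Enum):
    CLINICAL = "clinical"
    PATHOLOGICAL = "pathological"


#: Note types eligible for abstracting each stage kind.  Clinical stage is
#: abstracted from operative reports, history & physicals, discharge/transfer
#: summaries and progress notes; pathological stage from pathology reports,
#: history & physicals and progress notes.  Radiology and unknown types pass
#: neither filter.
STAGE_KIND_NOTE_TYPES: dict[StageKind, frozenset[NoteType]] = {
    StageKind.CLINICAL: frozenset(
        {
            NoteType.OPERATIVE,
            NoteType.HISTORY_PHYSICAL,
            NoteType.DISCHARGE_TRANSFER,
            NoteType.PROGRESS,
        }
    ),
    StageKind.PATHOLOGICAL: frozenset(
        {
            NoteType.PATHOLOGY,
            NoteType.HISTORY_PHYSICAL,
            NoteType.PROGRESS,
        }
    ),
}


@dataclass(frozen=True)
class ClinicalNote:
    """One dated, typed free-text document for a patient."""

    patient_id: str
    note_id: str
    note_type: NoteType
    date: datetime.date | None
    text: str


@dataclass
class PatientRecord:
    """All notes for one patient, sorted ascending by date (dateless last)."""

    patient_id: str
    notes: list[ClinicalNote] = field(default_factory=list)
    age_at_diagnosis: float | None = None


def _parse_date(value) -> datetime.date | None:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, datetime.date):
        return value
    return datetime.date.fromisoformat(str(value))


def read_corpus(path: str | Path, fmt: str = "jsonl") -> tuple[list[ClinicalNote], list[str]]:
    """Read a note corpus.

    Parameters
    ----------
    path
        Input file.  ``jsonl`` expects one JSON object per line with fields
        ``patient_id``, ``note_id``, ``note_type``, ``date``, ``text``;
        ``csv`` expects the same columns.
    fmt
        ``"jsonl"`` or ``"csv"``.

    Returns
    -------
    (notes, rejects)
        Parsed notes and a list of human-readable reject messages (rows
        missing ``patient_id`` or ``text``), each carrying the line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[int, dict]]
    if fmt == "jsonl":
        rows = []
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                rows.append((lineno, json.loads(line)))
    elif fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        rows = [(i + 2, rec) for i, rec in enumerate(df.to_dict("records"))]
    else:
        raise ValueError(f"unknown corpus format: {fmt!r}")

    notes: list[ClinicalNote] = []
    rejects: list[str] = []
    seen_ids: set[str] = set()
    for lineno, row in rows:
        pid = row.get("patient_id")
        text = row.get("text")
        if pid in (None, ""):
            rejects.append(f"line {lineno}: missing patient_id")
            continue
        if text is None:
            rejects.append(f"line {lineno}: missing text")
            continue
        note_id = str(row.get("note_id") or f"line{lineno}")
        if note_id in seen_ids:
            rejects.append(f"line {lineno}: duplicate note_id {note_id!r}")
            continue
        seen_ids.add(note_id)
        notes.append(
            ClinicalNote(
                patient_id=str(pid),
                note_id=note_id,
                note_type=NoteType.coerce(row.get("note_type")),
                date=_parse_date(row.get("date")),
                text=str(text),
            )
        )
    if not notes and not rejects:
        logger.warning("corpus %s is empty", path)
    if rejects:
        logger.warning("corpus %s: %d rows rejected", path, len(rejects))
    return notes, rejects


def write_corpus(notes: Iterable[ClinicalNote], path: str | Path) -> None:
    """Write notes as JSON-lines (the inverse of :func:`read_corpus`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(
                json.dumps(
                    {
                        "patient_id": note.patient_id,
                        "note_id": note.note_id,
                        "note_type": note.note_type.value,
                        "date": note.date.isoformat() if note.date else None,
                        "text": note.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def _note_sort_key(note: ClinicalNote):
    # dateless notes sort after dated ones; stable tie-break by note_id
    return (note.date is None, note.date or datetime.date.min, note.note_id)


def assemble_patients(notes: Iterable[ClinicalNote]) -> list[PatientRecord]:
    """Group notes per patient, ordered ascending by date.

    Ties on date break by ``note_id``; dateless notes sort last.  The result
    is a partition: every input note appears in exactly one record.
    """
    by_patient: dict[str, list[ClinicalNote]] = {}
    for note in notes:
        by_patient.setdefault(note.patient_id, []).append(note)
    records = []
    for pid in sorted(by_patient):
        records.append(
            PatientRecord(patient_id=pid, notes=sorted(by_patient[pid], key=_note_sort_key))
        )
    return records


def apply_cohort_filters(
    records: Sequence[PatientRecord],
    min_encounters: int = 2,
    max_age: float = 90,
) -> tuple[list[PatientRecord], dict[str, int]]:
    """Apply cohort exclusions in declared order; return survivors and a tally.

    A note counts as one encounter.  Patients with an unknown age are never
    excluded on age.
    """
    if min_encounters < 0:
        raise ValueError("min_encounters must be >= 0")
    tally = {"min_encounters": 0, "max_age": 0}
    kept = []
    for rec in records:
        if len(rec.notes) < min_encounters:
            tally["min_encounters"] += 1
            continue
        if rec.age_at_diagnosis is not None and rec.age_at_diagnosis > max_age:
            tally["max_age"] += 1
            continue
        kept.append(rec)
    return kept, tally


def select_notes_for_stage_kind(
    record: PatientRecord, stage_kind: StageKind | str
) -> list[ClinicalNote]:
    """Notes eligible for abstracting the given stage kind, order preserved."""
    kind = StageKind(stage_kind)
    allowed = STAGE_KIND_NOTE_TYPES[kind]
    return [n for n in record.notes if n.note_type in allowed]


def read_stage_table(path: str | Path) -> pd.DataFrame:
    """Read a registry / gold / prediction table (empty cell = missing)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df.replace("", pd.NA)
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def write_stage_table(df: pd.DataFrame, path: str | Path) -> None:
    df = df.copy()
    df.to_csv(path, index=False, na_rep="")
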