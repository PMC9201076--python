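import datetime

import pytest

from tnmstage import ClinicalNote, NoteType, default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def make_note(
    patient_id="P1",
    note_id="N1",
    note_type=NoteType.PROGRESS,
    date="2015-03-01",
    text="",
):
    return ClinicalNote(
        patient_id=patient_id,
        note_id=note_id,
        note_type=NoteType.coerce(note_type),
        date=datetime.date.fromisoformat(date) if date else None,
        text=text,
    )


@pytest.fixture
def note_factory():
    return make_note
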