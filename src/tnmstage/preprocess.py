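"""Text normalization feeding the ML arm.

The chain is: sentence boundary detection -> tokenization -> lowercase ->
drop punctuation-only and single-letter alphabetic tokens -> spell out
numbers.  The rule engine deliberately consumes *raw* sentence text instead,
because punctuation and short alphanumerics ("pT1N2M0.", "t2a") are
stage-bearing.

Number spelling: integers 0-20 become single number words ("thirteen");
larger integers and all decimals are spelled digit-by-digit ("2405" ->
"two four zero five", "4.5" -> "four point five").  Mixed alphanumeric
tokens such as "t2a" are preserved intact — they carry staging signal.

The sentence splitter is rule-based with a fixed clinical abbreviation
list; it is deterministic and needs no learned model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .corpus import PatientRecord, StageKind, select_notes_for_stage_kind

#: Abbreviations whose trailing period does not end a sentence.
ABBREVIATIONS = frozenset(
    {
        "dr", "mr", "mrs", "ms", "prof", "jr", "sr", "st", "vs", "etc",
        "e.g", "i.e", "approx", "dept", "fig", "inc", "ltd", "hx", "dx",
        "tx", "fx", "pt", "pts", "resp", "neg", "pos", "min", "max",
    }
)

_NUM_WORDS = [
    "zero", "one", "two", "three", "four", "five", "six", "seven", "eight",
    "nine", "ten", "eleven", "twelve", "thirteen", "fourteen", "fifteen",
    "sixteen", "seventeen", "eighteen", "nineteen", "twenty",
]
_WORD_TO_NUM = {w: i for i, w in enumerate(_NUM_WORDS)}
_DIGIT_WORDS = _NUM_WORDS[:10]


@dataclass(frozen=True)
class Sentence:
    """One sentence of a note; ``char_span`` slices the note text exactly."""

    text: str
    index: int
    char_span: tuple[int, int]
    note_id: str | None = None


@dataclass
class TokenStream:
    tokens: list[str] = field(default_factory=list)
    sentence: Sentence | None = None


_BOUNDARY = re.compile(r"[.!?]+(?=\s|$)|\n+")
_TOKEN = re.compile(r"\d+\.\d+|[A-Za-z0-9]+")


def split_sentences(text: str, note_id: str | None = None) -> list[Sentence]:
    """Split note text into sentences with exact character spans.

    Boundaries are sentence-final punctuation followed by whitespace (or end
    of text) and newlines, except after known clinical abbreviations.
    Concatenating the spans covers all non-whitespace text.
    """
    if not text:
        return []
    cut_points = [0]
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        if m.group(0)[0] == ".":
            # look back at the word before the period
            prev = re.search(r"([A-Za-z][A-Za-z.]*)\.$", text[: m.start() + 1])
            if prev and prev.group(1).lower().rstrip(".") in ABBREVIATIONS:
                continue
            if prev and len(prev.group(1)) == 1:
                continue  # initials such as "J."
        cut_points.append(end)
    cut_points.append(len(text))

    sentences: list[Sentence] = []
    for start, stop in zip(cut_points, cut_points[1:]):
        segment = text[start:stop]
        stripped = segment.strip()
        if not stripped:
            continue
        lead = len(segment) - len(segment.lstrip())
        span = (start + lead, start + lead + len(stripped))
        sentences.append(
            Sentence(text=stripped, index=len(sentences), char_span=span, note_id=note_id)
        )
    return sentences


def spell_integer(number: str) -> list[str]:
    """Spell an integer literal as number words (single word up to twenty,
    digit-by-digit beyond)."""
    value = int(number)
    if 0 <= value <= 20 and number == str(value):
        return [_NUM_WORDS[value]]
    return [_DIGIT_WORDS[int(d)] for d in number]


def unspell_number(words: list[str]) -> str:
    """Inverse of :func:`spell_integer` for integers (round-trip check)."""
    if len(words) == 1 and words[0] in _WORD_TO_NUM:
        return str(_WORD_TO_NUM[words[0]])
    digits = []
    for w in words:
        if w not in _WORD_TO_NUM or _WORD_TO_NUM[w] > 9:
            raise ValueError(f"not a spelled digit: {w!r}")
        digits.append(str(_WORD_TO_NUM[w]))
    return "".join(digits)


def _spell_float(literal: str) -> list[str]:
    whole, frac = literal.split(".")
    out = [_DIGIT_WORDS[int(d)] for d in whole]
    out.append("point")
    out.extend(_DIGIT_WORDS[int(d)] for d in frac)
    return out


def normalize_tokens(sentence: Sentence | str) -> TokenStream:
    """Tokenize and normalize one sentence for vectorization.

    Deterministic and idempotent on its own output rendered as text.
    """
    sent = sentence if isinstance(sentence, Sentence) else None
    text = sentence.text if isinstance(sentence, Sentence) else sentence
    tokens: list[str] = []
    for m in _TOKEN.finditer(text):
        tok = m.group(0).lower()
        if "." in tok:
            tokens.extend(_spell_float(tok))
        elif tok.isdigit():
            tokens.extend(spell_integer(tok))
        elif tok.isalpha() and len(tok) == 1:
            continue
        else:
            tokens.append(tok)
    return TokenStream(tokens=tokens, sentence=sent)


def concatenate_patient_text(
    record: PatientRecord, stage_kind: StageKind | str
) -> list[Sentence]:
    """All sentences from the stage-kind-eligible notes, in date order."""
    sentences: list[Sentence] = []
    for note in select_notes_for_stage_kind(record, stage_kind):
        sentences.extend(split_sentences(note.text, note_id=note.note_id))
    return sentences
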