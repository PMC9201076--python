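"""Rule-based TNM stage extraction.

Four layers, applied per sentence and then aggregated per patient:

1. **Compact-pattern grammar** — recognizes prefixed or bare concatenated
   TNM shorthand such as ``pT1N2M0`` or ``cT2a N0 M0``.  The kind prefix
   (``c`` = clinical, ``p``/``yp`` = pathological) applies to every
   component of one pattern.
2. **Narrative term mapping** — staging lexicon terms that carry a mapped
   numeral ("extracapsular extension" -> T3), bare stage tokens with no
   prefix ("t3a" alone, flagged ambiguous), and overall-stage phrases
   ("stage 1 prostate cancer", recorded but never converted to TNM).
3. **ConText-style contextual flagging** — negation, historical,
   hypothetical and other-experiencer scopes opened by trigger terms and
   bounded by termination terms or same-type triggers.
4. **Patient-level resolution** — discard negated/hypothetical/
   other-experiencer mentions (historical retained), route by prefix or
   note type, take the modal numeral (recency breaks ties), then
   dichotomize into the binary task categories.

A negated specific value with no surviving positive evidence asserts the
complementary benign value on the binary axes only: a negated M1 yields M0,
a negated N1 yields N0; never for T.
"""

from __future__ import annotations

import datetime
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .corpus import (
    ClinicalNote,
    NoteType,
    PatientRecord,
    StageKind,
    TASKS,
    select_notes_for_stage_kind,
)
from .lexicon import Lexicon, TargetTerm, match_modifiers, match_targets
from .preprocess import split_sentences

logger = logging.getLogger(__name__)

CLINICAL = "clinical"
PATHOLOGICAL = "pathological"
UNSPECIFIED = "unspecified"

#: Legal mention-level numeral ranges per axis.
MENTION_RANGE = {"T": (0, 4), "N": (0, 3), "M": (0, 1)}

#: task id per (stage kind, axis)
TASK_IDS = {
    (CLINICAL, "T"): "cT",
    (CLINICAL, "N"): "cN",
    (CLINICAL, "M"): "cM",
    (PATHOLOGICAL, "T"): "pT",
    (PATHOLOGICAL, "N"): "pN",
}

#: Binary task category domains after dichotomization.
TASK_CATEGORIES = {
    "cT": ("T1-2", "T3-4"),
    "cN": ("N0", "N1"),
    "cM": ("M0", "M1"),
    "pT": ("T2", "T3-4"),
    "pN": ("N0", "N1"),
}


@dataclass
class ContextFlags:
    negated: bool = False
    historical: bool = False
    hypothetical: bool = False
    experiencer_other: bool = False


@dataclass
class StageMention:
    """One detected stage assertion within a sentence."""

    axis: str  # T | N | M | overall
    numeral: int
    subtype: str | None = None  # a-c, T only
    prefix: str = UNSPECIFIED  # clinical | pathological | unspecified
    context: ContextFlags = field(default_factory=ContextFlags)
    span: tuple[int, int] = (0, 0)
    source: str = "compact_pattern"  # compact_pattern | narrative_term
    ambiguous: bool = False
    # provenance attached by the patient-level pipeline
    note_id: str | None = None
    note_type: NoteType | None = None
    date: datetime.date | None = None
    sentence_index: int | None = None
    sentence_text: str | None = None


@dataclass
class ResolvedField:
    """One resolved, dichotomized patient-level stage field."""

    category: str
    numeral: int | None
    provenance: list[StageMention]
    ambiguous: bool = False
    from_negation: bool = False


@dataclass
class PatientStage:
    """Per-patient dichotomized stage fields keyed by task id (cT..pN)."""

    patient_id: str
    fields: dict[str, ResolvedField] = field(default_factory=dict)

    def category(self, task: str) -> str | None:
        f = self.fields.get(task)
        return f.category if f else None


_PREFIX_MAP = {"c": CLINICAL, "p": PATHOLOGICAL, "yp": PATHOLOGICAL}

_COMPACT = re.compile(
    r"\b(?P<prefix>yp|c|p)?"
    r"(?=[tnm]\d)"
    r"(?:t(?P<t>\d)(?P<tsub>[a-c])?)?"
    r"(?:\s*n(?P<n>\d))?"
    r"(?:\s*m(?P<m>\d))?"
    r"\b",
    re.IGNORECASE,
)

_BARE_TOKEN = re.compile(r"\b(?:t(?P<t>[0-4])(?P<tsub>[a-c])?|n(?P<n>[0-3])|m(?P<m>[01]))\b", re.I)

_OVERALL = re.compile(r"\bstage\s+(?P<num>[1-4]|iv|iii|ii|i)\b", re.I)
_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4}


def _in_range(axis: str, numeral: int) -> bool:
    lo, hi = MENTION_RANGE[axis]
    return lo <= numeral <= hi


def parse_compact_tnm(sentence_text: str) -> list[StageMention]:
    """Parse compact TNM shorthand from raw sentence text.

    A pattern needs a kind prefix or at least two axis components; a bare
    single component ("t3a" alone) is left to the narrative detector, which
    flags it ambiguous.  Out-of-range numerals yield no mention.
    """
    mentions: list[StageMention] = []
    for m in _COMPACT.finditer(sentence_text):
        if m.start() == m.end():
            continue
        prefix_raw = m.group("prefix")
        prefix = _PREFIX_MAP[prefix_raw.lower()] if prefix_raw else UNSPECIFIED
        components: list[StageMention] = []
        for axis, group, sub_group in (("T", "t", "tsub"), ("N", "n", None), ("M", "m", None)):
            raw = m.group(group)
            if raw is None:
                continue
            numeral = int(raw)
            if not _in_range(axis, numeral):
                logger.debug("compact component %s%s out of range, skipped", axis, raw)
                continue
            subtype = m.group(sub_group).lower() if sub_group and m.group(sub_group) else None
            start, end = m.span(group)
            components.append(
                StageMention(
                    axis=axis,
                    numeral=numeral,
                    subtype=subtype,
                    prefix=prefix,
                    span=(start - 1, m.span(sub_group)[1] if subtype else end),
                    source="compact_pattern",
                )
            )
        if prefix == UNSPECIFIED and len(components) < 2:
            continue
        mentions.extend(components)
    return mentions


def render_compact(mentions: Sequence[StageMention]) -> str:
    """Render mentions from one compact pattern back to its canonical string."""
    if not mentions:
        return ""
    prefix = mentions[0].prefix
    letter = {CLINICAL: "c", PATHOLOGICAL: "p", UNSPECIFIED: ""}[prefix]
    parts = []
    for axis in ("T", "N", "M"):
        for m in mentions:
            if m.axis == axis:
                parts.append(f"{axis}{m.numeral}{m.subtype or ''}")
                break
    return letter + "".join(parts)


def detect_narrative_mentions(
    sentence_text: str, target_terms: Iterable[TargetTerm]
) -> list[StageMention]:
    """Detect lexicon-term, bare-token and overall-stage mentions.

    Lexicon terms carrying a mapped numeral yield mentions with the term's
    stage-kind hint as prefix.  Bare unprefixed stage tokens ("t3a") and
    overall-stage phrases ("stage 1 prostate cancer") are flagged ambiguous;
    overall-stage mentions use axis ``overall`` and are never converted to
    TNM values.
    """
    mentions: list[StageMention] = []
    term_spans: list[tuple[int, int]] = []
    for term, span in match_targets(sentence_text, target_terms):
        term_spans.append(span)
        if term.numeral is None:
            continue
        mentions.append(
            StageMention(
                axis=term.axis,
                numeral=term.numeral,
                prefix=term.stage_kind_hint,
                span=span,
                source="narrative_term",
            )
        )
    taken = list(term_spans)

    def overlaps_taken(span):
        return any(span[0] < e and s < span[1] for s, e in taken)

    for m in _OVERALL.finditer(sentence_text):
        raw = m.group("num").lower()
        numeral = _ROMAN.get(raw, None) or int(raw) if raw.isdigit() or raw in _ROMAN else None
        if numeral is None or overlaps_taken(m.span()):
            continue
        mentions.append(
            StageMention(
                axis="overall",
                numeral=numeral,
                span=m.span(),
                source="narrative_term",
                ambiguous=True,
            )
        )
        taken.append(m.span())
    for m in _BARE_TOKEN.finditer(sentence_text):
        if overlaps_taken(m.span()):
            continue
        if m.group("t") is not None:
            axis, numeral = "T", int(m.group("t"))
            subtype = (m.group("tsub") or "").lower() or None
        elif m.group("n") is not None:
            axis, numeral, subtype = "N", int(m.group("n")), None
        else:
            axis, numeral, subtype = "M", int(m.group("m")), None
        mentions.append(
            StageMention(
                axis=axis,
                numeral=numeral,
                subtype=subtype,
                span=m.span(),
                source="narrative_term",
                ambiguous=True,
            )
        )
        taken.append(m.span())
    return mentions


_FLAG_BY_TYPE = {
    "negation": "negated",
    "historical": "historical",
    "hypothetical": "hypothetical",
    "experiencer_other": "experiencer_other",
}


def apply_context(
    sentence_text: str,
    mentions: Sequence[StageMention],
    modifier_triggers,
) -> list[StageMention]:
    """Set ConText flags on mentions according to trigger scopes.

    A trigger opens a scope in its direction, bounded by the sentence end,
    a termination trigger, or another trigger of the same type.  Pseudo
    triggers (matched longest-first) shadow embedded triggers and open no
    scope.  A trigger lying inside a mention's own span never flags that
    mention.
    """
    trig_matches = match_modifiers(sentence_text, modifier_triggers)
    terminations = [span for trig, span in trig_matches if trig.modifier_type == "termination"]
    by_type: dict[str, list[tuple[int, int]]] = {}
    for trig, span in trig_matches:
        by_type.setdefault(trig.modifier_type, []).append(span)

    n = len(sentence_text)
    for trig, (ts, te) in trig_matches:
        flag = _FLAG_BY_TYPE.get(trig.modifier_type)
        if flag is None:
            continue
        same_type = [s for s in by_type[trig.modifier_type] if s != (ts, te)]
        scopes: list[tuple[int, int]] = []
        if trig.direction in ("forward", "bidirectional"):
            end = n
            for s, _ in terminations:
                if s >= te:
                    end = min(end, s)
            for s, _ in same_type:
                if s >= te:
                    end = min(end, s)
            scopes.append((te, end))
        if trig.direction in ("backward", "bidirectional"):
            start = 0
            for _, e in terminations:
                if e <= ts:
                    start = max(start, e)
            for _, e in same_type:
                if e <= ts:
                    start = max(start, e)
            scopes.append((start, ts))
        for m in mentions:
            ms, me = m.span
            if ms < te and ts < me:
                continue  # trigger inside / overlapping the mention itself
            for ss, se in scopes:
                if ms < se and ss < me:
                    setattr(m.context, flag, True)
                    break
    return list(mentions)


def extract_sentence_mentions(sentence_text: str, lexicon: Lexicon) -> list[StageMention]:
    """All mentions in one raw sentence, contextual flags applied."""
    compact = parse_compact_tnm(sentence_text)
    compact_spans = [m.span for m in compact]
    narrative = [
        m
        for m in detect_narrative_mentions(sentence_text, lexicon.targets)
        if not any(m.span[0] < e and s < m.span[1] for s, e in compact_spans)
    ]
    mentions = compact + narrative
    return apply_context(sentence_text, mentions, lexicon.modifiers)


def extract_note_mentions(note: ClinicalNote, lexicon: Lexicon) -> list[StageMention]:
    out = []
    for sentence in split_sentences(note.text, note_id=note.note_id):
        for m in extract_sentence_mentions(sentence.text, lexicon):
            out.append(
                replace(
                    m,
                    note_id=note.note_id,
                    note_type=note.note_type,
                    date=note.date,
                    sentence_index=sentence.index,
                    sentence_text=sentence.text,
                )
            )
    return out


def dichotomize(stage_kind: str, axis: str, numeral: int) -> str:
    """Collapse a raw stage numeral into the binary task category.

    Clinical T: 1-2 vs 3-4; clinical/pathological N: 0 vs >=1; clinical M:
    0 vs 1; pathological T: <=2 vs 3-4.  Pathological M is unsupported
    (assigned only after prostatectomy and vanishingly rare).
    """
    kind = StageKind(stage_kind).value
    if axis == "M" and kind == PATHOLOGICAL:
        raise ValueError("pathological M stage is not a supported task")
    if not _in_range(axis, numeral):
        raise ValueError(f"numeral {numeral} illegal for axis {axis}")
    if axis == "T":
        if kind == CLINICAL:
            return "T1-2" if numeral <= 2 else "T3-4"
        return "T2" if numeral <= 2 else "T3-4"
    if axis == "N":
        return "N0" if numeral == 0 else "N1"
    return "M0" if numeral == 0 else "M1"


def _route(mention: StageMention) -> str:
    """Stage kind a mention is evidence for: its prefix, else by note type."""
    if mention.prefix != UNSPECIFIED:
        return mention.prefix
    if mention.note_type == NoteType.PATHOLOGY:
        return PATHOLOGICAL
    return CLINICAL


def _recency_key(m: StageMention):
    return (
        m.date is not None,
        m.date or datetime.date.min,
        m.note_id or "",
        m.sentence_index or 0,
        m.span,
    )


def resolve_patient_stage(
    mentions: Sequence[StageMention], stage_kind: StageKind | str
) -> dict[str, ResolvedField]:
    """Resolve all mentions of one patient into per-axis dichotomized fields.

    Deterministic and invariant to mention list order: the modal numeral is
    chosen per axis, ties broken by the most recent supporting mention
    (note date, then note id, then position in text).
    """
    kind = StageKind(stage_kind).value
    axes = ("T", "N") if kind == PATHOLOGICAL else ("T", "N", "M")
    resolved: dict[str, ResolvedField] = {}
    for axis in axes:
        task = TASK_IDS[(kind, axis)]
        pool = [m for m in mentions if m.axis == axis]
        routed = [m for m in pool if _route(m) == kind]
        active = [
            m
            for m in routed
            if not (m.context.negated or m.context.hypothetical or m.context.experiencer_other)
        ]
        if active:
            counts: dict[int, int] = {}
            for m in active:
                counts[m.numeral] = counts.get(m.numeral, 0) + 1
            top = max(counts.values())
            modal = {num for num, c in counts.items() if c == top}
            if len(modal) == 1:
                chosen = modal.pop()
            else:
                chosen = max(
                    (m for m in active if m.numeral in modal), key=_recency_key
                ).numeral
            support = sorted((m for m in active if m.numeral == chosen), key=_recency_key)
            resolved[task] = ResolvedField(
                category=dichotomize(kind, axis, chosen),
                numeral=chosen,
                provenance=support,
                ambiguous=any(m.ambiguous for m in support),
            )
            continue
        # complementary assertion: negated positive value on a binary axis
        if axis in ("N", "M"):
            negs = [
                m
                for m in routed
                if m.context.negated
                and not (m.context.hypothetical or m.context.experiencer_other)
                and m.numeral >= 1
            ]
            if negs:
                resolved[task] = ResolvedField(
                    category=dichotomize(kind, axis, 0),
                    numeral=0,
                    provenance=sorted(negs, key=_recency_key),
                    ambiguous=any(m.ambiguous for m in negs),
                    from_negation=True,
                )
    return resolved


def extract_patient_stage(
    record: PatientRecord,
    lexicon: Lexicon,
    stage_kinds: Sequence[str] = (CLINICAL, PATHOLOGICAL),
) -> PatientStage:
    """Run the full rule pipeline for one patient."""
    stage = PatientStage(patient_id=record.patient_id)
    for kind in stage_kinds:
        mentions: list[StageMention] = []
        for note in select_notes_for_stage_kind(record, kind):
            mentions.extend(extract_note_mentions(note, lexicon))
        stage.fields.update(resolve_patient_stage(mentions, kind))
    return stage


def extract_stage_table(
    records: Sequence[PatientRecord],
    lexicon: Lexicon,
    stage_kinds: Sequence[str] = (CLINICAL, PATHOLOGICAL),
) -> pd.DataFrame:
    """Rule-engine predictions for a cohort, in the stage-table schema."""
    rows = []
    for rec in records:
        stage = extract_patient_stage(rec, lexicon, stage_kinds)
        row = {"patient_id": rec.patient_id}
        for task in TASKS:
            row[task] = stage.category(task)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["patient_id"] + TASKS)
    return df.astype("object").where(pd.notna(df), pd.NA)
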