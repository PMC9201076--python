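"""Staging target-term and contextual-modifier lexicons.

Two complementary dictionaries drive both extraction arms:

* **target terms** — phrases that assert (or anchor discussion of) primary
  tumor extent (T), regional node involvement (N) or distant metastasis (M).
  A term may carry a mapped stage numeral (e.g. "extracapsular extension"
  maps to T3 under AJCC 7th-edition prostate criteria) or act as a bare
  anchor used only to locate stage-bearing context.
* **modifier triggers** — NegEx/ConText-style phrases that open negation,
  historical, hypothetical or other-experiencer scopes, plus pseudo-triggers
  (which block a shorter embedded trigger) and termination terms (which
  close scopes).

The bundled lexicon is a clinically curated set built from AJCC 7th-edition
prostate T/N/M criteria and common narrative synonyms; it is a plain
tab-separated file so sites can substitute their own terminology.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

AXES = ("T", "N", "M")

#: Legal mapped numerals per axis for lexicon entries and mentions.
AXIS_NUMERAL_RANGE = {"T": (0, 4), "N": (0, 3), "M": (0, 1)}

MODIFIER_TYPES = (
    "negation",
    "historical",
    "hypothetical",
    "experiencer_other",
    "pseudo",
    "termination",
)
DIRECTIONS = ("forward", "backward", "bidirectional")


@dataclass(frozen=True)
class TargetTerm:
    surface: str
    axis: str
    numeral: int | None = None
    stage_kind_hint: str = "unspecified"  # clinical | pathological | unspecified
    source: str = "expert"  # AJCC | expert | embedding_expansion


@dataclass(frozen=True)
class ModifierTrigger:
    surface: str
    modifier_type: str
    direction: str = "forward"


@dataclass
class Lexicon:
    targets: list[TargetTerm]
    modifiers: list[ModifierTrigger]

    def targets_for_axis(self, axis: str) -> list[TargetTerm]:
        return [t for t in self.targets if t.axis == axis]


def _norm_surface(s: str) -> str:
    return re.sub(r"\s+", " ", s.strip().lower())


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon file.

    The file is tab-separated UTF-8 with ``#`` comments and two sections
    introduced by ``[targets]`` and ``[modifiers]`` lines.  Target rows are
    ``surface<TAB>axis<TAB>numeral<TAB>kind<TAB>source`` (numeral may be
    empty for anchor-only terms); modifier rows are
    ``surface<TAB>type<TAB>direction``.  Invalid rows are rejected and
    logged; duplicate surfaces are collapsed with a warning.
    """
    targets: list[TargetTerm] = []
    modifiers: list[ModifierTrigger] = []
    seen_t: dict[str, TargetTerm] = {}
    seen_m: dict[str, ModifierTrigger] = {}
    section = None
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if line.strip() in ("[targets]", "[modifiers]"):
            section = line.strip()
            continue
        cols = [c.strip() for c in line.split("\t")]
        if section == "[targets]":
            if len(cols) < 2:
                logger.warning("lexicon line %d: too few columns, rejected", lineno)
                continue
            surface = _norm_surface(cols[0])
            axis = cols[1].upper()
            numeral = cols[2] if len(cols) > 2 else ""
            kind = (cols[3] if len(cols) > 3 else "") or "unspecified"
            source = (cols[4] if len(cols) > 4 else "") or "expert"
            if not surface or axis not in AXES:
                logger.warning("lexicon line %d: invalid axis %r, rejected", lineno, axis)
                continue
            if numeral:
                lo, hi = AXIS_NUMERAL_RANGE[axis]
                try:
                    num = int(numeral)
                except ValueError:
                    logger.warning("lexicon line %d: bad numeral %r, rejected", lineno, numeral)
                    continue
                if not lo <= num <= hi:
                    logger.warning(
                        "lexicon line %d: numeral %d out of range for %s, rejected",
                        lineno, num, axis,
                    )
                    continue
            else:
                num = None
            if kind not in ("clinical", "pathological", "unspecified"):
                logger.warning("lexicon line %d: bad kind %r, rejected", lineno, kind)
                continue
            term = TargetTerm(surface, axis, num, kind, source)
            if surface in seen_t:
                logger.warning("lexicon line %d: duplicate target %r collapsed", lineno, surface)
                continue
            seen_t[surface] = term
            targets.append(term)
        elif section == "[modifiers]":
            if len(cols) < 2:
                logger.warning("lexicon line %d: too few columns, rejected", lineno)
                continue
            surface = _norm_surface(cols[0])
            mtype = cols[1]
            direction = (cols[2] if len(cols) > 2 else "") or "forward"
            if not surface or mtype not in MODIFIER_TYPES or direction not in DIRECTIONS:
                logger.warning("lexicon line %d: invalid modifier row, rejected", lineno)
                continue
            if surface in seen_m:
                logger.warning("lexicon line %d: duplicate modifier %r collapsed", lineno, surface)
                continue
            trig = ModifierTrigger(surface, mtype, direction)
            seen_m[surface] = trig
            modifiers.append(trig)
        else:
            logger.warning("lexicon line %d: outside any section, ignored", lineno)
    return Lexicon(targets=targets, modifiers=modifiers)


def default_lexicon() -> Lexicon:
    """The bundled prostate staging lexicon."""
    path = resources.files("tnmstage").joinpath("data/lexicon.tsv")
    return load_lexicon(str(path))


def _compile_surfaces(surfaces: Sequence[str]) -> re.Pattern | None:
    if not surfaces:
        return None
    # longest-first alternation => longest-match-wins at each position
    parts = sorted(set(surfaces), key=len, reverse=True)
    alts = [re.escape(p).replace(r"\ ", r"\s+") for p in parts]
    return re.compile(r"\b(?:" + "|".join(alts) + r")\b", re.IGNORECASE)


def match_surfaces(sentence: str, surfaces: Sequence[str]) -> list[tuple[str, tuple[int, int]]]:
    """Case-insensitive longest-match-wins matching at word boundaries.

    Returns ``(normalized_surface, (start, end))`` pairs with 0-based
    half-open character spans; spans never overlap.
    """
    pattern = _compile_surfaces(surfaces)
    if pattern is None:
        return []
    out = []
    for m in pattern.finditer(sentence):
        out.append((_norm_surface(m.group(0)), m.span()))
    return out


def match_targets(sentence: str, terms: Iterable[TargetTerm]) -> list[tuple[TargetTerm, tuple[int, int]]]:
    """Match target terms in a raw sentence (longest-match-wins, no overlaps)."""
    terms = list(terms)
    by_surface = {t.surface: t for t in terms}
    return [
        (by_surface[s], span)
        for s, span in match_surfaces(sentence, list(by_surface))
        if s in by_surface
    ]


def match_modifiers(
    sentence: str, modifiers: Iterable[ModifierTrigger]
) -> list[tuple[ModifierTrigger, tuple[int, int]]]:
    """Match modifier triggers; pseudo triggers shadow embedded shorter ones."""
    modifiers = list(modifiers)
    by_surface = {m.surface: m for m in modifiers}
    return [
        (by_surface[s], span)
        for s, span in match_surfaces(sentence, list(by_surface))
        if s in by_surface
    ]
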