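"""Synthetic prostate-cancer note corpora with known ground truth.

The generator stands in for PHI-restricted institutional data.  It emulates
the statistical structure the extractors assume: a cohort whose
registry-observed stage marginals match a large real-world prostate cancer
cohort (clinical T1 44%, T2 19%, T3 3%, T4 1%, 33% missing; N0 61%, N1 3%;
M0 62%, M1 5%; about a third of patients undergo prostatectomy and acquire
pathological stage, pT2 51%, pT3-4 30%); date-ordered longitudinal notes of
mixed types per patient; stage rendered as compact TNM shorthand or
narrative phrasings; and configurable rates of negated, historical,
hypothetical and prefix-ambiguous mentions plus distractor sentences.

Every patient has a *true* stage per applicable axis, drawn from the
normalized non-missing mass; the registry cell is then blanked
independently with the missing mass, and note documentation is dropped
independently at ``p_missing_documentation``.  Registry missingness is thus
independent of what the notes say, so some missing registry fields are
recoverable from text and some are not — which is what makes imputation
accounting non-trivial.
"""

from __future__ import annotations

import dataclasses
import datetime
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import ClinicalNote, NoteType, REGISTRY_COLUMNS, TASKS
from .rules import CLINICAL, PATHOLOGICAL, dichotomize

_AXIS_OF_TASK = {"cT": "T", "cN": "N", "cM": "M", "pT": "T", "pN": "N"}
_KIND_OF_TASK = {"cT": CLINICAL, "cN": CLINICAL, "cM": CLINICAL, "pT": PATHOLOGICAL, "pN": PATHOLOGICAL}

CLINICAL_NOTE_TYPES = [
    NoteType.HISTORY_PHYSICAL,
    NoteType.PROGRESS,
    NoteType.OPERATIVE,
    NoteType.DISCHARGE_TRANSFER,
]


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Stage probabilities are the registry-observed marginals of the emulated
    cohort; each ``*_missing`` rate is the independent probability that the
    registry cell is blank.  True stages are drawn from the normalized
    non-missing mass, so registry marginals converge to the configured
    numbers.
    """

    n_patients: int = 100
    seed: int = 0
    clinical_t: dict[int, float] = field(default_factory=lambda: {1: 0.44, 2: 0.19, 3: 0.03, 4: 0.01})
    clinical_t_missing: float = 0.33
    clinical_n: dict[int, float] = field(default_factory=lambda: {0: 0.61, 1: 0.03})
    clinical_n_missing: float = 0.36
    clinical_m: dict[int, float] = field(default_factory=lambda: {0: 0.62, 1: 0.05})
    clinical_m_missing: float = 0.33
    surgery_fraction: float = 0.33
    path_t: dict[int, float] = field(default_factory=lambda: {2: 0.51, 3: 0.27, 4: 0.03})
    path_t_missing: float = 0.19
    path_n: dict[int, float] = field(default_factory=lambda: {0: 0.75, 1: 0.03})
    path_n_missing: float = 0.22
    notes_per_patient: tuple[int, int] = (2, 5)
    p_negation_sentence: float = 0.15
    p_historical: float = 0.05
    p_hypothetical: float = 0.05
    p_ambiguous_prefix: float = 0.20
    p_compact_pattern: float = 0.60
    p_missing_documentation: float = 0.10

    def validate(self) -> None:
        problems = []
        for name, probs, missing in (
            ("clinical_t", self.clinical_t, self.clinical_t_missing),
            ("clinical_n", self.clinical_n, self.clinical_n_missing),
            ("clinical_m", self.clinical_m, self.clinical_m_missing),
            ("path_t", self.path_t, self.path_t_missing),
            ("path_n", self.path_n, self.path_n_missing),
        ):
            total = sum(probs.values()) + missing
            if abs(total - 1.0) > 1e-9:
                problems.append(f"{name}: probabilities + missing mass sum to {total}, not 1")
            if any(not 0 <= p <= 1 for p in list(probs.values()) + [missing]):
                problems.append(f"{name}: probability outside [0, 1]")
        for name in (
            "surgery_fraction",
            "p_negation_sentence",
            "p_historical",
            "p_hypothetical",
            "p_ambiguous_prefix",
            "p_compact_pattern",
            "p_missing_documentation",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                problems.append(f"{name}: {v} outside [0, 1]")
        if self.n_patients < 0:
            problems.append("n_patients must be >= 0")
        lo, hi = self.notes_per_patient
        if not (1 <= lo <= hi):
            problems.append("notes_per_patient must be a range with 1 <= lo <= hi")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PatientTruth:
    patient_id: str
    age: int
    surgery: bool
    raw: dict[str, str] = field(default_factory=dict)  # task -> e.g. "T2"
    subtype: dict[str, str] = field(default_factory=dict)  # task -> a-c
    dichotomized: dict[str, str] = field(default_factory=dict)
    documented: dict[str, bool] = field(default_factory=dict)


@dataclass
class GroundTruth:
    patients: dict[str, PatientTruth] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Chart-review-style gold labels.

        A stage can only be abstracted by an annotator if some note documents
        it, so undocumented axes are emitted as missing; the true underlying
        value stays available on :class:`PatientTruth`.
        """
        rows = []
        for truth in self.patients.values():
            row = {"patient_id": truth.patient_id, "age": truth.age, "surgery": truth.surgery}
            for task in TASKS:
                documented = truth.documented.get(task, False)
                row[task] = truth.raw.get(task, "") if documented else ""
                row[f"{task}_documented"] = documented
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class Template:
    style: str
    axis: str  # T | N | M | *
    numeral: str  # digit or *
    kind: str  # any | clinical | pathological
    text: str


def load_templates(path: str | Path | None = None) -> list[Template]:
    if path is None:
        path = resources.files("tnmstage").joinpath("data/templates.txt")
    templates = []
    for raw in Path(str(path)).read_text(encoding="utf-8").splitlines():
        line = raw.rstrip()
        if not line or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 5:
            raise ValueError(f"bad template line: {raw!r}")
        templates.append(Template(*[c.strip() for c in cols[:4]], cols[4].strip()))
    return templates


def _pick(rng: np.random.Generator, items: list):
    return items[int(rng.integers(len(items)))]


def _select(templates, style, axis=None, numeral=None, kind=None):
    out = []
    for t in templates:
        if t.style != style:
            continue
        if axis is not None and t.axis not in ("*", axis):
            continue
        if numeral is not None and t.numeral not in ("*", str(numeral)):
            continue
        if kind is not None and t.kind not in ("any", kind):
            continue
        out.append(t)
    return out


def render_stage_sentence(
    axis: str,
    numeral: int,
    prefix: str,
    style: str,
    rng: np.random.Generator,
    subtype: str | None = None,
    templates: list[Template] | None = None,
) -> str:
    """Render one stage-bearing sentence.

    ``style`` is ``compact`` (parseable shorthand such as ``cT2aN0M0``),
    ``narrative`` (lexicon-term phrasing) or ``ambiguous`` (prefix-less
    phrasing such as "he has t3a prostate cancer").
    """
    templates = templates if templates is not None else load_templates()
    tok = f"{axis}{numeral}{subtype or ''}"
    if style == "compact":
        letter = {CLINICAL: "c", PATHOLOGICAL: "p"}.get(prefix, "")
        frame = _pick(rng, _select(templates, "compact"))
        return frame.text.format(tnm=f"{letter}{tok}")
    if style == "narrative":
        kind = prefix if prefix in (CLINICAL, PATHOLOGICAL) else None
        candidates = _select(templates, "narrative", axis=axis, numeral=numeral, kind=kind)
        if not candidates:
            raise ValueError(f"no narrative template for {axis}{numeral} ({prefix})")
        return _pick(rng, candidates).text
    if style == "ambiguous":
        frame = _pick(rng, _select(templates, "ambiguous", axis=axis))
        return frame.text.format(tok=tok, tok_lower=tok.lower())
    raise ValueError(f"unknown style {style!r}")


def _sample_categorical(rng, probs: dict[int, float]) -> int:
    keys = sorted(probs)
    weights = np.array([probs[k] for k in keys], dtype=float)
    weights /= weights.sum()
    return int(keys[int(rng.choice(len(keys), p=weights))])


def _conditional_kernel(
    row_marginal: dict[int, float],
    col_marginal: dict[int, float],
    concordance: float = 0.1,
) -> dict[int, dict[int, float]]:
    """Joint kernel coupling clinical and pathological stage of one tumor.

    Clinical and pathological stage are correlated measurements of the same
    disease, so pathological values are sampled *conditionally* on the
    clinical value.  A concordance-weighted affinity (``concordance`` is the
    per-step discordance penalty) is calibrated by iterative proportional
    fitting so that both configured marginals are preserved exactly.
    Returns ``P(col | row)`` per row value.
    """
    rows = sorted(row_marginal)
    cols = sorted(col_marginal)
    r = np.array([row_marginal[k] for k in rows], dtype=float)
    c = np.array([col_marginal[k] for k in cols], dtype=float)
    r /= r.sum()
    c /= c.sum()
    # clinical values below the pathological floor couple to the floor value
    floor = cols[0]
    A = np.array(
        [[concordance ** abs(max(rv, floor) - cv) for cv in cols] for rv in rows],
        dtype=float,
    )
    J = A / A.sum()
    for _ in range(200):
        J *= (r / J.sum(axis=1))[:, None]
        J *= c / J.sum(axis=0)
    kernel = {}
    for i, rv in enumerate(rows):
        p = J[i] / J[i].sum()
        kernel[rv] = {cv: float(p[j]) for j, cv in enumerate(cols)}
    return kernel


_T_SUBTYPES = {1: ["a", "b", "c", "c"], 2: ["a", "b", "c"], 3: ["a", "b"], 4: []}


def simulate_corpus(
    config: SimulationConfig,
) -> tuple[list[ClinicalNote], GroundTruth, pd.DataFrame]:
    """Generate a labeled synthetic corpus.

    Returns date-ordered notes, the ground truth (true stages, subtypes,
    dichotomized categories and per-axis documentation flags) and a registry
    table with independent missingness.  Seed-reproducible: identical config
    gives byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    templates = load_templates()
    notes: list[ClinicalNote] = []
    truth = GroundTruth()
    registry_rows = []

    missing_rate = {
        "cT": config.clinical_t_missing,
        "cN": config.clinical_n_missing,
        "cM": config.clinical_m_missing,
        "pT": config.path_t_missing,
        "pN": config.path_n_missing,
    }
    kernel_pt = _conditional_kernel(config.clinical_t, config.path_t)
    kernel_pn = _conditional_kernel(config.clinical_n, config.path_n)

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        age = int(np.clip(round(rng.normal(67, 8)), 45, 89))
        surgery = bool(rng.random() < config.surgery_fraction)
        pt = PatientTruth(patient_id=pid, age=age, surgery=surgery)

        tasks = ["cT", "cN", "cM"] + (["pT", "pN"] if surgery else [])
        registry_row = {"patient_id": pid}
        numerals = {
            "cT": _sample_categorical(rng, config.clinical_t),
            "cN": _sample_categorical(rng, config.clinical_n),
            "cM": _sample_categorical(rng, config.clinical_m),
        }
        if surgery:
            numerals["pT"] = _sample_categorical(rng, kernel_pt[numerals["cT"]])
            numerals["pN"] = _sample_categorical(rng, kernel_pn[numerals["cN"]])
        for task in tasks:
            numeral = numerals[task]
            p_missing = missing_rate[task]
            axis = _AXIS_OF_TASK[task]
            pt.raw[task] = f"{axis}{numeral}"
            if axis == "T" and _T_SUBTYPES.get(numeral):
                pt.subtype[task] = str(_pick(rng, _T_SUBTYPES[numeral]))
            pt.dichotomized[task] = dichotomize(_KIND_OF_TASK[task], axis, numeral)
            pt.documented[task] = bool(rng.random() >= config.p_missing_documentation)
            registry_row[task] = "" if rng.random() < p_missing else pt.raw[task]
        for task in TASKS:
            registry_row.setdefault(task, "")
            pt.documented.setdefault(task, False)
        registry_rows.append(registry_row)
        truth.patients[pid] = pt

        # --- note skeleton: date-ordered, typed -----------------------------
        n_extra = int(rng.integers(config.notes_per_patient[0], config.notes_per_patient[1] + 1))
        note_types = [NoteType.HISTORY_PHYSICAL]
        pool = [NoteType.PROGRESS, NoteType.PROGRESS, NoteType.PROGRESS,
                NoteType.RADIOLOGY, NoteType.DISCHARGE_TRANSFER]
        for _ in range(max(0, n_extra - 1)):
            note_types.append(_pick(rng, pool))
        if surgery:
            note_types.append(NoteType.OPERATIVE)
            note_types.append(NoteType.PATHOLOGY)
        base = datetime.date(2012, 1, 1) + datetime.timedelta(days=int(rng.integers(0, 1500)))
        dates = []
        d = base
        for _ in note_types:
            dates.append(d)
            d = d + datetime.timedelta(days=int(rng.integers(7, 90)))
        sentences_per_note: list[list[str]] = [[] for _ in note_types]
        clinical_idx = [j for j, t in enumerate(note_types) if t in CLINICAL_NOTE_TYPES]
        pathology_idx = [j for j, t in enumerate(note_types) if t == NoteType.PATHOLOGY]

        # --- primary stage sentences ----------------------------------------
        compact_parts: dict[str, list[tuple[str, int, str | None]]] = {CLINICAL: [], PATHOLOGICAL: []}
        for task in tasks:
            if not pt.documented[task]:
                continue
            axis = _AXIS_OF_TASK[task]
            kind = _KIND_OF_TASK[task]
            numeral = int(pt.raw[task][1])
            subtype = pt.subtype.get(task)
            if rng.random() < config.p_ambiguous_prefix:
                style = "ambiguous"
            elif rng.random() < config.p_compact_pattern:
                style = "compact"
            else:
                style = "narrative"
            target_idx = pathology_idx if kind == PATHOLOGICAL else clinical_idx
            if style == "compact":
                compact_parts[kind].append((axis, numeral, subtype))
                continue
            sentence = render_stage_sentence(
                axis, numeral, kind if style == "narrative" else "unspecified",
                style, rng, subtype=subtype, templates=templates,
            )
            sentences_per_note[_pick(rng, target_idx)].append(sentence)
        for kind, parts in compact_parts.items():
            if not parts:
                continue
            letter = "c" if kind == CLINICAL else "p"
            order = {"T": 0, "N": 1, "M": 2}
            parts = sorted(parts, key=lambda p: order[p[0]])
            tnm = letter + "".join(f"{a}{n}{s or ''}" for a, n, s in parts)
            frame = _pick(rng, _select(templates, "compact"))
            target_idx = pathology_idx if kind == PATHOLOGICAL else clinical_idx
            sentences_per_note[_pick(rng, target_idx)].append(frame.text.format(tnm=tnm))

        # --- noise sentences (always consistent with the truth) -------------
        if rng.random() < config.p_negation_sentence:
            benign = []
            if int(pt.raw["cT"][1]) <= 2:
                benign.append("T")
            if pt.raw["cN"] == "N0":
                benign.append("N")
            if pt.raw["cM"] == "M0":
                benign.append("M")
            if benign:
                axis = str(_pick(rng, benign))
                tmpl = _pick(rng, _select(templates, "negation", axis=axis))
                sentences_per_note[_pick(rng, clinical_idx)].append(tmpl.text)
        if rng.random() < config.p_historical:
            task = str(_pick(rng, ["cT", "cN", "cM"]))
            tok = pt.raw[task] + pt.subtype.get(task, "")
            tmpl = _pick(rng, _select(templates, "historical"))
            sentences_per_note[_pick(rng, clinical_idx)].append(
                tmpl.text.format(tok=tok, tok_lower=tok.lower())
            )
        if rng.random() < config.p_hypothetical:
            tmpl = _pick(rng, _select(templates, "hypothetical"))
            sentences_per_note[_pick(rng, clinical_idx)].append(tmpl.text)

        # --- distractors and assembly ---------------------------------------
        distractors = _select(templates, "distractor")
        for j, note_type in enumerate(note_types):
            n_distract = int(rng.integers(1, 4))
            texts = list(sentences_per_note[j])
            for _ in range(n_distract):
                t = _pick(rng, distractors)
                texts.append(t.text.format(psa=f"{rng.uniform(0.5, 25):.1f}"))
            order2 = rng.permutation(len(texts))
            body = " ".join(texts[k] for k in order2)
            notes.append(
                ClinicalNote(
                    patient_id=pid,
                    note_id=f"{pid}-N{j:02d}",
                    note_type=note_type,
                    date=dates[j],
                    text=body,
                )
            )

    registry = pd.DataFrame(registry_rows, columns=REGISTRY_COLUMNS).replace("", pd.NA)
    return notes, truth, registry
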