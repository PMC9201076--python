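"""Semi-supervised ML stage classification.

For each of the five binary staging tasks the arm works as follows: find the
keyword-bearing sentences in the task-appropriate note subset (a sentence
counts as context if it contains an axis-matching lexicon term or a compact
TNM component for that axis), represent each context sentence as the mean of
its in-vocabulary skip-gram token vectors, average those sentence vectors
into one patient vector, and classify it with a binary SVM tuned by random
hyperparameter search (macro-F1 over 5-fold cross-validation on the training
portion of a stratified 80/20 split).

Patients with no keyword context are *degenerate*: their vector is all
zeros, they are excluded from training, and at prediction time they abstain
rather than default-predict, so the imputation accounting can distinguish
"no evidence" from "predicted".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .corpus import PatientRecord, TASKS, select_notes_for_stage_kind
from .embeddings import EmbeddingModel, train_embeddings
from .lexicon import Lexicon, match_targets
from .preprocess import normalize_tokens, split_sentences
from .rules import (
    CLINICAL,
    PATHOLOGICAL,
    TASK_CATEGORIES,
    detect_narrative_mentions,
    parse_compact_tnm,
)

logger = logging.getLogger(__name__)

TASK_KIND = {"cT": CLINICAL, "cN": CLINICAL, "cM": CLINICAL, "pT": PATHOLOGICAL, "pN": PATHOLOGICAL}
TASK_AXIS = {"cT": "T", "cN": "N", "cM": "M", "pT": "T", "pN": "N"}


@dataclass
class PatientVector:
    patient_id: str
    task: str
    vector: np.ndarray
    n_context_sentences: int
    degenerate: bool


@dataclass
class TrainedClassifier:
    task: str
    estimator: Pipeline  # StandardScaler -> SVC
    categories: tuple[str, str]
    hyperparameters: dict
    cv_scores: list[float]
    seed: int
    heldout_metrics: dict = field(default_factory=dict)


def _is_context_sentence(text: str, axis: str, axis_terms) -> bool:
    """Keyword-bearing for the axis: a lexicon term (value-mapped or anchor),
    a compact TNM component, or a bare stage token of that axis."""
    if match_targets(text, axis_terms):
        return True
    if any(m.axis == axis for m in parse_compact_tnm(text)):
        return True
    return any(m.axis == axis for m in detect_narrative_mentions(text, ()))


def build_patient_vector(
    record: PatientRecord,
    task: str,
    embeddings: EmbeddingModel,
    lexicon: Lexicon,
) -> PatientVector:
    """Average keyword-context sentence vectors into one patient vector."""
    axis = TASK_AXIS[task]
    axis_terms = lexicon.targets_for_axis(axis)
    sentence_vectors: list[np.ndarray] = []
    for note in select_notes_for_stage_kind(record, TASK_KIND[task]):
        for sentence in split_sentences(note.text, note_id=note.note_id):
            if not _is_context_sentence(sentence.text, axis, axis_terms):
                continue
            toks = [t for t in normalize_tokens(sentence).tokens if t in embeddings]
            if not toks:
                continue
            sentence_vectors.append(
                np.mean([embeddings.vector(t) for t in toks], axis=0)
            )
    if not sentence_vectors:
        return PatientVector(record.patient_id, task, np.zeros(embeddings.dim), 0, True)
    return PatientVector(
        record.patient_id,
        task,
        np.mean(sentence_vectors, axis=0),
        len(sentence_vectors),
        False,
    )


def _sample_params(rng: np.random.Generator, n: int) -> list[dict]:
    """Random SVM search space: kernel, C, RBF bandwidth, class weighting."""
    params = []
    for _ in range(n):
        kernel = str(rng.choice(["linear", "rbf"]))
        p = {
            "kernel": kernel,
            "C": float(10 ** rng.uniform(-2, 2)),
            "class_weight": [None, "balanced"][int(rng.integers(2))],
        }
        if kernel == "rbf":
            p["gamma"] = float(10 ** rng.uniform(-3, 1))
        params.append(p)
    return params


def train_task_classifier(
    vectors: Sequence[PatientVector],
    labels: Mapping[str, str],
    seed: int = 0,
    n_search: int = 50,
) -> TrainedClassifier:
    """Train one binary SVM with random hyperparameter search.

    Degenerate vectors and unlabeled patients are dropped.  Data are split
    80/20 (stratified); ``n_search`` configurations are scored by mean
    macro-F1 over (up to) 5-fold CV on the training portion; the winner is
    refit on the full training portion and evaluated on the held-out 20%.
    Deterministic given identical data and seed.
    """
    task = vectors[0].task
    usable = [v for v in vectors if not v.degenerate and labels.get(v.patient_id) is not None]
    if not usable:
        raise ValueError(f"task {task}: no labeled, non-degenerate patients")
    X = np.stack([v.vector for v in usable])
    y = np.array([labels[v.patient_id] for v in usable])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"task {task}: labels contain a single class {classes[0]!r}")
    if counts.min() < 2:
        raise ValueError(f"task {task}: fewer than 2 examples in class {classes[counts.argmin()]!r}")

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.2, random_state=seed, stratify=y
    )
    rng = np.random.default_rng(seed)
    n_folds = int(min(5, np.unique(y_tr, return_counts=True)[1].min()))
    cv = StratifiedKFold(n_splits=max(2, n_folds), shuffle=True, random_state=seed)
    best_score, best_params, best_fold_scores = -1.0, None, []
    for params in _sample_params(rng, n_search):
        fold_scores = []
        for tr_idx, va_idx in cv.split(X_tr, y_tr):
            clf = make_pipeline(StandardScaler(), SVC(**params))
            clf.fit(X_tr[tr_idx], y_tr[tr_idx])
            fold_scores.append(
                f1_score(y_tr[va_idx], clf.predict(X_tr[va_idx]), average="macro")
            )
        score = float(np.mean(fold_scores))
        if score > best_score:
            best_score, best_params, best_fold_scores = score, params, fold_scores
    final = make_pipeline(StandardScaler(), SVC(**best_params))
    final.fit(X_tr, y_tr)
    y_pred = final.predict(X_te)
    heldout = {
        "n_train": int(len(y_tr)),
        "n_test": int(len(y_te)),
        "f1_macro": float(f1_score(y_te, y_pred, average="macro")),
        "per_category": {},
    }
    for cat in classes:
        tp = int(np.sum((y_pred == cat) & (y_te == cat)))
        fp = int(np.sum((y_pred == cat) & (y_te != cat)))
        fn = int(np.sum((y_pred != cat) & (y_te == cat)))
        prec = tp / (tp + fp) if tp + fp else None
        rec = tp / (tp + fn) if tp + fn else None
        f1 = (
            2 * prec * rec / (prec + rec)
            if prec is not None and rec is not None and (prec + rec)
            else (0.0 if prec is not None and rec is not None else None)
        )
        heldout["per_category"][str(cat)] = {"precision": prec, "recall": rec, "f1": f1}
    cats = TASK_CATEGORIES[task]
    return TrainedClassifier(
        task=task,
        estimator=final,
        categories=cats,
        hyperparameters=best_params,
        cv_scores=[float(s) for s in best_fold_scores],
        seed=seed,
        heldout_metrics=heldout,
    )


def predict(
    classifier: TrainedClassifier, vectors: Sequence[PatientVector]
) -> dict[str, str | None]:
    """Per-patient category, or ``None`` (abstain) for degenerate vectors."""
    out: dict[str, str | None] = {}
    if not vectors:
        return out
    live = [v for v in vectors if not v.degenerate]
    for v in vectors:
        if v.degenerate:
            out[v.patient_id] = None
    if live:
        X = np.stack([v.vector for v in live])
        if X.shape[1] != classifier.estimator.n_features_in_:
            raise ValueError(
                f"vector dimension {X.shape[1]} does not match classifier "
                f"({classifier.estimator.n_features_in_})"
            )
        for v, pred in zip(live, classifier.estimator.predict(X)):
            out[v.patient_id] = str(pred)
    return out


@dataclass
class MLPipeline:
    """One shared embedding model per stage kind plus one classifier per task."""

    embeddings: dict[str, EmbeddingModel]
    classifiers: dict[str, TrainedClassifier]
    lexicon: Lexicon

    def predict_table(self, records: Sequence[PatientRecord]) -> pd.DataFrame:
        rows = {r.patient_id: {"patient_id": r.patient_id} for r in records}
        for task, clf in self.classifiers.items():
            emb = self.embeddings[TASK_KIND[task]]
            vecs = [build_patient_vector(r, task, emb, self.lexicon) for r in records]
            for pid, cat in predict(clf, vecs).items():
                rows[pid][task] = cat
        df = pd.DataFrame(list(rows.values()))
        for task in TASKS:
            if task not in df.columns:
                df[task] = pd.NA
        return df[["patient_id"] + TASKS].astype("object").where(lambda d: d.notna(), pd.NA)


def train_ml_pipeline(
    records: Sequence[PatientRecord],
    gold: pd.DataFrame,
    lexicon: Lexicon,
    seed: int = 0,
    tasks: Iterable[str] = TASKS,
    d: int = 100,
    window: int = 5,
    n_search: int = 50,
    epochs: int = 5,
) -> MLPipeline:
    """Train embeddings (one per stage kind) and one SVM per task.

    ``gold`` is a stage table; raw values (``T1``, ``N0``...) are
    dichotomized into task categories before training.
    """
    from .evaluate import normalize_category  # local import to avoid a cycle

    from .preprocess import concatenate_patient_text

    tasks = list(tasks)
    kinds = sorted({TASK_KIND[t] for t in tasks})
    embeddings: dict[str, EmbeddingModel] = {}
    for kind in kinds:
        streams = []
        for rec in records:
            for sent in concatenate_patient_text(rec, kind):
                toks = normalize_tokens(sent).tokens
                if toks:
                    streams.append(toks)
        embeddings[kind] = train_embeddings(
            streams, d=d, window=window, seed=seed, epochs=epochs
        )
    gold = gold.set_index("patient_id") if "patient_id" in gold.columns else gold
    classifiers: dict[str, TrainedClassifier] = {}
    for i, task in enumerate(tasks):
        labels = {
            pid: normalize_category(task, val)
            for pid, val in gold[task].items()
            if pd.notna(val)
        }
        emb = embeddings[TASK_KIND[task]]
        vecs = [build_patient_vector(r, task, emb, lexicon) for r in records]
        classifiers[task] = train_task_classifier(
            vecs, labels, seed=seed + i, n_search=n_search
        )
    return MLPipeline(embeddings=embeddings, classifiers=classifiers, lexicon=lexicon)
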