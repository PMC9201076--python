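"""Scoring and registry-imputation accounting.

Predictions are compared with gold labels per binary task using one-vs-rest
TP/FP/FN/TN counts, precision, recall and F1, plus Cohen's kappa per task.
Zero-denominator metrics are marked undefined (``None``), never silently 0.
Abstentions and missing gold labels are excluded pairwise and counted, so
every denominator is visible.

Imputation writes NLP predictions into *empty* registry cells only; a
populated cell is never overwritten — disagreements are counted as
conflicts.  The report gives, per task, the missing count and the number
and percentage of missing fields imputed, broken down by category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .corpus import TASKS
from .rules import CLINICAL, PATHOLOGICAL, TASK_CATEGORIES, dichotomize

_TASK_KIND = {"cT": CLINICAL, "cN": CLINICAL, "cM": CLINICAL, "pT": PATHOLOGICAL, "pN": PATHOLOGICAL}
_TASK_AXIS = {"cT": "T", "cN": "N", "cM": "M", "pT": "T", "pN": "N"}


def normalize_category(task: str, value) -> str | None:
    """Map a raw stage value (``T1``, ``N0``...) or an already-dichotomized
    category onto the task's binary domain; ``None`` for missing."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA:
        return None
    value = str(value).strip()
    if not value:
        return None
    if value in TASK_CATEGORIES[task]:
        return value
    m = value.upper().replace(" ", "")
    axis = _TASK_AXIS[task]
    if m.startswith(axis) and len(m) >= 2 and m[1].isdigit():
        return dichotomize(_TASK_KIND[task], axis, int(m[1]))
    raise ValueError(f"cannot interpret {value!r} as a {task} category")


@dataclass
class MetricsReport:
    per_task: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return self.per_task

    def f1(self, task: str, category: str):
        return self.per_task[task]["categories"][category]["f1"]


def _safe_div(num: int, den: int) -> float | None:
    return num / den if den else None


def _f1(prec, rec):
    if prec is None or rec is None:
        return None
    return 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0


def score(predictions: pd.DataFrame, gold: pd.DataFrame) -> MetricsReport:
    """Score a prediction table against gold labels.

    Raw gold values are dichotomized first.  Pairs where either side is
    missing are dropped (pairwise deletion) and counted as abstentions /
    missing gold.
    """
    pred = predictions.set_index("patient_id")
    gld = gold.set_index("patient_id")
    shared = pred.index.intersection(gld.index)
    if len(shared) == 0:
        raise ValueError("prediction and gold patient id sets do not overlap")
    report = MetricsReport()
    for task in TASKS:
        if task not in pred.columns or task not in gld.columns:
            continue
        y_pred, y_gold = [], []
        n_abstain = n_gold_missing = 0
        for pid in shared:
            g = normalize_category(task, gld.at[pid, task])
            p = normalize_category(task, pred.at[pid, task])
            if g is None:
                n_gold_missing += 1
                continue
            if p is None:
                n_abstain += 1
                continue
            y_gold.append(g)
            y_pred.append(p)
        cats = TASK_CATEGORIES[task]
        entry: dict = {
            "n_scored": len(y_gold),
            "n_abstained": n_abstain,
            "n_gold_missing": n_gold_missing,
            "categories": {},
        }
        yg = np.array(y_gold)
        yp = np.array(y_pred)
        for cat in cats:
            tp = int(np.sum((yp == cat) & (yg == cat)))
            fp = int(np.sum((yp == cat) & (yg != cat)))
            fn = int(np.sum((yp != cat) & (yg == cat)))
            tn = int(np.sum((yp != cat) & (yg != cat)))
            prec = _safe_div(tp, tp + fp)
            rec = _safe_div(tp, tp + fn)
            entry["categories"][cat] = {
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "tn": tn,
                "precision": prec,
                "recall": rec,
                "f1": _f1(prec, rec),
            }
        distinct = set(yg) | set(yp)
        entry["kappa"] = (
            float(cohen_kappa_score(yg, yp)) if len(y_gold) and len(distinct) >= 2 else None
        )
        report.per_task[task] = entry
    return report


def agreement(labels_a: pd.DataFrame, labels_b: pd.DataFrame) -> dict[str, float | None]:
    """Cohen's kappa per task between two label tables.

    Undefined (``None``) when fewer than two distinct categories appear
    across both raters' paired non-missing labels.
    """
    a = labels_a.set_index("patient_id")
    b = labels_b.set_index("patient_id")
    shared = a.index.intersection(b.index)
    out: dict[str, float | None] = {}
    for task in TASKS:
        if task not in a.columns or task not in b.columns:
            continue
        ya, yb = [], []
        for pid in shared:
            va = normalize_category(task, a.at[pid, task])
            vb = normalize_category(task, b.at[pid, task])
            if va is None or vb is None:
                continue
            ya.append(va)
            yb.append(vb)
        if not ya or len(set(ya) | set(yb)) < 2:
            out[task] = None
            continue
        out[task] = float(cohen_kappa_score(ya, yb))
    return out


@dataclass
class ImputationReport:
    per_task: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return self.per_task


def impute(
    registry: pd.DataFrame, predictions: pd.DataFrame
) -> tuple[pd.DataFrame, ImputationReport]:
    """Fill missing registry stage fields from predictions.

    Only empty cells are written (with the dichotomized category); populated
    cells are never overwritten, and disagreements with populated cells are
    counted as conflicts.  Idempotent: re-imputing the augmented table
    changes nothing.  Imputed cells are marked in ``<task>_imputed``
    provenance columns.
    """
    aug = registry.copy().set_index("patient_id")
    pred = predictions.set_index("patient_id")
    report = ImputationReport()
    for task in TASKS:
        flag_col = f"{task}_imputed"
        if flag_col not in aug.columns:
            aug[flag_col] = False
        aug[flag_col] = aug[flag_col].fillna(False).astype(bool)
        total = len(aug)
        missing_ids = [pid for pid in aug.index if normalize_category(task, aug.at[pid, task]) is None]
        n_missing = len(missing_ids)
        imputed_by_cat: dict[str, int] = {c: 0 for c in TASK_CATEGORIES[task]}
        conflicts = 0
        for pid in aug.index:
            if pid not in pred.index or task not in pred.columns:
                continue
            p = normalize_category(task, pred.at[pid, task])
            if p is None:
                continue
            existing = normalize_category(task, aug.at[pid, task])
            if existing is None:
                aug.at[pid, task] = p
                aug.at[pid, flag_col] = True
                imputed_by_cat[p] += 1
            elif existing != p and not aug.at[pid, flag_col]:
                conflicts += 1
        n_imputed = sum(imputed_by_cat.values())
        report.per_task[task] = {
            "total": total,
            "missing_n": n_missing,
            "missing_pct": 100.0 * n_missing / total if total else 0.0,
            "imputed_n": n_imputed,
            "imputed_pct_of_missing": 100.0 * n_imputed / n_missing if n_missing else 0.0,
            "imputed_by_category": imputed_by_cat,
            "conflicts": conflicts,
        }
    return aug.reset_index(), report
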