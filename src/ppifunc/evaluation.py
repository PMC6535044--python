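"""Multi-label precision / recall / F-score for function predictions.

Per scored protein TP = |pred & true|, FP = |pred - true|, FN = |true -
pred|; micro-averaging (the default) pools the counts before applying

    P = TP / (TP + FP),  R = TP / (TP + FN),  F = 2PR / (P + R)

with the 0/0 cases defined as 0. Unpredictable proteins are excluded from
the counts and tallied separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .predict import UNPREDICTABLE, FunctionPrediction


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float
    n_scored: int = 0
    n_unpredictable: int = 0


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics_from_counts(tp: int, fp: int, fn: int) -> Metrics:
    p, r = precision_recall(tp, fp, fn)
    return Metrics(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f_score=f_score(p, r))


def score_multilabel(
    predictions: Sequence[FunctionPrediction],
    truth: Mapping[str, set[str]],
    averaging: str = "micro",
) -> Metrics:
    """Score predicted label sets against true label sets.

    ``micro`` pools TP/FP/FN over all scored proteins; ``macro`` averages
    per-protein precision and recall before combining. Every scored
    (non-unpredictable) protein must carry a non-empty truth set.
    """
    if averaging not in ("micro", "macro"):
        raise ValueError(f"unknown averaging {averaging!r}")
    scored = [p for p in predictions if p.status != UNPREDICTABLE]
    n_unpred = len(predictions) - len(scored)
    tp = fp = fn = 0
    per_p: list[float] = []
    per_r: list[float] = []
    for pred in scored:
        true_set = truth.get(pred.protein)
        if not true_set:
            raise ValueError(f"empty or missing truth for scored protein {pred.protein!r}")
        t = len(pred.functions & true_set)
        f = len(pred.functions - true_set)
        n = len(true_set - pred.functions)
        tp, fp, fn = tp + t, fp + f, fn + n
        pp, rr = precision_recall(t, f, n)
        per_p.append(pp)
        per_r.append(rr)
    if averaging == "micro" or not scored:
        p, r = precision_recall(tp, fp, fn)
    else:
        p = sum(per_p) / len(per_p)
        r = sum(per_r) / len(per_r)
    return Metrics(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=p,
        recall=r,
        f_score=f_score(p, r),
        n_scored=len(scored),
        n_unpredictable=n_unpred,
    )


def write_metrics(metrics: Metrics, path: str | Path) -> None:
    """JSON report with counts and two-decimal P/R/F."""
    payload = {
        "tp": metrics.tp,
        "fp": metrics.fp,
        "fn": metrics.fn,
        "n_scored": metrics.n_scored,
        "n_unpredictable": metrics.n_unpredictable,
        "precision": round(metrics.precision, 2),
        "recall": round(metrics.recall, 2),
        "f_score": round(metrics.f_score, 2),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
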