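"""Multi-label evaluation: precision, recall, F1.

Both example-based averaging (mean of per-document metrics) and
micro-averaging (pooled true/false positive counts) are reported,
plus a per-label F1 table for error analysis.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field


def prf(predicted: set[str], gold: set[str]) -> tuple[float, float, float]:
    """Per-document precision, recall, F1 for label sets.

    Conventions: empty prediction has precision 1 when gold is also
    empty, else 0; empty gold has recall 1; F1 is 0 when p + r = 0.
    """
    inter = len(predicted & gold)
    if predicted:
        p = inter / len(predicted)
    else:
        p = 1.0 if not gold else 0.0
    r = inter / len(gold) if gold else 1.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


@dataclass
class EvalReport:
    per_doc: dict[str, tuple[float, float, float]]
    example_precision: float
    example_recall: float
    example_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    per_label_f1: dict[str, float]
    n_docs: int
    tp: int
    fp: int
    fn: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_docs": self.n_docs,
            "example": {
                "precision": self.example_precision,
                "recall": self.example_recall,
                "f1": self.example_f1,
            },
            "micro": {
                "precision": self.micro_precision,
                "recall": self.micro_recall,
                "f1": self.micro_f1,
            },
            "counts": {"tp": self.tp, "fp": self.fp, "fn": self.fn},
            "per_label_f1": self.per_label_f1,
            **self.extras,
        }

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def evaluate_corpus(
    predictions: dict[str, set[str] | list[str]],
    gold: dict[str, set[str] | list[str]],
) -> EvalReport:
    """Corpus-level report over matching doc_id sets."""
    missing = sorted(set(gold) ^ set(predictions))
    if missing:
        raise ValueError(
            f"prediction/gold doc_id sets differ; mismatched ids: {missing}"
        )
    per_doc = {}
    tp = fp = fn = 0
    label_tp: dict[str, int] = {}
    label_fp: dict[str, int] = {}
    label_fn: dict[str, int] = {}
    for did in sorted(gold):
        p_set = set(predictions[did])
        g_set = set(gold[did])
        per_doc[did] = prf(p_set, g_set)
        tp += len(p_set & g_set)
        fp += len(p_set - g_set)
        fn += len(g_set - p_set)
        for lbl in p_set & g_set:
            label_tp[lbl] = label_tp.get(lbl, 0) + 1
        for lbl in p_set - g_set:
            label_fp[lbl] = label_fp.get(lbl, 0) + 1
        for lbl in g_set - p_set:
            label_fn[lbl] = label_fn.get(lbl, 0) + 1

    n = len(per_doc)
    ex_p = sum(v[0] for v in per_doc.values()) / n
    ex_r = sum(v[1] for v in per_doc.values()) / n
    ex_f = sum(v[2] for v in per_doc.values()) / n
    mi_p = tp / (tp + fp) if tp + fp else (1.0 if tp + fn == 0 else 0.0)
    mi_r = tp / (tp + fn) if tp + fn else 1.0
    mi_f = 2 * mi_p * mi_r / (mi_p + mi_r) if mi_p + mi_r > 0 else 0.0

    per_label_f1 = {}
    for lbl in sorted(set(label_tp) | set(label_fp) | set(label_fn)):
        ltp = label_tp.get(lbl, 0)
        lp = ltp / (ltp + label_fp.get(lbl, 0)) if ltp + label_fp.get(lbl, 0) else 0.0
        lr = ltp / (ltp + label_fn.get(lbl, 0)) if ltp + label_fn.get(lbl, 0) else 0.0
        per_label_f1[lbl] = 2 * lp * lr / (lp + lr) if lp + lr > 0 else 0.0

    return EvalReport(
        per_doc=per_doc,
        example_precision=ex_p,
        example_recall=ex_r,
        example_f1=ex_f,
        micro_precision=mi_p,
        micro_recall=mi_r,
        micro_f1=mi_f,
        per_label_f1=per_label_f1,
        n_docs=n,
        tp=tp,
        fp=fp,
        fn=fn,
    )
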