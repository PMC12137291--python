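"""Per-class precision/recall/F1 and micro/macro/weighted aggregation.

For each class *c*: recall = TP/(TP+FN), precision = TP/(TP+FP),
F1 = 2·P·R/(P+R).  Aggregates:

micro
    computed from pooled TP/FP/FN over all classes (equals accuracy for
    single-label multiclass data);
macro
    the unweighted mean of per-class values — emphasizes minority classes
    and is the ranking criterion for model comparison;
weighted
    the support-weighted mean (support = number of true instances).

Undefined ratios (empty denominators) are taken as 0.  Values are kept at
full precision; the percentage scale at 2 decimals is provided for
reporting.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .labels import CLASSES

__all__ = ["confusion_counts", "report", "rank_models", "macro_f1_of"]


def confusion_counts(
    truth: Sequence, predicted: Sequence, classes: Sequence[str] = CLASSES
) -> pd.DataFrame:
    """Per-class TP/FP/FN/support table.

    Raises ``ValueError`` on length mismatch or labels outside *classes*.
    """
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if len(truth) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted"
        )
    known = set(classes)
    bad = (set(truth) | set(predicted)) - known
    if bad:
        raise ValueError(f"labels outside scheme: {sorted(map(str, bad))}")
    rows = []
    for c in classes:
        t, p = truth == c, predicted == c
        tp = int(np.sum(t & p))
        rows.append(
            {
                "class": c,
                "tp": tp,
                "fp": int(p.sum()) - tp,
                "fn": int(t.sum()) - tp,
                "support": int(t.sum()),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def _f1(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def report(counts: pd.DataFrame) -> dict:
    """Full metrics report from a confusion-count table.

    Returns nested dicts: ``per_class[c]`` with precision/recall/f1/support
    on the 0–1 scale, ``aggregates[kind]`` for kind in micro/macro/weighted,
    and ``percent`` mirrors of both at 2 decimals on the 0–100 scale.
    """
    if int(counts["support"].sum()) == 0:
        raise ValueError("all supports are zero; nothing to evaluate")
    per_class: dict[str, dict[str, float]] = {}
    for c, row in counts.iterrows():
        p = _ratio(row.tp, row.tp + row.fp)
        r = _ratio(row.tp, row.tp + row.fn)
        per_class[c] = {
            "precision": p,
            "recall": r,
            "f1": _f1(p, r),
            "support": int(row.support),
        }
    tp, fp, fn = (int(counts[k].sum()) for k in ("tp", "fp", "fn"))
    micro_p, micro_r = _ratio(tp, tp + fp), _ratio(tp, tp + fn)
    supports = np.array([v["support"] for v in per_class.values()], dtype=float)
    w = supports / supports.sum()

    def _mean(key: str) -> float:
        return float(np.mean([v[key] for v in per_class.values()]))

    def _wmean(key: str) -> float:
        return float(np.sum(w * [v[key] for v in per_class.values()]))

    aggregates = {
        "micro": {"precision": micro_p, "recall": micro_r, "f1": _f1(micro_p, micro_r)},
        "macro": {k: _mean(k) for k in ("precision", "recall", "f1")},
        "weighted": {k: _wmean(k) for k in ("precision", "recall", "f1")},
    }
    pct = lambda x: round(100.0 * x, 2)
    return {
        "per_class": per_class,
        "aggregates": aggregates,
        "percent": {
            "per_class": {
                c: {k: pct(v[k]) for k in ("precision", "recall", "f1")}
                for c, v in per_class.items()
            },
            "aggregates": {
                kind: {k: pct(v) for k, v in vals.items()}
                for kind, vals in aggregates.items()
            },
        },
    }


def evaluate(truth: Sequence, predicted: Sequence, classes: Sequence[str] = CLASSES) -> dict:
    """Convenience: confusion counts + report in one call."""
    return report(confusion_counts(truth, predicted, classes))


def macro_f1_of(per_class_f1_percent: Sequence[float]) -> float:
    """Macro F1 (percent, 2 dp) as the unweighted mean of per-class F1 values."""
    return round(float(np.mean(per_class_f1_percent)), 2)


def rank_models(reports: Mapping[str, dict]) -> list[tuple[str, dict]]:
    """Order named reports by macro F1 descending.

    Ties broken by weighted F1 descending, then by name ascending — the
    ranking criterion deliberately favors models that classify minority
    organ classes well.
    """
    if not reports:
        raise ValueError("at least one report is required")
    return sorted(
        reports.items(),
        key=lambda kv: (
            -kv[1]["aggregates"]["macro"]["f1"],
            -kv[1]["aggregates"]["weighted"]["f1"],
            kv[0],
        ),
    )
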