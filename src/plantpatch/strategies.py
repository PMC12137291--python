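"""Classifier-composition strategies producing a unified prediction table.

Three ways of turning patch-level model outputs into one final six-class
label per patch:

``multi6``
    A single 6-class model; the argmax class wins.
``chain``
    Six one-vs-rest binary models, one per class.  Each emits a 0/1 label
    (positive-class probability ≥ threshold) plus that probability; among
    the models emitting 1, the class with the highest positive probability
    wins.  If none emits 1, the class with the highest positive
    probability overall is used and the row is flagged as a fallback.
``hierarchical``
    A binary plant/background model first; patches it calls background are
    finalized immediately, the rest are passed to a 5-class organ model.

All tie-breaks follow the canonical class order.  Every strategy returns
one row per input patch.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .labels import CLASSES, PLANT_CLASSES
from .patch_grid import PatchRef

__all__ = ["predict_multi6", "predict_chain", "predict_hierarchical"]

PREDICTION_COLUMNS = [
    "image_id",
    "row",
    "col",
    "final_label",
    "confidence",
    "strategy",
    "fallback_flag",
]


def _proba_in_order(model, X: np.ndarray, order: Sequence[str]) -> np.ndarray:
    """Model probabilities re-indexed to canonical *order* of class names."""
    proba = model.predict_proba(X)
    col = {str(c): i for i, c in enumerate(model.classes_)}
    missing = [c for c in order if c not in col]
    if missing:
        raise ValueError(
            f"model classes {list(model.classes_)} do not cover required "
            f"classes {list(order)} (missing {missing})"
        )
    return proba[:, [col[c] for c in order]]


def _positive_proba(model, X: np.ndarray) -> np.ndarray:
    """Positive-class (label 1) probability from a 0/1 binary model."""
    proba = model.predict_proba(X)
    classes = [int(c) for c in model.classes_]
    if sorted(classes) != [0, 1]:
        raise ValueError(f"expected binary 0/1 model, got classes {classes}")
    return proba[:, classes.index(1)]


def _table(refs: Sequence[PatchRef], labels, conf, strategy: str, fallback) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "image_id": [r.image_id for r in refs],
            "row": [r.row for r in refs],
            "col": [r.col for r in refs],
            "final_label": labels,
            "confidence": np.asarray(conf, dtype=float),
            "strategy": strategy,
            "fallback_flag": fallback,
        }
    )


def predict_multi6(
    model, refs: Sequence[PatchRef], X: np.ndarray
) -> pd.DataFrame:
    """Six-class argmax over all patches.

    The model must emit probabilities over all six classes; ties go to the
    earlier class in canonical order.
    """
    if len(getattr(model, "classes_", ())) != 6:
        raise ValueError(
            f"multi6 strategy needs a 6-class model, got {len(model.classes_)} classes"
        )
    proba = _proba_in_order(model, X, CLASSES)
    best = proba.argmax(axis=1)  # first max -> canonical-order tie-break
    out = _table(
        refs,
        [CLASSES[i] for i in best],
        proba[np.arange(len(best)), best],
        "multi6",
        False,
    )
    for i, c in enumerate(CLASSES):
        out[f"p_{c}"] = proba[:, i]
    return out


def predict_chain(
    models: Mapping[str, object],
    refs: Sequence[PatchRef],
    X: np.ndarray,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Confidence fusion of six one-vs-rest binary classifiers.

    Semantics are patch-wise and model-order independent, so the six
    models may be evaluated in any order (or concurrently) with identical
    results.
    """
    missing = [c for c in CLASSES if c not in models]
    if missing:
        raise ValueError(f"missing binary model for class(es): {missing}")
    pos = np.column_stack([_positive_proba(models[c], X) for c in CLASSES])
    emitted = pos >= threshold
    masked = np.where(emitted, pos, -1.0)
    any_pos = emitted.any(axis=1)
    # argmax returns the first (canonical-order) class on exact ties
    best = np.where(any_pos, masked.argmax(axis=1), pos.argmax(axis=1))
    conf = pos[np.arange(len(best)), best]
    out = _table(
        refs, [CLASSES[i] for i in best], conf, "chain", ~any_pos
    )
    for i, c in enumerate(CLASSES):
        out[f"p_{c}"] = pos[:, i]
    return out


def predict_hierarchical(
    bg_model,
    plant_model,
    refs: Sequence[PatchRef],
    X: np.ndarray,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Plant/background binarization, then 5-class organ classification.

    Patches the binary model calls background are finalized with its
    positive-class confidence and never reach the organ model; the rest
    take the organ model's argmax among the five plant classes.
    """
    if len(getattr(plant_model, "classes_", ())) != 5:
        raise ValueError(
            f"hierarchical strategy needs a 5-class organ model, got "
            f"{len(plant_model.classes_)} classes"
        )
    p_bg = _positive_proba(bg_model, X)
    is_bg = p_bg >= threshold
    labels = np.empty(len(refs), dtype=object)
    conf = np.empty(len(refs), dtype=float)
    labels[is_bg] = "background"
    conf[is_bg] = p_bg[is_bg]
    plant_idx = np.flatnonzero(~is_bg)
    plant_proba = np.full((len(refs), 5), np.nan)
    if len(plant_idx):
        proba = _proba_in_order(plant_model, X[plant_idx], PLANT_CLASSES)
        best = proba.argmax(axis=1)
        labels[plant_idx] = [PLANT_CLASSES[i] for i in best]
        conf[plant_idx] = proba[np.arange(len(best)), best]
        plant_proba[plant_idx] = proba
    out = _table(refs, list(labels), conf, "hierarchical", False)
    out["p_background"] = p_bg
    for i, c in enumerate(PLANT_CLASSES):
        out[f"p_{c}"] = plant_proba[:, i]
    return out
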