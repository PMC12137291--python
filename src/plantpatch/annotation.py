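"""Labelled-patch tables: loading, color filtering, splitting, weighting.

Annotations live in a plain DataFrame with columns ``image_id``, ``row``,
``col``, ``label`` (lower-case class name) and optionally
``annotator_source``.  Each patch carries exactly one label and appears at
most once.

The dataset handling mirrors a strongly imbalanced training corpus:
a stratified 60/20/20 train/validation/test split, inverse-frequency class
weights ``w_c = 10 / (0.6 · N_c)`` (so that each class contributes equally
in expectation under weighted sampling of the 60% training portion), and a
with-replacement weighted sampler.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

from .labels import CLASSES, CODE, check_label
from .patch_grid import PatchRef

logger = logging.getLogger(__name__)

ANNOTATOR_SOURCES = ("manual", "color_filter_assisted", "synthetic_ground_truth")

KEY = ["image_id", "row", "col"]


def validate_annotations(table: pd.DataFrame) -> pd.DataFrame:
    """Check the single-label / no-duplicate invariants; return the table."""
    missing = [c for c in KEY + ["label"] if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    bad = set(table["label"]) - set(CLASSES)
    if bad:
        raise ValueError(f"label not in scheme: {sorted(bad)}")
    if table.duplicated(KEY).any():
        dup = table[table.duplicated(KEY)].iloc[0]
        raise ValueError(
            f"duplicate patch annotation: ({dup.image_id}, {dup.row}, {dup.col})"
        )
    return table


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Read and validate an annotation CSV (image_id, row, col, label)."""
    table = pd.read_csv(path, dtype={"image_id": str})
    if len(table) == 0:
        table = table.reindex(columns=KEY + ["label"])
    return validate_annotations(table)


def class_counts(table: pd.DataFrame) -> dict[str, int]:
    """Per-class annotation tally, in canonical class order (zeros included)."""
    counts = table["label"].value_counts()
    return {c: int(counts.get(c, 0)) for c in CLASSES}


# ---------------------------------------------------------------------------
# Color-based candidate filtering for rare classes
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ColorRule:
    """HSV predicate: a pixel matches if hue (degrees) is in range and
    saturation/value clear their minima."""

    hue_min: float
    hue_max: float
    min_saturation: float
    min_value: float

    def match_fraction(self, block: np.ndarray) -> float:
        hsv = rgb2hsv(np.asarray(block, dtype=np.uint8))
        hue = hsv[..., 0] * 360.0
        ok = (
            (hue >= self.hue_min)
            & (hue <= self.hue_max)
            & (hsv[..., 1] >= self.min_saturation)
            & (hsv[..., 2] >= self.min_value)
        )
        return float(ok.mean())


#: Default rules for the rare classes: yellow flowers, green buds and pods.
DEFAULT_COLOR_RULES: dict[str, ColorRule] = {
    "flower": ColorRule(40.0, 70.0, 0.4, 0.4),
    "bud": ColorRule(70.0, 160.0, 0.25, 0.25),
    "pod": ColorRule(70.0, 160.0, 0.25, 0.25),
}


def color_filter_candidates(
    patches: Sequence[tuple[PatchRef, np.ndarray]],
    rules: Mapping[str, ColorRule] | None = None,
    min_score: float = 0.05,
) -> dict[str, list[tuple[PatchRef, float]]]:
    """Rank unlabelled patches as candidates for rare classes by pixel color.

    For each target class, returns patches whose fraction of rule-matching
    pixels is at least *min_score*, sorted by that fraction descending
    (stable in input order on ties).
    """
    rules = DEFAULT_COLOR_RULES if rules is None else dict(rules)
    if not rules:
        raise ValueError("at least one color rule is required")
    out: dict[str, list[tuple[PatchRef, float]]] = {}
    for cls, rule in rules.items():
        check_label(cls)
        scored = [
            (ref, score)
            for ref, block in patches
            if (score := rule.match_fraction(block)) >= min_score
        ]
        scored.sort(key=lambda t: -t[1])  # python sort is stable
        out[cls] = scored
    return out


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DatasetSplit:
    """Disjoint train/validation/test partitions of an annotation table."""

    train: pd.DataFrame
    validation: pd.DataFrame
    test: pd.DataFrame
    fractions: tuple[float, float, float]
    seed: int

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))

    def manifest(self) -> pd.DataFrame:
        """Long-form manifest: image_id, row, col, label, partition."""
        parts = []
        for name, df in (
            ("train", self.train),
            ("val", self.validation),
            ("test", self.test),
        ):
            parts.append(df.assign(partition=name))
        return pd.concat(parts, ignore_index=True)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _largest_remainder(
    targets: dict[str, float], total: int, counts: dict[str, int]
) -> dict[str, int]:
    """Apportion *total* items across classes against real-valued *targets*.

    Floors first, then hands out the shortfall one unit at a time by largest
    fractional remainder; ties broken by descending class count, then by
    canonical class order.
    """
    base = {c: int(math.floor(t)) for c, t in targets.items()}
    shortfall = total - sum(base.values())
    order = sorted(
        targets,
        key=lambda c: (-(targets[c] - base[c]), -counts[c], CODE[c]),
    )
    for c in order[:shortfall]:
        base[c] += 1
    return base


def stratified_split(
    table: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Stratified train/validation/test split with exact global totals.

    Global validation and test sizes are each ``round-half-up(f · N)``;
    training receives the remainder.  Within each partition, classes are
    apportioned against their exact targets ``f · N_c`` by largest
    remainder, so per-class allocations differ from the exact targets by
    less than one patch.  Membership within a class is a seeded shuffle.
    """
    validate_annotations(table)
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    n = len(table)
    counts = {c: v for c, v in class_counts(table).items() if v > 0}
    n_val = _round_half_up(f_val * n)
    n_test = _round_half_up(f_test * n)
    val_alloc = _largest_remainder({c: f_val * v for c, v in counts.items()}, n_val, counts)
    test_alloc = _largest_remainder(
        {c: f_test * v for c, v in counts.items()}, n_test, counts
    )
    for c, v in counts.items():
        if v < 3:
            logger.warning(
                "class %r has only %d patches; some partitions will be empty", c, v
            )

    rng = np.random.default_rng(seed)
    val_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    train_idx: list[np.ndarray] = []
    for c in CLASSES:  # canonical order keeps the shuffle reproducible
        if c not in counts:
            continue
        idx = table.index[table["label"] == c].to_numpy()
        rng.shuffle(idx)
        nv, nt = val_alloc[c], test_alloc[c]
        val_idx.append(idx[:nv])
        test_idx.append(idx[nv : nv + nt])
        train_idx.append(idx[nv + nt :])

    def _take(chunks: list[np.ndarray]) -> pd.DataFrame:
        if not chunks:
            return table.iloc[0:0]
        return table.loc[np.concatenate(chunks)]

    return DatasetSplit(
        train=_take(train_idx),
        validation=_take(val_idx),
        test=_take(test_idx),
        fractions=fractions,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Class weights and weighted sampling
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ClassWeights:
    """Inverse-frequency sampling weights, one positive real per class."""

    weights: dict[str, float]

    def rounded(self, ndigits: int = 4) -> dict[str, float]:
        return {c: round(w, ndigits) for c, w in self.weights.items()}

    def __getitem__(self, cls: str) -> float:
        return self.weights[cls]


def class_weights(
    table_or_counts: pd.DataFrame | Mapping[str, int],
    train_fraction: float = 0.6,
) -> ClassWeights:
    """Weight each class as ``w_c = 1 / ((train_fraction · N_c) / 10)``.

    ``N_c`` is the total annotated count of class *c*; the 60% training
    share is taken as a real value, not a post-split integer.  Under
    weighted sampling the expected number of draws is then equal across
    classes.
    """
    if isinstance(table_or_counts, pd.DataFrame):
        counts = class_counts(table_or_counts)
    else:
        # mapping form also serves binary (0/1) label sets
        counts = {c: int(v) for c, v in table_or_counts.items()}
    for c, v in counts.items():
        if v <= 0:
            raise ValueError(f"cannot weight empty class: {c!r}")
    return ClassWeights({c: 10.0 / (train_fraction * v) for c, v in counts.items()})


def weighted_sample(
    table: pd.DataFrame,
    weights: ClassWeights,
    epoch_length: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw patches with replacement, probability proportional to class weight.

    *epoch_length* defaults to the table size.  Deterministic for a fixed
    seed.
    """
    if len(table) == 0:
        raise ValueError("cannot sample from an empty training set")
    epoch_length = len(table) if epoch_length is None else int(epoch_length)
    if epoch_length < 1:
        raise ValueError(f"epoch_length must be >= 1, got {epoch_length}")
    p = table["label"].map(weights.weights).to_numpy(dtype=np.float64)
    p /= p.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(table), size=epoch_length, replace=True, p=p)
    return table.iloc[idx]


def relabel_binary(table: pd.DataFrame, target_class: str) -> pd.DataFrame:
    """One-vs-rest relabelling: label 1 iff the patch is *target_class*."""
    check_label(target_class)
    out = table.copy()
    out["label"] = (table["label"] == target_class).astype(int)
    return out
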