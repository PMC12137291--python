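"""Dynamic phenotyping from per-image prediction tables.

Patch classification over a dated image series yields, per image, the
number of patches assigned to each organ class — a proxy for organ
abundance.  Across a series these tallies form trajectories from which
developmental events are read off: the *first appearance* of an organ
class (e.g. first flowering, first pod set) is the earliest date on which
its patch count reaches a threshold and stays there for a configurable
number of consecutive dates (persistence > 1 suppresses single-date
misclassification blips).
"""

from __future__ import annotations

import dataclasses
import datetime
from typing import Iterable, Sequence

import pandas as pd

from .labels import CLASSES, PLANT_CLASSES

__all__ = ["AbundanceRecord", "PhenotypeSeries", "abundance", "build_series"]


@dataclasses.dataclass(frozen=True)
class AbundanceRecord:
    """Per-class patch counts for one image."""

    plant_id: str
    capture_date: datetime.date
    view: str
    counts: dict[str, int]  # all six classes, zeros included
    total_patches: int


@dataclasses.dataclass
class PhenotypeSeries:
    """Date-ordered abundance trajectory plus first-appearance dates."""

    plant_id: str
    view: str
    records: list[AbundanceRecord]
    first_appearance: dict[str, datetime.date | None]

    def trajectory(self) -> pd.DataFrame:
        """Long table: date, one column per class, total."""
        return pd.DataFrame(
            [
                {"date": r.capture_date, **r.counts, "total": r.total_patches}
                for r in self.records
            ]
        )


def abundance(predictions: pd.DataFrame, image_meta) -> AbundanceRecord:
    """Tally final labels of one image's predictions into an AbundanceRecord.

    *image_meta* is anything with ``image_id``/``plant_id``/``capture_date``/
    ``view`` attributes (e.g. an ImageRecord).  All predictions must
    reference that image.
    """
    ids = set(predictions["image_id"].unique())
    if len(ids) > 1 or (ids and ids != {image_meta.image_id}):
        raise ValueError(
            f"predictions reference image(s) {sorted(ids)}, "
            f"expected only {image_meta.image_id!r}"
        )
    tally = predictions["final_label"].value_counts()
    counts = {c: int(tally.get(c, 0)) for c in CLASSES}
    return AbundanceRecord(
        plant_id=image_meta.plant_id,
        capture_date=image_meta.capture_date,
        view=image_meta.view,
        counts=counts,
        total_patches=len(predictions),
    )


def build_series(
    records: Iterable[AbundanceRecord],
    appearance_threshold: int = 1,
    persistence: int = 1,
) -> PhenotypeSeries:
    """Order records by date and locate each organ class's first appearance.

    ``first_appearance[c]`` is the earliest date *d* with
    ``count_c >= appearance_threshold`` on *d* and on the following
    ``persistence - 1`` dates; ``None`` if never satisfied.  The result is
    independent of the order records are supplied in.
    """
    records = sorted(records, key=lambda r: r.capture_date)
    if not records:
        raise ValueError("no abundance records supplied")
    plant_ids = {r.plant_id for r in records}
    views = {r.view for r in records}
    if len(plant_ids) > 1 or len(views) > 1:
        raise ValueError(
            f"records span multiple plants/views: {plant_ids} / {views}"
        )
    dates = [r.capture_date for r in records]
    if len(set(dates)) != len(dates):
        raise ValueError("duplicate capture dates within a (plant, view) series")

    first: dict[str, datetime.date | None] = {}
    for c in PLANT_CLASSES:
        first[c] = None
        hits = [r.counts[c] >= appearance_threshold for r in records]
        for i in range(len(records) - persistence + 1):
            if all(hits[i : i + persistence]):
                first[c] = records[i].capture_date
                break
    return PhenotypeSeries(
        plant_id=records[0].plant_id,
        view=records[0].view,
        records=records,
        first_appearance=first,
    )


def merge_views_max(series: Sequence[PhenotypeSeries]) -> pd.DataFrame:
    """Optional multi-view fusion: per date, the max count across views.

    Occluded organs in one view may be visible in another; the max is a
    conservative lower bound on true abundance.
    """
    frames = [s.trajectory().assign(view=s.view) for s in series]
    long = pd.concat(frames, ignore_index=True)
    return long.groupby("date", as_index=False)[list(CLASSES) + ["total"]].max()
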