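"""Data model for daily symptom-diary cohorts.

A cohort is a set of participants, each contributing a day x item table of
ordinal diary scores (a :class:`DiaryMatrix`), plus a binary relapse label per
participant.  Items are described by an :class:`ItemSchema` that records the
ordinal scale bounds and which items are positively valenced (and therefore
reverse-coded before any analysis, so that high always means severe).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Item",
    "ItemSchema",
    "DiaryMatrix",
    "Cohort",
    "DEFAULT_SCHEMA",
    "SchemaError",
    "DataIntegrityError",
]


class SchemaError(ValueError):
    """Input does not conform to the declared item schema."""


class DataIntegrityError(ValueError):
    """Input violates a structural integrity rule (e.g. duplicate days)."""


@dataclass(frozen=True)
class Item:
    """One diary item.

    Parameters
    ----------
    item_id:
        Short unique label used as a column name everywhere.
    display_name:
        Free-text prompt shown to participants.
    positively_valenced:
        True for items where a *high* score means feeling *well*
        (e.g. "cheerful"); such items are reverse-coded before analysis.
    """

    item_id: str
    display_name: str = ""
    positively_valenced: bool = False


@dataclass(frozen=True)
class ItemSchema:
    """Schema of diary items on a shared ordinal response scale."""

    items: tuple[Item, ...]
    scale_min: int = 1
    scale_max: int = 7

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise SchemaError(
                f"scale_min ({self.scale_min}) must be < scale_max ({self.scale_max})"
            )
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate item_ids: {dupes}")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def positive_ids(self) -> tuple[str, ...]:
        """Ids of positively valenced (to-be-reverse-coded) items."""
        return tuple(it.item_id for it in self.items if it.positively_valenced)

    @property
    def reflection_constant(self) -> int:
        """``scale_min + scale_max``; reverse-coding maps ``s`` to this minus ``s``."""
        return self.scale_min + self.scale_max

    def drop_items(self, item_ids: Iterable[str]) -> "ItemSchema":
        """Return a schema without the given items."""
        drop = set(item_ids)
        unknown = drop - set(self.item_ids)
        if unknown:
            raise SchemaError(f"unknown item_ids: {sorted(unknown)}")
        return replace(
            self, items=tuple(it for it in self.items if it.item_id not in drop)
        )


#: The 14-item once-daily psychosis symptom diary (seven-point Likert scale).
#: "Cheerful", "relaxed" and "in control" are positively valenced.
DEFAULT_SCHEMA = ItemSchema(
    items=(
        Item("anxious", "anxious"),
        Item("irritable", "irritable"),
        Item("sad", "sad"),
        Item("stressed", "stressed"),
        Item("cheerful", "cheerful", positively_valenced=True),
        Item("relaxed", "relaxed", positively_valenced=True),
        Item("in_control", "in control", positively_valenced=True),
        Item("suspicious", "suspicious"),
        Item("trouble_concentrating", "trouble concentrating"),
        Item("preoccupied_by_thoughts", "preoccupied by thoughts"),
        Item("others_dislike_me", "others dislike me"),
        Item("confused", "confused"),
        Item("others_influence_my_thoughts", "others influence my thoughts"),
        Item("unusual_sights_and_sounds", "unusual sights and sounds"),
    ),
    scale_min=1,
    scale_max=7,
)


@dataclass
class DiaryMatrix:
    """One participant's day x item table of ordinal diary scores.

    ``scores`` is a float DataFrame indexed by a strictly increasing
    ``DatetimeIndex`` of calendar dates, one column per item; missing entries
    are NaN.  Missing *days* are simply absent rows, missing single *items*
    are NaN within a present row.
    """

    participant_id: str
    scores: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.scores.index
        if not isinstance(idx, pd.DatetimeIndex):
            idx = pd.DatetimeIndex(idx)
            self.scores = self.scores.set_axis(idx, axis=0)
        if len(idx) > 1 and not idx.is_monotonic_increasing:
            raise DataIntegrityError(
                f"{self.participant_id}: dates must be strictly increasing"
            )
        if idx.has_duplicates:
            raise DataIntegrityError(
                f"{self.participant_id}: duplicate dates in diary"
            )
        self.scores = self.scores.astype(float)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(self.scores.columns)

    @property
    def n_days(self) -> int:
        """Number of diary days with at least one observed item."""
        return int(self.scores.notna().any(axis=1).sum())

    @property
    def n_complete_days(self) -> int:
        """Number of diary days with every item observed."""
        return int(self.scores.notna().all(axis=1).sum())

    def validate_against(self, schema: ItemSchema) -> None:
        """Check column set and score bounds against a schema."""
        if set(self.scores.columns) != set(schema.item_ids):
            raise SchemaError(
                f"{self.participant_id}: diary columns do not match schema "
                f"(diary: {sorted(self.scores.columns)})"
            )
        vals = self.scores.to_numpy()
        obs = vals[~np.isnan(vals)]
        if obs.size and ((obs < schema.scale_min) | (obs > schema.scale_max)).any():
            raise SchemaError(
                f"{self.participant_id}: scores outside "
                f"[{schema.scale_min}, {schema.scale_max}]"
            )

    def with_scores(self, scores: pd.DataFrame) -> "DiaryMatrix":
        return DiaryMatrix(self.participant_id, scores)


@dataclass
class Cohort:
    """A set of diaries plus binary relapse labels, under one item schema."""

    schema: ItemSchema
    diaries: dict[str, DiaryMatrix] = field(default_factory=dict)
    relapse_labels: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unlabelled_diary_ok = True  # labels may cover a subset during ingest
        del unlabelled_diary_ok
        missing = set(self.relapse_labels) - set(self.diaries)
        if missing:
            raise DataIntegrityError(
                f"labelled participants without a diary: {sorted(missing)}"
            )
        for pid, diary in self.diaries.items():
            if diary.participant_id != pid:
                raise DataIntegrityError(
                    f"diary keyed {pid} has participant_id {diary.participant_id}"
                )

    @property
    def participant_ids(self) -> tuple[str, ...]:
        return tuple(self.diaries)

    def subset(self, participant_ids: Iterable[str]) -> "Cohort":
        keep = list(participant_ids)
        return Cohort(
            schema=self.schema,
            diaries={p: self.diaries[p] for p in keep},
            relapse_labels={
                p: self.relapse_labels[p] for p in keep if p in self.relapse_labels
            },
        )

    def drop_items(self, item_ids: Iterable[str]) -> "Cohort":
        """Remove items cohort-wide (schema and every diary)."""
        drop = list(item_ids)
        schema = self.schema.drop_items(drop)
        diaries = {
            p: d.with_scores(d.scores.drop(columns=drop))
            for p, d in self.diaries.items()
        }
        return Cohort(schema=schema, diaries=diaries, relapse_labels=dict(self.relapse_labels))

    def map_scores(self, fn) -> "Cohort":
        """Apply ``fn(DiaryMatrix) -> DiaryMatrix`` to every diary."""
        return Cohort(
            schema=self.schema,
            diaries={p: fn(d) for p, d in self.diaries.items()},
            relapse_labels=dict(self.relapse_labels),
        )

    def labels_as_bool(self) -> Mapping[str, bool]:
        return {p: bool(v) for p, v in self.relapse_labels.items()}
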