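"""Symptom-score variability and cross-participant centrality dispersion.

Two per-item variability indices are computed on each participant's
(reverse-coded) diary: the overall sample standard deviation (SD) and the
root mean square of successive differences (RMSSD), an index of day-to-day
change.  RMSSD pairs must be calendar-adjacent (gap of exactly one day);
runs broken by a missing day contribute no pairs.

Inter-individual variability of network structure is summarised by the
standard deviation of each centrality index for each symptom across the
study sample (the dispersion table).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .metrics import CentralityProfile
from .schema import DiaryMatrix

__all__ = [
    "SymptomVariability",
    "symptom_variability",
    "centrality_dispersion",
]


@dataclass
class SymptomVariability:
    """Per-item SD and RMSSD for one participant."""

    participant_id: str
    values: pd.DataFrame  # index: item, columns: sd, rmssd


def symptom_variability(diary: DiaryMatrix) -> SymptomVariability:
    """Per-item SD (denominator n-1) and RMSSD of daily scores.

    RMSSD = sqrt(mean of (x_{t+1} - x_t)^2 over consecutive-calendar-day
    pairs with both days observed); NaN when an item has no such pair.
    """
    scores = diary.scores
    sd = scores.std(ddof=1)
    if len(scores) == 0:
        rmssd = pd.Series(np.nan, index=scores.columns)
    else:
        full = scores.reindex(
            pd.date_range(scores.index.min(), scores.index.max(), freq="D")
        )
        sq = full.diff() ** 2  # NaN wherever either day of the pair is missing
        rmssd = np.sqrt(sq.mean())  # pandas mean skips NaN; all-NaN -> NaN
    values = pd.DataFrame({"sd": sd, "rmssd": rmssd})
    return SymptomVariability(participant_id=diary.participant_id, values=values)


def centrality_dispersion(
    profiles: Iterable[CentralityProfile],
    indices: Sequence[str] = ("strength", "closeness", "betweenness"),
) -> pd.DataFrame:
    """SD of each centrality index per symptom across participants.

    All profiles must share one item set (centralities are computed after the
    global redundant-item removal); the sample SD uses denominator n-1.
    Returns a DataFrame indexed by item with one column per index.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("dispersion needs at least 2 centrality profiles")
    item_sets = {tuple(sorted(p.item_ids)) for p in profiles}
    if len(item_sets) != 1:
        raise ValueError(
            "profiles have differing item sets; compute centralities after "
            "global item removal"
        )
    out = {}
    for index in indices:
        stacked = pd.DataFrame(
            {p.participant_id: p.values[index] for p in profiles}
        )
        out[index] = stacked.std(axis=1, ddof=1)
    return pd.DataFrame(out)
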