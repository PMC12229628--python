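"""Preprocessing: reverse-coding, participant exclusion, redundant-item removal.

Reverse-coding reflects positively valenced items so that high scores always
mean greater symptom severity.  Exclusion removes participants who contributed
too few diary days or whose responses show minimal variation (stereotyped
responding), both of which destabilise a person-specific network.  Redundancy
detection flags item pairs whose correlation profiles with every other item
are statistically indistinguishable — evidence that the two items measure the
same construct — using the test for two dependent overlapping correlations in
its back-transformed-z form, and removes one member of each flagged pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .schema import Cohort, DiaryMatrix, ItemSchema

__all__ = [
    "reverse_code",
    "reverse_code_cohort",
    "apply_exclusions",
    "detect_redundant_items",
    "remove_redundant_items",
    "ExclusionReport",
    "RedundancyReport",
    "CandidatePair",
]


def reverse_code(diary: DiaryMatrix, schema: ItemSchema) -> DiaryMatrix:
    """Reflect positively valenced items: ``s -> scale_min + scale_max - s``.

    Other items and missing entries are unchanged.  The map is an involution
    (applying it twice restores the original diary) and preserves both the
    missingness pattern and every item's marginal variance.
    """
    scores = diary.scores.copy()
    for item in schema.positive_ids:
        if item in scores.columns:
            scores[item] = schema.reflection_constant - scores[item]
    return diary.with_scores(scores)


def reverse_code_cohort(cohort: Cohort) -> Cohort:
    """Apply :func:`reverse_code` to every diary in a cohort."""
    return cohort.map_scores(lambda d: reverse_code(d, cohort.schema))


@dataclass
class ExclusionReport:
    """Per-participant retention decision with reasons.

    ``entries`` maps participant_id to ``(retained, reasons)`` where reasons
    is a tuple drawn from ``{"too_few_days", "minimal_variation", "manual"}``.
    Every participant of the input cohort appears exactly once.
    """

    entries: dict[str, tuple[bool, tuple[str, ...]]] = field(default_factory=dict)

    @property
    def retained_ids(self) -> tuple[str, ...]:
        return tuple(p for p, (kept, _) in self.entries.items() if kept)

    @property
    def excluded_ids(self) -> tuple[str, ...]:
        return tuple(p for p, (kept, _) in self.entries.items() if not kept)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": list(self.entries),
                "retained": [kept for kept, _ in self.entries.values()],
                "reasons": [";".join(r) for _, r in self.entries.values()],
            }
        )


def apply_exclusions(
    cohort: Cohort,
    min_days: int = 100,
    min_distinct_responses: int = 2,
    manual_exclude: Iterable[str] = (),
) -> tuple[Cohort, ExclusionReport]:
    """Drop participants with too few diary days or minimal response variation.

    A participant is excluded when they contributed strictly fewer than
    ``min_days`` diary days (days with at least one observed item), or when
    *every* item has fewer than ``min_distinct_responses`` distinct observed
    values (stereotyped responding).  ``manual_exclude`` lets an analyst
    override retention for named participants.
    """
    manual = set(manual_exclude)
    report = ExclusionReport()
    keep: list[str] = []
    for pid, diary in cohort.diaries.items():
        reasons: list[str] = []
        if diary.n_days < min_days:
            reasons.append("too_few_days")
        n_distinct = diary.scores.nunique(dropna=True)
        if (n_distinct < min_distinct_responses).all():
            reasons.append("minimal_variation")
        if pid in manual:
            reasons.append("manual")
        retained = not reasons
        report.entries[pid] = (retained, tuple(reasons))
        if retained:
            keep.append(pid)
    if not keep:
        warnings.warn("all participants excluded; cohort is empty", stacklevel=2)
    return cohort.subset(keep), report


class CandidatePair(NamedTuple):
    item_a: str
    item_b: str
    zero_order_r: float
    proportion_significantly_different: float


@dataclass
class RedundancyReport:
    """Outcome of redundant-item detection.

    ``candidate_pairs`` are all pairs whose absolute zero-order correlation
    reached ``cor_min``; ``flagged_pairs`` is the subset whose correlation
    profiles with the remaining items differed significantly for fewer than
    ``flag_proportion`` of the comparisons; ``removed_items`` lists the
    lower-variance member of each flagged pair (subject to overrides).
    """

    candidate_pairs: list[CandidatePair] = field(default_factory=list)
    flagged_pairs: list[CandidatePair] = field(default_factory=list)
    removed_items: list[str] = field(default_factory=list)
    skipped_items: list[str] = field(default_factory=list)
    n_observations: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        flagged = {(p.item_a, p.item_b) for p in self.flagged_pairs}
        for p in self.candidate_pairs:
            rows.append(
                {
                    "item_a": p.item_a,
                    "item_b": p.item_b,
                    "zero_order_r": p.zero_order_r,
                    "prop_significantly_different": p.proportion_significantly_different,
                    "flagged": (p.item_a, p.item_b) in flagged,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "item_a",
                "item_b",
                "zero_order_r",
                "prop_significantly_different",
                "flagged",
            ],
        )


def _dependent_correlation_p(
    r_ac: float, r_bc: float, r_ab: float, n: int
) -> float:
    """Two-sided p for H0: rho(A,C) = rho(B,C) with overlapping variable C.

    Back-transformed-z form: the two correlations are Fisher-transformed and
    their difference standardised using the Dunn & Clark covariance evaluated
    at the back-transformed mean of the two z values.
    """
    za, zb = math.atanh(r_ac), math.atanh(r_bc)
    rm = math.tanh((za + zb) / 2.0)
    rm2 = rm * rm
    denom = (1.0 - rm2) ** 2
    cov = (r_ab * (1.0 - 2.0 * rm2) - 0.5 * rm2 * (1.0 - 2.0 * rm2 - r_ab * r_ab)) / denom
    cov = min(cov, 1.0 - 1e-12)
    z = (za - zb) * math.sqrt((n - 3) / (2.0 - 2.0 * cov))
    return 2.0 * stats.norm.sf(abs(z))


def _pooled_scores(
    diaries: DiaryMatrix | Iterable[DiaryMatrix] | pd.DataFrame,
) -> pd.DataFrame:
    if isinstance(diaries, pd.DataFrame):
        return diaries
    if isinstance(diaries, DiaryMatrix):
        return diaries.scores
    return pd.concat([d.scores for d in diaries], axis=0, ignore_index=True)


def detect_redundant_items(
    diaries: DiaryMatrix | Iterable[DiaryMatrix] | pd.DataFrame,
    cor_min: float = 0.50,
    p_threshold: float = 0.05,
    flag_proportion: float = 0.25,
    method: str = "pearson",
    keep_overrides: Mapping[frozenset, str] | None = None,
) -> RedundancyReport:
    """Flag near-redundant item pairs from pooled diary data.

    For each pair (A, B) with ``|r_AB| >= cor_min``, the zero-order
    correlations r(A, C) and r(B, C) are compared for every other item C with
    a two-sided dependent-overlapping-correlations test; the pair is flagged
    when fewer than ``flag_proportion`` of those m-2 comparisons are
    significant at ``p_threshold`` — i.e. the two items relate to the rest of
    the network near-identically.  For each flagged pair the lower-variance
    member is slated for removal (ties keep the lexicographically first item;
    ``keep_overrides`` maps ``frozenset({a, b})`` to the item to keep).

    Correlations are computed on listwise-complete pooled observations;
    constant items are skipped with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    pooled = _pooled_scores(diaries).dropna(axis=0, how="any")
    report = RedundancyReport(n_observations=len(pooled))
    variances = pooled.var(ddof=1)
    constant = [c for c in pooled.columns if not (variances[c] > 0)]
    if constant:
        warnings.warn(
            f"constant items skipped in redundancy detection: {constant}",
            stacklevel=2,
        )
        report.skipped_items = list(constant)
        pooled = pooled.drop(columns=constant)
    items = sorted(pooled.columns)
    if len(items) < 4:
        raise ValueError("redundancy detection needs at least 4 non-constant items")
    n = len(pooled)
    if n < 20:
        raise ValueError(
            f"redundancy detection needs >= 20 complete observations, got {n}"
        )
    corr = pooled[items].corr(method=method)
    overrides = {frozenset(k): v for k, v in (keep_overrides or {}).items()}

    for ia, a in enumerate(items):
        for b in items[ia + 1 :]:
            r_ab = float(corr.loc[a, b])
            if abs(r_ab) < cor_min:
                continue
            others = [c for c in items if c not in (a, b)]
            pvals = [
                _dependent_correlation_p(
                    float(corr.loc[a, c]), float(corr.loc[b, c]), r_ab, n
                )
                for c in others
            ]
            prop = float(np.mean([p < p_threshold for p in pvals]))
            pair = CandidatePair(a, b, r_ab, prop)
            report.candidate_pairs.append(pair)
            if prop < flag_proportion:
                report.flagged_pairs.append(pair)

    removed: list[str] = []
    for pair in report.flagged_pairs:
        a, b = pair.item_a, pair.item_b
        if a in removed or b in removed:
            continue
        key = frozenset((a, b))
        if key in overrides:
            keep = overrides[key]
            drop = b if keep == a else a
        else:
            va, vb = float(variances[a]), float(variances[b])
            # keep the higher-variance member; tie -> keep lexicographically first
            keep = a if va > vb or (va == vb) else b
            drop = b if keep == a else a
        removed.append(drop)
    report.removed_items = removed
    return report


def remove_redundant_items(cohort: Cohort, report: RedundancyReport) -> Cohort:
    """Drop the items named in ``report.removed_items`` cohort-wide."""
    if not report.removed_items:
        return cohort
    return cohort.drop_items(report.removed_items)
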