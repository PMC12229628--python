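"""Relapse-group comparison of network metrics with FDR control.

Every item x centrality-index combination is compared between the relapse and
non-relapse groups twice: on the raw index values and on within-participant
ranks (rank 1 = most central symptom), to separate absolute from relative
centrality effects.  Per-item SD/RMSSD and the network-level density metrics
(ASPL, global efficiency) are compared as well.  Each comparison runs a Welch
two-sample t-test and a Wilcoxon rank-sum (Mann-Whitney) test, two-sided;
the rank-sum p-value is exact when the combined sample is small and tie-free,
otherwise a tie- and continuity-corrected normal approximation.  P-values are
adjusted by Benjamini-Hochberg step-up within configurable families at
FDR <= q (default 0.10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import CentralityProfile, DensityMetrics
from .variability import SymptomVariability

__all__ = [
    "TestResult",
    "ComparisonTable",
    "rank_centralities",
    "two_sample_tests",
    "bh_adjust",
    "compare_cohort",
]

#: Largest combined sample size for which the rank-sum test is enumerated
#: exactly (when the data are tie-free).
EXACT_RANKSUM_MAX_N = 20


@dataclass
class TestResult:
    """Two-sample comparison of one metric between relapse groups."""

    metric_id: str
    mean_a: float  # relapse group
    mean_b: float  # non-relapse group
    t_statistic: float
    t_pvalue: float
    wilcoxon_statistic: float
    wilcoxon_pvalue: float
    n_a: int
    n_b: int


@dataclass
class ComparisonTable:
    """All group-comparison results with per-family BH adjustment."""

    results: pd.DataFrame
    q: float
    family_mode: str

    def to_frame(self) -> pd.DataFrame:
        return self.results


def rank_centralities(profile: CentralityProfile) -> pd.DataFrame:
    """Within-participant item ranks per index; rank 1 = most central.

    Ties receive average ranks, so a participant whose items all share one
    value gets rank (n+1)/2 everywhere.
    """
    return profile.values.rank(ascending=False, method="average")


def two_sample_tests(
    values_a: Sequence[float],
    values_b: Sequence[float],
    metric_id: str = "",
    use_welch: bool = True,
) -> TestResult:
    """Welch t-test and Wilcoxon rank-sum test between two groups, two-sided.

    The rank-sum test is computed by exact enumeration when the combined
    sample size is <= 20 and there are no ties, otherwise by the normal
    approximation with tie and continuity corrections.  Degenerate input
    (zero variance in both groups with equal means) yields t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        t_stat, t_p = 0.0, 1.0
    else:
        t_res = stats.ttest_ind(a, b, equal_var=not use_welch)
        t_stat, t_p = float(t_res.statistic), float(t_res.pvalue)
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if a.size + b.size <= EXACT_RANKSUM_MAX_N and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return TestResult(
        metric_id=metric_id,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=t_stat,
        t_pvalue=t_p,
        wilcoxon_statistic=float(res.statistic),
        wilcoxon_pvalue=float(res.pvalue),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def bh_adjust(
    pvalues: Sequence[float], q: float = 0.10
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment and rejection flags at FDR q.

    Returns ``(adjusted_p, reject)``; adjusted p_(i) = min_{j>=i} m p_(j)/j
    capped at 1.  NaN p-values are passed through as NaN / not rejected and
    do not count towards m.
    """
    p = np.asarray(pvalues, dtype=float)
    adj = np.full(p.shape, np.nan)
    rej = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.any():
        reject, p_adj, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        adj[ok] = p_adj
        rej[ok] = reject
    return adj, rej


def _centrality_block(
    profiles: Mapping[str, CentralityProfile],
) -> pd.DataFrame:
    """Long table: participant x item x index x variant -> value."""
    rows = []
    for pid, prof in profiles.items():
        raw = prof.values
        rank = rank_centralities(prof)
        for variant, table in (("raw", raw), ("rank", rank)):
            stacked = table.stack()
            for (item, index), value in stacked.items():
                rows.append(
                    {
                        "participant_id": pid,
                        "item": item,
                        "index": index,
                        "variant": variant,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def compare_cohort(
    profiles: Mapping[str, CentralityProfile],
    variabilities: Mapping[str, SymptomVariability],
    densities: Mapping[str, DensityMetrics],
    labels: Mapping[str, bool],
    q: float = 0.10,
    family_mode: str = "blocked",
    use_welch: bool = True,
) -> ComparisonTable:
    """Compare all metrics between relapse and non-relapse participants.

    Families for BH adjustment (``family_mode='blocked'``, the default): one
    family per centrality index x {raw, rank} block, one for the variability
    indices, one for the density metrics.  ``family_mode='global'`` adjusts
    everything as a single family.  Both t-test and rank-sum p-values are
    adjusted (separately, within the same families).
    """
    if family_mode not in ("blocked", "global"):
        raise ValueError(f"unknown family_mode {family_mode!r}")
    relapse = [p for p in profiles if labels.get(p)]
    control = [p for p in profiles if p in labels and not labels[p]]
    unlabelled = [p for p in profiles if p not in labels]
    if unlabelled:
        raise ValueError(f"participants without relapse label: {sorted(unlabelled)}")
    if len(relapse) < 2 or len(control) < 2:
        raise ValueError(
            f"need >= 2 participants per group (relapse={len(relapse)}, "
            f"non-relapse={len(control)})"
        )

    rows: list[dict] = []

    def add(metric_id: str, family: str, item, index, variant, series: Mapping[str, float]):
        a = [series[p] for p in relapse]
        b = [series[p] for p in control]
        if np.isnan(a).any() or np.isnan(b).any():
            a = [v for v in a if not np.isnan(v)]
            b = [v for v in b if not np.isnan(v)]
        if len(a) < 2 or len(b) < 2:
            return
        res = two_sample_tests(a, b, metric_id=metric_id, use_welch=use_welch)
        rows.append(
            {
                "metric_id": metric_id,
                "family": family,
                "item": item,
                "index": index,
                "variant": variant,
                "mean_relapse": res.mean_a,
                "mean_nonrelapse": res.mean_b,
                "t": res.t_statistic,
                "p_t": res.t_pvalue,
                "w": res.wilcoxon_statistic,
                "p_w": res.wilcoxon_pvalue,
                "n_relapse": res.n_a,
                "n_nonrelapse": res.n_b,
            }
        )

    cent = _centrality_block(profiles)
    for (index, variant), block in cent.groupby(["index", "variant"], sort=True):
        family = f"{index}_{variant}"
        for item, sub in block.groupby("item", sort=True):
            series = dict(zip(sub["participant_id"], sub["value"]))
            add(f"{item}:{index}:{variant}", family, item, index, variant, series)

    items = None
    for pid, var in variabilities.items():
        items = tuple(var.values.index)
        break
    if items is not None:
        for vindex in ("sd", "rmssd"):
            for item in items:
                series = {
                    pid: float(var.values.loc[item, vindex])
                    for pid, var in variabilities.items()
                }
                add(f"{item}:{vindex}:raw", "variability", item, vindex, "raw", series)

    for dindex in ("aspl", "global_efficiency"):
        series = {pid: getattr(d, dindex) for pid, d in densities.items()}
        add(f"network:{dindex}:raw", "density", "network", dindex, "raw", series)

    results = pd.DataFrame(rows)
    if family_mode == "global":
        results["family"] = "all"
    for col, adj_col, rej_col in (("p_t", "p_t_adj", "rejected_t"),
                                  ("p_w", "p_w_adj", "rejected_w")):
        results[adj_col] = np.nan
        results[rej_col] = False
        for _, idx in results.groupby("family").groups.items():
            adj, rej = bh_adjust(results.loc[idx, col].to_numpy(), q=q)
            results.loc[idx, adj_col] = adj
            results.loc[idx, rej_col] = rej
    return ComparisonTable(results=results, q=q, family_mode=family_mode)
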