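"""Synthetic diary-cohort generator with known network ground truth.

The generator emulates the statistical structure the analysis assumes: each
participant has a true partial-correlation network (a shared sparse template
plus participant-specific perturbations), daily latent symptom vectors are
drawn from the corresponding Gaussian graphical model — optionally with AR(1)
day-to-day carry-over — and discretised onto the 1-7 diary scale through an
ordinal-probit threshold mechanism.  A relapse subgroup can have all its edge
magnitudes scaled by a density factor delta, the connectivity pattern the
hysteresis hypothesis predicts (delta = 1 is the hysteresis null).

Items are generated directly on the severity scale (no positively valenced
items), so estimated networks compare against the stored truth without a
valence flip.  Defaults mirror the cohort the analysis was designed for:
30 participants, 12 relapsers, 13 items, day counts ~ Normal(265.3, 114.3)
truncated to [100, 365].

Everything is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schema import Cohort, DiaryMatrix, Item, ItemSchema

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "make_truth",
    "simulate_diary",
    "generate_cohort",
]

#: Minimum allowed off-diagonal shrinkage factor during the positive-definite
#: repair; configurations needing more shrinkage are rejected as infeasible.
MIN_SHRINK = 0.5


def _equiprobable_thresholds(n_levels: int = 7) -> tuple[float, ...]:
    return tuple(stats.norm.ppf(k / n_levels) for k in range(1, n_levels))


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Attributes
    ----------
    n_participants, n_relapsers:
        Cohort size and relapse-subgroup size.
    n_items:
        Items in the true network (a planted duplicate, if any, is appended
        on top of these).
    days_mean, days_sd, days_min, days_max:
        Per-participant calendar-day counts ~ truncated Normal.
    base_edge_density:
        Fraction of item pairs with a nonzero template partial correlation.
    edge_weight_range:
        Magnitude interval for template partials.
    negative_edge_prob:
        Probability a template edge is negative.
    heterogeneity:
        SD of the participant-specific Gaussian perturbation added to each
        nonzero template edge; 0 makes all true networks identical.
    relapse_density_factor:
        Multiplier (delta) on relapse-group edge magnitudes; 1 = null.
    ar_phi:
        Lag-1 autocorrelation of the latent daily scores.
    likert_thresholds:
        Six strictly increasing cut-points mapping the standard-normal latent
        scale to scores 1-7; default = equiprobable bins.
    p_missing_day:
        Probability a calendar day's diary entry is missing entirely.
    planted_duplicate:
        If True, append a near-duplicate of the first item (latent copy plus
        Gaussian noise of SD ``duplicate_noise_sd``) for redundancy-detection
        tests.
    seed:
        Base seed; all randomness derives from it.
    """

    n_participants: int = 30
    n_relapsers: int = 12
    n_items: int = 13
    days_mean: float = 265.3
    days_sd: float = 114.3
    days_min: int = 100
    days_max: int = 365
    base_edge_density: float = 0.25
    edge_weight_range: tuple[float, float] = (0.1, 0.35)
    negative_edge_prob: float = 0.1
    heterogeneity: float = 0.0
    relapse_density_factor: float = 1.0
    ar_phi: float = 0.0
    likert_thresholds: tuple[float, ...] | None = None
    p_missing_day: float = 0.1
    planted_duplicate: bool = False
    duplicate_noise_sd: float = 0.1
    start_date: str = "2020-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_relapsers <= self.n_participants):
            raise ValueError("need 0 <= n_relapsers <= n_participants")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be >= 0")
        if self.relapse_density_factor <= 0:
            raise ValueError("relapse_density_factor must be > 0")
        if not abs(self.ar_phi) < 1:
            raise ValueError("|ar_phi| must be < 1")
        if not (0 <= self.p_missing_day < 1):
            raise ValueError("p_missing_day must be in [0, 1)")
        lo, hi = self.edge_weight_range
        if not (0 < lo <= hi < 1):
            raise ValueError("edge_weight_range must satisfy 0 < lo <= hi < 1")
        if self.likert_thresholds is not None:
            t = self.likert_thresholds
            if len(t) != 6 or any(t[i] >= t[i + 1] for i in range(5)):
                raise ValueError("likert_thresholds must be 6 strictly increasing cuts")

    @property
    def thresholds(self) -> tuple[float, ...]:
        if self.likert_thresholds is not None:
            return self.likert_thresholds
        return _equiprobable_thresholds(7)

    @property
    def item_ids(self) -> tuple[str, ...]:
        base = tuple(f"item{k:02d}" for k in range(1, self.n_items + 1))
        if self.planted_duplicate:
            return base + ("item01_dup",)
        return base

    def schema(self) -> ItemSchema:
        return ItemSchema(
            items=tuple(Item(i, i) for i in self.item_ids), scale_min=1, scale_max=7
        )


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic cohort."""

    template_partial: np.ndarray
    partials: dict[str, np.ndarray] = field(default_factory=dict)
    precisions: dict[str, np.ndarray] = field(default_factory=dict)
    labels: dict[str, bool] = field(default_factory=dict)
    shrink_factors: dict[str, float] = field(default_factory=dict)
    config: CohortConfig | None = None

    @property
    def item_ids(self) -> tuple[str, ...]:
        n = self.template_partial.shape[0]
        return tuple(f"item{k:02d}" for k in range(1, n + 1))


def _precision_from_partials(p: np.ndarray) -> np.ndarray:
    """Unit-diagonal precision matrix whose partial correlations equal ``p``."""
    omega = -p.copy()
    np.fill_diagonal(omega, 1.0)
    return omega


def _repair_pd(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Shrink off-diagonal partials uniformly until the precision is PD.

    Returns ``(partials, precision, shrink_factor)``; raises if the required
    factor would fall below :data:`MIN_SHRINK`.
    """
    factor = 1.0
    current = p
    while True:
        omega = _precision_from_partials(current)
        if np.linalg.eigvalsh(omega)[0] > 1e-8:
            return current, omega, factor
        factor *= 0.95
        if factor < MIN_SHRINK:
            raise ValueError(
                "cannot reach a positive-definite precision matrix even after "
                f"shrinking off-diagonals to {MIN_SHRINK} of their magnitude"
            )
        current = p * factor


def _participant_ids(n: int) -> list[str]:
    return [f"P{k:02d}" for k in range(1, n + 1)]


def make_truth(config: CohortConfig, rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Draw the template network and per-participant true networks.

    The template is a sparse symmetric matrix of partial correlations with
    ``base_edge_density`` of pairs nonzero, magnitudes uniform in
    ``edge_weight_range`` and signs negative with ``negative_edge_prob``.
    Each participant's truth adds N(0, heterogeneity) noise to every nonzero
    template edge; relapsers' off-diagonals are then multiplied by the
    density factor delta.  Any truth whose implied precision matrix is not
    positive definite is repaired by uniform off-diagonal shrinkage (the
    factor is recorded in ``shrink_factors``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.n_items
    iu = np.triu_indices(m, k=1)
    n_pairs = len(iu[0])
    edge_mask = rng.random(n_pairs) < config.base_edge_density
    lo, hi = config.edge_weight_range
    magnitudes = rng.uniform(lo, hi, size=n_pairs)
    signs = np.where(rng.random(n_pairs) < config.negative_edge_prob, -1.0, 1.0)
    template = np.zeros((m, m))
    template[iu] = np.where(edge_mask, magnitudes * signs, 0.0)
    template = template + template.T
    # the template must stay a valid GGM even after the relapse-group edge
    # scaling, so feasibility is enforced on the delta-scaled matrix up front
    # (per-participant repair below then only handles heterogeneity draws)
    worst = max(1.0, config.relapse_density_factor)
    _, _, factor = _repair_pd(template * worst)
    template = template * factor

    pids = _participant_ids(config.n_participants)
    shuffled = list(pids)
    rng.shuffle(shuffled)
    labels = {pid: (shuffled.index(pid) < config.n_relapsers) for pid in pids}

    truth = SyntheticTruth(template_partial=template, config=config)
    truth.labels = labels
    tri_mask = np.zeros((m, m), dtype=bool)
    tri_mask[iu] = edge_mask
    for pid in pids:
        pert = np.zeros((m, m))
        if config.heterogeneity > 0:
            noise = rng.normal(0.0, config.heterogeneity, size=n_pairs)
            pert[iu] = np.where(edge_mask, noise, 0.0)
            pert = pert + pert.T
        p = np.clip(template + pert, -0.95, 0.95)
        if labels[pid]:
            p = np.clip(p * config.relapse_density_factor, -0.95, 0.95)
        p_fixed, omega, factor = _repair_pd(p)
        truth.partials[pid] = p_fixed
        truth.precisions[pid] = omega
        truth.shrink_factors[pid] = factor
    return truth


def _latent_correlation(omega: np.ndarray) -> np.ndarray:
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def simulate_diary(
    omega: np.ndarray,
    n_days: int,
    config: CohortConfig,
    rng: np.random.Generator,
    participant_id: str = "P01",
) -> DiaryMatrix:
    """Simulate one participant's ordinal diary from a true precision matrix.

    Latent daily vectors follow a zero-mean Gaussian with the correlation
    implied by ``omega``; with ``ar_phi != 0`` they follow a stationary AR(1)
    whose marginal distribution is that same Gaussian.  Each coordinate is
    discretised to 1-7 by the configured thresholds; whole days are dropped
    independently with ``p_missing_day``; dates run consecutively from
    ``config.start_date``.
    """
    corr = _latent_correlation(omega)
    chol = np.linalg.cholesky(corr)
    m = corr.shape[0]
    eps = rng.standard_normal((n_days, m)) @ chol.T
    phi = config.ar_phi
    if phi != 0.0:
        latent = np.empty_like(eps)
        latent[0] = eps[0]  # stationary start: marginal variance already corr
        scale = np.sqrt(1.0 - phi**2)
        for t in range(1, n_days):
            latent[t] = phi * latent[t - 1] + scale * eps[t]
    else:
        latent = eps
    if config.planted_duplicate:
        dup = latent[:, 0] + rng.normal(0.0, config.duplicate_noise_sd, size=n_days)
        latent = np.column_stack([latent, dup])
    cuts = np.asarray(config.thresholds)
    scores = 1 + np.searchsorted(cuts, latent).reshape(latent.shape)
    keep = rng.random(n_days) >= config.p_missing_day
    dates = pd.date_range(config.start_date, periods=n_days, freq="D")[keep]
    df = pd.DataFrame(
        scores[keep].astype(float), index=dates, columns=list(config.item_ids)
    )
    return DiaryMatrix(participant_id, df)


def generate_cohort(
    config: CohortConfig,
) -> tuple[Cohort, SyntheticTruth]:
    """Generate a full synthetic cohort plus its ground truth.

    Day counts are drawn per participant from the truncated normal declared
    in the config; relapse labels come from the seeded shuffle inside
    :func:`make_truth`.  Deterministic given ``config`` (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    truth = make_truth(config, rng)
    if config.days_sd > 0:
        a = (config.days_min - config.days_mean) / config.days_sd
        b = (config.days_max - config.days_mean) / config.days_sd
        counts = stats.truncnorm.rvs(
            a, b, loc=config.days_mean, scale=config.days_sd,
            size=config.n_participants, random_state=rng,
        )
        counts = np.rint(counts).astype(int)
    else:  # degenerate spread: every participant contributes the same span
        counts = np.full(config.n_participants, int(round(config.days_mean)))
    diaries: dict[str, DiaryMatrix] = {}
    for pid, n_days in zip(_participant_ids(config.n_participants), counts):
        diaries[pid] = simulate_diary(
            truth.precisions[pid], int(n_days), config, rng, participant_id=pid
        )
    cohort = Cohort(
        schema=config.schema(), diaries=diaries, relapse_labels=dict(truth.labels)
    )
    return cohort, truth


def true_network(truth: SyntheticTruth, pid: str):
    """The participant's true partial-correlation network as a SymptomNetwork."""
    from .network import SymptomNetwork

    p = truth.partials[pid]
    return SymptomNetwork(
        items=truth.item_ids,
        w=p.copy(),
        provenance={"participant_id": pid, "source": "synthetic-truth"},
    )


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """Convenience: same configuration, different seed."""
    return replace(config, seed=seed)
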