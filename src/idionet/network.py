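"""Non-regularized partial-correlation (Gaussian graphical model) estimation.

For one participant the day x item diary yields a pairwise correlation matrix
R; the partial correlation between items i and j given all others is obtained
from the precision matrix Omega = R^{-1} as

    w_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj),   w_ii = 0.

No lasso/EBIC regularization is applied: every edge is retained at its
estimated weight.  An optional ridge (added to the diagonal of R before
inversion) exists for near-singular inputs but defaults to 0; a singular
matrix without a ridge is an error rather than a silent regularization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import DiaryMatrix

__all__ = [
    "CorrelationMatrix",
    "SymptomNetwork",
    "correlation_matrix",
    "partial_correlation_network",
    "estimate_network",
    "ConstantItemError",
    "ConditioningError",
    "InsufficientDataError",
]


class ConstantItemError(ValueError):
    """An item has no variance in the analysed observations."""


class ConditioningError(np.linalg.LinAlgError, ValueError):
    """The correlation matrix is (near-)singular and no ridge was requested."""


class InsufficientDataError(ValueError):
    """Too few complete observations for a stable estimate."""


@dataclass
class CorrelationMatrix:
    """Pairwise correlations among items with the observation count used."""

    items: tuple[str, ...]
    r: np.ndarray
    n_effective: int
    method: str = "pearson"

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.items)
        if self.r.shape != (n, n):
            raise ValueError(f"correlation matrix shape {self.r.shape} != ({n},{n})")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class SymptomNetwork:
    """Symmetric weighted network of partial correlations (zero diagonal)."""

    items: tuple[str, ...]
    w: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        n = len(self.items)
        if self.w.shape != (n, n):
            raise ValueError(f"adjacency shape {self.w.shape} != ({n},{n})")
        if not np.allclose(self.w, self.w.T, atol=1e-10):
            raise ValueError("adjacency must be symmetric")
        if not np.allclose(np.diag(self.w), 0.0, atol=1e-12):
            raise ValueError("adjacency must have zero diagonal")

    @property
    def n_items(self) -> int:
        return len(self.items)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.w, index=list(self.items), columns=list(self.items))

    def permuted(self, order: list[int]) -> "SymptomNetwork":
        """Network with nodes re-ordered (same graph, relabelled storage)."""
        idx = np.asarray(order)
        return SymptomNetwork(
            items=tuple(self.items[i] for i in order),
            w=self.w[np.ix_(idx, idx)],
            provenance=dict(self.provenance),
        )


def correlation_matrix(
    diary: DiaryMatrix,
    method: str = "pearson",
    missing: str = "listwise",
) -> CorrelationMatrix:
    """Pairwise correlations of one participant's (reverse-coded) scores.

    ``missing='listwise'`` drops every day with any missing item, which keeps
    the resulting matrix positive semi-definite; ``'pairwise'`` uses all
    available pairs (n_effective is then the smallest pairwise count).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if missing not in ("listwise", "pairwise"):
        raise ValueError(f"unknown missing-data policy {missing!r}")
    scores = diary.scores
    items = tuple(scores.columns)
    if missing == "listwise":
        data = scores.dropna(axis=0, how="any")
        n_eff = len(data)
    else:
        data = scores
        pair_n = scores.notna().astype(int).T @ scores.notna().astype(int)
        n_eff = int(pair_n.to_numpy().min())
    constant = [
        c for c in items if data[c].dropna().nunique() <= 1
    ]
    if constant:
        raise ConstantItemError(
            f"{diary.participant_id}: constant item(s) {constant}; "
            "cannot correlate a constant column"
        )
    if n_eff < len(items) + 2:
        raise InsufficientDataError(
            f"{diary.participant_id}: {n_eff} complete observations for "
            f"{len(items)} items; need at least {len(items) + 2}"
        )
    if method == "pearson":
        r = data.corr(method="pearson", min_periods=2).to_numpy()
    else:
        r = data.corr(method="spearman", min_periods=2).to_numpy()
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(items=items, r=r, n_effective=n_eff, method=method)


def partial_correlation_network(
    corr: CorrelationMatrix,
    ridge: float = 0.0,
    provenance: dict | None = None,
) -> SymptomNetwork:
    """Invert a correlation matrix into a partial-correlation network.

    With ``Omega = (R + ridge*I)^{-1}`` the edge weights are
    ``w_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)`` (i != j) and ``w_ii = 0``.
    A singular R with ``ridge=0`` raises :class:`ConditioningError` naming
    the most collinear item pairs and advising a ridge.
    """
    r = corr.r.copy()
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if ridge > 0:
        r = r + ridge * np.eye(len(corr.items))
    cond = np.linalg.cond(r)
    if not np.isfinite(cond) or cond > 1e12:
        tri = np.abs(np.triu(corr.r, k=1))
        i, j = np.unravel_index(np.argmax(tri), tri.shape)
        raise ConditioningError(
            "correlation matrix is singular or ill-conditioned "
            f"(cond={cond:.3g}); most collinear pair: "
            f"{corr.items[i]} / {corr.items[j]} (r={corr.r[i, j]:.4f}). "
            "Consider a small ridge or removing redundant items."
        )
    omega = np.linalg.inv(r)
    d = np.sqrt(np.diag(omega))
    w = -omega / np.outer(d, d)
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    prov = dict(provenance or {})
    prov.update(
        {
            "method": corr.method,
            "n_effective": corr.n_effective,
            "ridge": ridge,
            "condition_number": float(cond),
        }
    )
    return SymptomNetwork(items=corr.items, w=w, provenance=prov)


def estimate_network(
    diary: DiaryMatrix,
    method: str = "pearson",
    missing: str = "listwise",
    ridge: float = 0.0,
) -> SymptomNetwork:
    """Estimate one participant's non-regularized partial-correlation network.

    Composition of :func:`correlation_matrix` and
    :func:`partial_correlation_network`; deterministic given the diary and
    settings.
    """
    corr = correlation_matrix(diary, method=method, missing=missing)
    return partial_correlation_network(
        corr, ridge=ridge, provenance={"participant_id": diary.participant_id}
    )


def partial_corr_3var(r_ab: float, r_ac: float, r_bc: float) -> float:
    """First-order partial correlation of A and B given C (recursive formula).

    Reference identity used as an independent oracle for the precision-matrix
    route on 3-variable problems:
    ``p_AB.C = (r_AB - r_AC r_BC) / sqrt((1 - r_AC^2)(1 - r_BC^2))``.
    """
    return (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))


def edge_significance_mask(
    network: SymptomNetwork, alpha: float = 0.05
) -> np.ndarray:
    """Boolean mask of edges significant at ``alpha`` (off by default in runs).

    Uses the t approximation for a partial correlation with
    ``n_effective - k`` degrees of freedom (k = items conditioned on + 2).
    """
    n_eff = network.provenance.get("n_effective")
    if n_eff is None:
        raise ValueError("network provenance lacks n_effective")
    k = network.n_items
    df = n_eff - k
    if df <= 0:
        raise InsufficientDataError("not enough observations for edge tests")
    w = np.clip(network.w, -0.999999, 0.999999)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = w * np.sqrt(df / (1 - w**2))
    p = 2 * stats.t.sf(np.abs(t), df)
    np.fill_diagonal(p, 1.0)
    return p < alpha
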