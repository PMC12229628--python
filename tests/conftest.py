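"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from idionet.network import SymptomNetwork
from idionet.schema import DiaryMatrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_diary(values, participant_id="P01", items=None, start="2021-01-01"):
    """Build a DiaryMatrix from a 2-D list/array (rows = consecutive days)."""
    arr = np.asarray(values, dtype=float)
    if items is None:
        items = [f"i{k}" for k in range(arr.shape[1])]
    dates = pd.date_range(start, periods=arr.shape[0], freq="D")
    return DiaryMatrix(participant_id, pd.DataFrame(arr, index=dates, columns=items))


def make_network(items, edges, pid="P01"):
    """Build a SymptomNetwork from {(a, b): weight} edge dict."""
    items = list(items)
    pos = {it: k for k, it in enumerate(items)}
    w = np.zeros((len(items), len(items)))
    for (a, b), weight in edges.items():
        w[pos[a], pos[b]] = w[pos[b], pos[a]] = weight
    return SymptomNetwork(
        items=tuple(items), w=w, provenance={"participant_id": pid}
    )


# ---------------------------------------------------------------------------
# Brute-force graph oracle: exhaustive simple-path enumeration.  Independent
# of the package's Dijkstra/Brandes code paths by construction.
# ---------------------------------------------------------------------------

def enumerate_all_paths(w, rtol=1e-9):
    """All-pairs geodesics by exhaustive simple-path enumeration.

    Returns (dist, geodesics) where geodesics[(s, t)] is the list of
    node-tuples realising the minimum length within relative tolerance.
    """
    n = w.shape[0]
    aw = np.abs(np.asarray(w, dtype=float))
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    geodesics = {}
    for s, t in itertools.combinations(range(n), 2):
        best = np.inf
        paths = []
        inner = [v for v in range(n) if v not in (s, t)]
        for r in range(len(inner) + 1):
            for mid in itertools.permutations(inner, r):
                path = (s, *mid, t)
                length = 0.0
                ok = True
                for a, b in zip(path, path[1:]):
                    if aw[a, b] == 0:
                        ok = False
                        break
                    length += 1.0 / aw[a, b]
                if not ok:
                    continue
                paths.append((length, path))
                best = min(best, length)
        if math.isinf(best):
            continue
        dist[s, t] = dist[t, s] = best
        geodesics[(s, t)] = [
            p for (ln, p) in paths if math.isclose(ln, best, rel_tol=rtol)
        ]
    return dist, geodesics


def oracle_metrics(w, rtol=1e-9):
    """Strength, closeness, betweenness, ASPL and efficiency by enumeration."""
    n = w.shape[0]
    aw = np.abs(np.asarray(w, dtype=float))
    dist, geodesics = enumerate_all_paths(w, rtol=rtol)
    strength = aw.sum(axis=1)
    closeness = np.zeros(n)
    for i in range(n):
        row = np.delete(dist[i], i)
        closeness[i] = 0.0 if (row.size and np.isinf(row).any()) else (
            1.0 / row.sum() if row.size else 0.0
        )
    betweenness = np.zeros(n)
    for (s, t), paths in geodesics.items():
        sigma = len(paths)
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            betweenness[v] += through / sigma
    iu = np.triu_indices(n, k=1)
    pairs = dist[iu]
    finite = np.isfinite(pairs)
    aspl = float(pairs[finite].mean()) if finite.any() else float("nan")
    eff = float(np.where(finite, 1.0 / np.where(finite, pairs, 1.0), 0.0).mean()) \
        if pairs.size else 0.0
    return {
        "dist": dist,
        "strength": strength,
        "closeness": closeness,
        "betweenness": betweenness,
        "aspl": aspl,
        "global_efficiency": eff,
        "fraction_reachable": float(finite.mean()) if pairs.size else 1.0,
    }


def random_weighted_network(rng, n_nodes=None, density=0.6, allow_negative=True):
    """Random small symmetric weighted graph for oracle comparisons."""
    if n_nodes is None:
        n_nodes = int(rng.integers(3, 7))
    w = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    mask = rng.random(len(iu[0])) < density
    mags = rng.uniform(0.05, 0.9, size=len(iu[0]))
    signs = rng.choice([-1.0, 1.0], size=len(iu[0])) if allow_negative else 1.0
    w[iu] = np.where(mask, mags * signs, 0.0)
    w = w + w.T
    items = tuple(f"n{k}" for k in range(n_nodes))
    return SymptomNetwork(items=items, w=w, provenance={})


def bh_oracle(pvalues, q):
    """Literal step-up definition of Benjamini-Hochberg (independent oracle)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    if k_star:
        reject[order[:k_star]] = True
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adjusted[idx] = running
    return adjusted, reject


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
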