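"""Simplified time-delay information-theoretic network inference.

A directed network is inferred from a single time course in three steps:

1. initial-change detection (IcE): per node, the first time index whose
   fold change relative to the first observation crosses an up or down
   threshold — nodes that change earlier are candidate regulators of nodes
   that change later;
2. pairwise time-lagged mutual information between temporally ordered node
   pairs, with significance judged against a bootstrap null built by
   resampling one of the two series;
3. pruning of indirect edges with the data-processing inequality (in a true
   chain a -> b -> c the indirect pair a,c carries the smallest MI).

Entropies use equal-width discretization and base-2 logs. Edge signs are
assigned from the lagged Pearson correlation at the maximizing lag; the
benchmark's scoring ignores signs, so this is informational only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import SignedNetwork
from .simulate import TimeCourse

__all__ = [
    "TDParams",
    "MIMatrix",
    "ice",
    "entropy",
    "mutual_information",
    "dpi_prune",
    "infer_tdaracne",
]


@dataclass
class TDParams:
    """Thresholds and estimator settings for the time-delay inference.

    tau_up / tau_down are fold-change thresholds (> 1 and < 1) for the
    initial-change detector; n_bins the equal-width discretization level;
    max_lag the largest time-shift searched; the bootstrap settings control
    the per-pair significance null; dpi_tolerance relaxes the
    data-processing-inequality pruning (0 = strict).
    """

    tau_up: float = 1.2
    tau_down: float = 0.8
    n_bins: int = 4
    max_lag: int = 3
    n_bootstrap: int = 100
    significance_alpha: float = 0.05
    dpi_tolerance: float = 0.15

    def __post_init__(self) -> None:
        if not self.tau_up > 1 > self.tau_down > 0:
            raise ValueError("require tau_up > 1 > tau_down > 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.max_lag < 1 or self.n_bootstrap < 1:
            raise ValueError("max_lag and n_bootstrap must be positive")
        if not 0 < self.significance_alpha < 1:
            raise ValueError("significance_alpha must be in (0, 1)")
        if self.dpi_tolerance < 0:
            raise ValueError("dpi_tolerance must be non-negative")


@dataclass
class MIMatrix:
    values: np.ndarray  # n×n nonnegative lagged MI
    lags: np.ndarray    # n×n maximizing lag


def ice(series: np.ndarray, tau_up: float, tau_down: float) -> int | None:
    """First index whose fold change from the initial value crosses a threshold.

    Returns the smallest j >= 1 with series[j]/series[0] >= tau_up or
    series[j]/series[0] <= tau_down, or None when the series never departs.
    """
    if not tau_up > 1 > tau_down > 0:
        raise ValueError("require tau_up > 1 > tau_down > 0")
    s = np.asarray(series, dtype=float)
    if s[0] <= 0:
        raise ValueError("first observation must be positive for fold change")
    ratio = s[1:] / s[0]
    hits = np.flatnonzero((ratio >= tau_up) | (ratio <= tau_down))
    return int(hits[0]) + 1 if hits.size else None


def entropy(probabilities: np.ndarray) -> float:
    """Shannon entropy -sum p log2 p in bits, with 0 log 0 = 0."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return np.zeros(x.size, dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = 4) -> float:
    """Empirical MI (bits) after equal-width discretization of each variable."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if x.size < n_bins:
        raise ValueError("series shorter than the number of bins")
    xd = _discretize(x, n_bins)
    yd = _discretize(y, n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (xd, yd), 1.0)
    joint /= joint.sum()
    hx = entropy(joint.sum(axis=1))
    hy = entropy(joint.sum(axis=0))
    hxy = entropy(joint.ravel())
    return max(hx + hy - hxy, 0.0)


def _max_lagged_mi(xa: np.ndarray, xb: np.ndarray, params: TDParams) -> tuple[float, int]:
    """Max over lags 1..max_lag of MI(x_a(t), x_b(t + lag))."""
    best, best_lag = -1.0, 1
    for lag in range(1, params.max_lag + 1):
        if xa.size - lag < params.n_bins:
            break
        mi = mutual_information(xa[:-lag], xb[lag:], params.n_bins)
        if mi > best:
            best, best_lag = mi, lag
    return (best if best >= 0 else 0.0), best_lag


def dpi_prune(mi: MIMatrix, edges: set[tuple[int, int]],
              tolerance: float = 0.0) -> set[tuple[int, int]]:
    """Remove indirect edges violating the data-processing inequality.

    For every directed triangle a->b, b->c, a->c present in the edge set,
    the shortcut a->c is removed when MI(a,c) < min(MI(a,b), MI(b,c)) *
    (1 - tolerance). All triangles are judged against the original MI
    values simultaneously.
    """
    values = mi.values
    doomed = set()
    for (a, c) in edges:
        for b in range(values.shape[0]):
            if b in (a, c):
                continue
            if (a, b) in edges and (b, c) in edges:
                bound = min(values[a, b], values[b, c]) * (1.0 - tolerance)
                if values[a, c] < bound:
                    doomed.add((a, c))
                    break
    return edges - doomed


def infer_tdaracne(tc: TimeCourse, params: TDParams | None = None,
                   seed: int = 0) -> SignedNetwork:
    """Infer a directed signed network from one time course.

    Ordered pairs (a, b) are tested only when IcE(a) <= IcE(b) (temporal
    precedence); an edge is kept when its maximal lagged MI exceeds the
    (1 - alpha) quantile of a bootstrap null obtained by resampling the
    source series with replacement. Surviving edges are DPI-pruned.
    """
    params = params or TDParams()
    n = tc.n_nodes
    m = tc.n_points
    if m < 2 * params.max_lag + params.n_bins:
        raise ValueError("time course too short for the requested lags and bins")
    if n < 2:
        return SignedNetwork(np.zeros((n, n), dtype=int), list(tc.node_labels))

    # Step 1: initial-change indices; fold change needs positive baselines,
    # so lift everything by a small offset (expression scale is >= 0).
    states = tc.states
    offset = 1e-2 * max(float(states.max()), 1e-6)
    shifted = states - min(float(states.min()), 0.0) + offset
    ice_idx = [ice(shifted[:, a], params.tau_up, params.tau_down) for a in range(n)]

    rng = np.random.default_rng(seed)
    mi_values = np.zeros((n, n))
    mi_lags = np.ones((n, n), dtype=int)
    edges: set[tuple[int, int]] = set()
    for a in range(n):
        if ice_idx[a] is None:
            continue  # never-changing nodes cannot be sources
        for b in range(n):
            if a == b or ice_idx[b] is None or ice_idx[a] > ice_idx[b]:
                continue
            mi_ab, lag = _max_lagged_mi(states[:, a], states[:, b], params)
            mi_values[a, b] = mi_ab
            mi_lags[a, b] = lag
            null = np.empty(params.n_bootstrap)
            for k in range(params.n_bootstrap):
                resampled = rng.choice(states[:, a], size=m, replace=True)
                null[k], _ = _max_lagged_mi(resampled, states[:, b], params)
            if mi_ab > np.quantile(null, 1.0 - params.significance_alpha):
                edges.add((a, b))

    mi = MIMatrix(values=mi_values, lags=mi_lags)
    edges = dpi_prune(mi, edges, params.dpi_tolerance)

    adj = np.zeros((n, n), dtype=int)
    for (a, b) in edges:
        lag = mi_lags[a, b]
        r = np.corrcoef(states[:-lag, a], states[lag:, b])[0, 1]
        adj[b, a] = -1 if (np.isfinite(r) and r < 0) else 1
    return SignedNetwork(adj, list(tc.node_labels))
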