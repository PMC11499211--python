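"""Centrality measures on directed weighted behavior networks.

Three node-level measures characterize a behavior-transition network:

* **in-strength** -- total weight of incoming links: how strongly a behavior
  is entered from other behaviors;
* **out-strength** -- total weight of outgoing links: how strongly a behavior
  leads into other behaviors;
* **betweenness** -- for node v, the sum over ordered pairs (s, t), s,t != v,
  of the fraction of shortest directed s->t paths passing through v
  (fractional counting under ties).  In ``binary`` mode (default) an edge
  exists wherever the weight is positive and has unit length -- the classical
  count-of-shortest-paths formulation.  In ``weighted`` mode an edge of
  weight w has length 1/w, so heavily used transitions are short.

Centralities are compared across days on a per-network z-scale: within one
network the six node values are standardized to mean 0 and population SD 1
(all zeros if the raw values are constant).
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

from .transitions import NODE_ORDER, BehaviorNetwork, TransitionMatrix

__all__ = [
    "in_strength",
    "out_strength",
    "betweenness",
    "zscore",
    "centrality_table",
]

BetweennessMode = Literal["binary", "weighted"]

# Relative tolerance for "equal length" when counting shortest paths with
# floating-point edge lengths.  Exact for binary (integer) lengths.
_TIE_RTOL = 1e-12


def _as_weights(net) -> np.ndarray:
    if isinstance(net, BehaviorNetwork):
        return net.weights
    if isinstance(net, TransitionMatrix):
        return net.weights
    return np.asarray(net, dtype=float)


def in_strength(net) -> np.ndarray:
    """Column sums of the weight matrix: total incoming weight per node."""
    return _as_weights(net).sum(axis=0)


def out_strength(net) -> np.ndarray:
    """Row sums of the weight matrix: total outgoing weight per node."""
    return _as_weights(net).sum(axis=1)


def _edge_lengths(weights: np.ndarray, mode: BetweennessMode) -> np.ndarray:
    """Length matrix with np.inf where no edge exists (weight 0; no self-edges)."""
    lengths = np.full(weights.shape, np.inf)
    present = weights > 0
    np.fill_diagonal(present, False)
    if mode == "binary":
        lengths[present] = 1.0
    elif mode == "weighted":
        lengths[present] = 1.0 / weights[present]
    else:
        raise ValueError(f"unknown betweenness mode {mode!r}")
    return lengths


def _single_source(lengths: np.ndarray, s: int) -> tuple[np.ndarray, np.ndarray]:
    """Dijkstra distances and shortest-path counts from source ``s``.

    Path counts accumulate fractionally under ties; positive edge lengths
    guarantee the relaxation order is valid.
    """
    n = lengths.shape[0]
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    dist[s] = 0.0
    sigma[s] = 1.0
    done = np.zeros(n, dtype=bool)
    for _ in range(n):
        cand = np.where(~done, dist, np.inf)
        u = int(np.argmin(cand))
        if not np.isfinite(cand[u]):
            break
        done[u] = True
        for v in range(n):
            if done[v] or not np.isfinite(lengths[u, v]):
                continue
            nd = dist[u] + lengths[u, v]
            tol = _TIE_RTOL * (1.0 + abs(nd))
            if nd < dist[v] - tol:
                dist[v] = nd
                sigma[v] = sigma[u]
            elif abs(nd - dist[v]) <= tol:
                sigma[v] += sigma[u]
    return dist, sigma


def betweenness(net, mode: BetweennessMode = "binary") -> np.ndarray:
    """Fractional shortest-path betweenness per node (unnormalized).

    For each ordered pair (s, t) with a directed path, node v (distinct from
    both) receives sigma_st(v) / sigma_st, where sigma_st counts shortest
    s->t paths and sigma_st(v) those through v.  Unreachable pairs contribute
    nothing.  Raw values are reported; normalization is unnecessary because
    downstream comparison is on z-scores.
    """
    weights = _as_weights(net)
    n = weights.shape[0]
    lengths = _edge_lengths(weights, mode)
    dist = np.empty((n, n))
    sigma = np.empty((n, n))
    for s in range(n):
        dist[s], sigma[s] = _single_source(lengths, s)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t or not np.isfinite(dist[s, t]):
                continue
            for v in range(n):
                if v == s or v == t:
                    continue
                through = dist[s, v] + dist[v, t]
                if not np.isfinite(through):
                    continue
                tol = _TIE_RTOL * (1.0 + abs(through) + abs(dist[s, t]))
                if abs(through - dist[s, t]) <= tol:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, population SD 1; all zeros for a constant vector."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("zscore requires at least 2 values")
    sd = x.std()  # population SD: per-network standardization, not a sample
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def centrality_table(
    net: BehaviorNetwork, mode: BetweennessMode = "binary"
) -> pd.DataFrame:
    """Raw and z-standardized centralities of one network as a tidy table.

    One row per (node, measure) with columns
    ``group, phase, ppd, code, metric, raw, z``; z-scores are computed within
    this network across its six nodes.
    """
    measures = {
        "in_strength": in_strength(net),
        "out_strength": out_strength(net),
        "betweenness": betweenness(net, mode=mode),
    }
    rows = []
    for metric, raw in measures.items():
        z = zscore(raw)
        for i, code in enumerate(NODE_ORDER):
            rows.append(
                {
                    "group": net.group,
                    "phase": net.phase,
                    "ppd": net.ppd,
                    "code": code,
                    "metric": metric,
                    "raw": float(raw[i]),
                    "z": float(z[i]),
                }
            )
    return pd.DataFrame(rows)
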