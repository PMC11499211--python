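"""From scan-sample sequences to transition matrices and behavior networks.

A *transition* is a pair of adjacent scan samples with different codes.
Transitions are only counted within one observation period -- never across
the gaps between periods, where hours of unobserved behavior lie.

Two scopes exist for the transition count:

* ``all`` (default) -- counted on the raw 7-code sequence; this is the
  fragmentation statistic analyzed per phase and day.
* ``network`` -- counted between the 6 network nodes after removing the
  standalone licking code ``L``, matching the off-diagonal sum of the
  transition matrix.

``L`` is excluded from networks because it rarely occurs alone (licking
during high crouch is its own code, HG/L).  Two removal policies are
provided since either is defensible:

* ``bridge`` (default) -- delete L slots and let their neighbors become
  adjacent, preserving sequence continuity;
* ``drop`` -- discard any adjacent pair touching an L slot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .ethogram import CODES, NETWORK_NODES, PERIODS, Dataset, EthogramError

__all__ = [
    "NODE_ORDER",
    "TransitionMatrix",
    "BehaviorNetwork",
    "transition_count",
    "occurrence_counts",
    "transition_matrix",
    "phase_aggregate",
    "build_group_network",
]

#: Fixed node order of every transition matrix and network.
NODE_ORDER: tuple[str, ...] = NETWORK_NODES
_NODE_INDEX = {c: i for i, c in enumerate(NODE_ORDER)}
_N_NODES = len(NODE_ORDER)

LPolicy = Literal["bridge", "drop"]
Scope = Literal["all", "network"]

#: Phases and the periods they aggregate.
PHASES: tuple[str, ...] = ("LIGHT", "DARK")
PHASE_PERIODS = {"LIGHT": ("AM", "PM"), "DARK": ("DARK",)}


@dataclass(frozen=True)
class TransitionMatrix:
    """Directed transition weights between the 6 network nodes.

    ``weights[i, j]`` is the (possibly fractional, after averaging) number of
    observed switches from ``NODE_ORDER[i]`` to ``NODE_ORDER[j]``.  The
    diagonal is structurally zero: staying in a behavior is not a link.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (_N_NODES, _N_NODES):
            raise ValueError(f"weights must be {_N_NODES}x{_N_NODES}")
        if np.any(w < 0):
            raise ValueError("transition weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("transition matrix must have a zero diagonal (no self-links)")
        object.__setattr__(self, "weights", w)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def __add__(self, other: "TransitionMatrix") -> "TransitionMatrix":
        return TransitionMatrix(self.weights + other.weights)


@dataclass(frozen=True)
class BehaviorNetwork:
    """Group-averaged directed weighted behavior-transition network.

    ``node_sizes[i]`` is the mean number of scan samples in which node
    ``NODE_ORDER[i]`` was observed per period (node size in the network
    graph); ``edges`` holds the group-mean transition weights.
    """

    edges: TransitionMatrix
    node_sizes: np.ndarray
    group: str
    phase: str
    ppd: int
    n_dams: int

    def __post_init__(self) -> None:
        sizes = np.asarray(self.node_sizes, dtype=float)
        if sizes.shape != (_N_NODES,):
            raise ValueError(f"node_sizes must have shape ({_N_NODES},)")
        if np.any(sizes < 0):
            raise ValueError("node sizes must be non-negative")
        object.__setattr__(self, "node_sizes", sizes)

    @property
    def weights(self) -> np.ndarray:
        return self.edges.weights


def _network_pairs(
    codes: Sequence[str], l_policy: LPolicy
) -> Iterable[tuple[str, str]]:
    if l_policy == "bridge":
        kept = [c for c in codes if c != "L"]
        return zip(kept, kept[1:])
    if l_policy == "drop":
        return (
            (a, b) for a, b in zip(codes, codes[1:]) if a != "L" and b != "L"
        )
    raise ValueError(f"unknown l_policy {l_policy!r}")


def transition_count(
    codes: Sequence[str], scope: Scope = "all", l_policy: LPolicy = "bridge"
) -> int:
    """Number of adjacent scan pairs with differing codes.

    ``scope="all"`` compares the raw 7-code sequence (the per-phase
    fragmentation statistic); ``scope="network"`` first removes ``L`` slots
    under ``l_policy`` and equals the off-diagonal sum of
    :func:`transition_matrix` for the same policy.
    """
    if len(codes) == 0:
        raise ValueError("transition_count requires a non-empty sequence")
    if scope == "all":
        return sum(a != b for a, b in zip(codes, codes[1:]))
    if scope == "network":
        return sum(a != b for a, b in _network_pairs(codes, l_policy))
    raise ValueError(f"unknown scope {scope!r}")


def occurrence_counts(codes: Sequence[str]) -> dict[str, int]:
    """Scan-sample tally per behavior code; values sum to ``len(codes)``."""
    if len(codes) == 0:
        raise ValueError("occurrence_counts requires a non-empty sequence")
    counts = dict.fromkeys(CODES, 0)
    for c in codes:
        counts[c] += 1
    return counts


def transition_matrix(
    codes: Sequence[str], l_policy: LPolicy = "bridge"
) -> TransitionMatrix:
    """Count directed switches between the 6 network nodes in one sequence.

    L slots are removed first (see module docstring for the two policies);
    each remaining adjacent pair (a, b) with a != b increments ``weights[a, b]``.
    Equal pairs contribute nothing (no self-links).
    """
    if len(codes) == 0:
        raise ValueError("transition_matrix requires a non-empty sequence")
    w = np.zeros((_N_NODES, _N_NODES), dtype=float)
    for a, b in _network_pairs(codes, l_policy):
        if a != b:
            w[_NODE_INDEX[a], _NODE_INDEX[b]] += 1
    return TransitionMatrix(w)


def _node_occurrences(codes: Sequence[str]) -> np.ndarray:
    counts = occurrence_counts(codes)
    return np.array([counts[c] for c in NODE_ORDER], dtype=float)


def phase_aggregate(
    dataset: Dataset, dam_id: str, ppd: int, l_policy: LPolicy = "bridge"
) -> dict[str, tuple[TransitionMatrix, np.ndarray]]:
    """Per-dam LIGHT and DARK transition matrices and node-occurrence vectors.

    The light phase is the element-wise mean of the AM and PM sessions (the
    two light observation periods were statistically indistinguishable and
    are averaged, not concatenated); the dark phase is the single dark
    session's values.

    Raises
    ------
    EthogramError
        If any of the dam's AM/PM/DARK sessions for this day is missing.
    """
    mats: dict[str, TransitionMatrix] = {}
    occs: dict[str, np.ndarray] = {}
    for period in PERIODS:
        session = dataset.session(dam_id, ppd, period)  # raises if missing
        mats[period] = transition_matrix(session.codes, l_policy)
        occs[period] = _node_occurrences(session.codes)
    out: dict[str, tuple[TransitionMatrix, np.ndarray]] = {}
    for phase, periods in PHASE_PERIODS.items():
        weights = np.mean([mats[p].weights for p in periods], axis=0)
        sizes = np.mean([occs[p] for p in periods], axis=0)
        out[phase] = (TransitionMatrix(weights), sizes)
    return out


def build_group_network(
    dataset: Dataset,
    group: str,
    phase: str,
    ppd: int,
    l_policy: LPolicy = "bridge",
) -> BehaviorNetwork:
    """Average per-dam phase-aggregated matrices into one group network.

    Every dam of ``group`` holding at least one session on ``ppd`` must hold
    all three periods (enforced by :func:`phase_aggregate`).  Edge weights
    and node sizes are element-wise means over dams, so they may be
    fractional.
    """
    if phase not in PHASE_PERIODS:
        raise ValueError(f"unknown phase {phase!r}, expected one of {PHASES}")
    dams = [
        d
        for d in dataset.dam_ids(group)
        if any(dataset.has_session(d, ppd, p) for p in PERIODS)
    ]
    if not dams:
        raise EthogramError(f"no {group} dams with sessions on ppd {ppd}")
    per_dam = [phase_aggregate(dataset, d, ppd, l_policy)[phase] for d in dams]
    weights = np.mean([m.weights for m, _ in per_dam], axis=0)
    sizes = np.mean([s for _, s in per_dam], axis=0)
    return BehaviorNetwork(
        edges=TransitionMatrix(weights),
        node_sizes=sizes,
        group=group,
        phase=phase,
        ppd=ppd,
        n_dams=len(dams),
    )
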