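"""Overlap planning and plaid composition.

Overlap between planted triclusters is controlled by four quotas: the
percentage of triclusters allowed to overlap, the maximum number that may
overlap simultaneously (the group size k), the maximum percentage of shared
elements (relative to the smaller tricluster of a pair), and per-dimension
caps on shared rows/columns/contexts.  Values in shared regions combine
under a plaid coherency: additive (sum of contributions), multiplicative
(product), interpoled (average), or none (the last-generated tricluster
wins).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .core import ConfigError, PlaidCoherency


@dataclass(frozen=True)
class OverlapConfig:
    """Overlap quotas and plaid coherency.

    Percentages are in [0, 100].  ``pct_rows``/``pct_cols``/``pct_ctxs``
    default to 100 (a pair may share a whole dimension).
    """

    plaid: PlaidCoherency = PlaidCoherency.NO_OVERLAP
    pct_triclusters: float = 0.0
    max_group_size: int = 0
    pct_elements: float = 0.0
    pct_rows: float = 100.0
    pct_cols: float = 100.0
    pct_ctxs: float = 100.0

    def __post_init__(self) -> None:
        for name in ("pct_triclusters", "pct_elements", "pct_rows", "pct_cols", "pct_ctxs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ConfigError(f"{name} must be in [0, 100], got {v}")
        if self.plaid is not PlaidCoherency.NO_OVERLAP and self.pct_triclusters > 0:
            if self.max_group_size < 2:
                raise ConfigError(
                    "overlapping requested but max_group_size < 2 "
                    f"(got {self.max_group_size})"
                )

    @property
    def active(self) -> bool:
        return (
            self.plaid is not PlaidCoherency.NO_OVERLAP
            and self.pct_triclusters > 0
            and self.pct_elements > 0
        )


@dataclass
class OverlapGroup:
    """A set of triclusters designated to overlap, with its interaction graph."""

    members: list[int]
    edges: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class OverlapPlan:
    """Output of :func:`plan_overlap_groups`: groups plus singletons."""

    groups: list[OverlapGroup]
    singletons: list[int]
    config: OverlapConfig

    def partner_edges(self, tric_id: int) -> list[int]:
        for g in self.groups:
            if tric_id in g.members:
                return [b if a == tric_id else a for a, b in g.edges if tric_id in (a, b)]
        return []

    def group_of(self, tric_id: int) -> OverlapGroup | None:
        for g in self.groups:
            if tric_id in g.members:
                return g
        return None


def _connected(n: int, edges: list[tuple[int, int]]) -> bool:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    return len({find(i) for i in range(n)}) == 1


def _sample_interaction_graph(k: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Connected graph on k nodes: pairwise-only up to fully k-wise regimes.

    Uniform over all connected labeled graphs for k <= 5 (exhaustive
    enumeration is cheap there); larger groups use a random spanning tree
    plus independent extra edges.
    """
    if k <= 1:
        return []
    all_edges = list(itertools.combinations(range(k), 2))
    if k <= 5:
        connected = [
            [all_edges[i] for i in range(len(all_edges)) if mask >> i & 1]
            for mask in range(1 << len(all_edges))
            if _connected(k, [all_edges[i] for i in range(len(all_edges)) if mask >> i & 1])
        ]
        return connected[rng.integers(len(connected))]
    # random spanning tree (each new node attaches to a previous one) + coin-flip extras
    edges = {(int(rng.integers(i)), i) for i in range(1, k)}
    for e in all_edges:
        if e not in edges and rng.random() < 0.5:
            edges.add(e)
    return sorted(edges)


def plan_overlap_groups(
    n_triclusters: int, cfg: OverlapConfig, rng: np.random.Generator
) -> OverlapPlan:
    """Partition tricluster ids into overlap groups and singletons.

    ``floor(n * pct_triclusters)`` triclusters are marked overlapping and
    split into groups of ``max_group_size``; a remainder of one becomes a
    singleton (it cannot overlap alone), a larger remainder forms a smaller
    final group.  Within each group an interaction graph is drawn, ranging
    from pairwise-only to fully k-wise interactions.
    """
    if n_triclusters < 1:
        raise ConfigError("need at least one tricluster")
    ids = list(range(n_triclusters))
    if not cfg.active:
        return OverlapPlan(groups=[], singletons=ids, config=cfg)
    k = cfg.max_group_size
    n_over = math.floor(n_triclusters * cfg.pct_triclusters / 100.0)
    groups: list[OverlapGroup] = []
    pos = 0
    while pos + 2 <= n_over:
        size = min(k, n_over - pos)
        members = ids[pos : pos + size]
        local_edges = _sample_interaction_graph(len(members), rng)
        groups.append(
            OverlapGroup(members, [(members[a], members[b]) for a, b in local_edges])
        )
        pos += size
    singletons = ids[pos:]
    return OverlapPlan(groups=groups, singletons=singletons, config=cfg)


def max_shared_elements(size_a: int, size_b: int, pct_elements: float) -> int:
    """Cell quota a pair may share: ``floor(pct * min(size_a, size_b))``."""
    if size_a < 1 or size_b < 1:
        raise ConfigError("tricluster sizes must be >= 1")
    return math.floor(pct_elements / 100.0 * min(size_a, size_b))


def compose_plaid(
    contributions: list[float], plaid: PlaidCoherency, c: float = 0.0
) -> float:
    """Value of a cell shared by several triclusters.

    ``contributions`` are the per-tricluster clean values in generation
    order.  additive: ``c + sum``; multiplicative: ``c + prod``; interpoled:
    ``c + mean``; none: the last-generated tricluster's value.  The base
    offset ``c`` defaults to 0 (each contribution already carries its own
    seed).
    """
    if not contributions:
        raise ConfigError("compose_plaid needs at least one contribution")
    if plaid in (PlaidCoherency.NONE, PlaidCoherency.NO_OVERLAP):
        return float(contributions[-1])
    if plaid is PlaidCoherency.ADDITIVE:
        return float(c + sum(contributions))
    if plaid is PlaidCoherency.MULTIPLICATIVE:
        return float(c + math.prod(contributions))
    # interpoled: average of the q overlapping contributions
    return float(c + sum(contributions) / len(contributions))
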