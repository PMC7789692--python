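"""Tricluster structure: how many, how big, and where.

Sizes per dimension follow a uniform or normal distribution (rounded
half-to-even and clipped to ``[1, dim]``).  Placement samples each index
subset uniformly; a contiguous dimension (features or contexts, useful for
time series) instead takes a consecutive run whose start is uniform on
``[0, dim - len]``.

Overlap placement follows the overlap plan group by group: the first member
of a group is placed freely, each subsequent member copies a sub-block of an
already-placed partner (sized to the shared-element quota and per-dimension
caps) and samples its remaining indices outside the partner.  Incidental
overlaps between triclusters not designated to overlap are forbidden, so the
ground-truth report labels overlap exactly; infeasible requests degrade
gracefully by placing as many triclusters as possible and warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import ConfigError, TriclusterSpec
from .overlap import OverlapPlan, max_shared_elements


@dataclass(frozen=True)
class SizeDistribution:
    """Per-dimension tricluster size law: uniform(a, b) or normal(mean, stdev)."""

    dist: str
    a: float | None = None
    b: float | None = None
    mean: float | None = None
    stdev: float | None = None

    def __post_init__(self) -> None:
        if self.dist == "uniform":
            if self.a is None or self.b is None or self.a > self.b:
                raise ConfigError("uniform size distribution requires a <= b")
        elif self.dist == "normal":
            if self.mean is None or self.stdev is None or self.stdev < 0:
                raise ConfigError("normal size distribution requires mean and stdev >= 0")
        else:
            raise ConfigError(f"unknown size distribution {self.dist!r}")

    def sample(self, dim: int, rng: np.random.Generator) -> int:
        if self.dist == "uniform":
            if self.a > dim:
                raise ConfigError(
                    f"size distribution U({self.a}, {self.b}) lies outside [1, {dim}]"
                )
            v = rng.integers(int(self.a), int(self.b) + 1)
        else:
            v = np.round(rng.normal(self.mean, self.stdev))  # round half-to-even
        return int(min(max(v, 1), dim))


@dataclass(frozen=True)
class StructureConfig:
    """Number, size laws and contiguity of the planted triclusters."""

    n_triclusters: int
    rows: SizeDistribution
    cols: SizeDistribution
    ctxs: SizeDistribution
    contiguity: str = "none"  # none | features | contexts

    def __post_init__(self) -> None:
        if self.n_triclusters < 0:
            raise ConfigError("n_triclusters must be >= 0")
        if self.contiguity not in ("none", "features", "contexts"):
            raise ConfigError(f"contiguity must be none|features|contexts, got {self.contiguity!r}")


def sample_sizes(
    cfg: StructureConfig, dims: tuple[int, int, int], rng: np.random.Generator
) -> list[tuple[int, int, int]]:
    """One ``(|I|, |J|, |K|)`` triple per requested tricluster."""
    return [
        (
            cfg.rows.sample(dims[0], rng),
            cfg.cols.sample(dims[1], rng),
            cfg.ctxs.sample(dims[2], rng),
        )
        for _ in range(cfg.n_triclusters)
    ]


class PlacementWarning(UserWarning):
    """Fewer triclusters placed than requested."""


@dataclass
class Skeleton:
    """Index sets of a placed tricluster, before pattern synthesis."""

    id: int
    rows: list[int]
    cols: list[int]
    ctxs: list[int]

    @property
    def index_sets(self) -> tuple[list[int], list[int], list[int]]:
        return (self.rows, self.cols, self.ctxs)

    @property
    def volume(self) -> int:
        return len(self.rows) * len(self.cols) * len(self.ctxs)


def cell_overlap(a: Skeleton | TriclusterSpec, b: Skeleton | TriclusterSpec) -> int:
    """Number of cells shared by two blocks (product of per-dim intersections)."""
    pairs = sorted(
        zip((a.rows, a.cols, a.ctxs), (b.rows, b.cols, b.ctxs)),
        key=lambda p: min(len(p[0]), len(p[1])),
    )  # smallest dimension first: cheapest disjointness rejection
    n = 1
    for xa, xb in pairs:
        m = len(set(xa) & set(xb))
        if m == 0:
            return 0
        n *= m
    return n


def _sample_subset(dim: int, size: int, contiguous: bool, rng: np.random.Generator) -> list[int]:
    if contiguous:
        start = int(rng.integers(0, dim - size + 1))  # U(0, dim - len)
        return list(range(start, start + size))
    return sorted(rng.choice(dim, size=size, replace=False).tolist())


def _shared_then_fresh(
    partner: list[int],
    n_shared: int,
    new_len: int,
    dim: int,
    contiguous: bool,
    rng: np.random.Generator,
) -> list[int] | None:
    """Index set of length ``new_len`` sharing exactly ``n_shared`` indices
    with ``partner``; ``None`` if infeasible under contiguity/bounds."""
    if contiguous:
        p0, p1 = partner[0], partner[-1]
        sides = []
        if p1 - n_shared + 1 + new_len - 1 <= dim - 1:  # extend rightward past p1
            sides.append("right")
        if p0 + n_shared - 1 - (new_len - 1) >= 0:  # extend leftward past p0
            sides.append("left")
        if not sides:
            return None
        side = sides[int(rng.integers(len(sides)))]
        start = p1 - n_shared + 1 if side == "right" else p0 + n_shared - new_len
        return list(range(start, start + new_len))
    shared = rng.choice(len(partner), size=n_shared, replace=False)
    shared_idx = [partner[s] for s in shared]
    outside = np.setdiff1d(np.arange(dim), np.asarray(partner, dtype=int))
    if new_len - n_shared > len(outside):
        return None
    fresh = rng.choice(outside, size=new_len - n_shared, replace=False).tolist()
    return sorted(shared_idx + fresh)


def _shared_dim_counts(
    partner_shape: tuple[int, int, int],
    new_shape: tuple[int, int, int],
    quota: int,
    caps: tuple[float, float, float],
    rng: np.random.Generator,
) -> tuple[int, int, int] | None:
    """Per-dimension shared index counts with product in [1, quota]."""
    max_s = [
        math.floor(c / 100.0 * min(p, n))
        for c, p, n in zip(caps, partner_shape, new_shape)
    ]
    if quota < 1 or any(m < 1 for m in max_s):
        return None
    s = [int(rng.integers(1, m + 1)) for m in max_s]
    while s[0] * s[1] * s[2] > quota:
        axis = int(np.argmax(s))
        if s[axis] == 1:  # quota < 1 shared cell cannot happen (quota >= 1)
            break
        s[axis] -= 1
    return tuple(s)


def place_triclusters(
    sizes: list[tuple[int, int, int]],
    dims: tuple[int, int, int],
    contiguity: str,
    overlap_plan: OverlapPlan,
    rng: np.random.Generator,
    max_attempts: int = 10000,
) -> list[Skeleton]:
    """Assign index sets to every tricluster, honoring the overlap plan.

    Returns the maximal placed set (with a :class:`PlacementWarning`) when a
    tricluster cannot be placed within ``max_attempts`` rejection retries.
    """
    for (a, b, c) in sizes:
        if a > dims[0] or b > dims[1] or c > dims[2]:
            raise ConfigError(f"tricluster size {(a, b, c)} exceeds dataset dims {dims}")
    contig = (False, contiguity == "features", contiguity == "contexts")
    cfg = overlap_plan.config
    caps = (cfg.pct_rows, cfg.pct_cols, cfg.pct_ctxs)

    # process singletons and groups in id order; inside a group, BFS order so
    # every member after the first has an already-placed graph neighbor
    order: list[int] = []
    for g in overlap_plan.groups:
        seen = [g.members[0]]
        queue = [g.members[0]]
        while queue:
            cur = queue.pop(0)
            for a, b in g.edges:
                nxt = b if a == cur else a if b == cur else None
                if nxt is not None and nxt not in seen:
                    seen.append(nxt)
                    queue.append(nxt)
        for m in g.members:  # disconnected safety (graphs are connected by construction)
            if m not in seen:
                seen.append(m)
        order.extend(seen)
    order.extend(overlap_plan.singletons)

    placed: dict[int, Skeleton] = {}
    for tid in order:
        shape = sizes[tid]
        group = overlap_plan.group_of(tid)
        partners = [p for p in overlap_plan.partner_edges(tid) if p in placed]
        allowed = set(group.members) - {tid} if group else set()
        ok = None
        for _ in range(max_attempts):
            if partners:
                partner = placed[partners[int(rng.integers(len(partners)))]]
                quota = max_shared_elements(
                    partner.volume, shape[0] * shape[1] * shape[2], cfg.pct_elements
                )
                s = _shared_dim_counts(
                    tuple(len(x) for x in partner.index_sets), shape, quota, caps, rng
                )
                if s is None:
                    partners = []  # quota or caps forbid any overlap: place freely
                    continue
                idx_sets = [
                    _shared_then_fresh(p_idx, s[ax], shape[ax], dims[ax], contig[ax], rng)
                    for ax, p_idx in enumerate(partner.index_sets)
                ]
                if any(x is None for x in idx_sets):
                    continue
            else:
                idx_sets = [
                    _sample_subset(dims[ax], shape[ax], contig[ax], rng) for ax in range(3)
                ]
            cand = Skeleton(tid, *idx_sets)
            if _admissible(cand, placed, allowed, cfg, caps):
                ok = cand
                break
        if ok is None:
            warnings.warn(
                f"could not place tricluster {tid} after {max_attempts} attempts; "
                f"placed {len(placed)} of {len(sizes)}",
                PlacementWarning,
                stacklevel=2,
            )
            continue
        placed[tid] = ok
    return [placed[tid] for tid in sorted(placed)]


def _admissible(
    cand: Skeleton,
    placed: dict[int, Skeleton],
    allowed_partners: set[int],
    cfg,
    caps: tuple[float, float, float],
) -> bool:
    for oid, other in placed.items():
        ov = cell_overlap(cand, other)
        if oid not in allowed_partners:
            if ov != 0:
                return False
            continue
        if ov == 0:
            continue
        if ov > max_shared_elements(cand.volume, other.volume, cfg.pct_elements):
            return False
        for ax, cap in enumerate(caps):
            a, b = cand.index_sets[ax], other.index_sets[ax]
            if len(set(a) & set(b)) > math.floor(cap / 100.0 * min(len(a), len(b))):
                return False
    return True
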