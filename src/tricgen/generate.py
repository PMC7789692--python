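"""End-to-end generation pipeline.

Stages, in order: background fill, structure planning (sizes, overlap
groups, placement), pattern synthesis, stamping (with plaid composition in
overlap regions), and quality injection last — so a run with the same seed
and quality switched off reproduces the clean grid bit-identically.
"""

from __future__ import annotations

import warnings as _warnings
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .background import generate_background
from .config import GeneratorConfig
from .core import (
    Dataset,
    Pattern,
    PatternTriple,
    PlaidCoherency,
    TemporalProfile,
    TriclusterSpec,
)
from .overlap import OverlapPlan, compose_plaid, plan_overlap_groups
from .patterns import build_numeric, build_order_preserving, build_symbolic
from .quality import inject_quality
from .report import SolutionReport, build_report
from .structure import PlacementWarning, place_triclusters, sample_sizes


@dataclass
class GenerationResult:
    dataset: Dataset
    report: SolutionReport
    plan: OverlapPlan
    warnings: list[str] = field(default_factory=list)


_AXIS_NAME = {0: "rows", 1: "cols", 2: "ctxs"}


def _index_of(sorted_list: list[int], value: int) -> int | None:
    pos = bisect_left(sorted_list, value)
    if pos < len(sorted_list) and sorted_list[pos] == value:
        return pos
    return None


def generate(config: GeneratorConfig, seed: int | None = None) -> GenerationResult:
    """Generate a dataset and its ground-truth solution from ``config``.

    ``seed`` overrides ``config.seed``; identical (config, seed) pairs yield
    bit-identical datasets and reports.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    alphabet = config.build_alphabet()
    background = config.build_background()
    overlap_cfg = config.build_overlap()
    structure = config.build_structure()
    quality = config.build_quality()
    pool = config.pattern_pool()
    profile = config.temporal_profile()
    dims = config.dataset.dims

    grid = generate_background(dims, alphabet, background, rng)

    messages: list[str] = []
    sizes = sample_sizes(structure, dims, rng)
    if structure.n_triclusters == 0:
        plan = OverlapPlan(groups=[], singletons=[], config=overlap_cfg)
    else:
        plan = plan_overlap_groups(structure.n_triclusters, overlap_cfg, rng)
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always", PlacementWarning)
        skeletons = place_triclusters(sizes, dims, structure.contiguity, plan, rng)
    for w in caught:
        messages.append(str(w.message))
        _warnings.warn(w.message, PlacementWarning, stacklevel=2)

    plaid = overlap_cfg.plaid
    trics: list[TriclusterSpec] = []
    for sk in skeletons:
        triple: PatternTriple = pool[int(rng.integers(len(pool)))]
        shape = (len(sk.rows), len(sk.cols), len(sk.ctxs))
        t = TriclusterSpec(
            id=sk.id, rows=sk.rows, cols=sk.cols, ctxs=sk.ctxs, triple=triple, plaid=plaid
        )
        if triple.is_order_preserving:
            axis = triple.op_axis
            prof = profile if axis == 2 else TemporalProfile.NA
            t.triple = PatternTriple(triple.row, triple.col, triple.ctx, prof)
            t.values, t.permutation = build_order_preserving(
                shape, _AXIS_NAME[axis], prof, alphabet, rng, background
            )
        elif alphabet.kind == "symbolic":
            t.template, t.context_seeds = build_symbolic(triple, shape, alphabet, rng)
        else:
            t.seed, t.row_factors, t.col_factors, t.ctx_factors = build_numeric(
                triple, shape, alphabet, rng
            )
        trics.append(t)

    _stamp(grid, trics, alphabet, plaid)

    dataset = Dataset(
        alphabet=alphabet, values=grid, triclusters=trics, background=background
    )
    inject_quality(dataset, quality, rng)
    report = build_report(dataset, plan)
    return GenerationResult(dataset=dataset, report=report, plan=plan, warnings=messages)


def _stamp(
    grid: np.ndarray,
    trics: list[TriclusterSpec],
    alphabet,
    plaid: PlaidCoherency,
) -> None:
    """Write clean tricluster blocks into the grid, composing overlaps."""
    from .core import reconstruct_block

    counts = np.zeros(grid.shape, dtype=np.int16)
    for t in trics:
        ix = np.ix_(t.rows, t.cols, t.ctxs)
        grid[ix] = reconstruct_block(t)  # id order: last stamped wins (plaid "none")
        counts[ix] += 1
    if plaid in (PlaidCoherency.NONE, PlaidCoherency.NO_OVERLAP):
        return
    shared = np.argwhere(counts >= 2)
    if len(shared) == 0:
        return
    blocks = {t.id: reconstruct_block(t) for t in trics}
    for i, j, k in shared:
        contributions = []
        for t in trics:
            li = _index_of(t.rows, int(i))
            lj = _index_of(t.cols, int(j)) if li is not None else None
            lk = _index_of(t.ctxs, int(k)) if lj is not None else None
            if lk is not None:
                contributions.append(float(blocks[t.id][li, lj, lk]))
        v = compose_plaid(contributions, plaid)
        if alphabet.kind == "integer":
            v = float(np.rint(v))
        grid[i, j, k] = min(max(v, alphabet.lo), alphabet.hi)
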