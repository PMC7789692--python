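"""Core domain model for three-way datasets with planted triclusters.

A three-way dataset relates ``n_obs`` observations x ``n_feat`` features x
``n_ctx`` contexts (contexts are typically time points, as in gene-sample-time
expression data or patient-feature-time clinical records).  A *tricluster* is a
subspace ``(I, J, K)`` of that grid whose cells satisfy a coherence model:
constant, additive (``c + alpha_i + beta_j + gamma_k``), multiplicative
(``c * alpha_i * beta_j * gamma_k``), or order-preserving (a shared linear
ordering along one dimension).

Values are stored in a single ``float64`` grid for every dataset type: numeric
datasets store the values themselves, symbolic datasets store 0-based *ranks*
into the alphabet's ordered symbol list.  ``NaN`` encodes the MISSING sentinel
inside the grid; the public API exposes :data:`MISSING` instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np


class _Missing:
    """Sentinel for absent cells, distinct from every alphabet value."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"


#: The missing-value sentinel.  Serialized as an empty TSV field.
MISSING = _Missing()


class Pattern(str, Enum):
    """Per-dimension coherence pattern."""

    ORDER_PRESERVING = "order_preserving"
    CONSTANT = "constant"
    ADDITIVE = "additive"
    MULTIPLICATIVE = "multiplicative"
    NONE = "none"


class TemporalProfile(str, Enum):
    """Ordering profile for an order-preserving context dimension."""

    INCREASING = "increasing"
    DECREASING = "decreasing"
    RANDOM = "random"
    NA = "n/a"


class PlaidCoherency(str, Enum):
    """How overlapping tricluster contributions combine in shared cells."""

    ADDITIVE = "additive"
    MULTIPLICATIVE = "multiplicative"
    INTERPOLED = "interpoled"
    NONE = "none"
    NO_OVERLAP = "no_overlap"


class ConfigError(ValueError):
    """An inadmissible generator configuration."""


@dataclass(frozen=True)
class Alphabet:
    """Admissible value set of a dataset.

    ``kind`` is one of ``symbolic``, ``integer``, ``real``.  For symbolic
    alphabets the order of ``symbols`` defines the total order used by
    order-preserving patterns and by rank distance in quality injection.
    """

    kind: str
    symbols: tuple[str, ...] | None = None
    min_value: float | None = None
    max_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "symbolic":
            if not self.symbols:
                raise ConfigError("symbolic alphabet requires a non-empty symbol list")
            if len(set(self.symbols)) != len(self.symbols):
                raise ConfigError("alphabet symbols must be unique")
        elif self.kind in ("integer", "real"):
            if self.min_value is None or self.max_value is None:
                raise ConfigError("numeric alphabet requires min_value and max_value")
            if not self.min_value < self.max_value:
                raise ConfigError("numeric alphabet requires min_value < max_value")
            if self.kind == "integer" and (
                self.min_value != int(self.min_value) or self.max_value != int(self.max_value)
            ):
                raise ConfigError("integer alphabet bounds must be integers")
        else:
            raise ConfigError(f"unknown alphabet kind {self.kind!r}")

    # -- internal (rank/value) representation helpers ------------------------

    @property
    def is_numeric(self) -> bool:
        return self.kind in ("integer", "real")

    @property
    def n_symbols(self) -> int:
        """Number of discrete elements (symbolic and integer alphabets)."""
        if self.kind == "symbolic":
            return len(self.symbols)
        if self.kind == "integer":
            return int(self.max_value) - int(self.min_value) + 1
        raise ConfigError("a real-valued alphabet has no discrete element count")

    @property
    def lo(self) -> float:
        """Lower bound in internal units (rank 0 for symbolic)."""
        return 0.0 if self.kind == "symbolic" else float(self.min_value)

    @property
    def hi(self) -> float:
        """Upper bound in internal units (rank n-1 for symbolic)."""
        if self.kind == "symbolic":
            return float(len(self.symbols) - 1)
        return float(self.max_value)

    def rank(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def symbol(self, rank: int | float) -> str:
        return self.symbols[int(rank)]

    def contains(self, internal_value: float) -> bool:
        """Whether an internal-representation value lies in the alphabet."""
        if math.isnan(internal_value):
            return False
        if self.kind == "real":
            return self.lo <= internal_value <= self.hi
        return (
            self.lo <= internal_value <= self.hi
            and internal_value == int(internal_value)
        )

    def to_external(self, internal_value: float):
        """Internal grid value -> user-facing value (symbol / int / float)."""
        if math.isnan(internal_value):
            return MISSING
        if self.kind == "symbolic":
            return self.symbols[int(internal_value)]
        if self.kind == "integer":
            return int(internal_value)
        return float(internal_value)


@dataclass(frozen=True)
class BackgroundSpec:
    """Distribution filling cells outside every tricluster.

    ``family`` is one of ``uniform``, ``normal``, ``discrete``, ``missing``.
    ``mean``/``stdev`` apply to ``normal`` (in value units for numeric
    alphabets, rank units for symbolic); ``probabilities`` applies to
    ``discrete`` (one weight per alphabet element, in order).
    """

    family: str
    mean: float | None = None
    stdev: float | None = None
    probabilities: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "normal", "discrete", "missing"):
            raise ConfigError(f"unknown background family {self.family!r}")
        if self.family == "normal":
            if self.mean is None or self.stdev is None or self.stdev < 0:
                raise ConfigError("normal background requires mean and stdev >= 0")
        if self.family == "discrete":
            if not self.probabilities:
                raise ConfigError("discrete background requires probabilities")
            if abs(sum(self.probabilities) - 1.0) > 1e-9:
                raise ConfigError("discrete probabilities must sum to 1")
            if any(p < 0 for p in self.probabilities):
                raise ConfigError("discrete probabilities must be non-negative")

    def validate_for(self, alphabet: Alphabet) -> None:
        if self.family == "discrete":
            if alphabet.kind == "real":
                raise ConfigError("discrete background is invalid for a real-valued alphabet")
            if len(self.probabilities) != alphabet.n_symbols:
                raise ConfigError(
                    "discrete background needs one probability per alphabet element "
                    f"({alphabet.n_symbols}), got {len(self.probabilities)}"
                )


@dataclass(frozen=True)
class PatternTriple:
    """(row, column, context) coherence assignment of one tricluster."""

    row: Pattern
    col: Pattern
    ctx: Pattern
    temporal_profile: TemporalProfile = TemporalProfile.NA

    @property
    def patterns(self) -> tuple[Pattern, Pattern, Pattern]:
        return (self.row, self.col, self.ctx)

    @property
    def is_order_preserving(self) -> bool:
        return Pattern.ORDER_PRESERVING in self.patterns

    @property
    def op_axis(self) -> int | None:
        """Axis index (0=rows, 1=cols, 2=ctxs) carrying the ordering, if any."""
        for axis, p in enumerate(self.patterns):
            if p is Pattern.ORDER_PRESERVING:
                return axis
        return None

    @property
    def model(self) -> str:
        """Coherence family: order_preserving | additive | multiplicative |
        constant (numeric Eq. families) or symbolic template logic."""
        if self.is_order_preserving:
            return "order_preserving"
        if Pattern.ADDITIVE in self.patterns:
            return "additive"
        if Pattern.MULTIPLICATIVE in self.patterns:
            return "multiplicative"
        return "constant"

    def __str__(self) -> str:
        s = f"({self.row.value}, {self.col.value}, {self.ctx.value})"
        if self.temporal_profile is not TemporalProfile.NA:
            s += f" [{self.temporal_profile.value}]"
        return s


@dataclass
class TriclusterSpec:
    """A planted tricluster: location, pattern triple and compact value model.

    Numeric non-order-preserving triclusters carry a seed ``c`` plus one factor
    per row/column/context (additive factors default to 0 on constant
    dimensions, multiplicative to 1).  Symbolic triclusters carry a template
    seed matrix (repeated across contexts) or one seed per context.
    Order-preserving triclusters store their values explicitly together with
    the shared ordering permutation, because the seed+factor form cannot
    express them.  All stored values use the internal representation (ranks
    for symbolic alphabets).
    """

    id: int
    rows: list[int]
    cols: list[int]
    ctxs: list[int]
    triple: PatternTriple
    seed: float | None = None
    row_factors: np.ndarray | None = None
    col_factors: np.ndarray | None = None
    ctx_factors: np.ndarray | None = None
    template: np.ndarray | None = None          # |I| x |J|, symbolic ranks
    context_seeds: list[np.ndarray] | None = None  # |K| matrices, symbolic ranks
    values: np.ndarray | None = None            # |I|x|J|x|K| explicit block (OP)
    permutation: np.ndarray | None = None       # ordering permutation (OP)
    plaid: PlaidCoherency = PlaidCoherency.NO_OVERLAP
    quality_counts: tuple[int, int, int] = (0, 0, 0)  # (missing, noise, error)

    def __post_init__(self) -> None:
        for name, idx in (("rows", self.rows), ("cols", self.cols), ("ctxs", self.ctxs)):
            if len(idx) < 1:
                raise ConfigError(f"tricluster {self.id}: empty {name} index set")
            if sorted(set(idx)) != list(idx):
                raise ConfigError(f"tricluster {self.id}: {name} must be sorted and duplicate-free")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.rows), len(self.cols), len(self.ctxs))

    @property
    def volume(self) -> int:
        a, b, c = self.shape
        return a * b * c

    def cells(self) -> Iterable[tuple[int, int, int]]:
        """Global (i, j, k) cells of the block, in row-major local order."""
        for i in self.rows:
            for j in self.cols:
                for k in self.ctxs:
                    yield (i, j, k)


class UnsupportedReconstructionError(TypeError):
    """Raised when asking the compact model for an order-preserving cell."""


def reconstruct_cell(t: TriclusterSpec, i: int, j: int, k: int) -> float:
    """Clean (pre-quality) internal value of local cell ``(i, j, k)`` of ``t``.

    Additive model: ``c + alpha_i + beta_j + gamma_k``; multiplicative:
    ``c * alpha_i * beta_j * gamma_k``; symbolic: template / context-seed
    lookup (returns the rank).  Order-preserving triclusters store values
    explicitly and are rejected here.
    """
    ni, nj, nk = t.shape
    if not (0 <= i < ni and 0 <= j < nj and 0 <= k < nk):
        raise IndexError(f"local index ({i}, {j}, {k}) out of range for shape {t.shape}")
    if t.triple.is_order_preserving:
        raise UnsupportedReconstructionError(
            "order-preserving triclusters store explicit values; use t.values"
        )
    if t.template is not None or t.context_seeds is not None:
        if t.context_seeds is not None:
            return float(t.context_seeds[k][i, j])
        return float(t.template[i, j])
    model = t.triple.model
    if model == "multiplicative":
        return float(t.seed * t.row_factors[i] * t.col_factors[j] * t.ctx_factors[k])
    # additive; the constant model is its all-zero-factor limit
    return float(t.seed + t.row_factors[i] + t.col_factors[j] + t.ctx_factors[k])


def reconstruct_block(t: TriclusterSpec) -> np.ndarray:
    """Whole clean block of ``t`` as a ``|I| x |J| x |K|`` array."""
    if t.values is not None:
        return t.values
    ni, nj, nk = t.shape
    if t.context_seeds is not None:
        return np.stack([s for s in t.context_seeds], axis=2).astype(float)
    if t.template is not None:
        return np.repeat(t.template[:, :, None].astype(float), nk, axis=2)
    if t.triple.model == "multiplicative":
        return (
            t.seed
            * t.row_factors[:, None, None]
            * t.col_factors[None, :, None]
            * t.ctx_factors[None, None, :]
        )
    return (
        t.seed
        + t.row_factors[:, None, None]
        + t.col_factors[None, :, None]
        + t.ctx_factors[None, None, :]
    )


def covered_cells(ts: Sequence[TriclusterSpec]) -> set[tuple[int, int, int]]:
    """Union of the Cartesian products I x J x K over all triclusters."""
    out: set[tuple[int, int, int]] = set()
    for t in ts:
        out.update(t.cells())
    return out


@dataclass
class Dataset:
    """A generated three-way dataset with its planted triclusters.

    ``values`` is a ``(n_obs, n_feat, n_ctx)`` float grid in internal
    representation (NaN = missing).  Quality bookkeeping records the flat
    indices of every degraded cell by category.
    """

    alphabet: Alphabet
    values: np.ndarray
    triclusters: list[TriclusterSpec] = field(default_factory=list)
    background: BackgroundSpec | None = None
    missing_cells: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    noise_cells: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    error_cells: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def value(self, i: int, j: int, k: int):
        """User-facing value at ``(i, j, k)`` (symbol, number, or MISSING)."""
        return self.alphabet.to_external(self.values[i, j, k])

    def is_missing(self, i: int, j: int, k: int) -> bool:
        return bool(np.isnan(self.values[i, j, k]))

    def coverage(self) -> float:
        """Fraction of dataset cells belonging to >= 1 tricluster."""
        return len(covered_cells(self.triclusters)) / self.n_cells
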