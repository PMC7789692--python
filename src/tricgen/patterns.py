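"""Pattern admissibility and per-tricluster value synthesis.

A tricluster's coherence is declared by a triple ``(P_row, P_col, P_ctx)``
drawn from {order_preserving, constant, additive, multiplicative, none}.
Admissibility rules:

* order_preserving may occupy exactly one dimension; the other two must be
  none (only the ordering is planted, no further coherence);
* constant combines only with itself, additive, or multiplicative;
* additive and multiplicative never combine (they map to different models);
* none appears only in order-preserving or constant triples;
* symbolic datasets reject additive and multiplicative entirely.

This accepts 24 triples for numeric datasets and 10 for symbolic ones.

Synthesis guarantees that every clean value of the built block lies inside
the alphabet: seeds and factors are sampled, the block's min/max is checked
by direct evaluation, and factor amplitudes are shrunk on violation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .background import sample_values
from .core import (
    Alphabet,
    BackgroundSpec,
    ConfigError,
    Pattern,
    PatternTriple,
    TemporalProfile,
)

_NUMERIC_TYPES = ("real", "integer")


@dataclass(frozen=True)
class TripleViolation:
    """Structured description of a broken admissibility rule."""

    rule: str
    detail: str

    def __bool__(self) -> bool:  # a violation is falsy as an "ok" flag
        return False


def validate_triple(triple: PatternTriple, dataset_type: str) -> TripleViolation | None:
    """Return ``None`` if the triple is admissible, else the broken rule.

    ``dataset_type`` is one of ``symbolic``, ``integer``, ``real``.  Pure and
    total: inadmissibility is reported, never raised.
    """
    ps = triple.patterns
    n_op = sum(p is Pattern.ORDER_PRESERVING for p in ps)
    has_add = Pattern.ADDITIVE in ps
    has_mul = Pattern.MULTIPLICATIVE in ps
    has_none = Pattern.NONE in ps

    if n_op > 1:
        return TripleViolation(
            "single-order-preserving-dimension",
            "order_preserving may be assigned to one dimension only",
        )
    if n_op == 1:
        if any(p not in (Pattern.ORDER_PRESERVING, Pattern.NONE) for p in ps):
            return TripleViolation(
                "order-preserving-others-none",
                "the two non-ordered dimensions of an order-preserving triple must be none",
            )
        return None
    if has_add and has_mul:
        return TripleViolation(
            "additive-multiplicative-exclusive",
            "additive and multiplicative patterns cannot be combined",
        )
    if (has_add or has_mul) and dataset_type == "symbolic":
        return TripleViolation(
            "symbolic-no-arithmetic-patterns",
            "symbolic datasets admit no additive/multiplicative patterns",
        )
    if has_none and (has_add or has_mul):
        return TripleViolation(
            "none-only-with-op-or-constant",
            "none combines only with order-preserving or constant patterns",
        )
    if all(p is Pattern.NONE for p in ps):
        return TripleViolation(
            "at-least-one-coherent-dimension",
            "a tricluster needs coherence on at least one dimension",
        )
    return None


def admissible_triples(dataset_type: str) -> list[PatternTriple]:
    """All admissible triples for a dataset type, in a fixed canonical order."""
    out = []
    for row, col, ctx in itertools.product(Pattern, repeat=3):
        t = PatternTriple(row, col, ctx)
        if validate_triple(t, dataset_type) is None:
            out.append(t)
    return out


def triples_for_families(dataset_type: str, families: list[str]) -> list[PatternTriple]:
    """Admissible triples whose coherence family is in ``families``.

    Families are the four coherence types: ``constant``, ``additive``,
    ``multiplicative``, ``order_preserving``.
    """
    fams = set(families)
    unknown = fams - {"constant", "additive", "multiplicative", "order_preserving"}
    if unknown:
        raise ConfigError(f"unknown pattern families: {sorted(unknown)}")
    picked = [t for t in admissible_triples(dataset_type) if t.model in fams]
    if not picked:
        raise ConfigError(
            f"no admissible {dataset_type} triple in families {sorted(fams)}"
        )
    return picked


# ---------------------------------------------------------------------------
# numeric synthesis
# ---------------------------------------------------------------------------


def _sample_seed(alphabet: Alphabet, rng: np.random.Generator, nonzero: bool) -> float:
    """Seed c ~ uniform over the middle half of the alphabet range."""
    span = alphabet.hi - alphabet.lo
    lo, hi = alphabet.lo + span / 4.0, alphabet.hi - span / 4.0
    if alphabet.kind == "integer" and np.ceil(lo) > np.floor(hi):
        lo, hi = alphabet.lo, alphabet.hi  # middle half holds no integer
    for _ in range(100):
        if alphabet.kind == "integer":
            c = float(rng.integers(int(np.ceil(lo)), int(np.floor(hi)) + 1))
        else:
            c = float(rng.uniform(lo, hi))
        if not nonzero or c != 0.0:
            return c
    # degenerate middle half {0}: fall back to an extreme for a usable sign
    return float(alphabet.hi) if abs(alphabet.hi) >= abs(alphabet.lo) else float(alphabet.lo)


def _block_extrema_additive(c, fs):
    lo = c + sum(f.min() for f in fs)
    hi = c + sum(f.max() for f in fs)
    return lo, hi


def _block_extrema_multiplicative(c, fs):
    block = c * fs[0][:, None, None] * fs[1][None, :, None] * fs[2][None, None, :]
    return float(block.min()), float(block.max())


def build_numeric(
    triple: PatternTriple,
    dims: tuple[int, int, int],
    alphabet: Alphabet,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Sample ``(c, alpha, beta, gamma)`` realizing ``triple`` on ``dims``.

    Constant dimensions get all-0 (additive model) or all-1 (multiplicative)
    factors.  The block's min/max is evaluated directly and the factor
    amplitudes halved until every cell is inside the alphabet; if no
    non-degenerate assignment fits, all factors collapse to the constant
    model (the additive/multiplicative limit).
    """
    if alphabet.kind not in _NUMERIC_TYPES:
        raise ConfigError("build_numeric requires a numeric alphabet")
    v = validate_triple(triple, alphabet.kind)
    if v is not None:
        raise ConfigError(f"inadmissible triple {triple}: {v.detail}")
    if triple.is_order_preserving:
        raise ConfigError("order-preserving triclusters store explicit values")

    model = triple.model
    multiplicative = model == "multiplicative"
    c = _sample_seed(alphabet, rng, nonzero=multiplicative)
    span = alphabet.hi - alphabet.lo
    integer = alphabet.kind == "integer"

    factors: list[np.ndarray] = []
    if multiplicative:
        bound = alphabet.hi if c > 0 else -alphabet.lo  # |values| may grow to this
        r = max(1.0, (bound / abs(c)) ** (1.0 / 3.0))
        for pat, n in zip(triple.patterns, dims):
            if pat is Pattern.MULTIPLICATIVE:
                if integer:
                    f = rng.integers(1, max(1, int(np.floor(r))) + 1, size=n).astype(float)
                else:
                    f = rng.uniform(1.0, r, size=n)
            else:  # constant dimension
                f = np.ones(n)
            factors.append(f)
        neutral = np.ones
        extrema = _block_extrema_multiplicative
    else:
        amp = span / (2.0 * max(dims))
        for pat, n in zip(triple.patterns, dims):
            if pat is Pattern.ADDITIVE:
                if integer:
                    a = int(np.floor(amp))
                    f = rng.integers(-a, a + 1, size=n).astype(float) if a >= 1 else np.zeros(n)
                else:
                    f = rng.uniform(-amp, amp, size=n)
            else:  # constant dimension
                f = np.zeros(n)
            factors.append(f)
        neutral = np.zeros
        extrema = _block_extrema_additive

    for _ in range(64):
        lo, hi = extrema(c, factors)
        if lo >= alphabet.lo - 1e-9 and hi <= alphabet.hi + 1e-9:
            break
        # shrink toward the neutral factor
        if multiplicative:
            factors = [1.0 + (f - 1.0) / 2.0 for f in factors]
        else:
            factors = [f / 2.0 for f in factors]
        if integer:
            factors = [np.rint(f) for f in factors]
    else:  # pragma: no cover - the constant limit always fits
        factors = [neutral(n) for n in dims]
    lo, hi = extrema(c, factors)
    if lo < alphabet.lo - 1e-9 or hi > alphabet.hi + 1e-9:
        # alphabet too narrow for any non-degenerate assignment
        factors = [neutral(n) for n in dims]
    return c, factors[0], factors[1], factors[2]


# ---------------------------------------------------------------------------
# symbolic synthesis
# ---------------------------------------------------------------------------


def build_symbolic(
    triple: PatternTriple,
    dims: tuple[int, int, int],
    alphabet: Alphabet,
    rng: np.random.Generator,
) -> tuple[np.ndarray | None, list[np.ndarray] | None]:
    """Template seed and/or per-context seeds (rank matrices) for ``triple``.

    A constant context pattern repeats one ``|I| x |J|`` template across
    contexts; a none context pattern draws an independent seed per context.
    Inside a seed, a constant dimension repeats one symbol along it and a
    none dimension is filled with independent draws.
    """
    if alphabet.kind != "symbolic":
        raise ConfigError("build_symbolic requires a symbolic alphabet")
    v = validate_triple(triple, "symbolic")
    if v is not None:
        raise ConfigError(f"inadmissible triple {triple}: {v.detail}")
    if triple.is_order_preserving:
        raise ConfigError("order-preserving triclusters store explicit values")

    ni, nj, nk = dims
    n_sym = alphabet.n_symbols

    def one_seed() -> np.ndarray:
        if triple.row is Pattern.CONSTANT and triple.col is Pattern.CONSTANT:
            return np.full((ni, nj), float(rng.integers(n_sym)))
        if triple.row is Pattern.CONSTANT:  # constant down rows: one symbol per column
            return np.tile(rng.integers(n_sym, size=nj).astype(float), (ni, 1))
        if triple.col is Pattern.CONSTANT:  # constant along columns: one symbol per row
            return np.tile(rng.integers(n_sym, size=ni).astype(float)[:, None], (1, nj))
        return rng.integers(n_sym, size=(ni, nj)).astype(float)  # (none, none, constant)

    if triple.ctx is Pattern.CONSTANT:
        return one_seed(), None
    return None, [one_seed() for _ in range(nk)]


# ---------------------------------------------------------------------------
# order-preserving synthesis
# ---------------------------------------------------------------------------

_AXIS_NAMES = {"rows": 0, "cols": 1, "ctxs": 2}


def build_order_preserving(
    dims: tuple[int, int, int],
    op_dimension: str,
    temporal_profile: TemporalProfile,
    alphabet: Alphabet,
    rng: np.random.Generator,
    background: BackgroundSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Explicit value block plus the shared ordering permutation ``pi``.

    One permutation of the order-preserving dimension is drawn for the whole
    block; every fiber along that dimension, read in ``pi`` order, is
    non-decreasing (ties allowed).  The ordering is maintained across the
    other two dimensions.  For an ordered context dimension the temporal
    profile fixes ``pi``: increasing -> identity, decreasing -> reversal,
    random -> uniform permutation.  Fiber values are drawn from the
    background distribution restricted to the alphabet (uniform if the
    background is the null/missing family).
    """
    if op_dimension not in _AXIS_NAMES:
        raise ConfigError(f"op_dimension must be rows|cols|ctxs, got {op_dimension!r}")
    axis = _AXIS_NAMES[op_dimension]
    n_op = dims[axis]

    if op_dimension == "ctxs" and temporal_profile is TemporalProfile.INCREASING:
        pi = np.arange(n_op)
    elif op_dimension == "ctxs" and temporal_profile is TemporalProfile.DECREASING:
        pi = np.arange(n_op)[::-1].copy()
    else:
        pi = rng.permutation(n_op)

    if background is None or background.family == "missing":
        background = BackgroundSpec(family="uniform")
    draws = sample_values(int(np.prod(dims)), alphabet, background, rng).reshape(dims)
    # sort each fiber along the OP axis, then scatter into pi order:
    # value at position pi[t] is the t-th smallest of its fiber.
    ordered = np.sort(draws, axis=axis)
    block = np.empty_like(ordered)
    idx: list = [slice(None)] * 3
    src: list = [slice(None)] * 3
    for t in range(n_op):
        idx[axis] = int(pi[t])
        src[axis] = t
        block[tuple(idx)] = ordered[tuple(src)]
    return block, pi
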