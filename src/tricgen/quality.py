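"""Quality degradation: missing values, noise, and errors.

Background cells (outside every tricluster) receive *exact* counts —
``floor(|B| * pct)`` per category — while each tricluster receives a count
drawn uniformly from ``[0, floor(|t| * pct_max)]``, so planted structures
vary in how degraded they are.  Noise moves a value by at most the noise
deviation ``N_deviation`` (absolute difference for numeric alphabets, rank
distance for symbolic); an error moves it strictly farther.  Within one run
the three target cell sets are disjoint, so every degraded cell has a single
well-defined label in the solution report.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import Alphabet, BackgroundSpec, ConfigError, Dataset, TriclusterSpec


@dataclass(frozen=True)
class QualityConfig:
    """Degradation percentages (exact for the background, maxima for
    triclusters) and the noise/error boundary ``noise_deviation``."""

    missing_background: float = 0.0
    noise_background: float = 0.0
    error_background: float = 0.0
    missing_triclusters: float = 0.0
    noise_triclusters: float = 0.0
    error_triclusters: float = 0.0
    noise_deviation: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "missing_background", "noise_background", "error_background",
            "missing_triclusters", "noise_triclusters", "error_triclusters",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ConfigError(f"{name} must be in [0, 100], got {v}")
        bg = self.missing_background + self.noise_background + self.error_background
        tr = self.missing_triclusters + self.noise_triclusters + self.error_triclusters
        if bg > 100.0 or tr > 100.0:
            raise ConfigError("missing + noise + error percentages exceed 100% for one scope")
        if self.noise_deviation < 0:
            raise ConfigError("noise_deviation must be >= 0")

    def validate_for(self, alphabet: Alphabet, background: BackgroundSpec) -> None:
        if alphabet.kind in ("integer", "symbolic"):
            if self.noise_deviation != int(self.noise_deviation):
                raise ConfigError(
                    "noise_deviation must be an integer for integer/symbolic alphabets"
                )
        if background.family == "missing" and (
            self.noise_background > 0 or self.error_background > 0
        ):
            raise ConfigError(
                "noise/error on a fully-missing background is undefined"
            )


class QualityWarning(UserWarning):
    """A degradation could not be applied (e.g. no admissible replacement)."""


# ---------------------------------------------------------------------------
# single-value perturbations
# ---------------------------------------------------------------------------


def perturb_noise(
    value: float, alphabet: Alphabet, n_deviation: float, rng: np.random.Generator
) -> float:
    """Replace ``value`` by a different one at distance <= ``n_deviation``.

    Distance is the absolute difference for numeric alphabets and the rank
    distance for symbolic ones (``value`` is a rank there).  The replacement
    is uniform over the admissible set; if the set is empty the value is
    returned unchanged with a warning.
    """
    if math.isnan(value):
        return value
    if alphabet.kind == "real":
        lo = max(alphabet.lo, value - n_deviation)
        hi = min(alphabet.hi, value + n_deviation)
        if hi <= lo or n_deviation <= 0:
            warnings.warn("no admissible noisy replacement", QualityWarning, stacklevel=2)
            return value
        for _ in range(100):
            v = float(rng.uniform(lo, hi))
            if v != value:
                return v
        return value  # pragma: no cover - zero-probability fallthrough
    dmax = int(n_deviation)
    cands = [
        value + d
        for d in range(-dmax, dmax + 1)
        if d != 0 and alphabet.lo <= value + d <= alphabet.hi
    ]
    if not cands:
        warnings.warn("no admissible noisy replacement", QualityWarning, stacklevel=2)
        return value
    return float(cands[int(rng.integers(len(cands)))])


def _expected_background_value(alphabet: Alphabet, background: BackgroundSpec) -> float:
    """Expected value of the background law, in internal units."""
    if background.family == "normal":
        return float(np.clip(background.mean, alphabet.lo, alphabet.hi))
    if background.family == "discrete":
        elems = np.arange(int(alphabet.lo), int(alphabet.hi) + 1, dtype=float)
        return float(np.dot(elems, np.asarray(background.probabilities)))
    return (alphabet.lo + alphabet.hi) / 2.0  # uniform / missing: midpoint


def make_error(
    value: float,
    alphabet: Alphabet,
    n_deviation: float,
    scope: str,
    background: BackgroundSpec | None,
    rng: np.random.Generator,
) -> float:
    """Replace ``value`` by an error (deviation beyond the noise boundary).

    Background scope: the alphabet extreme (min or max) farther from the
    background distribution's expected value.  Tricluster scope: a uniform
    draw from the in-alphabet values at distance > ``n_deviation`` from the
    original; if that set is empty, the alphabet extreme farther from it.
    """
    if math.isnan(value):
        return value
    if scope == "background":
        if background is None:
            raise ConfigError("background scope requires the background spec")
        mu = _expected_background_value(alphabet, background)
        # tie broken toward the maximum
        return alphabet.lo if abs(alphabet.lo - mu) > abs(alphabet.hi - mu) else alphabet.hi
    if scope != "tricluster":
        raise ConfigError(f"scope must be background|tricluster, got {scope!r}")
    if alphabet.kind == "real":
        left = max(0.0, (value - n_deviation) - alphabet.lo)
        right = max(0.0, alphabet.hi - (value + n_deviation))
        if left <= 0 and right <= 0:
            return alphabet.lo if abs(alphabet.lo - value) > abs(alphabet.hi - value) else alphabet.hi
        if rng.uniform(0, left + right) < left:
            return float(rng.uniform(alphabet.lo, value - n_deviation))
        return float(rng.uniform(value + n_deviation, alphabet.hi))
    dmax = int(n_deviation)
    cands = [
        v
        for v in np.arange(alphabet.lo, alphabet.hi + 1)
        if abs(v - value) > dmax
    ]
    if not cands:
        return alphabet.lo if abs(alphabet.lo - value) > abs(alphabet.hi - value) else alphabet.hi
    return float(cands[int(rng.integers(len(cands)))])


# ---------------------------------------------------------------------------
# dataset-level injection
# ---------------------------------------------------------------------------


def _apply(
    dataset: Dataset,
    flat_cells: np.ndarray,
    kind: str,
    cfg: QualityConfig,
    rng: np.random.Generator,
    scope: str,
) -> None:
    vals = dataset.values.reshape(-1)
    for c in flat_cells:
        if kind == "missing":
            vals[c] = np.nan
        elif kind == "noise":
            vals[c] = perturb_noise(vals[c], dataset.alphabet, cfg.noise_deviation, rng)
        else:
            vals[c] = make_error(
                vals[c], dataset.alphabet, cfg.noise_deviation, scope, dataset.background, rng
            )


def _record(dataset: Dataset, kind: str, flat_cells: np.ndarray) -> None:
    attr = {"missing": "missing_cells", "noise": "noise_cells", "error": "error_cells"}[kind]
    setattr(dataset, attr, np.concatenate([getattr(dataset, attr), flat_cells]))


def inject_background(
    dataset: Dataset, cfg: QualityConfig, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Degrade exact background counts; returns ``(n_missing, n_noise, n_error)``.

    Background cells are all cells not covered by any tricluster.  The three
    target sets are disjoint, sampled uniformly without replacement.
    """
    cfg.validate_for(dataset.alphabet, dataset.background)
    dims = dataset.shape
    covered = np.zeros(dims, dtype=bool)
    for t in dataset.triclusters:
        covered[np.ix_(t.rows, t.cols, t.ctxs)] = True
    bg_flat = np.flatnonzero(~covered.reshape(-1))
    n_bg = len(bg_flat)
    n_m = math.floor(n_bg * cfg.missing_background / 100.0)
    n_n = math.floor(n_bg * cfg.noise_background / 100.0)
    n_e = math.floor(n_bg * cfg.error_background / 100.0)
    if n_m + n_n + n_e > n_bg:
        raise ConfigError("background quality demand exceeds the number of background cells")
    picked = rng.choice(bg_flat, size=n_m + n_n + n_e, replace=False)
    groups = (picked[:n_m], picked[n_m : n_m + n_n], picked[n_m + n_n :])
    for kind, cells in zip(("missing", "noise", "error"), groups):
        _apply(dataset, cells, kind, cfg, rng, scope="background")
        _record(dataset, kind, cells)
    return n_m, n_n, n_e


def inject_tricluster(
    t: TriclusterSpec,
    dataset: Dataset,
    cfg: QualityConfig,
    rng: np.random.Generator,
    degraded: set[int] | None = None,
) -> tuple[int, int, int]:
    """Degrade one planted tricluster with bounded random counts.

    Each category count is uniform on ``[0, floor(|t| * pct_max)]``; affected
    cells are sampled without replacement within the block, avoiding cells in
    ``degraded`` (shared bookkeeping across overlapping triclusters).  The
    realized counts are recorded in ``t.quality_counts``.
    """
    cfg.validate_for(dataset.alphabet, dataset.background or BackgroundSpec("uniform"))
    if degraded is None:
        degraded = set()
    vol = t.volume
    n_m = int(rng.integers(0, math.floor(vol * cfg.missing_triclusters / 100.0) + 1))
    n_n = int(rng.integers(0, math.floor(vol * cfg.noise_triclusters / 100.0) + 1))
    n_e = int(rng.integers(0, math.floor(vol * cfg.error_triclusters / 100.0) + 1))
    _, nj, nk = dataset.shape[0], dataset.shape[1], dataset.shape[2]
    block_flat = np.array(
        [(i * nj + j) * nk + k for (i, j, k) in t.cells()], dtype=np.int64
    )
    avail = np.array([c for c in block_flat if c not in degraded], dtype=np.int64)
    total = min(n_m + n_n + n_e, len(avail))
    n_m = min(n_m, total)
    n_n = min(n_n, total - n_m)
    n_e = min(n_e, total - n_m - n_n)
    picked = rng.choice(avail, size=n_m + n_n + n_e, replace=False) if len(avail) else avail
    groups = (picked[:n_m], picked[n_m : n_m + n_n], picked[n_m + n_n :])
    for kind, cells in zip(("missing", "noise", "error"), groups):
        _apply(dataset, cells, kind, cfg, rng, scope="tricluster")
        _record(dataset, kind, cells)
        degraded.update(int(c) for c in cells)
    t.quality_counts = (n_m, n_n, n_e)
    return n_m, n_n, n_e


def inject_quality(
    dataset: Dataset, cfg: QualityConfig, rng: np.random.Generator
) -> None:
    """Full-dataset degradation: triclusters (in id order), then background."""
    degraded: set[int] = set()
    for t in dataset.triclusters:
        inject_tricluster(t, dataset, cfg, rng, degraded)
    inject_background(dataset, cfg, rng)
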