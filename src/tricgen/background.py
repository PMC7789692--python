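"""Background generation: fill every cell from the configured distribution.

Triclusters are stamped over the background afterwards, so the background is
the data "in the absence of local correlations".  Four families are supported:
uniform, normal (Gaussian), discrete (per-element probabilities; symbolic or
integer alphabets only) and missing (a null background where every cell is
MISSING).

Boundary rule for normal backgrounds on bounded alphabets: sample, then clamp
to the alphabet range; integer alphabets round to the nearest integer and
symbolic alphabets discretize the clamped sample onto symbol ranks.  Clamping
is deterministic and keeps the nominal center of the distribution.
"""

from __future__ import annotations

import numpy as np

from .core import Alphabet, BackgroundSpec, ConfigError


def sample_values(
    n: int, alphabet: Alphabet, spec: BackgroundSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` internal-representation values from the background law.

    Also used by the pattern engine to fill order-preserving fibers, hence a
    flat-array interface.  The ``missing`` family yields all-NaN.
    """
    spec.validate_for(alphabet)
    if spec.family == "missing":
        return np.full(n, np.nan)
    if spec.family == "uniform":
        if alphabet.kind == "real":
            return rng.uniform(alphabet.lo, alphabet.hi, size=n)
        return rng.integers(int(alphabet.lo), int(alphabet.hi) + 1, size=n).astype(float)
    if spec.family == "discrete":
        elems = np.arange(int(alphabet.lo), int(alphabet.hi) + 1, dtype=float)
        return rng.choice(elems, size=n, p=np.asarray(spec.probabilities))
    # normal: sample then clamp into the alphabet
    draws = rng.normal(spec.mean, spec.stdev, size=n)
    draws = np.clip(draws, alphabet.lo, alphabet.hi)
    if alphabet.kind != "real":
        draws = np.rint(draws)
    return draws


def generate_background(
    dims: tuple[int, int, int],
    alphabet: Alphabet,
    spec: BackgroundSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """3D background grid of shape ``dims`` in internal representation."""
    if any(d < 1 for d in dims):
        raise ConfigError(f"dataset dimensions must be positive, got {dims}")
    n = int(np.prod(dims))
    return sample_values(n, alphabet, spec, rng).reshape(dims)
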