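"""Benchmark presets.

Ready-made configurations for three families of benchmarks shipped with the
generator:

* ``real/dataset1..5`` — configurations mimicking five published real-world
  three-way datasets (yeast cell-cycle expression, stock-market ratios,
  resting-state fMRI, bibsonomy triples, Dutch daily temperatures);
* ``base/R|S|B|C`` — clean 1000 x 100 x 10 datasets, one per data type
  (Real-valued, Symbolic, Binary, integer Contiguous), with 12 planted
  triclusters and no overlap or degradation;
* derived suites: ``scal/S1|S2|S3`` (10^7..10^9 cells), ``overlap/low|high``,
  ``quality/higher|lower``, ``rich/R|S|B|C``, and per-pattern-family suites
  ``patterns/<family>-<type>``.

The published sources for the fMRI configuration disagree on its feature
count (464 vs 494); these presets use 494.  Type-specific suites accept a
``-R|-S|-B|-C`` suffix; the bare name defaults to the real-valued variant.
"""

from __future__ import annotations

import copy

from .config import GeneratorConfig
from .core import ConfigError

_U = lambda a, b: {"dist": "uniform", "a": a, "b": b}  # noqa: E731


def _dataset(dtype, dims, alphabet, background):
    return {"dtype": dtype, "dims": list(dims), "alphabet": alphabet, "background": background}


_NO_OVERLAP = {
    "plaid": "no_overlap", "pct_triclusters": 0, "max_group_size": 0,
    "pct_elements": 0, "pct_rows": 0, "pct_cols": 0, "pct_ctxs": 0,
}

_REAL = {
    "real/dataset1": {
        "dataset": _dataset("real", (7679, 13, 14), {"min": 0, "max": 500}, {"family": "uniform"}),
        "triclusters": {
            "n": 7, "rows": _U(80, 400), "cols": _U(2, 4), "ctxs": _U(3, 13),
            "contiguity": "none", "patterns": "all",
        },
        "overlap": _NO_OVERLAP,
        "quality": {},
    },
    "real/dataset2": {
        "dataset": _dataset(
            "real", (3200, 30, 28), {"min": 5, "max": 1000},
            {"family": "normal", "mean": 500, "stdev": 150},
        ),
        "triclusters": {
            "n": 10, "rows": _U(100, 500), "cols": _U(10, 20), "ctxs": _U(5, 15),
            "contiguity": "none", "patterns": "all",
        },
        "overlap": {
            "plaid": "additive", "pct_triclusters": 40, "max_group_size": 2,
            "pct_elements": 50,
        },
        "quality": {
            "missing_background": 20, "noise_background": 10, "error_background": 10,
            "missing_triclusters": 10, "noise_triclusters": 15, "error_triclusters": 5,
            "noise_deviation": 2,
        },
    },
    "real/dataset3": {
        "dataset": _dataset("real", (20, 494, 94), {"min": -5, "max": 5}, {"family": "uniform"}),
        "triclusters": {
            "n": 5, "rows": _U(5, 15), "cols": _U(50, 200), "ctxs": _U(15, 50),
            "contiguity": "none", "patterns": "all",
        },
        "overlap": {
            "plaid": "additive", "pct_triclusters": 100, "max_group_size": 3,
            "pct_elements": 40,
        },
        "quality": {
            "noise_background": 20, "error_background": 15,
            "noise_triclusters": 10, "error_triclusters": 5, "noise_deviation": 1,
        },
    },
    "real/dataset4": {
        "dataset": _dataset(
            "integer", (51, 924, 2844), {"min": 0, "max": 1},
            {"family": "discrete", "probabilities": [0.7, 0.3]},
        ),
        "triclusters": {
            "n": 7000, "rows": _U(5, 8), "cols": _U(20, 70), "ctxs": _U(100, 400),
            "contiguity": "none", "patterns": "constant",
        },
        "overlap": {
            "plaid": "none", "pct_triclusters": 80, "max_group_size": 3000,
            "pct_elements": 70, "pct_rows": 100, "pct_cols": 80, "pct_ctxs": 80,
        },
        "quality": {},
    },
    "real/dataset5": {
        "dataset": _dataset(
            "real", (28, 20, 365), {"min": -10, "max": 30},
            {"family": "normal", "mean": 14, "stdev": 7},
        ),
        "triclusters": {
            "n": 128, "rows": _U(4, 4), "cols": _U(4, 4), "ctxs": _U(8, 8),
            "contiguity": "none", "patterns": "all",
        },
        "overlap": _NO_OVERLAP,
        "quality": {
            "missing_background": 15, "noise_background": 20, "error_background": 5,
            "missing_triclusters": 5, "noise_triclusters": 10, "error_triclusters": 2,
            "noise_deviation": 1,
        },
    },
}


def _base(dtype_letter: str) -> dict:
    datasets = {
        "R": _dataset(
            "real", (1000, 100, 10), {"min": -100, "max": 100},
            {"family": "normal", "mean": 0, "stdev": 30},
        ),
        "S": _dataset(
            "symbolic", (1000, 100, 10), {"symbols": ["1", "2", "3", "4", "5"]},
            {"family": "discrete", "probabilities": [0.1, 0.15, 0.3, 0.3, 0.15]},
        ),
        "B": _dataset("integer", (1000, 100, 10), {"min": 0, "max": 1}, {"family": "uniform"}),
        "C": _dataset("integer", (1000, 100, 10), {"min": 0, "max": 100}, {"family": "uniform"}),
    }
    patterns = {
        "R": "all",
        "S": ["order_preserving", "constant"],
        "B": "constant",
        "C": "all",
    }
    return {
        "dataset": datasets[dtype_letter],
        "triclusters": {
            "n": 12, "rows": _U(30, 50), "cols": _U(5, 10), "ctxs": _U(2, 4),
            "contiguity": "contexts" if dtype_letter == "C" else "none",
            "patterns": patterns[dtype_letter],
        },
        "overlap": dict(_NO_OVERLAP),
        "quality": {},
    }


_SCAL = {
    "scal/S1": ((1000, 100, 100), 120),
    "scal/S2": ((10000, 100, 100), 1200),
    "scal/S3": ((10000, 1000, 100), 12000),
}

_OVERLAP_PLAID = {"R": "additive", "S": "none", "B": "none", "C": "multiplicative"}

_QUALITY = {
    # (bg_m, bg_n, bg_e, tr_m, tr_n, tr_e, ndev per letter)
    "higher": (2, 10, 5, 2, 10, 5, {"R": 1, "S": 1, "B": 1, "C": 1}),
    "lower": (10, 30, 15, 5, 20, 8, {"R": 3, "S": 1, "B": 1, "C": 3}),
}

_RICH_OVERLAP = {
    "R": {"plaid": "additive", "pct_triclusters": 50, "max_group_size": 3, "pct_elements": 60},
    "S": {"plaid": "none", "pct_triclusters": 40, "max_group_size": 2, "pct_elements": 50},
    "B": {"plaid": "none", "pct_triclusters": 60, "max_group_size": 3, "pct_elements": 80},
    "C": {"plaid": "multiplicative", "pct_triclusters": 60, "max_group_size": 4, "pct_elements": 70},
}


def _split(name: str, default_letter: str = "R") -> tuple[str, str]:
    """'overlap/low-S' -> ('overlap/low', 'S'); bare names default to R."""
    if "-" in name:
        stem, letter = name.rsplit("-", 1)
        return stem, letter
    return name, default_letter


def preset_names() -> list[str]:
    """All registered preset names (type-suffixed variants enumerated)."""
    names = list(_REAL)
    names += [f"base/{x}" for x in "RSBC"]
    names += list(_SCAL)
    for stem, letters in (
        ("overlap/low", "RSBC"), ("overlap/high", "RSBC"),
        ("quality/higher", "RSBC"), ("quality/lower", "RSBC"),
    ):
        names += [f"{stem}-{x}" for x in letters]
    names += [f"rich/{x}" for x in "RSBC"]
    fams = {"R": ["constant", "additive", "multiplicative", "order_preserving"],
            "S": ["constant", "order_preserving"], "B": ["constant"],
            "C": ["constant", "additive", "multiplicative", "order_preserving"]}
    for letter, families in fams.items():
        names += [f"patterns/{f}-{letter}" for f in families]
    return names


def load_preset(name: str) -> GeneratorConfig:
    """Return the configuration registered under ``name``.

    See :func:`preset_names`; suites parameterized by data type accept a
    ``-R|-S|-B|-C`` suffix (default R).
    """
    if name in _REAL:
        return GeneratorConfig.model_validate(copy.deepcopy(_REAL[name]))
    if name.startswith("base/"):
        letter = name.split("/", 1)[1]
        if letter not in "RSBC":
            raise ConfigError(f"unknown preset {name!r}")
        return GeneratorConfig.model_validate(_base(letter))

    if name in _SCAL:
        dims, n = _SCAL[name]
        cfg = _base("R")
        cfg["dataset"]["dims"] = list(dims)
        cfg["triclusters"]["n"] = n
        return GeneratorConfig.model_validate(cfg)

    if name.startswith("rich/"):
        stem, letter = "rich", name.split("/", 1)[1]
    else:
        stem, letter = _split(name)
    if letter not in "RSBC":
        raise ConfigError(f"unknown preset {name!r}")

    if stem in ("overlap/low", "overlap/high"):
        cfg = _base(letter)
        if stem == "overlap/low":
            cfg["overlap"] = {
                "plaid": _OVERLAP_PLAID[letter], "pct_triclusters": 30,
                "max_group_size": 2, "pct_elements": 30,
                "pct_rows": 100, "pct_cols": 70, "pct_ctxs": 70,
            }
        else:
            cfg["overlap"] = {
                "plaid": _OVERLAP_PLAID[letter], "pct_triclusters": 75,
                "max_group_size": 3, "pct_elements": 70,
            }
        return GeneratorConfig.model_validate(cfg)

    if stem in ("quality/higher", "quality/lower"):
        level = stem.split("/", 1)[1]
        bg_m, bg_n, bg_e, tr_m, tr_n, tr_e, ndev = _QUALITY[level]
        cfg = _base(letter)
        cfg["quality"] = {
            "missing_background": bg_m, "noise_background": bg_n,
            "error_background": 0 if letter == "B" else bg_e,
            "missing_triclusters": tr_m, "noise_triclusters": tr_n,
            "error_triclusters": 0 if letter == "B" else tr_e,
            "noise_deviation": ndev[letter],
        }
        return GeneratorConfig.model_validate(cfg)

    if stem == "rich":
        cfg = _base(letter)
        cfg["dataset"]["dims"] = [1000, 100, 100]
        cfg["triclusters"]["n"] = 30
        cfg["triclusters"]["ctxs"] = _U(3, 5)
        cfg["overlap"] = dict(_RICH_OVERLAP[letter])
        ndev = {"R": 2, "S": 1, "B": 1, "C": 2}[letter]
        e = 0 if letter == "B" else 5
        cfg["quality"] = {
            "missing_background": 2, "noise_background": 10, "error_background": e,
            "missing_triclusters": 2, "noise_triclusters": 10, "error_triclusters": e,
            "noise_deviation": ndev,
        }
        return GeneratorConfig.model_validate(cfg)

    if stem.startswith("patterns/"):
        family = stem.split("/", 1)[1]
        cfg = _base(letter)
        cfg["triclusters"]["patterns"] = family
        return GeneratorConfig.model_validate(cfg)

    raise ConfigError(f"unknown preset {name!r}")
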