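"""Serialization: the TSV dataset file, the ground-truth solution files, and
configuration loading.

Dataset layout (``<stem>_data.tsv``): one slice block per context, in context
order, each preceded by a ``# context <k>`` header line; within a block, rows
are observations and tab-separated columns are features (the slice view of a
three-way dataset).  MISSING serializes as an empty field.  Floats are
written with ``repr`` so the round-trip is exact.

Solution files: ``<stem>_trics.json`` (schema-validated ground truth) and
``<stem>_trics.txt`` (human-readable rendering of the same report).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .config import GeneratorConfig
from .core import Alphabet, ConfigError, Dataset
from .report import SolutionReport


def _format_value(v: float, alphabet: Alphabet) -> str:
    if np.isnan(v):
        return ""
    if alphabet.kind == "symbolic":
        return alphabet.symbols[int(v)]
    if alphabet.kind == "integer":
        return str(int(v))
    return repr(float(v))


def write_dataset(dataset: Dataset, path_stem: str | Path) -> Path:
    """Write ``<stem>_data.tsv`` and return its path."""
    path = Path(f"{path_stem}_data.tsv")
    a = dataset.alphabet
    with open(path, "w") as fh:
        for k in range(dataset.shape[2]):
            fh.write(f"# context {k}\n")
            slice_ = dataset.values[:, :, k]
            for i in range(dataset.shape[0]):
                fh.write("\t".join(_format_value(v, a) for v in slice_[i]) + "\n")
    return path


def read_dataset(path: str | Path, alphabet: Alphabet) -> np.ndarray:
    """Parse a ``_data.tsv`` file back into the internal 3D grid."""
    slices: list[list[list[float]]] = []
    current: list[list[float]] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# context"):
                current = []
                slices.append(current)
                continue
            if current is None:
                raise ValueError("malformed dataset file: data before first context header")
            row = []
            for tok in line.split("\t"):
                if tok == "":
                    row.append(np.nan)
                elif alphabet.kind == "symbolic":
                    row.append(float(alphabet.rank(tok)))
                else:
                    row.append(float(tok))
            current.append(row)
    return np.stack([np.asarray(s, dtype=float) for s in slices], axis=2)


def write_solution(report: SolutionReport, path_stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>_trics.json`` and ``<stem>_trics.txt``."""
    json_path = Path(f"{path_stem}_trics.json")
    txt_path = Path(f"{path_stem}_trics.txt")
    json_path.write_text(json.dumps(report.model_dump(), indent=2) + "\n")
    txt_path.write_text(report.to_text())
    return txt_path, json_path


def read_solution(path: str | Path) -> SolutionReport:
    """Parse and validate a ``_trics.json`` file."""
    return SolutionReport.model_validate_json(Path(path).read_text())


def solution_schema() -> dict:
    """JSON schema of the solution report (also published in the repo)."""
    return SolutionReport.model_json_schema()


def load_config(path: str | Path) -> GeneratorConfig:
    """Load and validate a YAML or JSON generator configuration."""
    path = Path(path)
    raw = path.read_text()
    data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    if not isinstance(data, dict):
        raise ConfigError(f"configuration file {path} does not hold a mapping")
    return GeneratorConfig.model_validate(data)
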