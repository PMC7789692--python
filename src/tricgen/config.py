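"""Validated generator configuration.

A :class:`GeneratorConfig` fully describes one generation run: dataset type,
dimensions, alphabet and background; tricluster count, size laws, contiguity
and allowed pattern triples; overlap quotas and plaid coherency; quality
percentages; and an optional RNG seed.  Defaults are filled for everything
the user omits, and cross-field admissibility (discrete backgrounds, pattern
triples vs dataset type, symbolic plaid, quality budgets) is checked here so
that generation never starts from an inconsistent description.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, model_validator

from .core import (
    Alphabet,
    BackgroundSpec,
    ConfigError,
    Pattern,
    PatternTriple,
    PlaidCoherency,
    TemporalProfile,
)
from .overlap import OverlapConfig
from .patterns import admissible_triples, triples_for_families, validate_triple
from .quality import QualityConfig
from .structure import SizeDistribution, StructureConfig


class AlphabetModel(BaseModel):
    symbols: list[str] | None = None
    min: float | None = None
    max: float | None = None


class BackgroundModel(BaseModel):
    family: Literal["uniform", "normal", "discrete", "missing"] = "uniform"
    mean: float | None = None
    stdev: float | None = None
    probabilities: list[float] | None = None


class DatasetModel(BaseModel):
    dtype: Literal["real", "integer", "symbolic"]
    dims: tuple[int, int, int]
    alphabet: AlphabetModel = AlphabetModel()
    background: BackgroundModel = BackgroundModel()


class SizeModel(BaseModel):
    dist: Literal["uniform", "normal"] = "uniform"
    a: float | None = None
    b: float | None = None
    mean: float | None = None
    stdev: float | None = None


class TriclustersModel(BaseModel):
    n: int = 1
    rows: SizeModel = SizeModel(a=2, b=4)
    cols: SizeModel = SizeModel(a=2, b=4)
    ctxs: SizeModel = SizeModel(a=2, b=4)
    contiguity: Literal["none", "features", "contexts"] = "none"
    # "all", a list of family names, or a list of explicit [row, col, ctx] triples
    patterns: str | list[str] | list[list[str]] = "all"
    temporal_profile: Literal["increasing", "decreasing", "random"] = "random"


class OverlapModel(BaseModel):
    plaid: Literal["additive", "multiplicative", "interpoled", "none", "no_overlap"] = (
        "no_overlap"
    )
    pct_triclusters: float = 0.0
    max_group_size: int = 0
    pct_elements: float = 0.0
    pct_rows: float = 100.0
    pct_cols: float = 100.0
    pct_ctxs: float = 100.0


class QualityModel(BaseModel):
    missing_background: float = 0.0
    noise_background: float = 0.0
    error_background: float = 0.0
    missing_triclusters: float = 0.0
    noise_triclusters: float = 0.0
    error_triclusters: float = 0.0
    noise_deviation: float = 0.0


class GeneratorConfig(BaseModel):
    """Complete, validated description of one generation run."""

    dataset: DatasetModel
    triclusters: TriclustersModel = TriclustersModel()
    overlap: OverlapModel = OverlapModel()
    quality: QualityModel = QualityModel()
    seed: int | None = None

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        # building the domain objects performs all cross-field validation
        self.build_alphabet()
        self.build_background().validate_for(self.build_alphabet())
        self.build_structure()
        self.build_overlap()
        q = self.build_quality()
        q.validate_for(self.build_alphabet(), self.build_background())
        self.pattern_pool()
        if self.dataset.dtype == "symbolic" and self.overlap.plaid in (
            "additive", "multiplicative", "interpoled",
        ):
            raise ConfigError(
                f"plaid coherency {self.overlap.plaid!r} is invalid for symbolic data "
                "(only 'none' combines symbolic contributions)"
            )
        return self

    # -- domain-object builders ---------------------------------------------

    def build_alphabet(self) -> Alphabet:
        a = self.dataset.alphabet
        if self.dataset.dtype == "symbolic":
            if not a.symbols:
                raise ConfigError("symbolic dataset requires dataset.alphabet.symbols")
            return Alphabet(kind="symbolic", symbols=tuple(a.symbols))
        if a.min is None or a.max is None:
            raise ConfigError("numeric dataset requires dataset.alphabet.min and .max")
        return Alphabet(kind=self.dataset.dtype, min_value=a.min, max_value=a.max)

    def build_background(self) -> BackgroundSpec:
        b = self.dataset.background
        return BackgroundSpec(
            family=b.family,
            mean=b.mean,
            stdev=b.stdev,
            probabilities=tuple(b.probabilities) if b.probabilities else None,
        )

    def build_structure(self) -> StructureConfig:
        def dist(m: SizeModel) -> SizeDistribution:
            return SizeDistribution(dist=m.dist, a=m.a, b=m.b, mean=m.mean, stdev=m.stdev)

        t = self.triclusters
        return StructureConfig(
            n_triclusters=t.n,
            rows=dist(t.rows),
            cols=dist(t.cols),
            ctxs=dist(t.ctxs),
            contiguity=t.contiguity,
        )

    def build_overlap(self) -> OverlapConfig:
        o = self.overlap
        return OverlapConfig(
            plaid=PlaidCoherency(o.plaid),
            pct_triclusters=o.pct_triclusters,
            max_group_size=o.max_group_size,
            pct_elements=o.pct_elements,
            pct_rows=o.pct_rows,
            pct_cols=o.pct_cols,
            pct_ctxs=o.pct_ctxs,
        )

    def build_quality(self) -> QualityConfig:
        q = self.quality
        return QualityConfig(
            missing_background=q.missing_background,
            noise_background=q.noise_background,
            error_background=q.error_background,
            missing_triclusters=q.missing_triclusters,
            noise_triclusters=q.noise_triclusters,
            error_triclusters=q.error_triclusters,
            noise_deviation=q.noise_deviation,
        )

    def pattern_pool(self) -> list[PatternTriple]:
        """The admissible triples a tricluster may be assigned."""
        spec = self.triclusters.patterns
        dtype = self.dataset.dtype
        if spec == "all":
            return admissible_triples(dtype)
        if isinstance(spec, str):
            return triples_for_families(dtype, [spec])
        if spec and isinstance(spec[0], str):
            return triples_for_families(dtype, list(spec))
        pool = []
        for row, col, ctx in spec:
            t = PatternTriple(Pattern(row), Pattern(col), Pattern(ctx))
            v = validate_triple(t, dtype)
            if v is not None:
                raise ConfigError(f"inadmissible pattern triple {t} for {dtype}: {v.detail}")
            pool.append(t)
        if not pool:
            raise ConfigError("empty pattern triple list")
        return pool

    def temporal_profile(self) -> TemporalProfile:
        return TemporalProfile(self.triclusters.temporal_profile)
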