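"""Ground-truth solution report.

The report is the machine-readable triclustering solution shipped next to a
generated dataset: per-tricluster location, patterns, plaid coherency and
planted degradation, plus dataset-level coverage and global quality
percentages.  It is a pydantic model so the published JSON schema
(``tricgen/schemas/solution.schema.json``) is derived from it and every
emitted file can be validated by parsing it back.
"""

from __future__ import annotations

from pydantic import BaseModel

from .core import Dataset, covered_cells
from .overlap import OverlapPlan


class TriclusterReport(BaseModel):
    id: int
    size: tuple[int, int, int]
    n_cells: int
    rows: list[int]
    cols: list[int]
    ctxs: list[int]
    row_pattern: str
    col_pattern: str
    ctx_pattern: str
    temporal_profile: str
    plaid: str
    pct_missing: float
    pct_noise: float
    pct_errors: float


class OverlapGroupReport(BaseModel):
    members: list[int]
    edges: list[tuple[int, int]]


class SolutionReport(BaseModel):
    """Serializable ground truth for one generated dataset."""

    dims: tuple[int, int, int]
    dataset_type: str
    n_triclusters: int
    coverage: float
    pct_missing: float
    pct_noise: float
    pct_errors: float
    triclusters: list[TriclusterReport]
    overlap_groups: list[OverlapGroupReport] = []

    def to_text(self) -> str:
        """Human-readable rendering of the same information."""
        lines = [
            f"Dataset: {self.dims[0]} x {self.dims[1]} x {self.dims[2]} ({self.dataset_type})",
            f"Planted triclusters: {self.n_triclusters}",
            f"Coverage: {self.coverage:.6g}",
            f"Missing values on dataset: {self.pct_missing:.4g}%",
            f"Noise on dataset: {self.pct_noise:.4g}%",
            f"Errors on dataset: {self.pct_errors:.4g}%",
            "",
        ]
        for t in self.triclusters:
            lines += [
                f"Tricluster #{t.id}",
                f"  size: {t.size[0]} x {t.size[1]} x {t.size[2]} ({t.n_cells} cells)",
                f"  rows: {t.rows}",
                f"  cols: {t.cols}",
                f"  ctxs: {t.ctxs}",
                f"  patterns: ({t.row_pattern}, {t.col_pattern}, {t.ctx_pattern})"
                + (
                    f" profile={t.temporal_profile}"
                    if t.temporal_profile != "n/a"
                    else ""
                ),
                f"  plaid: {t.plaid}",
                f"  missing: {t.pct_missing:.4g}%  noise: {t.pct_noise:.4g}%  "
                f"errors: {t.pct_errors:.4g}%",
                "",
            ]
        if self.overlap_groups:
            lines.append("Overlap groups:")
            for g in self.overlap_groups:
                lines.append(f"  members {g.members} edges {g.edges}")
            lines.append("")
        return "\n".join(lines)


def build_report(dataset: Dataset, plan: OverlapPlan | None = None) -> SolutionReport:
    """Assemble the solution report from a generated dataset."""
    n_cells = dataset.n_cells
    coverage = (
        len(covered_cells(dataset.triclusters)) / n_cells if dataset.triclusters else 0.0
    )
    trics = []
    for t in dataset.triclusters:
        vol = t.volume
        n_m, n_n, n_e = t.quality_counts
        trics.append(
            TriclusterReport(
                id=t.id,
                size=t.shape,
                n_cells=vol,
                rows=list(t.rows),
                cols=list(t.cols),
                ctxs=list(t.ctxs),
                row_pattern=t.triple.row.value,
                col_pattern=t.triple.col.value,
                ctx_pattern=t.triple.ctx.value,
                temporal_profile=t.triple.temporal_profile.value,
                plaid=t.plaid.value,
                pct_missing=100.0 * n_m / vol,
                pct_noise=100.0 * n_n / vol,
                pct_errors=100.0 * n_e / vol,
            )
        )
    groups = []
    if plan is not None:
        placed = {t.id for t in dataset.triclusters}
        for g in plan.groups:
            members = [m for m in g.members if m in placed]
            if len(members) >= 2:
                groups.append(
                    OverlapGroupReport(
                        members=members,
                        edges=[e for e in g.edges if e[0] in placed and e[1] in placed],
                    )
                )
    return SolutionReport(
        dims=dataset.shape,
        dataset_type=dataset.alphabet.kind,
        n_triclusters=len(dataset.triclusters),
        coverage=coverage,
        pct_missing=100.0 * len(dataset.missing_cells) / n_cells,
        pct_noise=100.0 * len(dataset.noise_cells) / n_cells,
        pct_errors=100.0 * len(dataset.error_cells) / n_cells,
        triclusters=trics,
        overlap_groups=groups,
    )
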