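"""End-to-end wiring: parse → QC → baseline → pool → parameters → reports.

This is the library-level entry point the CLI and scripts drive.  The flow:

1. parse one or more Rate CSV exports into a single table;
2. exclude background/blank wells, normalize, screen (negative rates,
   negative spare respiratory capacity);
3. compute per-well parameters and ratios on normalized traces;
4. baseline each well by its own non-mitochondrial respiration and pool
   replicates per group into median curves;
5. compute group parameters with propagated errors;
6. write the wells and groups reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import metrics, qc_normalize, rate_io
from .model import QCReport, RateTable, Regime, Well
from .rate_io import GroupResult, WellResult

__all__ = ["RunConfig", "AnalysisResult", "analyze_tables", "run_analysis"]

log = logging.getLogger("mitoflux")

PathLike = Union[str, Path]


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    ``grouping_mode`` controls replicate pooling: ``technical`` pools wells
    by their full group label; ``biological`` pools by the label part before
    an optional "/" separator, so labels like ``donor3/plate1`` collapse to
    ``donor3``.  Well-level values never depend on the mode.
    ``se_formula`` selects σ/√n (standard error, default) or σ/n².
    """

    input_paths: list[str] = field(default_factory=list)
    n_measurements: int = 14
    output_root: str = "log"
    output_dir: str = "."
    grouping_mode: str = "technical"
    se_formula: str = "sqrt_n"

    def __post_init__(self) -> None:
        if self.n_measurements not in (12, 14):
            raise ValueError(f"n_measurements must be 12 or 14, got {self.n_measurements}")
        if not self.output_root:
            raise ValueError("output_root must be non-empty")
        if self.grouping_mode not in ("technical", "biological"):
            raise ValueError(f"unknown grouping_mode {self.grouping_mode!r}")


@dataclass
class AnalysisResult:
    """Everything one run produced, before/after report writing."""

    regime: Regime
    qc: QCReport
    well_results: list[WellResult]
    group_results: list[GroupResult]
    wells_path: Optional[Path] = None
    groups_path: Optional[Path] = None


def _pool_label(group: str, mode: str) -> str:
    if mode == "biological" and "/" in group:
        return group.split("/", 1)[0]
    return group


def analyze_tables(
    tables: Sequence[RateTable],
    n_measurements: int = 14,
    grouping_mode: str = "technical",
    se_formula: str = "sqrt_n",
) -> AnalysisResult:
    """Run QC, baselining, pooling and parameter calculation on parsed tables."""
    regime = metrics.resolve_regime(n_measurements)
    wells: list[Well] = []
    sources: list[str] = []
    for t in tables:
        if t.regime_total != n_measurements:
            raise ValueError(
                f"table with {t.regime_total} measurements cannot be analyzed "
                f"under the {n_measurements}-measurement regime"
            )
        wells.extend(t.wells)
        sources.extend(t.source_files)
    merged = RateTable(wells=wells, regime_total=n_measurements, source_files=sources)

    clean, qc = qc_normalize.apply_qc(merged, regime)

    well_results = [
        WellResult(w, _well_params_with_ratios(w, regime)) for w in clean.wells
    ]

    # pool per group label (possibly collapsed for biological replicates)
    pooled: dict[str, list[Well]] = {}
    for w in clean.wells:
        pooled.setdefault(_pool_label(w.group, grouping_mode), []).append(w)

    group_results: list[GroupResult] = []
    for label, members in pooled.items():
        baselined = [qc_normalize.baseline_well(w, regime) for w in members]
        for b in baselined:
            b.group = label
        profile = metrics.group_curve(baselined, regime, se_formula)
        ratio_wells = [w for w in members if metrics.ratio_eligible(w, regime)]
        params = metrics.group_parameters(profile, regime, ratio_wells, se_formula)
        # the baselined curve's own floor is ~0 by construction; report the
        # group's nMitoR as the median of the wells' pre-baseline floors
        params.nmitor = float(np.median([b.baseline_nmitor for b in baselined]))
        group_results.append(GroupResult(profile, params))

    return AnalysisResult(
        regime=regime, qc=qc, well_results=well_results, group_results=group_results
    )


def _well_params_with_ratios(well: Well, regime: Regime):
    params = metrics.well_parameters(well, regime)
    params.ratio_basal, params.ratio_max = metrics.well_ratios(well, regime)
    return params


def run_analysis(config: RunConfig) -> AnalysisResult:
    """Full run from input files to the two written reports."""
    table = rate_io.parse_rate_table(config.input_paths, config.n_measurements)
    Path(config.output_dir).mkdir(parents=True, exist_ok=True)
    result = analyze_tables(
        [table],
        n_measurements=config.n_measurements,
        grouping_mode=config.grouping_mode,
        se_formula=config.se_formula,
    )
    if not result.well_results:
        log.warning("no wells survived QC; reports will contain headers only")
    result.wells_path = rate_io.write_wells_report(
        result.well_results, config.output_root, config.output_dir
    )
    result.groups_path = rate_io.write_groups_report(
        result.group_results, config.output_root, config.output_dir,
        qc_summary=result.qc.summary(),
    )
    return result
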