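"""Per-well normalization, automated data cleaning, and cross-plate baselining.

Cleaning is removal-only: a well that violates a rule is discarded in full,
never repaired or imputed.  The rules are physical: rates below zero cannot
occur, and maximal respiration cannot fall below basal respiration (spare
respiratory capacity cannot be negative).
"""

from __future__ import annotations

import logging
from typing import Literal, Sequence

from .metrics import well_parameters
from .model import QCReason, QCReport, RateTable, Regime, Well

__all__ = ["normalize_well", "screen_well", "apply_qc", "baseline_well", "ZeroNormalizationError"]

log = logging.getLogger("mitoflux")

Verdict = Literal["pass", "negative_rate", "negative_SRC"]


class ZeroNormalizationError(ValueError):
    """Raised when a background/blank well (norm 0) is asked to normalize."""


def normalize_well(well: Well) -> Well:
    """Divide every OCR and ECAR measurement by the well's norm value.

    Units become per-normalization-unit (e.g. pmol O₂/min per 100k cells).
    Background and blank wells (norm 0) cannot be normalized and are
    rejected; QC excludes them before this step.
    """
    if well.norm_value == 0:
        raise ZeroNormalizationError(
            f"well {well.well_id} has normalization value 0 (background/blank)"
        )
    out = well.copy()
    out.ocr = out.ocr / well.norm_value
    out.ecar = out.ecar / well.norm_value
    out.normalized = True
    return out


def screen_well(well: Well, regime: Regime) -> Verdict:
    """Classify a normalized well against the data-cleaning rules.

    ``negative_rate`` if any OCR or ECAR measurement is below zero (checked
    first); else ``negative_SRC`` if the well's maximal respiration is below
    its basal respiration; else ``pass``.  Exactly-zero measurements pass
    the negative-rate rule ("below zero") — the ratio positivity rule deals
    with them separately.
    """
    if (well.ocr < 0).any() or (well.ecar < 0).any():
        return "negative_rate"
    params = well_parameters(well, regime)
    if params.src < 0:
        return "negative_SRC"
    return "pass"


def apply_qc(table: RateTable, regime: Regime) -> tuple[RateTable, QCReport]:
    """Exclude background wells, normalize the rest, and screen them.

    Returns a clean table of normalized, QC-passing wells plus a report
    accounting for every input well.  Reasons: ``background`` for wells
    whose norm entry was an explicit 0, ``zero_normalization`` for wells
    whose norm entry was blank, ``negative_rate`` / ``negative_SRC`` from
    :func:`screen_well`.  Groups left with zero surviving wells are logged
    as a warning and simply have no group-level output.
    """
    kept: list[Well] = []
    report = QCReport()
    for well in table.wells:
        if well.norm_value == 0:
            reason = QCReason.ZERO_NORMALIZATION if well.norm_missing else QCReason.BACKGROUND
            report.removed.append((well.well_id, well.group, reason))
            log.info("QC removed %s (group %s): %s", well.well_id, well.group, reason.value)
            continue
        normalized = well if well.normalized else normalize_well(well)
        verdict = screen_well(normalized, regime)
        if verdict != "pass":
            report.removed.append((well.well_id, well.group, QCReason(verdict)))
            log.info("QC removed %s (group %s): %s", well.well_id, well.group, verdict)
            continue
        kept.append(normalized)
    report.kept_count = len(kept)

    surviving_groups = {w.group for w in kept}
    for group in table.groups():
        if group and group not in surviving_groups:
            log.warning("group %s has no surviving wells after QC", group)

    clean = RateTable(
        wells=kept, regime_total=table.regime_total, source_files=list(table.source_files)
    )
    return clean, report


def baseline_well(well: Well, regime: Regime) -> Well:
    """Subtract the well's own non-mitochondrial respiration from its OCR.

    nMitoR — the median of the post-antimycin/rotenone measurements — is
    the least variable parameter across groups on a plate, so anchoring
    every well's antimycin/rotenone floor at zero removes additive
    plate-to-plate offsets before replicates from different plates are
    pooled.  ECAR is left untouched; the pre-baseline nMitoR is retained on
    the returned well for reporting.  Idempotent: a well already baselined
    has nMitoR 0 and is returned shifted by nothing.
    """
    params = well_parameters(well, regime)
    out = well.copy()
    out.ocr = out.ocr - params.nmitor
    if well.baseline_nmitor is None:
        out.baseline_nmitor = params.nmitor
    return out


def baseline_wells(wells: Sequence[Well], regime: Regime) -> list[Well]:
    return [baseline_well(w, regime) for w in wells]
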