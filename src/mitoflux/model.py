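"""Shared data model for extracellular-flux stress-test analysis.

A mitochondrial stress test records oxygen consumption rate (OCR) and
extracellular acidification rate (ECAR) for each well of a plate over a
sequence of measurements spanning four injection phases: basal, then after
oligomycin (ATP-synthase inhibitor), FCCP (uncoupler), and antimycin A +
rotenone (complex III/I inhibitors).  These types carry the per-well traces,
the measurement-regime layout, and the derived metabolic parameters.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np


class Phase(str, enum.Enum):
    """Injection phase of a single measurement."""

    BASAL = "basal"
    POST_OLIGOMYCIN = "post_oligomycin"
    POST_FCCP = "post_FCCP"
    POST_ANTIMYCIN_ROTENONE = "post_antimycin_rotenone"


class QCReason(str, enum.Enum):
    """Machine-readable reason for excluding a well from analysis."""

    BACKGROUND = "background"
    ZERO_NORMALIZATION = "zero_normalization"
    NEGATIVE_RATE = "negative_rate"
    NEGATIVE_SRC = "negative_SRC"


@dataclass(frozen=True)
class Measurement:
    """One (OCR, ECAR) reading; ``index`` is 1-based, matching M1...M14."""

    index: int
    ocr: float
    ecar: float
    phase: Optional[Phase] = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"measurement index must be >= 1, got {self.index}")


@dataclass(frozen=True)
class Regime:
    """Measurement-count layout mapping 1-based indices to injection phases.

    Two layouts exist: the 14-measurement regime is 5-3-3-3 (five basal
    readings, three after each injection); the 12-measurement regime is
    3-3-3-3.  ``basal_stat_idx`` is the subset of basal indices entering the
    basal-respiration mean: the last three basal measurements for the
    14-regime, the last two for the 12-regime.
    """

    total: int
    basal_idx: tuple[int, ...]
    oligo_idx: tuple[int, ...]
    fccp_idx: tuple[int, ...]
    antrot_idx: tuple[int, ...]
    basal_stat_idx: tuple[int, ...]

    def __post_init__(self) -> None:
        covered = sorted(self.basal_idx + self.oligo_idx + self.fccp_idx + self.antrot_idx)
        if covered != list(range(1, self.total + 1)):
            raise ValueError("regime index sets must partition 1..total")
        if not set(self.basal_stat_idx) <= set(self.basal_idx):
            raise ValueError("basal_stat_idx must be a subset of basal_idx")

    def phase_of(self, index: int) -> Phase:
        if index in self.basal_idx:
            return Phase.BASAL
        if index in self.oligo_idx:
            return Phase.POST_OLIGOMYCIN
        if index in self.fccp_idx:
            return Phase.POST_FCCP
        if index in self.antrot_idx:
            return Phase.POST_ANTIMYCIN_ROTENONE
        raise ValueError(f"index {index} outside regime 1..{self.total}")


@dataclass
class Well:
    """One assay well: a full trace plus group label and normalization value.

    ``ocr`` and ``ecar`` are arrays of length ``regime.total``; array
    position ``i`` holds measurement ``i + 1``.  ``norm_value`` is the
    per-well normalization quantity (e.g. cell number in units of 100k);
    0 marks a background/blank well.  ``baseline_nmitor`` records the
    well's own non-mitochondrial respiration once it has been subtracted
    from the OCR trace for cross-plate pooling.
    """

    well_id: str
    group: str
    norm_value: float
    ocr: np.ndarray
    ecar: np.ndarray
    is_background: bool = False
    norm_missing: bool = False
    normalized: bool = False
    baseline_nmitor: Optional[float] = None

    def __post_init__(self) -> None:
        self.ocr = np.asarray(self.ocr, dtype=float)
        self.ecar = np.asarray(self.ecar, dtype=float)
        if self.ocr.shape != self.ecar.shape or self.ocr.ndim != 1:
            raise ValueError("ocr and ecar must be 1-D arrays of equal length")
        if self.norm_value < 0:
            raise ValueError(f"norm_value must be >= 0, got {self.norm_value}")

    @property
    def n_measurements(self) -> int:
        return len(self.ocr)

    def measurements(self, regime: Optional[Regime] = None) -> Iterator[Measurement]:
        """Iterate the trace as :class:`Measurement` records (1-based)."""
        for i, (o, e) in enumerate(zip(self.ocr, self.ecar), start=1):
            phase = regime.phase_of(i) if regime is not None else None
            yield Measurement(index=i, ocr=float(o), ecar=float(e), phase=phase)

    def values_at(self, indices: Sequence[int], which: str = "ocr") -> np.ndarray:
        """Values at the given 1-based measurement indices."""
        arr = self.ocr if which == "ocr" else self.ecar
        return arr[np.asarray(indices, dtype=int) - 1]

    def copy(self) -> "Well":
        return replace(self, ocr=self.ocr.copy(), ecar=self.ecar.copy())


@dataclass
class RateTable:
    """All wells parsed from one or more Rate-format plate exports."""

    wells: list[Well]
    regime_total: int
    source_files: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for w in self.wells:
            if w.n_measurements != self.regime_total:
                raise ValueError(
                    f"well {w.well_id} has {w.n_measurements} measurements, "
                    f"expected {self.regime_total}"
                )

    def __len__(self) -> int:
        return len(self.wells)

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            seen.setdefault(w.group, None)
        return list(seen)


@dataclass
class MetabolicParams:
    """The six stress-test parameters plus OCR:ECAR ratios and errors.

    All rate parameters are in the units of the (normalized) OCR trace:

    * ``nmitor`` — non-mitochondrial respiration, median of the post-
      antimycin/rotenone measurements;
    * ``pl`` — proton leak, median post-oligomycin OCR above nmitor;
    * ``br`` — basal respiration, mean of the last basal measurements
      above nmitor;
    * ``atp`` — ATP-linked respiration, ``br - pl``;
    * ``mr`` — maximal respiration, peak post-FCCP OCR above nmitor;
    * ``src`` — spare respiratory capacity, ``mr - br``.

    ``ratio_basal``/``ratio_max`` are the dimensionless OCR:ECAR ratios at
    basal and maximal respiration; ``None`` when the well or group is
    excluded from ratio calculations by the positivity rule.  ``err_*``
    terms are populated for group-level results; ``degenerate_error`` flags
    single-replicate groups whose errors are reported as 0.
    """

    nmitor: float
    pl: float
    br: float
    atp: float
    mr: float
    src: float
    ratio_basal: Optional[float] = None
    ratio_max: Optional[float] = None
    err_nmitor: Optional[float] = None
    err_pl: Optional[float] = None
    err_br: Optional[float] = None
    err_atp: Optional[float] = None
    err_mr: Optional[float] = None
    err_src: Optional[float] = None
    err_ratio_basal: Optional[float] = None
    err_ratio_max: Optional[float] = None
    degenerate_error: bool = False

    def __post_init__(self) -> None:
        if not math.isclose(self.atp, self.br - self.pl, rel_tol=0.0, abs_tol=1e-12 * max(1.0, abs(self.br))):
            raise ValueError("ATP must equal BR - PL")
        if not math.isclose(self.src, self.mr - self.br, rel_tol=0.0, abs_tol=1e-12 * max(1.0, abs(self.mr))):
            raise ValueError("SRC must equal MR - BR")

    RATE_FIELDS = ("nmitor", "pl", "br", "atp", "mr", "src")


@dataclass
class GroupProfile:
    """Per-group median measurement curves with standard errors.

    ``curve_ocr``/``curve_ecar`` hold the median replicate value at each
    measurement; ``se_ocr``/``se_ecar`` the standard error across replicate
    wells.  ``median_well_ids`` records, per measurement, which well
    supplied the median OCR (used to look up OCR:ECAR ratios).
    """

    group: str
    n_wells: int
    curve_ocr: np.ndarray
    se_ocr: np.ndarray
    curve_ecar: np.ndarray
    se_ecar: np.ndarray
    median_well_ids: list[str]
    degenerate: bool = False

    def __post_init__(self) -> None:
        n = len(self.curve_ocr)
        for arr in (self.se_ocr, self.curve_ecar, self.se_ecar):
            if len(arr) != n:
                raise ValueError("curve arrays must have equal length")
        if self.n_wells < 1:
            raise ValueError("a group profile needs at least one well")


@dataclass
class QCReport:
    """Accounting of wells removed by quality control, with reasons."""

    removed: list[tuple[str, str, QCReason]] = field(default_factory=list)
    kept_count: int = 0

    def reasons_by_well(self) -> dict[str, QCReason]:
        return {well_id: reason for well_id, _, reason in self.removed}

    def summary(self) -> str:
        counts: dict[QCReason, int] = {}
        for _, _, reason in self.removed:
            counts[reason] = counts.get(reason, 0) + 1
        parts = [f"{r.value}={n}" for r, n in sorted(counts.items(), key=lambda kv: kv[0].value)]
        return f"kept={self.kept_count} removed={len(self.removed)}" + (
            " (" + ", ".join(parts) + ")" if parts else ""
        )
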