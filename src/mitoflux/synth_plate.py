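"""Synthetic stress-test plate generator with known ground truth.

Emulates the four-phase OCR trace of a mitochondrial stress test — basal
plateau, drop after oligomycin, peak after FCCP, floor after antimycin
A/rotenone — as phase levels plus i.i.d. Gaussian measurement noise, with
additive plate-level batch offsets and optionally planted QC violations
(negated measurements, FCCP suppressed below basal).  No biophysical
kinetics: levels plus noise is enough to exercise every pipeline stage
against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .metrics import resolve_regime
from .model import RateTable, Well
from .rate_io import write_rate_csv

__all__ = ["GroupTruth", "SynthSpec", "simulate_tables", "simulate_plate", "inject_artifacts"]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class GroupTruth:
    """Ground-truth metabolic parameters for one simulated group.

    Rates are in normalized units (per 100k cells); ``atp`` and ``src``
    are implied (BR − PL and MR − BR).  ``ecar_basal`` is the ECAR level
    before oligomycin; ``ecar_postoligo`` the level afterwards (glycolytic
    compensation raises acidification once ATP synthase is blocked).
    """

    nmitor: float = 10.0
    pl: float = 15.0
    br: float = 50.0
    mr: float = 90.0
    ecar_basal: float = 10.0
    ecar_postoligo: float = 20.0

    def validate(self) -> None:
        if not (self.mr >= self.br >= self.pl >= 0):
            raise ValueError(
                f"ground truth must satisfy mr >= br >= pl >= 0, got "
                f"mr={self.mr}, br={self.br}, pl={self.pl}"
            )
        if self.nmitor < 0:
            raise ValueError(f"nmitor must be >= 0, got {self.nmitor}")
        if self.ecar_basal <= 0 or self.ecar_postoligo <= 0:
            raise ValueError("ECAR levels must be positive")

    @property
    def atp(self) -> float:
        return self.br - self.pl

    @property
    def src(self) -> float:
        return self.mr - self.br


def _default_groups() -> dict[str, GroupTruth]:
    return {
        "A": GroupTruth(),
        "B": GroupTruth(nmitor=8.0, pl=10.0, br=35.0, mr=60.0, ecar_basal=14.0, ecar_postoligo=26.0),
    }


@dataclass
class SynthSpec:
    """Full description of a simulated experiment.

    Defaults model a typical activated human immune-cell assay normalized
    per 100k cells: two groups, six replicate wells each, spread over two
    plates; measurement noise sd of 1 rate unit (2% of the basal OCR of
    50); additive plate offsets drawn from N(0, 2.5²) (5% of basal).
    ``neg_rate_prob``/``src_inversion_prob`` are per-well probabilities of
    planting a negative-measurement or an inverted (MR < BR) artifact.
    """

    groups: dict[str, GroupTruth] = field(default_factory=_default_groups)
    n_wells: int = 6
    n_plates: int = 2
    noise_sd: float = 1.0
    plate_offset_sd: float = 2.5
    neg_rate_prob: float = 0.0
    src_inversion_prob: float = 0.0
    norm_value: float = 1.0
    n_measurements: int = 14
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name, g in self.groups.items():
            try:
                g.validate()
            except ValueError as e:
                problems.append(f"group {name}: {e}")
        if self.noise_sd < 0:
            problems.append(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.plate_offset_sd < 0:
            problems.append(f"plate_offset_sd must be >= 0, got {self.plate_offset_sd}")
        for nm, p in (("neg_rate_prob", self.neg_rate_prob), ("src_inversion_prob", self.src_inversion_prob)):
            if not (0 <= p <= 1):
                problems.append(f"{nm} must be in [0, 1], got {p}")
        if self.norm_value <= 0:
            problems.append(f"norm_value must be > 0, got {self.norm_value}")
        if self.n_wells < 1 or self.n_plates < 1:
            problems.append("n_wells and n_plates must be >= 1")
        if self.n_measurements not in (12, 14):
            problems.append(f"n_measurements must be 12 or 14, got {self.n_measurements}")
        if problems:
            raise ValueError("invalid SynthSpec: " + "; ".join(problems))


_COORDS = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]


def _phase_levels(truth: GroupTruth, regime) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free normalized OCR/ECAR trace for one group."""
    ocr = np.empty(regime.total)
    ecar = np.empty(regime.total)
    ocr_level = {
        "basal": truth.nmitor + truth.br,
        "post_oligomycin": truth.nmitor + truth.pl,
        "post_FCCP": truth.nmitor + truth.mr,
        "post_antimycin_rotenone": truth.nmitor,
    }
    ecar_level = {
        "basal": truth.ecar_basal,
        "post_oligomycin": truth.ecar_postoligo,
        "post_FCCP": truth.ecar_postoligo,
        "post_antimycin_rotenone": truth.ecar_postoligo,
    }
    for i in range(1, regime.total + 1):
        phase = regime.phase_of(i).value
        ocr[i - 1] = ocr_level[phase]
        ecar[i - 1] = ecar_level[phase]
    return ocr, ecar


def simulate_tables(
    spec: SynthSpec,
) -> tuple[list[RateTable], dict]:
    """Generate one :class:`RateTable` per plate plus a ground-truth record.

    Per well, the normalized trace is the group's phase levels plus the
    plate's additive offset plus N(0, noise_sd²) per measurement; the
    stored (pre-normalization) rates are the normalized trace times the
    well's norm value, so the analysis pipeline recovers the normalized
    trace exactly.  Artifacts are planted after noise.  The truth record
    carries the per-group parameters, plate offsets, and the planted list.
    """
    spec.validate()
    regime = resolve_regime(spec.n_measurements)
    rng = np.random.default_rng(spec.seed)
    offsets = rng.normal(0.0, spec.plate_offset_sd, size=spec.n_plates)

    tables: list[RateTable] = []
    planted: list[tuple[str, str]] = []
    for p in range(spec.n_plates):
        wells: list[Well] = []
        coord_iter = iter(_COORDS)
        for gname, truth in spec.groups.items():
            ocr_level, ecar_level = _phase_levels(truth, regime)
            for _ in range(spec.n_wells):
                coord = next(coord_iter)
                ocr = ocr_level + offsets[p] + rng.normal(0.0, spec.noise_sd, regime.total)
                ecar = ecar_level + rng.normal(0.0, spec.noise_sd, regime.total)
                wells.append(
                    Well(
                        well_id=f"plate{p + 1}:{coord}",
                        group=gname,
                        norm_value=spec.norm_value,
                        ocr=ocr * spec.norm_value,
                        ecar=ecar * spec.norm_value,
                    )
                )
        table = RateTable(wells=wells, regime_total=regime.total, source_files=[f"plate{p + 1}"])
        table, plate_planted = inject_artifacts(table, spec, rng=rng)
        planted.extend(plate_planted)
        tables.append(table)

    truth_record = {
        "seed": spec.seed,
        "plate_offsets": [float(o) for o in offsets],
        "planted": planted,
        "groups": {
            name: {
                "nmitor": g.nmitor,
                "pl": g.pl,
                "br": g.br,
                "atp": g.atp,
                "mr": g.mr,
                "src": g.src,
                "ecar_basal": g.ecar_basal,
                "ecar_postoligo": g.ecar_postoligo,
            }
            for name, g in spec.groups.items()
        },
    }
    return tables, truth_record


def inject_artifacts(
    table: RateTable,
    spec: SynthSpec,
    rng: Optional[np.random.Generator] = None,
) -> tuple[RateTable, list[tuple[str, str]]]:
    """Plant QC violations into a table; returns (table, planted list).

    Each well is independently selected with probability ``neg_rate_prob``
    to have one measurement's OCR or ECAR negated, else with probability
    ``src_inversion_prob`` to have its FCCP-phase values suppressed below
    the basal level so spare respiratory capacity goes negative.  The
    planted list records ``(well_id, mode)``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    regime = resolve_regime(table.regime_total)
    planted: list[tuple[str, str]] = []
    for w in table.wells:
        u = rng.uniform()
        if u < spec.neg_rate_prob:
            j = int(rng.integers(0, regime.total))
            which = "ocr" if rng.uniform() < 0.5 else "ecar"
            arr = w.ocr if which == "ocr" else w.ecar
            arr[j] = -abs(arr[j]) - 1.0  # strictly negative even if noise crossed zero
            planted.append((w.well_id, "negative_rate"))
        elif u < spec.neg_rate_prob + spec.src_inversion_prob:
            basal_mean = float(np.mean(w.values_at(regime.basal_stat_idx, "ocr")))
            floor = float(np.median(w.values_at(regime.antrot_idx, "ocr")))
            # pin the FCCP plateau halfway between floor and basal: MR < BR
            level = floor + 0.5 * (basal_mean - floor)
            for idx in regime.fccp_idx:
                w.ocr[idx - 1] = level
            planted.append((w.well_id, "negative_SRC"))
    return table, planted


def simulate_plate(
    spec: SynthSpec, out_dir: PathLike
) -> tuple[list[Path], Path]:
    """Write one Rate CSV per simulated plate plus a ground-truth sidecar.

    Files are ``plate<k>.csv`` in ``out_dir``; the sidecar ``truth.txt`` is
    key=value text recording the seed, plate offsets, per-group parameters
    and planted artifacts.  Output is byte-identical for a fixed spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables, truth = simulate_tables(spec)
    paths = []
    for p, table in enumerate(tables, start=1):
        paths.append(write_rate_csv(table, out_dir / f"plate{p}.csv"))
    lines = [f"seed={truth['seed']}"]
    for p, off in enumerate(truth["plate_offsets"], start=1):
        lines.append(f"plate{p}_offset={off!r}")
    for name, g in truth["groups"].items():
        for key, val in g.items():
            lines.append(f"group.{name}.{key}={val!r}")
    for well_id, mode in truth["planted"]:
        lines.append(f"planted.{well_id}={mode}")
    truth_path = out_dir / "truth.txt"
    truth_path.write_text("\n".join(lines) + "\n")
    return paths, truth_path
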