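"""Reading Rate-format plate exports and writing the two result reports.

The input is the "Rate" tab of an extracellular-flux assay export saved as
CSV — one row per well × measurement — with a normalization column added by
the investigator (cell number, total protein, ...; "0" marks background
wells, blank cells are treated as 0).  Output is a pair of tab-delimited
text reports: per-well values and per-group pooled curves/parameters.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import GroupProfile, MetabolicParams, RateTable, Regime, Well

__all__ = [
    "parse_rate_table",
    "write_rate_csv",
    "write_wells_report",
    "write_groups_report",
    "RateParseError",
    "WellResult",
    "GroupResult",
]

PathLike = Union[str, Path]

REQUIRED_COLUMNS = ("well", "group", "measurement", "ocr", "ecar", "norm")


class RateParseError(ValueError):
    """Fatal problem in a Rate CSV: the analysis cannot proceed."""


def _resolve_columns(df: pd.DataFrame, path: PathLike) -> dict[str, str]:
    lower = {c.strip().lower(): c for c in df.columns}
    mapping = {}
    for name in REQUIRED_COLUMNS:
        if name not in lower:
            raise RateParseError(
                f"{path}: required column {name!r} not found (have: {list(df.columns)}); "
                "the analysis will not run without well, group, measurement index, "
                "OCR, ECAR and normalization columns"
            )
        mapping[name] = lower[name]
    return mapping


def _to_float(raw: str, path: PathLike, row: int, column: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise RateParseError(
            f"{path} row {row}: cannot parse {column} value {raw!r} as a number"
        ) from None


def parse_rate_table(
    paths: Sequence[PathLike], n_measurements: int = 14
) -> RateTable:
    """Read one or more Rate CSV files into a single :class:`RateTable`.

    Each well must have exactly ``n_measurements`` rows (14 by default, 12
    for the short regime).  Well ids are namespaced by source file stem so
    wells from different plates never collide.  Background wells (norm
    entry "0") and blank-norm wells are retained, flagged, and left for QC
    to exclude.

    Raises :class:`RateParseError` for a missing normalization column, a
    well with the wrong number of measurements, an unparseable numeric
    cell, or inconsistent group/norm entries within a well.
    """
    if not paths:
        raise RateParseError("no input files given")
    wells: list[Well] = []
    sources: list[str] = []
    for path in paths:
        sources.append(str(path))
        df = pd.read_csv(path, dtype=str, keep_default_na=False, skip_blank_lines=True)
        cols = _resolve_columns(df, path)
        stem = Path(path).stem
        # preserve first-appearance well order for deterministic output
        order: dict[str, list[int]] = {}
        for i in df.index:
            coord = df.at[i, cols["well"]].strip()
            if not coord:
                raise RateParseError(f"{path} row {i + 2}: empty well id")
            order.setdefault(coord, []).append(i)
        for coord, rows in order.items():
            well_id = f"{stem}:{coord}"
            if len(rows) != n_measurements:
                raise RateParseError(
                    f"{path}: well {coord} has {len(rows)} measurement rows, "
                    f"expected {n_measurements}"
                )
            groups = {df.at[i, cols["group"]].strip() for i in rows}
            if len(groups) != 1:
                raise RateParseError(
                    f"{path}: well {coord} has conflicting group labels {sorted(groups)}"
                )
            group = groups.pop()
            norm_raw = {df.at[i, cols["norm"]].strip() for i in rows}
            if len(norm_raw) != 1:
                raise RateParseError(
                    f"{path}: well {coord} has conflicting normalization entries "
                    f"{sorted(norm_raw)}"
                )
            raw = norm_raw.pop()
            norm_missing = raw == ""
            norm_value = 0.0 if norm_missing else _to_float(raw, path, rows[0] + 2, "norm")
            if norm_value < 0:
                raise RateParseError(
                    f"{path}: well {coord} has negative normalization value {norm_value}"
                )
            if not group and norm_value > 0:
                raise RateParseError(
                    f"{path}: well {coord} has a normalization value but no group label"
                )
            ocr = np.empty(n_measurements)
            ecar = np.empty(n_measurements)
            seen = np.zeros(n_measurements, dtype=bool)
            for i in rows:
                rowno = i + 2  # 1-based, counting the header line
                m = _to_float(df.at[i, cols["measurement"]], path, rowno, "measurement")
                idx = int(m)
                if idx != m or not (1 <= idx <= n_measurements):
                    raise RateParseError(
                        f"{path} row {rowno}: measurement index {m!r} outside "
                        f"1..{n_measurements} for well {coord}"
                    )
                if seen[idx - 1]:
                    raise RateParseError(
                        f"{path}: well {coord} has duplicate measurement index {idx}"
                    )
                seen[idx - 1] = True
                ocr[idx - 1] = _to_float(df.at[i, cols["ocr"]], path, rowno, "OCR")
                ecar[idx - 1] = _to_float(df.at[i, cols["ecar"]], path, rowno, "ECAR")
            wells.append(
                Well(
                    well_id=well_id,
                    group=group,
                    norm_value=norm_value,
                    ocr=ocr,
                    ecar=ecar,
                    is_background=(norm_value == 0 and not norm_missing),
                    norm_missing=norm_missing,
                )
            )
    return RateTable(wells=wells, regime_total=n_measurements, source_files=sources)


def write_rate_csv(table: RateTable, path: PathLike) -> Path:
    """Serialize a table back to the Rate CSV dialect.

    Numeric values are written with full ``repr`` precision so that a
    parse → write → parse round trip preserves every value exactly.
    """
    path = Path(path)
    lines = ["Well,Group,Measurement,OCR,ECAR,Norm"]
    for w in table.wells:
        coord = w.well_id.split(":", 1)[1] if ":" in w.well_id else w.well_id
        norm = "" if w.norm_missing else repr(float(w.norm_value))
        for i in range(table.regime_total):
            lines.append(
                f"{coord},{w.group},{i + 1},{float(w.ocr[i])!r},{float(w.ecar[i])!r},{norm}"
            )
    _atomic_write(path, "\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# result reports


class WellResult:
    """A surviving well with its normalized trace and per-well parameters."""

    def __init__(self, well: Well, params: MetabolicParams):
        self.well = well
        self.params = params


class GroupResult:
    """A group's pooled profile and parameters with propagated errors."""

    def __init__(self, profile: GroupProfile, params: MetabolicParams):
        self.profile = profile
        self.params = params


def _fmt(value: Optional[float]) -> str:
    return "NA" if value is None else f"{value:.6g}"


PARAM_FIELDS = ("nmitor", "pl", "br", "atp", "mr", "src", "ratio_basal", "ratio_max")


def _atomic_write(path: Path, text: str) -> None:
    """Write via a temp file + rename so a failed run leaves no partial file."""
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), prefix=path.name + ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_wells_report(
    well_results: Sequence[WellResult],
    output_root: str = "log",
    directory: PathLike = ".",
) -> Path:
    """Write ``wells_<root>.txt``: one row per surviving well.

    Columns: group, well, the normalized OCR then ECAR trace (ocr_1..N,
    ecar_1..N), then nmitor, pl, br, atp, mr, src, ratio_basal, ratio_max.
    Ratios of ratio-excluded wells print as NA.  Numbers use %.6g.
    """
    path = Path(directory) / f"wells_{output_root}.txt"
    if well_results:
        n = well_results[0].well.n_measurements
    else:
        n = 0
    header = (
        ["group", "well"]
        + [f"ocr_{i + 1}" for i in range(n)]
        + [f"ecar_{i + 1}" for i in range(n)]
        + list(PARAM_FIELDS)
    )
    lines = ["\t".join(header)]
    for res in well_results:
        w, p = res.well, res.params
        fields = [w.group, w.well_id]
        fields += [_fmt(float(v)) for v in w.ocr]
        fields += [_fmt(float(v)) for v in w.ecar]
        fields += [_fmt(getattr(p, f)) for f in PARAM_FIELDS]
        lines.append("\t".join(fields))
    _atomic_write(path, "\n".join(lines) + "\n")
    return path


def write_groups_report(
    group_results: Sequence[GroupResult],
    output_root: str = "log",
    directory: PathLike = ".",
    qc_summary: Optional[str] = None,
) -> Path:
    """Write ``groups_<root>.txt``: per group, the median measurement curve
    with standard errors and the metabolic parameters with propagated error.

    Each group is a block: a header line, a curve table (measurement, OCR
    median ± SE, ECAR median ± SE), and a parameter table (value, error).
    Single-well groups print zero errors and are marked degenerate.
    """
    path = Path(directory) / f"groups_{output_root}.txt"
    lines: list[str] = []
    if qc_summary:
        lines.append(f"# qc\t{qc_summary}")
    for res in group_results:
        prof, p = res.profile, res.params
        tag = "\tdegenerate_errors" if p.degenerate_error else ""
        lines.append(f"# group\t{prof.group}\tn_wells\t{prof.n_wells}{tag}")
        lines.append("measurement\tocr_median\tocr_se\tecar_median\tecar_se")
        for j in range(len(prof.curve_ocr)):
            lines.append(
                "\t".join(
                    [
                        str(j + 1),
                        _fmt(float(prof.curve_ocr[j])),
                        _fmt(float(prof.se_ocr[j])),
                        _fmt(float(prof.curve_ecar[j])),
                        _fmt(float(prof.se_ecar[j])),
                    ]
                )
            )
        lines.append("parameter\tvalue\terror")
        for f in PARAM_FIELDS:
            lines.append(
                "\t".join([f, _fmt(getattr(p, f)), _fmt(getattr(p, "err_" + f))])
            )
    _atomic_write(path, "\n".join(lines) + "\n")
    return path
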