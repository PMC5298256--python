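from __future__ import annotations

import numpy as np
import pytest

from mitoflux import RateTable, Well, resolve_regime

# the worked example trace: basal 58..62, post-oligomycin 24..26,
# post-FCCP 95/100/98, post-antimycin/rotenone 10/12/11
EXAMPLE_OCR = [58, 59, 60, 61, 62, 24, 25, 26, 95, 100, 98, 10, 12, 11]
EXAMPLE_PARAMS = {"nmitor": 11, "pl": 14, "br": 50, "atp": 36, "mr": 89, "src": 39}


def make_well(
    ocr,
    ecar=None,
    well_id="plate:A1",
    group="G1",
    norm=1.0,
    **kwargs,
) -> Well:
    ocr = np.asarray(ocr, dtype=float)
    if ecar is None:
        ecar = np.full_like(ocr, 10.0)
    return Well(
        well_id=well_id,
        group=group,
        norm_value=norm,
        ocr=ocr,
        ecar=np.asarray(ecar, dtype=float),
        **kwargs,
    )


def make_table(wells) -> RateTable:
    n = wells[0].n_measurements
    return RateTable(wells=list(wells), regime_total=n, source_files=["synthetic"])


@pytest.fixture
def regime14():
    return resolve_regime(14)


@pytest.fixture
def regime12():
    return resolve_regime(12)


@pytest.fixture
def example_well() -> Well:
    return make_well(EXAMPLE_OCR)


def write_rate_csv_text(path, wells, n_measurements=14, norm_overrides=None):
    """Write a Rate CSV fixture from (well, group, norm, ocr, ecar) specs."""
    lines = ["Well,Group,Measurement,OCR,ECAR,Norm"]
    for coord, group, norm, ocr, ecar in wells:
        for i in range(n_measurements):
            lines.append(f"{coord},{group},{i + 1},{ocr[i]},{ecar[i]},{norm}")
    path.write_text("\n".join(lines) + "\n")
    return path
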