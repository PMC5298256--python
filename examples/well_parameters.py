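"""Compute the six stress-test parameters for a single well.

A mitochondrial stress test trace has four phases: basal respiration, then
responses to oligomycin, FCCP, and antimycin A + rotenone.  The parameters
decompose oxygen consumption into its sources.
"""

import numpy as np

from mitoflux import Well, resolve_regime, well_parameters, well_ratios

# 14-measurement trace (5-3-3-3): basal ~60, post-oligomycin ~25,
# post-FCCP ~95-100, post-antimycin/rotenone ~11
ocr = [58, 59, 60, 61, 62, 24, 25, 26, 95, 100, 98, 10, 12, 11]
ecar = [10] * 5 + [10] * 3 + [8, 8, 10] + [10] * 3

well = Well(
    well_id="demo:A1",
    group="resting",
    norm_value=1.0,  # rates already per 100k cells
    ocr=np.array(ocr, float),
    ecar=np.array(ecar, float),
)

regime = resolve_regime(14)
p = well_parameters(well, regime)
rb, rm = well_ratios(well, regime)

print(f"non-mitochondrial respiration (nMitoR): {p.nmitor:g}")
print(f"proton leak (PL):                       {p.pl:g}")
print(f"basal respiration (BR):                 {p.br:g}")
print(f"ATP-linked respiration (ATP = BR-PL):   {p.atp:g}")
print(f"maximal respiration (MR):               {p.mr:g}")
print(f"spare respiratory capacity (SRC=MR-BR): {p.src:g}")
print(f"OCR:ECAR at basal respiration:          {rb:g}")
print(f"OCR:ECAR at maximal respiration:        {rm:g}")
print()
print("All rates are above the antimycin/rotenone floor (nMitoR), in the")
print("units of the normalized OCR; the ratios are dimensionless and rise")
print("when cells rely on oxidative phosphorylation over glycolysis.")
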