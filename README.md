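# mitoflux

Automated analysis of extracellular-flux (XF) **mitochondrial stress test**
plates: per-well normalization, objective quality control, cross-plate
baselining, outlier-resistant replicate pooling, metabolic parameter
calculation, and standard-error propagation — plus a synthetic plate
simulator with known ground truth for validating every stage.

## The problem

Plate-based XF instruments measure the oxygen consumption rate (OCR,
pmol O₂/min) and extracellular acidification rate (ECAR, mpH/min) of live
cells while three compounds are injected in sequence: **oligomycin**
(ATP-synthase inhibitor), **FCCP** (uncoupler), and **antimycin A +
rotenone** (complex III/I inhibitors). The resulting four-phase trace
decomposes respiration into its sources — but combining replicate wells
across several plates, rejecting physically impossible readings, and
attaching honest uncertainties to derived parameters is tedious and
subjective when done by hand. `mitoflux` automates it for studies (e.g.
human immune-cell bioenergetics) that spread limited samples over many
96-well plates.

## The model

For a well's OCR measurements `M1..M14` (default 5-3-3-3 layout: five
basal readings, three after each injection; a 12-measurement 3-3-3-3
layout is also supported):

```
nMitoR = median(M12, M13, M14)          non-mitochondrial respiration
PL     = median(M6, M7, M8) − nMitoR    proton leak
BR     = mean(M3, M4, M5)   − nMitoR    basal respiration
ATP    = BR − PL                        ATP-linked respiration
MR     = max(M9, M10, M11)  − nMitoR    maximal respiration
SRC    = MR − BR                        spare respiratory capacity
```

OCR:ECAR ratios (oxidative vs glycolytic reliance) are computed at basal
(mean OCR ÷ mean ECAR over `M3..M5`) and maximal respiration (highest
post-FCCP OCR ÷ its own ECAR), only where all involved values are
positive.

The pipeline: rates are divided by a per-well normalization value (cell
number, protein, ...); wells with any negative OCR/ECAR or negative SRC
are discarded whole; each surviving well is baselined by subtracting its
own nMitoR (the least group-dependent parameter) so additive
plate-to-plate offsets cancel; replicates pool by the per-measurement
**median**; group errors are standard errors (σ/√n) propagated by
root-sum-square for sums/differences and relative root-sum-square for
ratios, with three-operand medians carrying the chosen operand's error.

## Worked example

```sh
python examples/well_parameters.py
```

prints, for the trace `58 59 60 61 62 | 24 25 26 | 95 100 98 | 10 12 11`:

```
non-mitochondrial respiration (nMitoR): 11
proton leak (PL):                       14
basal respiration (BR):                 50
ATP-linked respiration (ATP = BR-PL):   36
maximal respiration (MR):               89
spare respiratory capacity (SRC=MR-BR): 39
OCR:ECAR at basal respiration:          6.1
OCR:ECAR at maximal respiration:        12.5
```

i.e. of the basal 50 units of mitochondrial respiration, 36 drive ATP
synthesis and 14 leak across the membrane; FCCP reveals 39 units of spare
capacity. `examples/simulate_and_analyze.py` runs the full pipeline on
simulated plates and compares recovered parameters against ground truth;
`examples/error_propagation.py` checks the error rules by Monte Carlo.

## Command line

```sh
mitoflux simulate --seed 7 --outdir sim/        # Rate CSVs + truth sidecar
mitoflux analyze sim/plate1.csv sim/plate2.csv  # -> wells_log.txt, groups_log.txt
mitoflux analyze data/*.csv --measurements 12 --output run7 --grouping biological
```

`analyze` reads Rate-format CSV exports (columns Well, Group, Measurement,
OCR, ECAR, Norm; norm `0` marks background wells) and writes two
tab-delimited reports: per-well values and per-group median curves plus
parameters ± propagated error. Every QC removal is logged with its
reason.

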