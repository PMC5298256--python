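# Methods

## Assay and data model

A mitochondrial stress test measures each well's oxygen consumption rate
(OCR) and extracellular acidification rate (ECAR) over a fixed sequence of
measurements spanning four injection phases: basal, post-oligomycin,
post-FCCP, and post-antimycin A/rotenone. Two measurement regimes are
supported: 14 measurements laid out 5-3-3-3 (the default) and 12 laid out
3-3-3-3. Measurement indices are 1-based (`M1..M14`) throughout.

Input is the "Rate"-style CSV export — one row per well × measurement —
with required columns (case-insensitive) `Well, Group, Measurement, OCR,
ECAR, Norm`; extra columns (Time, PER, pH, ...) are ignored. The `Norm`
column holds the per-well normalization quantity (cell number in 100k, µg
protein, ...). An explicit `0` marks a background well; a blank cell is
treated as 0 but recorded separately (`zero_normalization` vs
`background` in the QC report), since a blank usually means a forgotten
entry rather than a deliberate blank well. Multiple plate files
concatenate into one table; well ids are namespaced by file stem so
plates never collide.

## Pipeline

1. **Normalization.** Every OCR and ECAR value is divided by the well's
   norm value; all downstream computation uses normalized rates.
2. **Screening.** A well is discarded whole (never repaired) if any OCR
   or ECAR measurement is below zero (physically impossible), or if its
   spare respiratory capacity is negative (maximal respiration cannot be
   below basal). The negative-rate rule is checked first. Both rules are
   scale-invariant, so screening order relative to normalization is
   immaterial; we normalize first. Exactly-zero values pass screening
   ("below zero") but exclude a well from ratio calculations (which
   require values "above zero").
3. **Baselining.** Each surviving well's own nMitoR — the median of its
   post-antimycin/rotenone OCR — is subtracted from its OCR trace.
   nMitoR is the least group-dependent parameter on a plate, so this
   anchors every well's floor at zero and cancels additive
   plate-to-plate offsets before pooling. Subtraction (rather than
   rescaling) is the unique convention under which all derived
   parameters are invariant, since every formula already subtracts
   nMitoR. ECAR is not baselined. Baselining is idempotent; the
   pre-baseline nMitoR is retained for reporting.
4. **Pooling.** Replicates pool per group by the per-measurement
   **median** (resistant to the outliers and sensor glitches that would
   drag a mean), with the standard error across replicates as the
   per-measurement error. An even replicate count takes the mean of the
   two central values. The well supplying each median (closest to it;
   ties by lexicographic well id) is recorded for ratio lookup.
5. **Parameters.** The well-level formulas (README) are applied to the
   group median curve. The group's reported nMitoR is the median of the
   member wells' pre-baseline floors — the baselined curve's own floor is
   ≈0 by construction and would carry no information.

Technical vs biological replication is purely a relabeling: `analyze
--grouping biological` collapses group labels of the form
`<biological>/<technical>` to their prefix before pooling; well-level
results never change.

## Error handling

Per-measurement group errors are standard errors of the mean, σ/√n with
the sample (n−1) standard deviation. (A σ/n² variant is available via
`se_formula="n_squared"` for strict replication of an alternative printed
convention; σ/√n is the default because the quantity is named and used as
a standard error.) Derived parameters propagate errors by the standard
rules: ε(a±b) = √(εa²+εb²); ε(a/b) = |a/b|·√((εa/a)²+(εb/b)²); the error
of a mean of k measurements is √(Σεᵢ²)/k. Medians and maxima over three
operands are order statistics, not smooth combinations, so they carry
**the error of the operand chosen** without propagation; ties in the
post-FCCP argmax resolve to the earliest measurement.

Group OCR:ECAR ratios use only ratio-eligible wells (all involved values
positive). The basal ratio is the mean over the last basal measurements
of the median-OCR well's ratio at each measurement; its error combines
the per-measurement quotient-rule errors by the mean rule. The maximal
ratio is the median-well ratio at the post-FCCP measurement with the
highest median OCR, with a quotient-rule error from that measurement's
OCR/ECAR standard errors. The quotient rule is a first-order
approximation, accurate to a few percent for relative errors up to ~10%
(verified against Monte Carlo in the test suite).

Single-well groups report all errors as 0 and are flagged `degenerate`
rather than omitted: the estimate is still data, only its uncertainty is
unknown.

## Synthetic plates

The simulator models the trace as phase levels plus noise — no drug
kinetics or oxygen diffusion. Per well, the normalized OCR mean is
`nMitoR + {BR, PL, MR, 0}` for the four phases; ECAR has a basal level and
a higher post-oligomycin level (glycolytic compensation) that persists for
the remaining phases. The FCCP phase is a flat plateau at MR, the
simplest shape that exercises the max-of-three rule. To each well's trace
are added an **additive per-plate offset** (consistent with subtractive
baselining) drawn from N(0, `plate_offset_sd`²) and i.i.d. Gaussian
measurement noise N(0, `noise_sd`²), matching the normality expected of
replicate rates. Stored pre-normalization rates are the normalized trace
× the well's norm value.

Defaults describe a typical activated immune-cell experiment normalized
per 100k cells: two groups (nMitoR/PL/BR/MR of 10/15/50/90 and
8/10/35/60; ECAR 10→20 and 14→26), 6 replicate wells per group, 2 plates,
`noise_sd` 1.0 (2% of the basal OCR of 50), `plate_offset_sd` 2.5 (5% of
basal). Artifact plumbing plants, per selected well, either one negated
measurement or an FCCP plateau pinned halfway between the well's own
floor and basal level (forcing SRC < 0); planted wells are recorded so QC
can be checked exactly.

What the simulator does **not** emulate: transient-phase drift within a
phase, heteroscedastic or correlated noise, edge-well effects, partial
drug response, or non-Gaussian outliers. Passing recovery tests therefore
demonstrates correctness of the analysis arithmetic and the
batch-offset/QC machinery, not robustness to every failure mode of real
instruments.

## Numerical choices and limitations

- Parameters satisfy ATP = BR − PL and SRC = MR − BR identically (enforced
  by the result type). Baselined vs un-baselined parameter equality holds
  to machine precision (last-ulp rounding of shifted means), not bitwise.
- Reports print with `%.6g`; files are written atomically (temp +
  rename) and are byte-deterministic for fixed input and version.
- An empty post-QC result writes header-only reports with a warning
  rather than failing, so batch runs survive one bad plate.
- Group parameters may alternatively be computed as the median of
  per-well parameters (`group_parameters_from_wells`); the default is
  parameters-of-the-median-curve. The two differ under replicate
  heterogeneity; the alternative is exposed for sensitivity analysis.
- No between-group inference (t-tests, ANOVA, AUC) and no plotting:
  scope ends at per-group parameters with errors.

## Validation problem sizes

The test suite validates against an independent brute-force
implementation on 100 randomized instances of ≤5 wells × 14 measurements;
QC exactness on a 96-well plate with 11 planted violations;
error-propagation rules against 10⁵-draw Monte Carlo; and parameter
recovery (BR/MR/SRC within 10% of truth in ≥95% of runs) over 200 seeded
simulated experiments at the default study conditions. The whole suite
runs in a few seconds on one CPU.
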