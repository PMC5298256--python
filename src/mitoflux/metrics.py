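"""Metabolic parameter calculations, replicate pooling, and error handling.

Well-level parameters are computed from the well's own OCR trace; group-level
parameters are computed from the per-measurement median curve across replicate
wells, with standard errors propagated by the usual rules for sums and
quotients.  Medians over three operands carry the error of the chosen operand
rather than a propagated term, because a three-point median is an order
statistic, not a smooth combination.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .model import GroupProfile, MetabolicParams, Regime, Well

__all__ = [
    "resolve_regime",
    "well_parameters",
    "well_ratios",
    "ratio_eligible",
    "group_curve",
    "group_parameters",
    "group_parameters_from_wells",
    "standard_error",
    "propagate_sum_error",
    "propagate_ratio_error",
]

REGIME_14 = Regime(
    total=14,
    basal_idx=(1, 2, 3, 4, 5),
    oligo_idx=(6, 7, 8),
    fccp_idx=(9, 10, 11),
    antrot_idx=(12, 13, 14),
    basal_stat_idx=(3, 4, 5),
)

REGIME_12 = Regime(
    total=12,
    basal_idx=(1, 2, 3),
    oligo_idx=(4, 5, 6),
    fccp_idx=(7, 8, 9),
    antrot_idx=(10, 11, 12),
    basal_stat_idx=(2, 3),
)


class UnsupportedRegimeError(ValueError):
    """Raised for measurement counts other than 12 or 14."""


def resolve_regime(n_measurements: int) -> Regime:
    """Return the phase layout for a 14- (5-3-3-3) or 12- (3-3-3-3) run."""
    if n_measurements == 14:
        return REGIME_14
    if n_measurements == 12:
        return REGIME_12
    raise UnsupportedRegimeError(
        f"unsupported measurement count {n_measurements}: only 14 (5-3-3-3) "
        f"and 12 (3-3-3-3) regimes are implemented"
    )


def _median3_choice(values: np.ndarray) -> tuple[float, int]:
    """Median of a small operand set plus the 0-based position chosen.

    For an odd count the chosen operand is the middle order statistic; ties
    are broken by the earliest position.  (Even counts do not occur in the
    regime layouts but are handled as the lower-middle operand for safety.)
    """
    order = np.argsort(values, kind="stable")
    mid = order[(len(values) - 1) // 2]
    return float(np.median(values)), int(mid)


def well_parameters(well: Well, regime: Regime) -> MetabolicParams:
    """Compute the six metabolic parameters from one well's OCR trace.

    nMitoR = median of the post-antimycin/rotenone measurements;
    PL = median post-oligomycin − nMitoR; BR = mean of the last basal
    measurements − nMitoR; ATP = BR − PL; MR = max post-FCCP − nMitoR;
    SRC = MR − BR.  Because every parameter except nMitoR subtracts the
    well's own nMitoR, the results are identical on baselined and
    un-baselined traces.
    """
    ocr = well.ocr
    return _params_from_curve(ocr, regime)


def _params_from_curve(ocr: np.ndarray, regime: Regime) -> MetabolicParams:
    at = lambda idx: ocr[np.asarray(idx, dtype=int) - 1]
    nmitor = float(np.median(at(regime.antrot_idx)))
    pl = float(np.median(at(regime.oligo_idx))) - nmitor
    br = float(np.mean(at(regime.basal_stat_idx))) - nmitor
    mr = float(np.max(at(regime.fccp_idx))) - nmitor
    return MetabolicParams(nmitor=nmitor, pl=pl, br=br, atp=br - pl, mr=mr, src=mr - br)


def ratio_eligible(well: Well, regime: Regime) -> bool:
    """Whether every OCR and ECAR value entering a ratio is strictly positive.

    The basal ratio involves the last basal measurements; the maximal ratio
    involves the post-FCCP measurements.  A zero or negative value at any of
    these excludes the well from ratio calculations entirely.
    """
    idx = tuple(regime.basal_stat_idx) + tuple(regime.fccp_idx)
    return bool(
        np.all(well.values_at(idx, "ocr") > 0) and np.all(well.values_at(idx, "ecar") > 0)
    )


def well_ratios(well: Well, regime: Regime) -> tuple[Optional[float], Optional[float]]:
    """OCR:ECAR ratios at basal and maximal respiration for one well.

    Basal ratio: mean OCR over the last basal measurements divided by the
    mean ECAR over the same measurements.  Maximal ratio: the highest
    post-FCCP OCR divided by the ECAR of that same measurement.  Both are
    computed on normalized, un-baselined values and only when every involved
    value is above zero; otherwise ``(None, None)``.
    """
    if not ratio_eligible(well, regime):
        return None, None
    basal_ocr = well.values_at(regime.basal_stat_idx, "ocr")
    basal_ecar = well.values_at(regime.basal_stat_idx, "ecar")
    ratio_basal = float(np.mean(basal_ocr) / np.mean(basal_ecar))
    fccp_ocr = well.values_at(regime.fccp_idx, "ocr")
    k = int(np.argmax(fccp_ocr))  # earliest index wins ties
    idx = regime.fccp_idx[k]
    ratio_max = float(well.ocr[idx - 1] / well.ecar[idx - 1])
    return ratio_basal, ratio_max


def standard_error(values: Sequence[float], formula: str = "sqrt_n") -> float:
    """Standard error of the mean of replicate values.

    Sample (n−1) standard deviation divided by √n.  A single replicate has
    no dispersion estimate: the error is reported as 0 (callers flag such
    groups as degenerate).  ``formula="n_squared"`` divides σ by n² instead,
    for strict replication of the alternative printed convention.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("standard_error of an empty sample is undefined")
    n = vals.size
    if n == 1:
        return 0.0
    sd = float(np.std(vals, ddof=1))
    if formula == "sqrt_n":
        return sd / math.sqrt(n)
    if formula == "n_squared":
        return sd / n**2
    raise ValueError(f"unknown SE formula {formula!r}")


def propagate_sum_error(ea: float, eb: float) -> float:
    """Error of a sum or difference: root-sum-square of the operand errors."""
    return math.hypot(ea, eb)


def propagate_ratio_error(a: float, ea: float, b: float, eb: float) -> float:
    """Error of the quotient a/b, reported on the ratio's scale.

    Relative errors combine in quadrature: ε = |a/b| · √((εa/a)² + (εb/b)²).
    """
    if a == 0 or b == 0:
        raise ValueError("ratio error propagation requires non-zero values")
    rel = math.hypot(ea / a, eb / b)
    return abs(a / b) * rel


def _mean_error(errors: Sequence[float]) -> float:
    """Error of a mean of k measurements: √(Σε²)/k."""
    errs = np.asarray(errors, dtype=float)
    return float(np.sqrt(np.sum(errs**2)) / errs.size)


def group_curve(
    wells: Sequence[Well], regime: Regime, se_formula: str = "sqrt_n"
) -> GroupProfile:
    """Median measurement curve across replicate wells, with standard errors.

    For each measurement the OCR and ECAR medians across replicates are
    taken (the median resists outliers that would drag a mean), with the
    standard error of the replicate values as the per-measurement error.
    The well supplying each OCR median is recorded for ratio lookup: the
    well whose OCR is closest to the median, ties broken by lexicographic
    well id.
    """
    if not wells:
        raise ValueError("cannot build a group curve from an empty well list")
    groups = {w.group for w in wells}
    if len(groups) > 1:
        raise ValueError(f"group_curve received wells from multiple groups: {sorted(groups)}")
    n = len(wells)
    ocr = np.vstack([w.ocr for w in wells])
    ecar = np.vstack([w.ecar for w in wells])
    curve_ocr = np.median(ocr, axis=0)
    curve_ecar = np.median(ecar, axis=0)
    if n == 1:
        se_ocr = np.zeros(regime.total)
        se_ecar = np.zeros(regime.total)
    else:
        se_ocr = np.array([standard_error(ocr[:, j], se_formula) for j in range(regime.total)])
        se_ecar = np.array([standard_error(ecar[:, j], se_formula) for j in range(regime.total)])
    median_well_ids = []
    for j in range(regime.total):
        dist = np.abs(ocr[:, j] - curve_ocr[j])
        best = min(range(n), key=lambda i: (dist[i], wells[i].well_id))
        median_well_ids.append(wells[best].well_id)
    return GroupProfile(
        group=wells[0].group,
        n_wells=n,
        curve_ocr=curve_ocr,
        se_ocr=se_ocr,
        curve_ecar=curve_ecar,
        se_ecar=se_ecar,
        median_well_ids=median_well_ids,
        degenerate=(n == 1),
    )


def _median_term_error(curve: np.ndarray, se: np.ndarray, idx: Sequence[int]) -> float:
    """Error of a 3-point median term: the error of the operand chosen."""
    vals = curve[np.asarray(idx, dtype=int) - 1]
    _, pos = _median3_choice(vals)
    return float(se[idx[pos] - 1])


def group_parameters(
    profile: GroupProfile,
    regime: Regime,
    ratio_wells: Optional[Sequence[Well]] = None,
    se_formula: str = "sqrt_n",
) -> MetabolicParams:
    """Metabolic parameters of the group median curve, with propagated error.

    The six parameters apply the well-level formulas to the median OCR
    curve.  Errors: mean-based terms combine per-measurement standard
    errors as √(Σε²)/k; median- and max-based terms carry the error of the
    operand chosen; differences combine by root-sum-square.

    ``ratio_wells`` are the group's ratio-eligible, normalized,
    un-baselined wells.  The group basal ratio is the mean over the last
    basal measurements of the median-OCR well's ratio at each measurement;
    the maximal ratio is the median-well ratio at the post-FCCP measurement
    with the highest median OCR.  Ratio errors use the quotient rule on the
    chosen measurements' OCR/ECAR standard errors.
    """
    curve, se = profile.curve_ocr, profile.se_ocr
    params = _params_from_curve(curve, regime)

    err_nmitor = _median_term_error(curve, se, regime.antrot_idx)
    err_oligo_median = _median_term_error(curve, se, regime.oligo_idx)
    err_pl = propagate_sum_error(err_oligo_median, err_nmitor)
    basal_errs = se[np.asarray(regime.basal_stat_idx, dtype=int) - 1]
    err_br = propagate_sum_error(_mean_error(basal_errs), err_nmitor)
    err_atp = propagate_sum_error(err_br, err_pl)
    fccp_vals = curve[np.asarray(regime.fccp_idx, dtype=int) - 1]
    k_max = int(np.argmax(fccp_vals))  # earliest index wins ties
    err_mr = propagate_sum_error(float(se[regime.fccp_idx[k_max] - 1]), err_nmitor)
    err_src = propagate_sum_error(err_mr, err_br)

    ratio_basal = ratio_max = None
    err_ratio_basal = err_ratio_max = None
    if ratio_wells:
        ratio_basal, ratio_max, err_ratio_basal, err_ratio_max = _group_ratios(
            profile, regime, ratio_wells, se_formula
        )

    return MetabolicParams(
        nmitor=params.nmitor,
        pl=params.pl,
        br=params.br,
        atp=params.atp,
        mr=params.mr,
        src=params.src,
        ratio_basal=ratio_basal,
        ratio_max=ratio_max,
        err_nmitor=err_nmitor,
        err_pl=err_pl,
        err_br=err_br,
        err_atp=err_atp,
        err_mr=err_mr,
        err_src=err_src,
        err_ratio_basal=err_ratio_basal,
        err_ratio_max=err_ratio_max,
        degenerate_error=profile.degenerate,
    )


def _ratio_median_well(
    wells: Sequence[Well], j: int
) -> Well:
    """Well whose OCR at 1-based measurement ``j`` is closest to the median.

    The median here is over the ratio-eligible wells only, so the retained
    ratio always comes from a well with strictly positive values.
    """
    vals = np.array([w.ocr[j - 1] for w in wells])
    med = float(np.median(vals))
    dist = np.abs(vals - med)
    best = min(range(len(wells)), key=lambda i: (dist[i], wells[i].well_id))
    return wells[best]


def _group_ratios(
    profile: GroupProfile,
    regime: Regime,
    ratio_wells: Sequence[Well],
    se_formula: str,
) -> tuple[float, float, float, float]:
    ocr = np.vstack([w.ocr for w in ratio_wells])
    ecar = np.vstack([w.ecar for w in ratio_wells])

    # Basal: mean over the last basal measurements of the median-well ratios,
    # each ratio's error from the quotient rule on that measurement's SEs.
    ratios, errs = [], []
    for j in regime.basal_stat_idx:
        w = _ratio_median_well(ratio_wells, j)
        a, b = float(w.ocr[j - 1]), float(w.ecar[j - 1])
        ratios.append(a / b)
        ea = standard_error(ocr[:, j - 1], se_formula)
        eb = standard_error(ecar[:, j - 1], se_formula)
        errs.append(propagate_ratio_error(a, ea, b, eb))
    ratio_basal = float(np.mean(ratios))
    err_ratio_basal = _mean_error(errs)

    # Maximal: the ratio at the post-FCCP measurement with the highest
    # median OCR among eligible wells.
    fccp_medians = [float(np.median(ocr[:, j - 1])) for j in regime.fccp_idx]
    j_max = regime.fccp_idx[int(np.argmax(fccp_medians))]
    w = _ratio_median_well(ratio_wells, j_max)
    a, b = float(w.ocr[j_max - 1]), float(w.ecar[j_max - 1])
    ratio_max = a / b
    ea = standard_error(ocr[:, j_max - 1], se_formula)
    eb = standard_error(ecar[:, j_max - 1], se_formula)
    err_ratio_max = propagate_ratio_error(a, ea, b, eb)
    return ratio_basal, ratio_max, err_ratio_basal, err_ratio_max


def group_parameters_from_wells(wells: Sequence[Well], regime: Regime) -> MetabolicParams:
    """Alternative pooling: median of the per-well parameters.

    Instead of computing parameters from the median measurement curve
    (the default), take the median of each parameter across replicate
    wells.  The two agree when replicate traces are mutually consistent
    but can differ under heterogeneity; exposed for sensitivity checks.
    """
    if not wells:
        raise ValueError("no wells")
    per_well = [well_parameters(w, regime) for w in wells]
    med = lambda f: float(np.median([getattr(p, f) for p in per_well]))
    nmitor, pl, br, mr = med("nmitor"), med("pl"), med("br"), med("mr")
    return MetabolicParams(nmitor=nmitor, pl=pl, br=br, atp=br - pl, mr=mr, src=mr - br)
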