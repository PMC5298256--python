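"""Parameter formulas, pooling, and error-propagation arithmetic."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoflux import (
    MetabolicParams,
    group_curve,
    group_parameters,
    group_parameters_from_wells,
    propagate_ratio_error,
    propagate_sum_error,
    resolve_regime,
    standard_error,
    well_parameters,
    well_ratios,
)
from mitoflux.metrics import UnsupportedRegimeError

from tests.conftest import EXAMPLE_OCR, EXAMPLE_PARAMS, make_well
from tests.helpers_brute import LAYOUT_14, bf_group_params, bf_well_params


class TestResolveRegime:
    def test_14_is_5_3_3_3(self):
        r = resolve_regime(14)
        assert r.basal_idx == (1, 2, 3, 4, 5)
        assert r.oligo_idx == (6, 7, 8)
        assert r.fccp_idx == (9, 10, 11)
        assert r.antrot_idx == (12, 13, 14)
        assert r.basal_stat_idx == (3, 4, 5)

    def test_12_is_3_3_3_3(self):
        r = resolve_regime(12)
        assert r.basal_idx == (1, 2, 3)
        assert r.oligo_idx == (4, 5, 6)
        assert r.fccp_idx == (7, 8, 9)
        assert r.antrot_idx == (10, 11, 12)
        assert r.basal_stat_idx == (2, 3)

    @pytest.mark.parametrize("n", [0, 10, 13, 15])
    def test_other_counts_rejected(self, n):
        with pytest.raises(UnsupportedRegimeError):
            resolve_regime(n)


class TestWellParameters:
    def test_worked_example(self, regime14, example_well):
        p = well_parameters(example_well, regime14)
        for name, expected in EXAMPLE_PARAMS.items():
            assert getattr(p, name) == pytest.approx(expected, abs=1e-12)

    def test_constant_trace_has_only_nmitor(self, regime14):
        p = well_parameters(make_well([7.5] * 14), regime14)
        assert p.nmitor == 7.5
        assert p.pl == p.br == p.atp == p.mr == p.src == 0.0

    @given(shift=st.floats(-100, 100, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_shift_moves_only_nmitor(self, shift):
        regime14 = resolve_regime(14)
        base = well_parameters(make_well(EXAMPLE_OCR), regime14)
        shifted = well_parameters(
            make_well([v + shift for v in EXAMPLE_OCR]), regime14
        )
        assert shifted.nmitor == pytest.approx(base.nmitor + shift, abs=1e-9)
        for f in ("pl", "br", "atp", "mr", "src"):
            assert getattr(shifted, f) == pytest.approx(getattr(base, f), abs=1e-9)

    @given(
        ocr=st.lists(st.floats(1, 200), min_size=14, max_size=14),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_and_scales(self, ocr, scale):
        regime14 = resolve_regime(14)
        p = well_parameters(make_well(ocr), regime14)
        bf = bf_well_params(ocr, LAYOUT_14)
        for f in ("nmitor", "pl", "br", "atp", "mr", "src"):
            assert getattr(p, f) == pytest.approx(bf[f], rel=1e-12, abs=1e-12)
        ps = well_parameters(make_well([v * scale for v in ocr]), regime14)
        for f in ("nmitor", "pl", "br", "atp", "mr", "src"):
            assert getattr(ps, f) == pytest.approx(scale * bf[f], rel=1e-9, abs=1e-9)

    def test_identities_enforced_by_type(self):
        with pytest.raises(ValueError):
            MetabolicParams(nmitor=1, pl=1, br=2, atp=0, mr=3, src=1)


class TestWellRatios:
    def test_worked_example(self, regime14):
        ecar = [10] * 5 + [10] * 3 + [8, 8, 10] + [10] * 3
        w = make_well(EXAMPLE_OCR, ecar)
        rb, rm = well_ratios(w, regime14)
        assert rb == pytest.approx((60 + 61 + 62) / 30)  # 6.1
        assert rm == pytest.approx(100 / 8)  # 12.5, ECAR at the max-OCR point

    def test_identical_traces_give_unit_ratios(self, regime14):
        w = make_well(EXAMPLE_OCR, EXAMPLE_OCR)
        rb, rm = well_ratios(w, regime14)
        assert rb == pytest.approx(1.0)
        assert rm == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_involved_value_excludes(self, regime14, bad):
        ecar = [10.0] * 14
        ecar[3] = bad  # measurement 4, inside the basal-statistics window
        w = make_well(EXAMPLE_OCR, ecar)
        assert well_ratios(w, regime14) == (None, None)

    def test_nonpositive_outside_window_is_ignored(self, regime14):
        ecar = [10.0] * 14
        ecar[0] = 0.0  # measurement 1 enters no ratio
        w = make_well(EXAMPLE_OCR, ecar)
        rb, rm = well_ratios(w, regime14)
        assert rb is not None and rm is not None


class TestStandardError:
    def test_three_values(self):
        assert standard_error([2, 4, 6]) == pytest.approx(2 / math.sqrt(3))

    def test_constant_sample_and_singleton(self):
        assert standard_error([5, 5, 5]) == 0.0
        assert standard_error([5]) == 0.0

    def test_alternative_convention_divides_by_n_squared(self):
        assert standard_error([2, 4, 6], "n_squared") == pytest.approx(2 / 9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            standard_error([])


class TestErrorPropagation:
    def test_sum_rule_3_4_5(self):
        assert propagate_sum_error(3, 4) == pytest.approx(5)
        assert propagate_sum_error(0, 2.5) == 2.5
        assert propagate_sum_error(4, 3) == propagate_sum_error(3, 4)

    def test_ratio_rule_absolute_scale(self):
        # a/b = 10, relative error sqrt(0.01 + 0.01)
        err = propagate_ratio_error(100, 10, 10, 1)
        assert err == pytest.approx(10 * math.sqrt(0.02))

    def test_ratio_rule_zero_denominator_error(self):
        assert propagate_ratio_error(100, 10, 10, 0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            propagate_ratio_error(0, 1, 1, 1)

    def test_monte_carlo_difference(self):
        rng = np.random.default_rng(2024)
        a = rng.normal(50, 3, 100_000)
        b = rng.normal(20, 4, 100_000)
        assert propagate_sum_error(3, 4) == pytest.approx(np.std(a - b, ddof=1), rel=0.05)

    def test_monte_carlo_quotient_small_relative_errors(self):
        rng = np.random.default_rng(2025)
        a = rng.normal(100, 5, 100_000)  # 5% relative
        b = rng.normal(40, 2, 100_000)  # 5% relative
        assert propagate_ratio_error(100, 5, 40, 2) == pytest.approx(
            np.std(a / b, ddof=1), rel=0.05
        )


class TestGroupCurve:
    def test_median_and_se(self, regime14):
        wells = [make_well([v] * 14) for v in (5, 7, 9)]
        prof = group_curve(wells, regime14)
        assert np.allclose(prof.curve_ocr, 7)
        assert np.allclose(prof.se_ocr, 2 / math.sqrt(3))
        assert prof.median_well_ids == [wells[1].well_id] * 14

    def test_single_replicate_is_degenerate(self, regime14, example_well):
        prof = group_curve([example_well], regime14)
        assert prof.degenerate
        assert np.allclose(prof.curve_ocr, example_well.ocr)
        assert np.all(prof.se_ocr == 0)

    def test_even_count_averages_central_pair(self, regime14):
        wells = [make_well([v] * 14) for v in (1, 2, 10, 20)]
        prof = group_curve(wells, regime14)
        assert np.allclose(prof.curve_ocr, 6)

    def test_median_well_tie_breaks_lexicographically(self, regime14):
        # values 4 and 8 are equidistant from the median 6
        wells = [
            make_well([8] * 14, well_id="p:B1"),
            make_well([4] * 14, well_id="p:A1"),
        ]
        prof = group_curve(wells, regime14)
        assert prof.median_well_ids == ["p:A1"] * 14

    def test_mixed_groups_rejected(self, regime14):
        wells = [make_well([1] * 14, group="G1"), make_well([2] * 14, group="G2")]
        with pytest.raises(ValueError):
            group_curve(wells, regime14)

    def test_outlier_moves_median_at_most_one_order_statistic(self, regime14):
        rng = np.random.default_rng(7)
        clean = [make_well(rng.uniform(10, 100, 14)) for _ in range(5)]
        prof_clean = group_curve(clean, regime14)
        for outlier in (1e6, -1e6):
            spiked = [w.copy() for w in clean]
            spiked[2].ocr = np.full(14, outlier)
            prof = group_curve(spiked, regime14)
            for j in range(14):
                order = np.sort([w.ocr[j] for w in clean])
                lo, hi = order[1], order[3]  # adjacent order statistics
                assert lo - 1e-9 <= prof.curve_ocr[j] <= hi + 1e-9


class TestGroupParameters:
    def test_identical_wells_equal_well_parameters_with_zero_error(self, regime14):
        wells = [make_well(EXAMPLE_OCR, well_id=f"p:A{i}") for i in range(1, 4)]
        prof = group_curve(wells, regime14)
        p = group_parameters(prof, regime14, ratio_wells=wells)
        for name, expected in EXAMPLE_PARAMS.items():
            assert getattr(p, name) == pytest.approx(expected, abs=1e-12)
        for f in ("nmitor", "pl", "br", "atp", "mr", "src"):
            assert getattr(p, "err_" + f) == 0.0

    def test_three_distinct_wells_match_brute_force(self, regime14):
        rng = np.random.default_rng(42)
        traces = [rng.uniform(1, 200, 14).tolist() for _ in range(3)]
        wells = [make_well(t, well_id=f"p:A{i}") for i, t in enumerate(traces, 1)]
        p = group_parameters(group_curve(wells, regime14), regime14)
        bf = bf_group_params(traces, LAYOUT_14)
        for f in ("nmitor", "pl", "br", "atp", "mr", "src"):
            assert getattr(p, f) == pytest.approx(bf[f], rel=1e-12, abs=1e-12)

    def test_difference_error_combines_mean_and_chosen_operand(self, regime14):
        # basal SEs (3,0,0) -> mean error 1; chosen nMitoR operand error 4
        ocr = np.vstack(
            [np.array(EXAMPLE_OCR, float) for _ in range(3)]
        )
        # spread measurement 3 across wells for SE 3, measurement 14 for SE 4;
        # the curve's post-antimycin/rotenone median (10, 12, 11) picks
        # measurement 14, so its SE is the chosen-operand error
        sd3 = 3 * math.sqrt(3)
        ocr[:, 2] = [60 - sd3, 60.0, 60 + sd3]
        sd14 = 4 * math.sqrt(3)
        ocr[:, 13] = [11 - sd14, 11.0, 11 + sd14]
        wells = [make_well(ocr[i], well_id=f"p:A{i}") for i in range(3)]
        prof = group_curve(wells, regime14)
        assert prof.se_ocr[2] == pytest.approx(3)
        assert prof.se_ocr[13] == pytest.approx(4)
        p = group_parameters(prof, regime14)
        assert p.err_nmitor == pytest.approx(4)
        assert p.err_br == pytest.approx(math.sqrt(1 + 16))

    def test_group_ratio_of_identical_wells_is_well_ratio(self, regime14):
        ecar = [10] * 5 + [10] * 3 + [8, 8, 10] + [10] * 3
        wells = [make_well(EXAMPLE_OCR, ecar, well_id=f"p:A{i}") for i in range(3)]
        p = group_parameters(group_curve(wells, regime14), regime14, ratio_wells=wells)
        assert p.ratio_basal == pytest.approx(6.1)
        assert p.ratio_max == pytest.approx(12.5)
        assert p.err_ratio_basal == 0.0
        assert p.err_ratio_max == 0.0

    def test_well_median_pooling_alternative(self, regime14):
        wells = [make_well([v] * 14, well_id=f"p:A{v}") for v in (5, 7, 9)]
        p = group_parameters_from_wells(wells, regime14)
        assert p.nmitor == 7.0
        assert p.br == 0.0


class TestRegimeConsistency:
    def test_dropping_first_two_basal_reproduces_12_regime(self, regime14, regime12):
        p14 = well_parameters(make_well(EXAMPLE_OCR), regime14)
        trimmed = EXAMPLE_OCR[2:]
        p12 = well_parameters(make_well(trimmed), regime12)
        assert p12.nmitor == p14.nmitor
        assert p12.pl == p14.pl
        assert p12.mr == p14.mr
        # 12-regime BR = mean of (new) M2, M3 minus nMitoR = mean(61, 62) - 11
        assert p12.br == pytest.approx(61.5 - 11)
        assert p12.atp == pytest.approx(p12.br - p12.pl)
        assert p12.src == pytest.approx(p12.mr - p12.br)
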