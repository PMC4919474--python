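"""Curve-class assignment, cytotoxicity, triage and screen summarization."""

import numpy as np
import pytest

from ldscreen.curve_class import (
    ClassThresholds,
    CurveClass,
    CurveClassResult,
    Direction,
    Quality,
    assign_curve_class,
    efficacy,
    flag_cytotoxicity,
    summarize_screen,
    triage_quality,
)
from ldscreen.hill import fit_hill, hill_response
from ldscreen.screen_model import TitrationSeries
from ldscreen.simulate import STANDARD_GRID, simulate_titration


def _series(activity, cell_activity=None, conc=None):
    conc = STANDARD_GRID if conc is None else conc
    n = len(conc)
    cell = np.zeros(n) if cell_activity is None else np.asarray(cell_activity, float)
    return TitrationSeries("t", conc, np.asarray(activity, float), cell, np.zeros(n, bool))


def _classify(series, thresholds=ClassThresholds()):
    fit = fit_hill(series)
    return assign_curve_class(fit, series, thresholds), fit


class TestEfficacy:
    def test_flat_series_zero(self, flat_series):
        fit = fit_hill(flat_series)
        assert efficacy(fit, flat_series) == pytest.approx(0.0, abs=1e-6)

    def test_full_sigmoid_realizes_full_span(self):
        s = simulate_titration(
            {"top": 0.0, "bottom": -100.0, "ec50": 3.7e-7, "slope": 2.0}, seed=0
        )
        fit = fit_hill(s)
        assert efficacy(fit, s) == pytest.approx(100.0, abs=1.0)

    def test_midpoint_at_cmax_realizes_half_span(self):
        s = simulate_titration(
            {"top": 0.0, "bottom": -100.0, "ec50": STANDARD_GRID[-1], "slope": 1.0},
            seed=0,
        )
        fit = fit_hill(s)
        # at c_max the curve sits at (top+bottom)/2; the realized span is
        # about half the asymptotic span
        assert efficacy(fit, s) == pytest.approx(50.0, abs=2.0)


class TestAssignCurveClass:
    def test_full_sigmoid_is_cc1_1_inhibitor(self):
        s = simulate_titration(
            {"top": 0.0, "bottom": -100.0, "ec50": 3.7e-7, "slope": 2.0}, seed=0
        )
        res, _ = _classify(s)
        assert res.curve_class is CurveClass.CC1_1
        assert res.direction is Direction.INHIBITOR

    def test_partial_efficacy_full_curve_is_cc1_2(self):
        s = simulate_titration(
            {"top": 0.0, "bottom": -50.0, "ec50": 3.7e-7, "slope": 2.0}, seed=0
        )
        res, _ = _classify(s)
        assert res.curve_class is CurveClass.CC1_2

    def test_unreached_asymptote_high_efficacy_is_cc2_1(self):
        s = simulate_titration(
            {"top": 0.0, "bottom": -150.0, "ec50": STANDARD_GRID[-1] / 2, "slope": 1.0},
            seed=0,
        )
        res, _ = _classify(s)
        assert res.curve_class is CurveClass.CC2_1
        assert res.efficacy >= 80.0

    def test_midpoint_beyond_range_is_cc2_2(self):
        s = simulate_titration(
            {"top": 0.0, "bottom": -120.0, "ec50": STANDARD_GRID[-1] * 1.2, "slope": 1.0},
            seed=0,
        )
        res, _ = _classify(s)
        assert res.curve_class is CurveClass.CC2_2

    def test_single_active_point_is_cc3(self):
        a = np.zeros(7)
        a[-1] = -40.0
        res, _ = _classify(_series(a))
        assert res.curve_class is CurveClass.CC3
        assert res.direction is Direction.INHIBITOR
        assert res.efficacy == pytest.approx(40.0)

    def test_flat_series_is_cc4_inactive(self, flat_series):
        fit = fit_hill(flat_series)
        res = assign_curve_class(fit, flat_series)
        assert res.curve_class is CurveClass.CC4
        assert res.direction is Direction.INACTIVE

    def test_activator_direction(self):
        s = simulate_titration(
            {"top": 0.0, "bottom": 90.0, "ec50": 3.7e-7, "slope": 2.0}, seed=0
        )
        res, _ = _classify(s)
        assert res.direction is Direction.ACTIVATOR

    def test_every_series_gets_exactly_one_class(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = rng.normal(0, 30, size=7)
            res, _ = _classify(_series(a))
            assert res.curve_class in CurveClass
            assert (res.curve_class is CurveClass.CC4) == (
                res.direction is Direction.INACTIVE
            )

    def test_raising_eff_high_only_demotes_full_to_partial(self):
        rng = np.random.default_rng(6)
        base = ClassThresholds()
        stricter = ClassThresholds(eff_high=95.0)
        promote = {
            CurveClass.CC1_2: CurveClass.CC1_1,
            CurveClass.CC2_2: CurveClass.CC2_1,
        }
        for _ in range(20):
            span = rng.uniform(30, 150)
            s = simulate_titration(
                {"top": 0.0, "bottom": -span, "ec50": 10 ** rng.uniform(-8, -5),
                 "slope": rng.uniform(0.8, 2.5)},
                seed=int(rng.integers(2**31)),
            )
            fit = fit_hill(s)
            before = assign_curve_class(fit, s, base).curve_class
            after = assign_curve_class(fit, s, stricter).curve_class
            if before is not after:
                assert promote.get(after) is before


class TestCytotoxicity:
    def test_healthy_cells_not_flagged(self, clean_sigmoid):
        assert not flag_cytotoxicity(clean_sigmoid)

    def test_dead_cells_everywhere_flagged(self):
        s = _series(np.zeros(7), cell_activity=np.full(7, -80.0))
        assert flag_cytotoxicity(s)

    def test_cell_drop_at_top_concentration_within_window(self):
        # EC50 two 1:5 dilutions below c_max: 25x EC50 still covers the top
        # concentration, so a cell collapse there counts
        ec50 = STANDARD_GRID[-1] / 5**2
        s = simulate_titration(
            {"top": 0.0, "bottom": -100.0, "ec50": ec50, "slope": 1.5}, seed=0
        )
        cell = np.zeros(7)
        cell[-1] = -80.0
        s = TitrationSeries(s.compound_id, s.concentrations, s.activity, cell, s.mask)
        fit = fit_hill(s)
        assert 25.0 * fit.ec50 >= STANDARD_GRID[-1]
        assert flag_cytotoxicity(s, fit=fit)

    def test_cell_drop_far_above_active_window_ignored(self):
        # potent compound (EC50 near the floor): a drop only at the top
        # concentration, >25x the EC50, is outside the active window
        s = simulate_titration(
            {"top": 0.0, "bottom": -100.0, "ec50": 9e-9, "slope": 1.5}, seed=0
        )
        cell = np.zeros(7)
        cell[-1] = -80.0
        s = TitrationSeries(s.compound_id, s.concentrations, s.activity, cell, s.mask)
        fit = fit_hill(s)
        assert not flag_cytotoxicity(s, fit=fit)


class TestTriage:
    def _result(self, cls, eff=100.0):
        return CurveClassResult(
            compound_id="x",
            curve_class=cls,
            direction=Direction.INHIBITOR if cls is not CurveClass.CC4 else Direction.INACTIVE,
            efficacy=eff,
        )

    def test_full_curve_nontoxic_is_high_quality(self):
        r = triage_quality(self._result(CurveClass.CC1_1), False, False)
        assert r.quality is Quality.HIGH

    def test_cc3_is_low_quality(self):
        r = triage_quality(self._result(CurveClass.CC3, eff=40.0), False, True)
        assert r.quality is Quality.LOW

    def test_cytotoxic_full_curve_demoted(self):
        r = triage_quality(self._result(CurveClass.CC1_1), True, True)
        assert r.quality is Quality.LOW
        assert r.cytotoxic

    def test_partial_curve_needs_efficacy_and_series_support(self):
        partial = self._result(CurveClass.CC1_2, eff=60.0)
        assert triage_quality(partial, False, True).quality is Quality.HIGH
        assert triage_quality(partial, False, False).quality is Quality.LOW
        weak = self._result(CurveClass.CC1_2, eff=40.0)
        assert triage_quality(weak, False, True).quality is Quality.LOW

    def test_inactive_has_no_quality_tier(self):
        r = triage_quality(self._result(CurveClass.CC4, eff=0.0), False, False)
        assert r.quality is Quality.NONE


class TestSummarizeScreen:
    @staticmethod
    def _block(cls, quality, direction, count, start):
        return [
            CurveClassResult(
                compound_id=f"c{start + i}",
                curve_class=cls,
                direction=direction,
                efficacy=50.0,
                quality=quality,
            )
            for i in range(count)
        ]

    def test_reported_class_counts_aggregate_to_screen_totals(self):
        # the published screen's per-class inhibitor counts: HQ 248 (cc1.1),
        # 203 (cc1.2), 831 (cc2.1), 1341 (cc2.2); LQ 1479 (cc1.2),
        # 2147 (cc2.2), 5532 (cc3)
        spec = [
            (CurveClass.CC1_1, Quality.HIGH, 248),
            (CurveClass.CC1_2, Quality.HIGH, 203),
            (CurveClass.CC2_1, Quality.HIGH, 831),
            (CurveClass.CC2_2, Quality.HIGH, 1341),
            (CurveClass.CC1_2, Quality.LOW, 1479),
            (CurveClass.CC2_2, Quality.LOW, 2147),
            (CurveClass.CC3, Quality.LOW, 5532),
        ]
        results, start = [], 0
        for cls, q, n in spec:
            results += self._block(cls, q, Direction.INHIBITOR, n, start)
            start += n
        summary = summarize_screen(results)
        assert summary.hq_inhibitors == 2623
        assert summary.lq_inhibitors == 9158
        assert summary.n_compounds == 2623 + 9158

    def test_totals_conserve_counts(self):
        rng = np.random.default_rng(9)
        classes = list(CurveClass)
        results = []
        for i in range(200):
            cls = classes[int(rng.integers(len(classes)))]
            q = (
                Quality.NONE
                if cls is CurveClass.CC4
                else [Quality.HIGH, Quality.LOW][int(rng.integers(2))]
            )
            d = (
                Direction.INACTIVE
                if cls is CurveClass.CC4
                else [Direction.INHIBITOR, Direction.ACTIVATOR][int(rng.integers(2))]
            )
            results.append(CurveClassResult(f"c{i}", cls, d, 50.0, q))
        s = summarize_screen(results)
        assert (
            s.hq_inhibitors + s.hq_activators + s.lq_inhibitors + s.lq_activators
            + s.inactive
            == 200
        )
        assert sum(s.counts.values()) == 200

    def test_duplicate_compound_rejected(self):
        r = CurveClassResult("dup", CurveClass.CC4, Direction.INACTIVE, 0.0)
        with pytest.raises(ValueError, match="dup"):
            summarize_screen([r, r])

    def test_empty_screen_all_zero(self):
        s = summarize_screen([])
        assert s.n_compounds == 0
        assert s.hq_inhibitors == s.lq_inhibitors == s.inactive == 0
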