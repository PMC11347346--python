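"""BED model tests: exact reference values, algebraic identities,
calibration of the background repopulation rate, and the comparison table."""

import math

import numpy as np
import pytest
import sympy as sp

from fracsurv.bed import (
    DAY_CONVENTIONS,
    STANDARD_REGIMEN,
    REFERENCE_BED_ROWS,
    BEDParameterError,
    CalibrationError,
    FractionationRegimen,
    MissingDurationError,
    RepopulationParamsDD,
    RepopulationParamsDI,
    bed_dd,
    bed_di,
    bed_simp,
    bed_table,
    calibrate_background_rate,
    duration_from_fractions,
    reference_regimens,
    weekday_elapsed_days,
)


def _round2(x: float) -> float:
    return math.floor(x * 100 + 0.5) / 100


class TestBedSimp:
    @pytest.mark.parametrize(
        "m,d,expected",
        [(m, d, simp) for (m, d, _w, _bid, _dd, _di, simp) in REFERENCE_BED_ROWS],
    )
    def test_reference_rows_exact(self, m, d, expected):
        reg = FractionationRegimen(m, d)
        assert _round2(bed_simp(reg, 10.0)) == pytest.approx(expected, abs=1e-9)

    def test_vanishing_fraction_dose_limit(self):
        reg = FractionationRegimen(30, 1e-9)
        assert bed_simp(reg, 10.0) == pytest.approx(30 * 1e-9, rel=1e-6)

    @pytest.mark.parametrize("m,d,r", [(0, 2.0, 10.0), (10, -1.0, 10.0), (10, 2.0, 0.0)])
    def test_invalid_parameters_rejected(self, m, d, r):
        with pytest.raises(BEDParameterError):
            bed_simp(FractionationRegimen(m, d), r)


class TestReductions:
    def test_di_reduces_to_simp_when_repopulation_off(self):
        # T = 23 days < T_k = 28.6 for an 18-fraction schedule, and g = 0
        reg = FractionationRegimen(18, 3.0)
        p = RepopulationParamsDI(g=0.0)
        assert reg.elapsed_days() < p.T_k
        assert bed_di(reg, p) == pytest.approx(bed_simp(reg, p.r), abs=1e-12)

    def test_dd_reduces_to_simp_when_threshold_infinite(self):
        reg = FractionationRegimen(35, 2.0)
        p = RepopulationParamsDD(C=math.inf, g=0.0)
        assert bed_dd(reg, p) == pytest.approx(bed_simp(reg, p.r), abs=1e-12)

    def test_dd_with_infinite_threshold_keeps_background_term(self):
        reg = FractionationRegimen(35, 2.0)
        p = RepopulationParamsDD(C=math.inf, g=0.02)
        t = reg.elapsed_days()
        expected = bed_simp(reg, p.r) - p.g * t / p.alpha
        assert bed_dd(reg, p) == pytest.approx(expected, abs=1e-12)

    def test_dd_requires_positive_duration(self):
        reg = FractionationRegimen(1, 2.0)
        with pytest.raises(MissingDurationError):
            bed_dd(reg, RepopulationParamsDD())


def test_dd_closed_form_matches_printed_term_structure():
    """The reconstructed DD closed form, put over the common denominator
    r*alpha, must expand to the pattern
    r*lam*(exp(-k) - 1)*max(0, T - C/k) + (alpha*d*m - T*g)*r + m*alpha*d^2
    with k = m*alpha*d*(d+r)/(r*T)."""
    m, d, r, a, lam, g, T, C = sp.symbols("m d r alpha lam g T C", positive=True)
    k = m * a * d * (d + r) / (r * T)
    M = sp.Symbol("M", positive=True)  # stands for max(0, T - C/k)
    ours = (m * a * d * (d + r) / r - g * T - lam * (1 - sp.exp(-k)) * M) / a
    printed = (
        r * lam * (sp.exp(-k) - 1) * M + (a * d * m - T * g) * r + m * a * d**2
    ) / (r * a)
    assert sp.simplify(ours - printed) == 0


class TestDayConventions:
    def test_standard_schedule_duration(self):
        weeks, t = duration_from_fractions(35, 1)
        assert weeks == 7.0
        assert t == 46.0  # Monday start, Friday finish

    def test_bid_schedule_weeks(self):
        weeks, _ = duration_from_fractions(60, 2)
        assert weeks == 6.0

    def test_single_week(self):
        weeks, _ = duration_from_fractions(5, 1)
        assert weeks == 1.0

    def test_weekday_matches_weekly_formula_for_whole_weeks(self):
        for m in (5, 10, 25, 35, 40):
            assert weekday_elapsed_days(m) == 7.0 * (m / 5) - 3.0

    def test_unknown_convention_rejected(self):
        with pytest.raises(BEDParameterError):
            STANDARD_REGIMEN.elapsed_days("tuesday-start")


class TestCalibration:
    def _qd_rows(self, col):
        idx = {"dd": 4, "di": 5}[col]
        return [
            (FractionationRegimen(m, d, 1, w), row[idx])
            for row in REFERENCE_BED_ROWS
            for (m, d, w, bid) in [row[:4]]
            if not bid and (m, d) != (35, 2.0)
        ]

    def test_single_anchor_calibration_reproduces_once_daily_rows(self):
        """g fitted on the standard 35x2 row only; all other once-daily rows
        must land within 0.1 Gy (dose-dependent) / 0.5 Gy (dose-independent)."""
        qd_dd, qd_di = self._qd_rows("dd"), self._qd_rows("di")
        g_dd, conv = calibrate_background_rate(
            [(STANDARD_REGIMEN, 62.19)], "DD", validation_rows=qd_dd
        )
        g_di, conv_di = calibrate_background_rate(
            [(STANDARD_REGIMEN, 64.17)], "DI", validation_rows=qd_di
        )
        assert 0 < g_dd < 0.05 and 0 < g_di < 0.05
        p_dd = RepopulationParamsDD(g=g_dd)
        for reg, target in qd_dd:
            assert bed_dd(reg, p_dd, conv) == pytest.approx(target, abs=0.1)
        p_di = RepopulationParamsDI(g=g_di)
        for reg, target in qd_di:
            assert bed_di(reg, p_di, conv_di) == pytest.approx(target, abs=0.5)

    def test_anchor_at_zero_g_model_value_gives_zero(self):
        reg = FractionationRegimen(35, 2.0)
        target = bed_di(reg, RepopulationParamsDI(g=0.0))
        g, _ = calibrate_background_rate([(reg, target)], "DI", convention="weekday")
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_solution_matches_brute_force_scan(self):
        """The linear-in-g least-squares solution attains the grid minimum of
        the squared anchor error over g in [0, 0.05]."""
        anchors = [(STANDARD_REGIMEN, 64.17), (FractionationRegimen(25, 2.4, 1, 5.0), 64.80)]
        g_star, conv = calibrate_background_rate(anchors, "DI", convention="weekday")
        grid = np.linspace(0, 0.05, 2001)
        sse = []
        for g in grid:
            p = RepopulationParamsDI(g=float(g))
            sse.append(sum((bed_di(r, p, "weekday") - t) ** 2 for r, t in anchors))
        g_grid = grid[int(np.argmin(sse))]
        assert g_star == pytest.approx(g_grid, abs=grid[1] - grid[0])

    def test_unfittable_anchor_raises_with_residuals(self):
        # no g >= 0 can push the BED above the no-repopulation value
        reg = FractionationRegimen(35, 2.0)
        with pytest.raises(CalibrationError, match="residual"):
            calibrate_background_rate([(reg, 200.0)], "DI", convention="weekday", tol=0.5)


class TestBedTable:
    def test_standard_self_difference_is_zero(self):
        tab = bed_table([STANDARD_REGIMEN], (10.0,))
        row = tab[(tab.fractions == 35) & (tab.alpha_beta == 10.0)].iloc[0]
        for col in ("bed_simp_diff_standard", "bed_di_diff_standard", "bed_dd_diff_standard"):
            assert row[col] == 0.0

    def test_hypofractionated_row_difference(self):
        tab = bed_table([FractionationRegimen(18, 3.0, 1, 3.6)], (10.0,))
        row = tab[tab.fractions == 18].iloc[0]
        assert row["bed_simp_diff_standard"] == pytest.approx(-13.80, abs=1e-9)

    def test_row_order_invariance(self):
        regs = reference_regimens()
        t1 = bed_table(regs, (10.0,))
        t2 = bed_table(list(reversed(regs)), (10.0,))
        assert t1.equals(t2)

    def test_sign_pattern_hypofractionated_vs_standard(self):
        """Hypofractionated schedules raise the dose-dependent BED but lower
        the no-repopulation BED relative to the 35x2 standard."""
        tab = bed_table(reference_regimens(), (10.0,))
        hypo = tab[tab.fractions.isin([18, 20, 25]) & tab.dose_per_fraction.isin([3.0, 2.75, 2.4])]
        assert (hypo["bed_dd_diff_standard"] > 0).all()
        assert (hypo["bed_simp_diff_standard"] < 0).all()


class TestMonotonicity:
    def test_simp_and_di_strictly_increase_in_dose_and_fractions(self):
        p = RepopulationParamsDI()
        for m in (10, 20, 35):
            doses = np.linspace(1.0, 4.0, 31)
            v_simp = [bed_simp(FractionationRegimen(m, float(d), 1, 6.0), 10.0) for d in doses]
            v_di = [bed_di(FractionationRegimen(m, float(d), 1, 6.0), p, "mon-fri") for d in doses]
            assert np.all(np.diff(v_simp) > 0) and np.all(np.diff(v_di) > 0)
        for d in (1.5, 2.0, 3.0):
            ms = range(5, 41)
            v_simp = [bed_simp(FractionationRegimen(m, d, 1, 6.0), 10.0) for m in ms]
            v_di = [bed_di(FractionationRegimen(m, d, 1, 6.0), p, "mon-fri") for m in ms]
            assert np.all(np.diff(v_simp) > 0) and np.all(np.diff(v_di) > 0)

    def test_dd_increases_in_dose_on_clinical_hypofractionation_range(self):
        # the dose-dependent model is piecewise in the acceleration onset and
        # can dip slightly at the kink for protracted low-dose schedules;
        # on the clinical range (m <= 35, d >= 1.8, derived duration) it rises
        p = RepopulationParamsDD()
        for m in (15, 20, 25, 30, 35):
            doses = np.arange(1.8, 4.001, 0.02)
            vals = [bed_dd(FractionationRegimen(m, float(d), 1), p) for d in doses]
            assert np.all(np.diff(vals) > 0), f"m={m}"

    def test_di_and_dd_non_increasing_in_duration(self):
        p_di, p_dd = RepopulationParamsDI(), RepopulationParamsDD()
        for m, d in ((35, 2.0), (20, 2.75), (25, 2.4)):
            weeks = np.arange(1.0, 12.01, 0.25)
            v_di = [bed_di(FractionationRegimen(m, d, 1, float(w)), p_di, "mon-fri") for w in weeks]
            v_dd = [bed_dd(FractionationRegimen(m, d, 1, float(w)), p_dd, "mon-fri") for w in weeks]
            assert np.all(np.diff(v_di) <= 1e-12)
            assert np.all(np.diff(v_dd) <= 1e-12)

    def test_negative_bed_logged_not_clamped(self, caplog):
        reg = FractionationRegimen(5, 1.0, 1, 50.0)
        with caplog.at_level("WARNING"):
            v = bed_di(reg, RepopulationParamsDI(g=0.05), "calendar")
        assert v < 0
        assert any("negative" in r.message for r in caplog.records)
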