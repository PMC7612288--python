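"""Planckian radiators, CCT, the CIE daylight model, locus fits and statistics."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from scipy import stats

from chromalight.colorimetry import xy_chromaticity
from chromalight.daylight import (
    DaylightRecord,
    cie_daylight_spd,
    compute_cct,
    daylight_locus_curve,
    daylight_locus_y,
    diurnal_summary,
    filter_low_signal,
    fit_quadratic_locus,
    pair_sun_shadow,
    planckian_spd,
    uv_1960,
    welch_t_one_tailed,
    _planck_uv,
)
from chromalight.errors import DomainError, FitError, ValidationError
from chromalight.spectra import SpectralDistribution, WavelengthGrid


class TestPlanck:
    def test_positive_everywhere(self, daylight_grid):
        assert (planckian_spd(6500, daylight_grid).values > 0).all()
        with pytest.raises(DomainError):
            planckian_spd(-5, daylight_grid)

    def test_wien_displacement(self, daylight_grid):
        """argmax(B) * T ~ 2.898e6 nm*K when the peak falls in range."""
        spd = planckian_spd(5000, daylight_grid)
        peak = spd.wavelengths[np.argmax(spd.values)]
        assert peak * 5000 == pytest.approx(2.898e6, rel=2e-3)

    def test_red_blue_ratio_decreases_with_temperature(self, daylight_grid):
        ratios = []
        for T in np.linspace(2000, 20000, 12):
            spd = planckian_spd(T, daylight_grid)
            ratios.append(spd.value_at(780) / spd.value_at(380))
        assert all(a > b for a, b in zip(ratios, ratios[1:]))


class TestCCT:
    @pytest.mark.parametrize("T", [2000, 4000, 6500, 10000, 20000])
    def test_self_inversion_within_half_percent(self, T, daylight_grid):
        point = xy_chromaticity(planckian_spd(T, daylight_grid))
        res = compute_cct(point, daylight_grid)
        assert res.converged
        assert res.duv_distance < 1e-6  # the point lies on the locus
        assert res.cct_K == pytest.approx(T, rel=5e-3)

    @pytest.mark.parametrize("T,grid_tol", [(6500, 10), (20000, 100)])
    def test_against_one_kelvin_grid_scan(self, T, grid_tol, daylight_grid):
        """Brute-force oracle: dense 1 K scan around the nominal temperature."""
        point = xy_chromaticity(planckian_spd(T, daylight_grid))
        u0, v0 = uv_1960(point.x, point.y)
        Ts = np.arange(T - 200, T + 200, 1.0)
        d = [np.hypot(*(np.array(_planck_uv(t, daylight_grid)) - (u0, v0))) for t in Ts]
        oracle = Ts[int(np.argmin(d))]
        assert compute_cct(point, daylight_grid).cct_K == pytest.approx(oracle, abs=grid_tol)

    def test_off_locus_point_flagged_unconverged(self, daylight_grid):
        res = compute_cct((0.30, 0.55), daylight_grid)  # deep green: duv is large
        assert not res.converged
        assert res.duv_distance > 0.05
        assert res.cct_K > 0  # value still reported


class TestCIEDaylightModel:
    def test_chromaticity_on_locus_relation(self, daylight_grid):
        for cct in (4000, 5000, 6500, 10000, 15000, 25000):
            p = xy_chromaticity(cie_daylight_spd(cct, daylight_grid))
            assert p.y == pytest.approx(float(daylight_locus_y(p.x)), abs=2e-3)

    def test_cct_round_trip(self, daylight_grid):
        p = xy_chromaticity(cie_daylight_spd(6500, daylight_grid))
        assert 6400 <= compute_cct(p, daylight_grid).cct_K <= 6600

    def test_higher_cct_has_more_short_wavelength_energy(self, daylight_grid):
        w = daylight_grid.wavelengths
        short = (w >= 380) & (w <= 480)

        def frac(cct):
            v = cie_daylight_spd(cct, daylight_grid).values
            return v[short].sum() / v.sum()

        assert frac(10000) > frac(6500)

    def test_out_of_range_rejected(self, daylight_grid):
        for cct in (3000, 30000):
            with pytest.raises(DomainError):
                cie_daylight_spd(cct, daylight_grid)

    def test_locus_curve_is_quadratic_and_consistent(self, daylight_grid):
        f = daylight_locus_curve()
        assert f(0.3127) == pytest.approx(-3.0 * 0.3127**2 + 2.87 * 0.3127 - 0.275, abs=1e-12)
        xs = np.linspace(0.25, 0.40, 9)
        second = np.diff(f(xs), 2)
        assert np.allclose(second, second[0], atol=1e-12)


class TestLocusFit:
    COEFS = (-1.38, 1.80, -0.0992)  # printed survey fit

    def test_exact_recovery_on_noiseless_points(self):
        a, b, c = self.COEFS
        x = np.linspace(0.25, 0.42, 40)
        fit = fit_quadratic_locus(np.column_stack([x, a * x**2 + b * x + c]))
        assert (fit.a, fit.b, fit.c) == pytest.approx(self.COEFS, abs=1e-10)
        assert fit.rms_residual < 1e-12

    def test_straight_line_gives_zero_curvature(self):
        x = np.linspace(0.2, 0.5, 20)
        fit = fit_quadratic_locus(np.column_stack([x, 2.0 * x + 1.0]))
        assert fit.a == pytest.approx(0.0, abs=1e-10)

    def test_unbiased_under_y_noise(self):
        """Monte-Carlo: mean coefficient error is statistically zero."""
        a, b, c = self.COEFS
        rng = np.random.default_rng(11)
        x = np.linspace(0.25, 0.42, 452)
        y0 = a * x**2 + b * x + c
        estimates = []
        for _ in range(200):
            fit = fit_quadratic_locus(np.column_stack([x, y0 + rng.normal(0, 1e-3, x.size)]))
            estimates.append((fit.a, fit.b, fit.c))
        estimates = np.array(estimates)
        bias = estimates.mean(axis=0) - np.array(self.COEFS)
        se = estimates.std(axis=0, ddof=1) / np.sqrt(len(estimates))
        assert (np.abs(bias) < 4 * se + 1e-12).all()

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(FitError):
            fit_quadratic_locus([(0.3, 0.3), (0.3, 0.31), (0.3, 0.32)])


def make_record(level, unit="cd/m2", condition="sun_plus_sky", t=0.0, cct=6500.0,
                site="rooftop"):
    grid = WavelengthGrid.daylight()
    spd = cie_daylight_spd(cct, grid)
    return DaylightRecord(
        timestamp=datetime(2013, 11, 20, 6, 0) + timedelta(minutes=t),
        site=site,
        condition=condition,
        spectrum=spd.with_values(spd.values, "radiance" if unit == "cd/m2" else "irradiance"),
        photometric_level=level,
        level_unit=unit,
    )


class TestLowSignalFilter:
    def test_threshold_is_strict(self):
        kept, removed = filter_low_signal([make_record(10.0), make_record(9.99)])
        assert [r.photometric_level for r in kept] == [10.0]
        assert [r.photometric_level for r in removed] == [9.99]

    def test_lux_records_use_their_own_threshold(self):
        rec = make_record(9.99, unit="lx", condition="toward_zenith")
        kept, removed = filter_low_signal([rec])
        assert removed == [rec]

    def test_constructed_survey_counts(self):
        """477 records with 25 constructed below threshold leave 452."""
        rng = np.random.default_rng(3)
        records = [make_record(float(v), t=i) for i, v in
                   enumerate(rng.uniform(10.0, 5000.0, 452))]
        records += [make_record(float(v), t=500 + i) for i, v in
                    enumerate(rng.uniform(0.01, 9.99, 25))]
        kept, removed = filter_low_signal(records)
        assert (len(kept), len(removed)) == (452, 25)
        kept2, removed2 = filter_low_signal(kept)
        assert len(kept2) == 452 and removed2 == []  # idempotent

    def test_missing_level_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            make_record(float("nan"))


class TestPairing:
    def test_close_records_pair(self):
        recs = [make_record(100, t=0), make_record(50, condition="shadow_sky", t=1)]
        assert len(pair_sun_shadow(recs, 15)) == 1

    def test_distant_records_do_not_pair(self):
        recs = [make_record(100, t=0), make_record(50, condition="shadow_sky", t=30)]
        assert pair_sun_shadow(recs, 15) == []

    def test_interleaved_series_matches_min_cost_oracle(self):
        """Exhaustive assignment oracle on a small interleaved series."""
        from itertools import permutations

        totals = [make_record(100, t=t) for t in (0, 10, 20, 33)]
        shadows = [make_record(50, condition="shadow_sky", t=t) for t in (1, 12, 19, 46)]
        pairs = pair_sun_shadow(totals + shadows, max_gap_minutes=15)

        def gap(t, s):
            return abs((t.timestamp - s.timestamp).total_seconds()) / 60.0

        best, best_cost = None, None
        for perm in permutations(range(len(shadows))):
            assign = [
                (i, j) for i, j in enumerate(perm) if gap(totals[i], shadows[j]) <= 15
            ]
            cost = (-len(assign), sum(gap(totals[i], shadows[j]) for i, j in assign))
            if best_cost is None or cost < best_cost:
                best, best_cost = assign, cost
        got = {(totals.index(t), shadows.index(s)) for t, s in pairs}
        assert got == set(best)
        paired_totals = {totals.index(t) for t, _ in pairs}
        assert paired_totals >= {0, 1, 2}


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 0.5

    def test_textbook_case_matches_hand_formula_and_scipy(self):
        a = np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1, 21.9, 22.6, 23.1, 19.6])
        b = np.array([27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0, 24.8, 20.2, 21.9, 22.1])
        t, df, p = welch_t_one_tailed(a, b, "less")
        # hand-expanded Welch formula, independent of the implementation path
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / 12 + vb / 12
        t_hand = (a.mean() - b.mean()) / np.sqrt(se2)
        df_hand = se2**2 / ((va / 12) ** 2 / 11 + (vb / 12) ** 2 / 11)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert df == pytest.approx(df_hand, rel=1e-12)
        res = stats.ttest_ind(a, b, equal_var=False, alternative="less")
        assert t == pytest.approx(res.statistic, rel=1e-12)
        assert p == pytest.approx(res.pvalue, rel=1e-9)

    def test_welch_df_bounds(self, rng):
        a = rng.normal(0, 1, 119)
        b = rng.normal(0, 5, 90)
        _, df, _ = welch_t_one_tailed(a, b)
        assert min(119, 90) - 1 < df < 119 + 90 - 2

    def test_degenerate_equal_constants_rejected(self):
        with pytest.raises(ValidationError):
            welch_t_one_tailed([2.0, 2.0], [2.0, 2.0])


class TestDiurnalSummary:
    def test_constant_spectrum_gives_constant_series(self):
        recs = [make_record(100.0, t=60 * i) for i in range(5)]
        out = diurnal_summary(recs)
        assert len(out) == 5
        assert np.allclose(out.cct_K, out.cct_K.iloc[0])
        assert np.allclose(out.log10_level, 2.0)

    def test_zero_level_records_excluded(self):
        recs = [make_record(100.0), make_record(0.0, t=5)]
        assert len(diurnal_summary(recs)) == 1


class TestRecordValidation:
    def test_unit_must_match_condition(self):
        with pytest.raises(ValidationError):
            make_record(100.0, unit="lx", condition="sun_plus_sky")
        with pytest.raises(ValidationError):
            make_record(100.0, unit="cd/m2", condition="toward_zenith")
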