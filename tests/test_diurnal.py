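"""Loess smoothing, photoperiod bounds and daily integration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isoflux import (
    day_bounds,
    integrate_daily,
    loess_smooth,
    propagate_sd_ratio,
    propagate_sd_sum,
)
from isoflux.diurnal import MMOL_H2O_TO_KG, UMOL_CO2_TO_G_C


class TestLoess:
    def test_constant_series(self):
        x = np.linspace(0, 10, 20)
        fit, se, flag = loess_smooth(x, np.full(20, 3.5))
        assert np.allclose(fit, 3.5)
        assert np.allclose(se, 0.0, atol=1e-10)
        assert flag == "ok"

    @pytest.mark.parametrize("span", [0.3, 0.75, 1.0])
    def test_exact_on_linear_data(self, span):
        x = np.linspace(0, 10, 25)
        y = 2.0 * x - 1.0
        fit, se, _ = loess_smooth(x, y, span=span)
        assert np.allclose(fit, y, atol=1e-8 * np.abs(y).max())
        assert np.allclose(se, 0.0, atol=1e-8)

    def test_degree_two_exact_on_quadratic(self):
        x = np.linspace(-3, 3, 30)
        y = 1.0 + 0.5 * x - 2.0 * x**2
        fit, _, _ = loess_smooth(x, y, span=0.5, degree=2)
        assert np.allclose(fit, y, atol=1e-8)

    def test_symmetric_data_symmetric_smooth(self):
        x = np.linspace(-5, 5, 21)
        y = np.cos(x) + 0.1 * x**2
        fit, _, _ = loess_smooth(x, y, span=0.5)
        assert np.allclose(fit, fit[::-1], atol=1e-10)

    def test_matches_statsmodels_on_linear_data(self):
        sm_lowess = pytest.importorskip("statsmodels.nonparametric.smoothers_lowess")
        x = np.linspace(0, 1, 40)
        y = 3.0 * x + 2.0
        ours, _, _ = loess_smooth(x, y, span=0.5, degree=1)
        theirs = sm_lowess.lowess(y, x, frac=0.5, return_sorted=False)
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_few_points_fall_back_to_linear(self):
        fit, se, flag = loess_smooth([0, 1, 2], [0.0, 1.0, 2.0], eval_x=[0.5])
        assert flag == "fallback_linear"
        assert fit[0] == pytest.approx(0.5)

    def test_linear_operator_additivity(self):
        x = np.linspace(0, 10, 30)
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=30), rng.normal(size=30)
        fa, _, _ = loess_smooth(x, a)
        fb, _, _ = loess_smooth(x, b)
        fab, _, _ = loess_smooth(x, a + b)
        assert np.allclose(fab, fa + fb, atol=1e-9)


def _meteo_day(date="2017-06-01", lit_start=12, lit_stop=40):
    ts = pd.date_range(f"{date} 00:00", periods=48, freq="30min")
    ppfd = np.zeros(48)
    ppfd[lit_start:lit_stop+1] = 800.0  # flat plateau: bounds at the plateau edges
    return pd.DataFrame({"timestamp": ts, "ppfd": ppfd})


class TestDayBounds:
    def test_plateau_bounds(self):
        meteo = _meteo_day()
        sunrise, sunset = day_bounds(meteo, "2017-06-01")
        assert sunrise == pd.Timestamp("2017-06-01 06:00")
        assert sunset == pd.Timestamp("2017-06-01 20:00")

    def test_all_dark_day(self):
        meteo = _meteo_day()
        meteo["ppfd"] = 0.0
        assert day_bounds(meteo, "2017-06-01") == (None, None)

    def test_ramp_extrapolates_to_zero_crossing(self):
        ts = pd.date_range("2017-06-01 00:00", periods=48, freq="30min")
        hours = ts.hour + ts.minute / 60
        ppfd = np.clip(100.0 * (hours - 6.0), 0, None)  # zero crossing at 06:00
        sunrise, _ = day_bounds(pd.DataFrame({"timestamp": ts, "ppfd": ppfd}), "2017-06-01")
        assert abs((sunrise - pd.Timestamp("2017-06-01 06:00")).total_seconds()) < 60

    def test_generator_bounds_match_configured_window(self, quiet_season):
        date = quiet_season.default_campaign_dates()[4]
        sr_h, ss_h = quiet_season.daylight_window(date)
        sunrise, sunset = day_bounds(quiet_season.meteo, date)
        got_sr = sunrise.hour + sunrise.minute / 60 + sunrise.second / 3600
        got_ss = sunset.hour + sunset.minute / 60 + sunset.second / 3600
        assert got_sr == pytest.approx(sr_h, abs=0.5)
        assert got_ss == pytest.approx(ss_h, abs=0.5)


def _smoothed_frame(date, start_h, stop_h, step_s=360.0, **values):
    t0 = pd.Timestamp(date) + pd.Timedelta(hours=start_h)
    t1 = pd.Timestamp(date) + pd.Timedelta(hours=stop_h)
    n = int((t1 - t0).total_seconds() / step_s) + 1
    ts = t0 + pd.to_timedelta(np.arange(n) * step_s, unit="s")
    frame = {"timestamp": ts}
    for key, val in values.items():
        frame[key] = np.full(n, float(val))
    return pd.DataFrame(frame)


class TestIntegrateDaily:
    def test_constant_fluxes(self):
        date = "2017-06-01"
        sm = _smoothed_frame(date, 6, 20, gpp=-10.0, reco=2.0, t=1.0, e=0.2)
        sunrise = pd.Timestamp(f"{date} 06:00")
        sunset = pd.Timestamp(f"{date} 20:00")
        day = integrate_daily(sm, date, sunrise, sunset)
        photoperiod = 14 * 3600
        # GPP/T: F x photoperiod; the zero anchors at the bounds cost half a
        # grid step per edge on this (idealised) step-shaped series
        assert day.gpp_sum == pytest.approx(-10 * photoperiod * UMOL_CO2_TO_G_C, rel=1e-2)
        assert day.t_sum == pytest.approx(1.0 * photoperiod * MMOL_H2O_TO_KG, rel=1e-2)
        # Reco/E continue all night at the same constant level: full-day sums
        assert day.reco_sum == pytest.approx(2.0 * 86400 * UMOL_CO2_TO_G_C, rel=1e-9)
        assert day.e_sum == pytest.approx(0.2 * 86400 * MMOL_H2O_TO_KG, rel=1e-9)
        # composition identities
        assert day.nee_sum == pytest.approx(day.gpp_sum + day.reco_sum, abs=1e-12)
        assert day.et_sum == pytest.approx(day.t_sum + day.e_sum, abs=1e-12)

    def test_zero_everywhere(self):
        date = "2017-06-01"
        sm = _smoothed_frame(date, 6, 20, gpp=0.0, reco=0.0, t=0.0, e=0.0)
        day = integrate_daily(
            sm, date, pd.Timestamp(f"{date} 06:00"), pd.Timestamp(f"{date} 20:00")
        )
        assert day.nee_sum == day.et_sum == day.gpp_sum == 0.0

    def test_all_dark_day_zero_photosynthesis(self):
        date = "2017-06-01"
        sm = _smoothed_frame(date, 10, 14, gpp=-3.0, reco=2.0, t=0.5, e=0.2)
        day = integrate_daily(sm, date, None, None)
        assert day.gpp_sum == 0.0 and day.t_sum == 0.0
        assert day.reco_sum > 0

    def test_additivity_in_the_flux_series(self):
        date = "2017-06-01"
        sunrise, sunset = pd.Timestamp(f"{date} 06:00"), pd.Timestamp(f"{date} 20:00")
        a = _smoothed_frame(date, 6, 20, gpp=-4.0, reco=1.0, t=0.6, e=0.1)
        b = _smoothed_frame(date, 6, 20, gpp=-6.0, reco=0.5, t=0.4, e=0.3)
        ab = a.copy()
        for c in ("gpp", "reco", "t", "e"):
            ab[c] = a[c] + b[c]
        da = integrate_daily(a, date, sunrise, sunset)
        db = integrate_daily(b, date, sunrise, sunset)
        dab = integrate_daily(ab, date, sunrise, sunset)
        for field in ("nee_sum", "et_sum", "gpp_sum", "reco_sum", "t_sum", "e_sum"):
            assert getattr(dab, field) == pytest.approx(
                getattr(da, field) + getattr(db, field), rel=1e-9, abs=1e-12
            )

    def test_short_window_flagged(self):
        date = "2017-06-01"
        sm = _smoothed_frame(date, 12, 13, gpp=-3.0, reco=2.0, t=0.5, e=0.2)
        day = integrate_daily(
            sm, date, pd.Timestamp(f"{date} 06:00"), pd.Timestamp(f"{date} 20:00")
        )
        assert "low_confidence_short_window" in day.flags

    def test_half_sine_day_matches_analytic_integral(self, quiet_season):
        # noise-free truth sampled finely and pushed through the integrator
        date = quiet_season.default_campaign_dates()[5]
        met = quiet_season._meteo_on(date)
        lit = met[met["ppfd"] > 5.0]
        t0 = pd.to_datetime(lit["timestamp"]).iloc[0]
        t1 = pd.to_datetime(lit["timestamp"]).iloc[-1]
        ts = pd.date_range(t0, t1, freq="6min")
        truth = quiet_season.truth_fluxes("CC", ts)
        sm = pd.DataFrame(
            {"timestamp": ts, **{c: truth[c].to_numpy() for c in ("gpp", "reco", "t", "e")}}
        )
        sunrise, sunset = day_bounds(quiet_season.meteo, date)
        day = integrate_daily(sm, date, sunrise, sunset)
        ref = quiet_season.truth_daily_sums("CC").set_index("date").loc[pd.Timestamp(date).date()]
        for field in ("gpp_sum", "reco_sum", "t_sum", "e_sum"):
            assert getattr(day, field) == pytest.approx(ref[field], rel=1e-2, abs=5e-3)


class TestErrorPropagation:
    def test_sum_in_quadrature(self):
        assert propagate_sd_sum([3.0, 4.0]) == 5.0
        assert propagate_sd_sum([0.0, 0.0, 0.0]) == 0.0

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            propagate_sd_sum([-1.0])

    def test_ratio_first_order(self):
        sd = propagate_sd_ratio(10.0, 1.0, 5.0, 0.5)
        assert sd == pytest.approx(2.0 * 0.1414214, rel=1e-5)

    @given(w=st.floats(0.1, 10))
    def test_sum_scaling(self, w):
        assert propagate_sd_sum([3.0, 4.0], weights=[w, w]) == pytest.approx(5.0 * w)
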