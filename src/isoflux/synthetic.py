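"""Synthetic grassland growing season with known ground truth.

The generator builds a full study world: 30-min meteorology over the season,
noise-free component fluxes (GPP, Reco, T, E) for four treatments, chamber
campaign tables whose mixing ratios are back-computed from the truth through
the inverted open-chamber flux equation, water-isotope tables constructed so
that the exact endmember inversion returns the true transpiration fraction,
and a continuous eddy-covariance series that is a biased, noisy transform of
the true control fluxes.  Every downstream stage of the pipeline can thereby
be tested against known truth.

Deliberate simplifications (see the methods note): radiation, temperature
and humidity follow smooth seasonal + diel cycles without day-to-day
synoptic variability, and respiration responds to the daily-mean temperature
(Q10 = 2) rather than to a sub-daily cycle.  Those two choices make the
world exactly consistent with the night-extrapolation and offset
interpolation rules, so that a zero-noise run round-trips to truth.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .chamber import CM2_PER_M2, molar_flow
from .config import TREATMENTS, TruthBundle
from .diurnal import MMOL_H2O_TO_KG, UMOL_CO2_TO_G_C
from .enviro import saturation_vapor_pressure
from .isotopes import CraigGordonParams, craig_gordon_delta_e

PPFD_THRESHOLD = 5.0  # consistent with diurnal.day_bounds

#: relative stage amplitudes (season start, four stage midpoints, season end)
#: following the spring start / summer peak / dieback / autumn peak pattern
STAGE_AMPLITUDES = {
    "gpp": (0.30, 0.55, 1.00, 0.45, 0.80, 0.72),
    "reco": (0.55, 0.70, 1.00, 0.85, 0.80, 0.75),
    "et": (0.40, 0.60, 1.00, 0.55, 0.80, 0.72),
}



def _rng(config: TruthBundle, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generated table
    return np.random.default_rng([int(config.seed) % 2**31, stream])


class SyntheticSeason:
    """A generated season: meteorology plus noise-free truth flux functions."""

    def __init__(self, config: TruthBundle):
        self.config = config
        self.n_days = (config.season_end - config.season_start).days + 1
        self._stage_curves = {
            name: self._build_stage_curve(vals)
            for name, vals in STAGE_AMPLITUDES.items()
        }
        self.meteo = self._build_meteo()

    # -- construction --------------------------------------------------------

    def _build_stage_curve(self, values) -> PchipInterpolator:
        c = self.config
        total = (c.season_end - c.season_start).days
        mids = []
        edges = [c.season_start, *c.stage_breaks, c.season_end]
        for a, b in zip(edges[:-1], edges[1:]):
            mids.append(((a - c.season_start).days + (b - c.season_start).days) / 2 / total)
        # guard nodes flatten the curve outside the campaign-covered window,
        # where the offset-calibration method holds its values constant
        x = np.array([0.0, 0.06, *mids, 0.93, 1.0])
        y = np.array([values[0], values[0], *values[1:5], values[5], values[5]])
        return PchipInterpolator(x, y)

    def _build_meteo(self) -> pd.DataFrame:
        c = self.config
        ts = pd.date_range(
            pd.Timestamp(c.season_start),
            pd.Timestamp(c.season_end) + pd.Timedelta(hours=23, minutes=30),
            freq="30min",
        )
        frame = pd.DataFrame({"timestamp": ts})
        f = self.season_fraction(ts)
        doy = ts.dayofyear.to_numpy()
        hour = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0

        s = self._diel_shape(doy, hour)
        tmean = self._daily_mean_temp(f)
        frame["air_temp"] = tmean + 5.0 * np.cos(2 * np.pi * (hour - 14.5) / 24.0)
        # constant absolute humidity within a day (62% of saturation at the
        # daily-mean temperature); the diel RH cycle follows from air_temp
        e_a = 0.62 * saturation_vapor_pressure(tmean)
        frame["rh"] = np.clip(
            100.0 * e_a / saturation_vapor_pressure(frame["air_temp"].to_numpy()),
            25.0,
            98.0,
        )
        frame["ppfd"] = (900.0 + 650.0 * np.sin(np.pi * f)) * s
        frame["pressure"] = 98.8
        frame["precip"] = self._precip(ts)
        frame["precip_sheltered"] = (1.0 - c.precip_exclusion_frac) * frame["precip"]
        return frame

    def _precip(self, ts: pd.DatetimeIndex) -> np.ndarray:
        c = self.config
        rng = _rng(c, 0)
        wet = rng.random(self.n_days) < 0.45
        amounts = rng.gamma(0.9, 6.0, self.n_days) * wet
        if amounts.sum() > 0:
            amounts *= c.precip_total_mm / amounts.sum()
        precip = np.zeros(len(ts))
        day_index = (ts.normalize() - pd.Timestamp(c.season_start)).days.to_numpy()
        per_day = 48
        for d in np.nonzero(wet)[0]:
            k = int(rng.integers(1, 7))
            slots = rng.choice(per_day, size=k, replace=False)
            base = np.searchsorted(day_index, d)
            precip[base + slots] += amounts[d] / k
        return precip

    # -- geometry / drivers --------------------------------------------------

    def season_fraction(self, timestamps) -> np.ndarray:
        """Position of each timestamp inside the season, in [0, 1]."""
        ts = pd.DatetimeIndex(pd.to_datetime(timestamps))
        days = (ts.normalize() - pd.Timestamp(self.config.season_start)).days.to_numpy()
        return days / max(self.n_days - 1, 1)

    @staticmethod
    def _daylength(doy: np.ndarray) -> np.ndarray:
        return 12.0 + 3.4 * np.sin(2 * np.pi * (doy - 80) / 365.0)

    def daylight_window(self, date) -> tuple[float, float]:
        """Configured (sunrise, sunset) in decimal hours for a date."""
        doy = pd.Timestamp(date).dayofyear
        daylen = float(self._daylength(np.array([doy]))[0])
        sr = 13.0 - daylen / 2.0
        return sr, sr + daylen

    def _diel_shape(self, doy: np.ndarray, hour: np.ndarray) -> np.ndarray:
        """Half-sine of the photoperiod: 0 at night, 1 at solar noon."""
        daylen = self._daylength(doy)
        sr = 13.0 - daylen / 2.0
        phase = (hour - sr) / daylen
        s = np.sin(np.pi * np.clip(phase, 0.0, 1.0))
        return np.where((phase > 0) & (phase < 1), s, 0.0)

    @staticmethod
    def _daily_mean_temp(f: np.ndarray) -> np.ndarray:
        return 9.0 + 12.0 * np.sin(np.pi * np.clip(0.05 + 0.85 * f, 0.0, 1.0))

    # -- truth ---------------------------------------------------------------

    def truth_fluxes(self, treatment: str, timestamps) -> pd.DataFrame:
        """Noise-free component fluxes at arbitrary timestamps.

        Columns: ``gpp``/``reco``/``nee`` (umol CO2 m-2 s-1, GPP negative),
        ``t``/``e``/``et`` (mmol H2O m-2 s-1) and ``ft`` = T/ET.
        """
        c = self.config
        eff = c.treatment_effects[treatment]
        ts = pd.DatetimeIndex(pd.to_datetime(timestamps))
        f = self.season_fraction(ts)
        doy = ts.dayofyear.to_numpy()
        hour = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
        s = self._diel_shape(doy, hour)
        tmean = self._daily_mean_temp(f)

        gpp = -c.gpp_max * self._stage_curves["gpp"](f) * s * eff.gpp
        reco = (
            c.reco_ref
            * self._stage_curves["reco"](f)
            * c.q10 ** ((tmean - 15.0) / 10.0)
            * eff.reco
        )
        t_flux = c.t_max * self._stage_curves["et"](f) * s * eff.et
        # evaporation: a constant soil baseline plus a radiation-driven
        # daytime component with a flat shoulder (s^4), so that the flux is
        # at its night level well before sunset and after sunrise
        e_flux = (
            c.e_base
            * self._stage_curves["et"](f)
            * (1.25 - 0.5 * f)
            * (0.25 + 0.75 * s**4)
            * eff.et
        )
        et = t_flux + e_flux
        with np.errstate(invalid="ignore", divide="ignore"):
            ft = np.where(et > 0, t_flux / et, 0.0)
        return pd.DataFrame(
            {
                "timestamp": ts,
                "gpp": gpp,
                "reco": reco,
                "nee": gpp + reco,
                "t": t_flux,
                "e": e_flux,
                "et": et,
                "ft": ft,
            }
        )

    def true_ft(self, timestamps, treatment: str = "CC") -> np.ndarray:
        """True transpiration fraction T/ET at the given times (in [0, 1])."""
        return self.truth_fluxes(treatment, timestamps)["ft"].to_numpy()

    def truth_daily_sums(self, treatment: str) -> pd.DataFrame:
        """Daily truth sums on the 30-min grid (rectangle rule).

        Carbon in g C m-2 d-1, water in kg H2O m-2 d-1; ``ft_day`` is the
        daily T/ET ratio of the sums.
        """
        truth = self.truth_fluxes(treatment, self.meteo["timestamp"])
        truth["date"] = pd.to_datetime(truth["timestamp"]).dt.date
        g = truth.groupby("date")
        out = pd.DataFrame(
            {
                "gpp_sum": g["gpp"].sum() * 1800 * UMOL_CO2_TO_G_C,
                "reco_sum": g["reco"].sum() * 1800 * UMOL_CO2_TO_G_C,
                "nee_sum": g["nee"].sum() * 1800 * UMOL_CO2_TO_G_C,
                "t_sum": g["t"].sum() * 1800 * MMOL_H2O_TO_KG,
                "e_sum": g["e"].sum() * 1800 * MMOL_H2O_TO_KG,
                "et_sum": g["et"].sum() * 1800 * MMOL_H2O_TO_KG,
            }
        )
        out["ft_day"] = out["t_sum"] / out["et_sum"]
        return out.reset_index()

    def truth_season_sums(self, treatment: str) -> dict[str, float]:
        daily = self.truth_daily_sums(treatment)
        return {
            key: float(daily[f"{key}_sum"].sum())
            for key in ("gpp", "reco", "nee", "t", "e", "et")
        }

    # -- sampling helpers ----------------------------------------------------

    def default_campaign_dates(self) -> list[dt.date]:
        """Evenly spaced campaign days covering the season.

        Even spacing makes the nearest-neighbour offset series an
        (approximately) midpoint-exact quadrature of slowly varying
        treatment contrasts; an uneven field schedule can be passed to
        :func:`sample_chamber_campaigns` explicitly.
        """
        c = self.config
        offsets = np.linspace(8, self.n_days - 11, c.n_campaigns).round().astype(int)
        return [
            c.season_start + dt.timedelta(days=int(min(o, self.n_days - 1)))
            for o in offsets
        ]

    def _meteo_on(self, date) -> pd.DataFrame:
        ts = pd.to_datetime(self.meteo["timestamp"])
        return self.meteo[ts.dt.date == pd.Timestamp(date).date()]


def generate_season(config: TruthBundle) -> SyntheticSeason:
    """Build the synthetic world for a configuration (seeded, deterministic)."""
    return SyntheticSeason(config)


def sheltered_precip(ambient_mm: float, exclusion_frac: float) -> float:
    """Precipitation reaching sheltered plots: (1 - exclusion) * ambient."""
    if not 0.0 <= exclusion_frac <= 1.0:
        raise ValueError("exclusion fraction must lie in [0, 1]")
    return (1.0 - exclusion_frac) * ambient_mm


# ---------------------------------------------------------------------------
# chamber + isotope campaign sampling
# ---------------------------------------------------------------------------

def _vapor_mixing_ratio(rh, air_temp, pressure) -> np.ndarray:
    """Ambient H2O mixing ratio (mmol mol-1) from RH, T and pressure."""
    e_a = np.asarray(rh, float) / 100.0 * saturation_vapor_pressure(air_temp)
    return e_a / np.asarray(pressure, float) * 1000.0


def _invert_h2o(et, w_in, n_mol, area_m2) -> np.ndarray:
    """Outlet H2O mixing ratio that the dilution-corrected flux equation
    maps back onto ``et`` exactly."""
    k = np.asarray(et, float) * area_m2 / n_mol
    return (k + np.asarray(w_in, float)) / (1.0 + k / 1000.0)


def sample_chamber_campaigns(
    season: SyntheticSeason,
    campaign_dates=None,
    n_plots: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample chamber observations and isotope observations from the truth.

    Each campaign day is sampled at the configured cadence over the
    photoperiod: one transparent-chamber (light) record per plot and time,
    followed six minutes later by a darkened-chamber record whose truth NEE
    is Reco.  Mixing ratios are obtained by inverting the same open-chamber
    flux equation the analysis uses, then flux-equivalent Gaussian noise is
    added.  Isotope observations are constructed so that the mass-balance /
    Craig-Gordon / steady-state inversion recovers the true transpiration
    fraction exactly before noise.

    Returns (chamber table, isotope table).
    """
    c = season.config
    if campaign_dates is None:
        campaign_dates = season.default_campaign_dates()
    if n_plots is None:
        n_plots = c.n_plots
    if rng is None:
        rng = _rng(c, 1)

    struct_rng = _rng(c, 17)  # per-plot structural truth, independent of noise
    plot_source_offset = {
        f"{trt}-{p+1}": float(struct_rng.normal(0.0, 0.4))
        for trt in TREATMENTS
        for p in range(n_plots)
    }

    area_m2 = c.chamber_area_cm2 / CM2_PER_M2
    chamber_rows: list[pd.DataFrame] = []
    iso_rows: list[pd.DataFrame] = []

    for date in campaign_dates:
        met = season._meteo_on(date)
        lit = met[met["ppfd"] > PPFD_THRESHOLD]
        step = max(1, int(round(c.sample_interval_min / 30)))
        lit = lit.iloc[::step]
        if lit.empty:
            continue
        ts = pd.to_datetime(lit["timestamp"]).reset_index(drop=True)
        air_temp = lit["air_temp"].to_numpy(float)
        pressure = lit["pressure"].to_numpy(float)
        rh = lit["rh"].to_numpy(float)
        n_mol = molar_flow(c.chamber_flow, air_temp, pressure)
        w_in = _vapor_mixing_ratio(rh, air_temp, pressure)
        f = season.season_fraction(ts)
        tmean = season._daily_mean_temp(f)
        # the evaporating surface runs slightly warmer than the daily mean,
        # keeping normalized humidity in the 0.6-0.7 range so the
        # evaporation and transpiration endmembers stay well separated
        t_soil = tmean + 2.0
        e_a = rh / 100.0 * saturation_vapor_pressure(air_temp)
        h_norm = np.clip(e_a / saturation_vapor_pressure(t_soil), 0.05, 0.9)
        delta_soil_true = c.delta_soil_mean + c.delta_soil_seasonal * f
        delta_v_in_true = c.delta_vapor_in + 2.0 * f

        for trt in TREATMENTS:
            truth = season.truth_fluxes(trt, ts)
            for p in range(n_plots):
                plot_id = f"{trt}-{p+1}"
                for dark in (False, True):
                    nee_true = truth["reco"] if dark else truth["nee"]
                    et_true = truth["e"] if dark else truth["et"]
                    nee_obs = nee_true + rng.normal(0, c.noise_sd_flux_co2, len(ts))
                    et_obs = et_true + rng.normal(0, c.noise_sd_flux_h2o, len(ts))
                    stamp = ts + pd.Timedelta(minutes=6) if dark else ts
                    chamber_rows.append(
                        pd.DataFrame(
                            {
                                "timestamp": stamp,
                                "plot_id": plot_id,
                                "treatment": trt,
                                "co2_in": c.co2_ambient,
                                "co2_out": c.co2_ambient + nee_obs * area_m2 / n_mol,
                                "h2o_in": w_in,
                                "h2o_out": _invert_h2o(et_obs, w_in, n_mol, area_m2),
                                "flow": c.chamber_flow,
                                "base_area": c.chamber_area_cm2,
                                "air_temp": air_temp,
                                "pressure": pressure,
                                "dark": dark,
                            }
                        )
                    )

                # isotope observations accompany the light records only
                delta_t = c.delta_source_mean + plot_source_offset[plot_id]
                params = [
                    CraigGordonParams.for_temperature(tc, c.eps_k) for tc in t_soil
                ]
                delta_e = np.array(
                    [
                        craig_gordon_delta_e(ds, dv, h, pr)[0]
                        for ds, dv, h, pr in zip(
                            delta_soil_true, delta_v_in_true, h_norm, params
                        )
                    ]
                )
                ft_true = truth["ft"].to_numpy()
                delta_et = delta_e + ft_true * (delta_t - delta_e)
                w_out0 = _invert_h2o(truth["et"].to_numpy(), w_in, n_mol, area_m2)
                delta_v_out = (
                    delta_et * (w_out0 - w_in) + w_in * delta_v_in_true
                ) / w_out0
                noise = lambda: rng.normal(0, c.noise_sd_delta, len(ts))  # noqa: E731
                iso_rows.append(
                    pd.DataFrame(
                        {
                            "timestamp": ts,
                            "plot_id": plot_id,
                            "treatment": trt,
                            "delta_v_in": delta_v_in_true + noise(),
                            "delta_v_out": delta_v_out + noise(),
                            "w_in": w_in,
                            "w_out": w_out0,
                            "delta_soil": delta_soil_true + noise(),
                            "delta_source": delta_t + noise(),
                            "t_soil": t_soil,
                            "h_norm": h_norm,
                        }
                    )
                )

    chamber = pd.concat(chamber_rows, ignore_index=True)
    iso = pd.concat(iso_rows, ignore_index=True)
    return chamber.sort_values(["timestamp", "plot_id"]).reset_index(drop=True), iso


def sample_ec_series(
    season: SyntheticSeason, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Half-hourly eddy-covariance NEE/ET for the control treatment.

    The series is the true CC flux plus the configured additive daily-sum
    bias (spread uniformly over the 48 half-hours of each day) plus Gaussian
    noise; rank order relative to the truth is preserved in expectation.
    """
    c = season.config
    if rng is None:
        rng = _rng(c, 2)
    ts = season.meteo["timestamp"]
    truth = season.truth_fluxes("CC", ts)
    bias_nee = c.ec_offset_nee / (48 * 1800 * UMOL_CO2_TO_G_C)
    bias_et = c.ec_offset_et / (48 * 1800 * MMOL_H2O_TO_KG)
    return pd.DataFrame(
        {
            "timestamp": pd.to_datetime(ts),
            "nee": truth["nee"] + bias_nee + rng.normal(0, c.ec_noise_sd_nee, len(ts)),
            "et": truth["et"] + bias_et + rng.normal(0, c.ec_noise_sd_et, len(ts)),
        }
    )
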