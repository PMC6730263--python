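"""Open dynamic chamber gas exchange.

Fluxes follow the steady-state open-system balance: a chamber of base area
``A`` is flushed at a known molar air flow ``n`` and the flux is the flow
times the inlet/outlet mixing-ratio difference per unit ground area,

    F = n * (chi_out - chi_in) / A .

Sign conventions: NEE < 0 is net carbon uptake (the outlet is depleted in
CO2), ET > 0 is water loss to the atmosphere, Reco (dark NEE) is stored
positive as a release, and GPP = NEE - Reco is negative for uptake.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

R_GAS = 8.314462618  # J mol-1 K-1
CM2_PER_M2 = 1e4

#: dark/light pairing window (nearest dark record, ties -> earlier)
PAIRING_WINDOW_MIN = 30.0


def molar_flow(flow, air_temp, pressure):
    """Convert a volumetric chamber flow to a molar air flow.

    Ideal gas: n = P * Vdot / (R * T).

    Parameters
    ----------
    flow : L min-1 (> 0)
    air_temp : degC
    pressure : kPa

    Returns
    -------
    mol air s-1 (scalar or array, following the inputs)
    """
    flow_arr = np.asarray(flow, dtype=float)
    if np.any(flow_arr <= 0):
        raise ValueError("chamber flow must be positive")
    t_k = np.asarray(air_temp, dtype=float) + 273.15
    if np.any(t_k <= 0):
        raise ValueError("air temperature below 0 K")
    vdot = flow_arr / 1000.0 / 60.0  # m3 s-1
    n = np.asarray(pressure, dtype=float) * 1000.0 * vdot / (R_GAS * t_k)
    n = np.asarray(n)
    return n if n.ndim else float(n)


def chamber_flux(obs: pd.DataFrame, dilution_correction: bool = True) -> pd.DataFrame:
    """Compute NEE and ET from chamber inlet/outlet mixing ratios.

    Parameters
    ----------
    obs : one row per chamber reading with columns ``timestamp``, ``plot_id``,
        ``treatment``, ``co2_in``/``co2_out`` (umol mol-1), ``h2o_in``/
        ``h2o_out`` (mmol mol-1), ``flow`` (L min-1), ``base_area`` (cm2),
        ``air_temp`` (degC), ``pressure`` (kPa), ``dark`` (bool).
    dilution_correction : divide the H2O flux by (1 - x_out), the outlet
        water mole fraction, to account for the water vapor added by the
        plot itself diluting the dry air stream.  Applied to ET only.

    Returns
    -------
    Frame with ``nee`` (umol CO2 m-2 s-1), ``et`` (mmol H2O m-2 s-1) and a
    ``flag`` column; condensation (h2o_out < h2o_in) yields negative ET and
    the flag ``condensation`` plus a warning, not an exception.
    """
    n = molar_flow(obs["flow"], obs["air_temp"], obs["pressure"])
    area = np.asarray(obs["base_area"], dtype=float) / CM2_PER_M2
    if np.any(area <= 0):
        raise ValueError("chamber base area must be positive")

    nee = n * (obs["co2_out"].to_numpy(float) - obs["co2_in"].to_numpy(float)) / area
    dw = obs["h2o_out"].to_numpy(float) - obs["h2o_in"].to_numpy(float)
    et = n * dw / area
    if dilution_correction:
        et = et / (1.0 - obs["h2o_out"].to_numpy(float) / 1000.0)

    flag = np.where(dw < 0, "condensation", "ok").astype(object)
    if np.any(dw < 0):
        warnings.warn(
            "h2o_out < h2o_in on some records (condensation); ET reported negative",
            stacklevel=2,
        )
    out = obs[["timestamp", "plot_id", "treatment", "dark"]].copy()
    out["nee"] = nee
    out["et"] = et
    out["flag"] = flag
    return out


def _pair_nearest(light_times: np.ndarray, dark_times: np.ndarray) -> np.ndarray:
    """Index of the nearest dark time for each light time; ties -> earlier."""
    idx = np.searchsorted(dark_times, light_times)
    left = np.clip(idx - 1, 0, dark_times.size - 1)
    right = np.clip(idx, 0, dark_times.size - 1)
    d_left = np.abs(light_times - dark_times[left])
    d_right = np.abs(light_times - dark_times[right])
    return np.where(d_left <= d_right, left, right)  # <= implements the tie rule


def partition_nee(
    fluxes: pd.DataFrame, window_minutes: float = PAIRING_WINDOW_MIN
) -> pd.DataFrame:
    """Split NEE into Reco and GPP using paired dark-chamber records.

    Each light record is matched to the temporally nearest dark record of the
    same plot within ``window_minutes`` (ties resolved to the earlier dark
    record).  Reco is the dark NEE (positive release); GPP = NEE - Reco.
    Light records with no dark partner inside the window are flagged
    ``unpartitioned`` and keep NaN Reco/GPP.  Dark records themselves carry
    Reco = NEE and GPP = 0.
    """
    df = fluxes.copy()
    df["reco"] = np.nan
    df["gpp"] = np.nan
    df["partition_flag"] = "ok"
    dark_mask = df["dark"].astype(bool).to_numpy()
    df.loc[dark_mask, "reco"] = df.loc[dark_mask, "nee"]
    df.loc[dark_mask, "gpp"] = 0.0

    window = pd.Timedelta(minutes=window_minutes)
    for _, sub in df.groupby("plot_id"):
        light = sub[~sub["dark"].astype(bool)]
        dark = sub[sub["dark"].astype(bool)].sort_values("timestamp")
        if light.empty:
            continue
        if dark.empty:
            df.loc[light.index, "partition_flag"] = "unpartitioned"
            continue
        lt = pd.to_datetime(light["timestamp"]).to_numpy()
        dt_ = pd.to_datetime(dark["timestamp"]).to_numpy()
        nearest = _pair_nearest(lt.astype("datetime64[ns]").astype(np.int64),
                                dt_.astype("datetime64[ns]").astype(np.int64))
        gap = np.abs(lt - dt_[nearest])
        ok = gap <= np.timedelta64(window.to_timedelta64())
        reco = dark["nee"].to_numpy(float)[nearest]
        idx = light.index
        df.loc[idx[ok], "reco"] = reco[ok]
        df.loc[idx[ok], "gpp"] = light["nee"].to_numpy(float)[ok] - reco[ok]
        df.loc[idx[~ok], "partition_flag"] = "unpartitioned"
    return df


def wue_can(gpp_daily, t_daily, gpp_sd=0.0, t_sd=0.0):
    """Canopy water use efficiency |GPP|/T in g C per kg H2O on daily sums.

    Returns (wue, sd, flag); T <= 0 is undefined and flagged.
    """
    gpp = np.asarray(gpp_daily, dtype=float)
    t = np.asarray(t_daily, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        wue = np.where(t > 0, np.abs(gpp) / t, np.nan)
        rel = np.sqrt(
            np.where(gpp != 0, (np.asarray(gpp_sd) / gpp) ** 2, 0.0)
            + np.where(t != 0, (np.asarray(t_sd) / t) ** 2, 0.0)
        )
        sd = np.abs(wue) * rel
    flag = np.where(t > 0, "ok", "undefined").astype(object)
    if np.ndim(gpp_daily) == 0 and np.ndim(t_daily) == 0:
        return float(wue), float(sd), str(flag)
    return wue, sd, flag


def wue_eco(nee_daily, et_daily, nee_sd=0.0, et_sd=0.0):
    """Ecosystem water use efficiency (-NEE)/ET in g C per kg H2O.

    NEE enters sign-flipped so that carbon assimilation gives positive
    efficiency; a net carbon source (NEE > 0) yields a negative value.
    Returns (wue, sd, flag); ET <= 0 is undefined and flagged.
    """
    nee = np.asarray(nee_daily, dtype=float)
    et = np.asarray(et_daily, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        wue = np.where(et > 0, -nee / et, np.nan)
        rel = np.sqrt(
            np.where(nee != 0, (np.asarray(nee_sd) / nee) ** 2, 0.0)
            + np.where(et != 0, (np.asarray(et_sd) / et) ** 2, 0.0)
        )
        sd = np.abs(wue) * rel
    flag = np.where(et > 0, "ok", "undefined").astype(object)
    if np.ndim(nee_daily) == 0 and np.ndim(et_daily) == 0:
        return float(wue), float(sd), str(flag)
    return wue, sd, flag
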