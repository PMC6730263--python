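"""Meteorological derivations and soil-moisture series utilities.

Vapor pressure deficit from the August-Roche-Magnus saturation curve, gap
filling of volumetric water content (VWC) records (linear for short gaps, a
replicate-offset reconstruction for broken sensors), and treatment summaries
of VWC relative to the control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Magnus coefficients (saturation pressure in kPa, temperature in degC).
MAGNUS_A = 17.625
MAGNUS_B = 243.04
MAGNUS_C = 0.61094

#: Gaps longer than this many days are reconstructed from replicate sensors
#: instead of linearly interpolated.
LONG_GAP_DAYS = 10

#: Number of pre-gap points used to estimate a broken sensor's offset.
OFFSET_WINDOW = 10


def saturation_vapor_pressure(air_temp: np.ndarray | float) -> np.ndarray | float:
    """Saturated vapor pressure e_s in kPa (August-Roche-Magnus form)."""
    t = np.asarray(air_temp, dtype=float)
    es = MAGNUS_C * np.exp(MAGNUS_A * t / (t + MAGNUS_B))
    return es if es.ndim else float(es)


def vpd_magnus(air_temp, rh):
    """Vapor pressure deficit in kPa from air temperature (degC) and RH (%).

    VPD = e_s(T) * (1 - RH/100); non-negative for RH in [0, 100].
    """
    rh_arr = np.asarray(rh, dtype=float)
    if np.any(rh_arr < 0) or np.any(rh_arr > 100):
        raise ValueError("relative humidity must lie in [0, 100] %")
    vpd = saturation_vapor_pressure(air_temp) * (1.0 - rh_arr / 100.0)
    vpd = np.asarray(vpd)
    return vpd if vpd.ndim else float(vpd)


def _gap_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """Start/stop (half-open) index pairs of consecutive-missing runs."""
    runs = []
    i = 0
    n = missing.size
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def gap_fill_vwc(
    series: pd.Series,
    replicates: pd.DataFrame | None = None,
    long_gap_days: int = LONG_GAP_DAYS,
    offset_window: int = OFFSET_WINDOW,
) -> pd.DataFrame:
    """Fill gaps in a daily VWC series, tracking provenance flags.

    Gaps of ``long_gap_days`` or fewer days are filled by linear interpolation
    between the bracketing measurements.  Longer gaps (a broken sensor) are
    reconstructed from replicate sensors: the mean offset between the broken
    sensor's last ``offset_window`` pre-gap values and the replicate mean at
    those same times is added to the replicate mean over the gap.

    Parameters
    ----------
    series : daily VWC of one sensor, indexed by a daily DatetimeIndex;
        gaps are NaN.
    replicates : optional frame of replicate sensors on the same index
        (columns = sensors); used only for long gaps.

    Returns
    -------
    DataFrame with columns ``vwc`` and ``flag``
    (``measured`` / ``interpolated`` / ``offset_modeled`` / ``missing``).
    """
    values = series.to_numpy(dtype=float).copy()
    flags = np.where(np.isnan(values), "missing", "measured").astype(object)
    rep_mean = (
        replicates.mean(axis=1).to_numpy(dtype=float) if replicates is not None else None
    )

    for start, stop in _gap_runs(np.isnan(values)):
        length = stop - start
        if length <= long_gap_days and start > 0 and stop < values.size:
            left, right = values[start - 1], values[stop]
            frac = np.arange(1, length + 1) / (length + 1)
            values[start:stop] = left + frac * (right - left)
            flags[start:stop] = "interpolated"
        elif rep_mean is not None:
            pre = np.arange(max(0, start - offset_window), start)
            ok = pre[~np.isnan(rep_mean[pre])] if pre.size else pre
            if ok.size == 0 or np.any(np.isnan(rep_mean[start:stop])):
                continue  # left missing, flagged as such
            offset = float(np.mean(values[ok] - rep_mean[ok]))
            values[start:stop] = rep_mean[start:stop] + offset
            flags[start:stop] = "offset_modeled"
    return pd.DataFrame({"vwc": values, "flag": flags}, index=series.index)


def treatment_vwc_difference(
    daily: pd.DataFrame,
    stage_windows: dict[str, tuple] | None = None,
    control: str = "CC",
) -> pd.DataFrame:
    """Percent difference in mean VWC of each treatment relative to control.

    Parameters
    ----------
    daily : long frame with columns ``date``, ``treatment``, ``vwc`` and
        optionally ``depth``.
    stage_windows : optional mapping stage label -> (start, end) dates; when
        given, differences are reported per stage.

    Returns
    -------
    Frame with columns ``treatment``, ``depth`` (if present), ``stage`` (if
    requested) and ``pct_vs_control`` = 100 * (mean_trt - mean_ctl) / mean_ctl.
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    group_cols = ["depth"] if "depth" in df.columns else []

    def _one(frame: pd.DataFrame, stage_label) -> list[dict]:
        rows = []
        keys = frame.groupby(group_cols) if group_cols else [((), frame)]
        for key, sub in keys:
            means = sub.groupby("treatment")["vwc"].mean()
            if control not in means or means[control] == 0:
                continue
            for trt, m in means.items():
                if trt == control:
                    continue
                row = {
                    "treatment": trt,
                    "pct_vs_control": 100.0 * (m - means[control]) / means[control],
                }
                if group_cols:
                    row["depth"] = key if np.isscalar(key) else key[0]
                if stage_label is not None:
                    row["stage"] = stage_label
                rows.append(row)
        return rows

    rows: list[dict] = []
    if stage_windows:
        for label, (start, end) in stage_windows.items():
            mask = (df["date"] >= pd.Timestamp(start)) & (df["date"] <= pd.Timestamp(end))
            rows.extend(_one(df[mask], label))
    else:
        rows.extend(_one(df, None))
    return pd.DataFrame(rows)
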