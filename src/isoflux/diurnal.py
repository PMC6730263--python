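"""Diel smoothing and daily integration of campaign fluxes.

Campaign-day flux series are smoothed by local polynomial regression (loess)
with a 68% confidence band (+- 1 standard error of the local fit) and then
integrated to daily sums under the night rules: transpiration and GPP are
zero at sunrise, at sunset and through the night; soil evaporation and
ecosystem respiration continue at night at the mean level of the first/last
measured hour; night NEE equals Reco and night ET equals E.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: unit conversions from per-second rates to daily mass sums
UMOL_CO2_TO_G_C = 12e-6  # umol CO2 -> g C
MMOL_H2O_TO_KG = 18e-6  # mmol H2O -> kg H2O

PPFD_DAYLIGHT_THRESHOLD = 5.0  # umol m-2 s-1
LOESS_SPAN_DEFAULT = 0.75
LOESS_DEGREE_DEFAULT = 1
NIGHT_EDGE_HOURS = 1.0  # averaging window for the night extrapolation
MIN_WINDOW_HOURS = 2.0  # shorter measurement windows are low-confidence


# ---------------------------------------------------------------------------
# loess
# ---------------------------------------------------------------------------

def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess_smooth(
    x,
    y,
    span: float = LOESS_SPAN_DEFAULT,
    degree: int = LOESS_DEGREE_DEFAULT,
    eval_x=None,
):
    """Local polynomial regression with tricube weights and a 68% band.

    At each evaluation point the nearest ``ceil(span * n)`` observations are
    weighted by the tricube kernel of their scaled distance and a degree-1
    (or 2) polynomial is fitted by weighted least squares.  The band is the
    pointwise standard error of that local fit, computed from the local
    weighted residual variance, so it collapses to zero in the noise-free
    limit.

    With fewer than 4 points the method falls back to linear interpolation
    with a zero band and ``flag`` set to ``fallback_linear``.

    Returns (fitted, se, flag).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be matching 1-d arrays")
    xe = x if eval_x is None else np.asarray(eval_x, dtype=float)

    if x.size < 4:
        fit = np.interp(xe, x, y)
        return fit, np.zeros_like(fit), "fallback_linear"

    order = np.argsort(x)
    xs, ys = x[order], y[order]
    k = max(degree + 2, int(np.ceil(span * xs.size)))
    k = min(k, xs.size)

    fit = np.empty(xe.size)
    se = np.empty(xe.size)
    for i, x0 in enumerate(xe):
        dist = np.abs(xs - x0)
        idx = np.argpartition(dist, k - 1)[:k]
        h = dist[idx].max()
        if h == 0:
            fit[i] = ys[idx][dist[idx] == 0].mean()
            se[i] = 0.0
            continue
        w = _tricube(dist[idx] / h)
        pos = w > 0
        xw, yw, ww = xs[idx][pos], ys[idx][pos], w[pos]
        # weighted design matrix centred on x0 for conditioning
        basis = np.vander(xw - x0, degree + 1, increasing=True)
        sw = np.sqrt(ww)
        beta, *_ = np.linalg.lstsq(basis * sw[:, None], yw * sw, rcond=None)
        fit[i] = beta[0]

        resid = yw - basis @ beta
        n_loc = int(pos.sum())
        dof = max(n_loc - (degree + 1), 1)
        sigma2 = np.sum(ww * resid**2) / np.sum(ww) * n_loc / dof
        # variance of the local estimate: l^T l * sigma^2 with
        # l = e1^T (X^T W X)^-1 X^T W
        xtwx = basis.T @ (basis * ww[:, None])
        try:
            cov_row = np.linalg.solve(xtwx, basis.T * ww)
        except np.linalg.LinAlgError:
            se[i] = np.nan
            continue
        l_vec = cov_row[0]
        se[i] = np.sqrt(max(sigma2, 0.0) * float(l_vec @ l_vec))
    return fit, se, "ok"


# ---------------------------------------------------------------------------
# photoperiod and integration
# ---------------------------------------------------------------------------

def day_bounds(
    meteo: pd.DataFrame, date, ppfd_threshold: float = PPFD_DAYLIGHT_THRESHOLD
):
    """Sunrise and sunset of a date from the PPFD record.

    Sunrise is estimated by back-extrapolating the morning PPFD ramp (the
    line through the first two above-threshold samples) to zero, clipped to
    the interval between the last dark and first lit sample; sunset
    symmetrically from the evening ramp.  With a single lit sample the
    bounds collapse to its timestamp.  Returns (sunrise, sunset), or
    (None, None) on an all-dark day.
    """
    ts = pd.to_datetime(meteo["timestamp"])
    day = meteo[ts.dt.date == pd.Timestamp(date).date()]
    ppfd = day["ppfd"].to_numpy(float)
    lit_idx = np.nonzero(ppfd > ppfd_threshold)[0]
    if lit_idx.size == 0:
        return None, None
    day_ts = pd.to_datetime(day["timestamp"]).reset_index(drop=True)

    def _zero_crossing(i_a, i_b, i_dark):
        # line through two lit samples, extrapolated to PPFD = 0
        p_a, p_b = ppfd[i_a], ppfd[i_b]
        t_a, t_b = day_ts.iloc[i_a], day_ts.iloc[i_b]
        if p_b == p_a:
            return t_a
        cross = t_a - (t_b - t_a) * float(p_a / (p_b - p_a))
        lo, hi = sorted(
            [day_ts.iloc[i_dark] if 0 <= i_dark < ppfd.size else t_a, t_a]
        )
        return min(max(cross, lo), hi)

    first, last = int(lit_idx[0]), int(lit_idx[-1])
    if last == first:
        return day_ts.iloc[first], day_ts.iloc[first]
    sunrise = _zero_crossing(first, first + 1, first - 1)
    sunset = _zero_crossing(last, last - 1, last + 1)
    return sunrise, sunset


@dataclass
class DailySum:
    """Daily flux integrals for one plot/treatment and date.

    Carbon sums in g C m-2 d-1 (NEE negative for a sink), water sums in
    kg H2O m-2 d-1.  The composition identities ``nee = gpp + reco`` and
    ``et = t + e`` hold by construction.
    """

    date: object
    label: str
    nee_sum: float
    et_sum: float
    gpp_sum: float
    reco_sum: float
    t_sum: float
    e_sum: float
    sunrise: object
    sunset: object
    nee_sd: float = 0.0
    et_sd: float = 0.0
    gpp_sd: float = 0.0
    reco_sd: float = 0.0
    t_sd: float = 0.0
    e_sd: float = 0.0
    flags: list = field(default_factory=list)


def _seconds_of_day(times, date) -> np.ndarray:
    base = pd.Timestamp(date)
    td = pd.DatetimeIndex(pd.to_datetime(np.atleast_1d(np.asarray(times, dtype=object)))) - base
    return td.total_seconds().to_numpy()


def _trapz_with_sd(t_sec, values, sds):
    """Trapezoid integral and quadrature SD (independence assumed)."""
    integral = float(np.trapezoid(values, t_sec))
    # trapezoid weights: w_i = (t_{i+1} - t_{i-1}) / 2 at interior points
    w = np.zeros_like(t_sec)
    if t_sec.size > 1:
        w[1:-1] = (t_sec[2:] - t_sec[:-2]) / 2.0
        w[0] = (t_sec[1] - t_sec[0]) / 2.0
        w[-1] = (t_sec[-1] - t_sec[-2]) / 2.0
    sd = float(np.sqrt(np.sum((w * np.asarray(sds)) ** 2)))
    return integral, sd


def _edge_mean(t_sec, values, sds, t_lo, t_hi):
    mask = (t_sec >= t_lo) & (t_sec <= t_hi)
    if not mask.any():
        mask = np.zeros_like(t_sec, bool)
        mask[np.argmin(np.abs(t_sec - (t_lo + t_hi) / 2))] = True
    n = mask.sum()
    return float(np.mean(values[mask])), float(
        np.sqrt(np.sum(np.asarray(sds)[mask] ** 2)) / n
    )


def integrate_daily(
    smoothed: pd.DataFrame,
    date,
    sunrise,
    sunset,
    label: str = "",
    night_edge_hours: float = NIGHT_EDGE_HOURS,
) -> DailySum:
    """Integrate smoothed component fluxes over one calendar day.

    Parameters
    ----------
    smoothed : frame with ``timestamp`` plus columns ``gpp``, ``reco``
        (umol CO2 m-2 s-1), ``t``, ``e`` (mmol H2O m-2 s-1) and optional
        ``<name>_sd`` companions, on the measured (daytime) window.
    date : the calendar day.
    sunrise, sunset : photoperiod bounds from :func:`day_bounds`.

    Notes
    -----
    GPP and T are anchored to zero at sunrise and sunset and integrated by
    the trapezoid rule; Reco and E are integrated over the measured window
    and extrapolated through the night at the mean of the first (last)
    measured hour; NEE and ET daily sums are composed from the parts, which
    makes the identities exact.  An all-dark day (no photoperiod) carries
    zero GPP and T sums.
    """
    sums = {}
    sds = {}
    flags = []
    t_sec = _seconds_of_day(smoothed["timestamp"], date)
    order = np.argsort(t_sec)
    t_sec = np.asarray(t_sec)[order]
    day_len = 86400.0

    t0, t1 = float(t_sec[0]), float(t_sec[-1])
    if (t1 - t0) < MIN_WINDOW_HOURS * 3600.0:
        flags.append("low_confidence_short_window")

    def col(name):
        v = smoothed[name].to_numpy(float)[order]
        s = (
            smoothed[f"{name}_sd"].to_numpy(float)[order]
            if f"{name}_sd" in smoothed
            else np.zeros_like(v)
        )
        return v, s

    sr = _seconds_of_day(pd.Series([sunrise]), date)[0] if sunrise is not None else None
    ss = _seconds_of_day(pd.Series([sunset]), date)[0] if sunset is not None else None

    # --- photosynthesis-coupled fluxes: zero outside [sunrise, sunset] ------
    for name, conv in (("gpp", UMOL_CO2_TO_G_C), ("t", MMOL_H2O_TO_KG)):
        v, s = col(name)
        if sr is None:
            sums[name], sds[name] = 0.0, 0.0
            continue
        inside = (t_sec > sr) & (t_sec < ss)
        tt = np.concatenate(([sr], t_sec[inside], [ss]))
        vv = np.concatenate(([0.0], v[inside], [0.0]))
        uu = np.concatenate(([0.0], s[inside], [0.0]))
        integral, sd = _trapz_with_sd(tt, vv, uu)
        sums[name] = integral * conv
        sds[name] = sd * conv

    # --- continuing fluxes: day trapezoid + night extrapolation -------------
    edge = night_edge_hours * 3600.0
    for name, conv in (("reco", UMOL_CO2_TO_G_C), ("e", MMOL_H2O_TO_KG)):
        v, s = col(name)
        day_int, day_sd = _trapz_with_sd(t_sec, v, s)
        start_val, start_sd = _edge_mean(t_sec, v, s, t0, t0 + edge)
        end_val, end_sd = _edge_mean(t_sec, v, s, t1 - edge, t1)
        night_int = start_val * t0 + end_val * (day_len - t1)
        night_var = (start_sd * t0) ** 2 + (end_sd * (day_len - t1)) ** 2
        sums[name] = (day_int + night_int) * conv
        sds[name] = float(np.sqrt(day_sd**2 + night_var)) * conv

    nee_sum = sums["gpp"] + sums["reco"]
    et_sum = sums["t"] + sums["e"]
    nee_sd = float(np.hypot(sds["gpp"], sds["reco"]))
    et_sd = float(np.hypot(sds["t"], sds["e"]))

    return DailySum(
        date=pd.Timestamp(date).date(),
        label=label,
        nee_sum=nee_sum,
        et_sum=et_sum,
        gpp_sum=sums["gpp"],
        reco_sum=sums["reco"],
        t_sum=sums["t"],
        e_sum=sums["e"],
        sunrise=sunrise,
        sunset=sunset,
        nee_sd=nee_sd,
        et_sd=et_sd,
        gpp_sd=sds["gpp"],
        reco_sd=sds["reco"],
        t_sd=sds["t"],
        e_sd=sds["e"],
        flags=flags,
    )


# ---------------------------------------------------------------------------
# error propagation helpers
# ---------------------------------------------------------------------------

def propagate_sd_sum(sds, weights=None) -> float:
    """SD of a (weighted) sum of independent terms: quadrature."""
    sds = np.asarray(sds, dtype=float)
    if np.any(sds < 0):
        raise ValueError("standard deviations must be non-negative")
    w = np.ones_like(sds) if weights is None else np.asarray(weights, dtype=float)
    return float(np.sqrt(np.sum((w * sds) ** 2)))


def propagate_sd_ratio(num, num_sd, den, den_sd) -> float:
    """First-order SD of a ratio num/den: relative variances add."""
    ratio = num / den
    rel_var = ((num_sd / num) ** 2 if num != 0 else 0.0) + (
        (den_sd / den) ** 2 if den != 0 else 0.0
    )
    return float(abs(ratio) * np.sqrt(rel_var))
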