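"""delta-18O based evapotranspiration partitioning.

The transpired fraction of evapotranspiration follows from a two-endmember
isotope mixing of the net water vapor flux,

    ft = T/ET = (dET - dE) / (dT - dE),

where dET is measured by chamber mass balance, dE is the Craig-Gordon
composition of soil evaporation, and dT is the source-water composition
under isotopic steady state.  All deltas are permil vs VSMOW; only the
oxygen-18 isotopologue is treated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: default kinetic fractionation, permil.  The fully turbulent-to-molecular
#: diffusion range for 18O spans 0 to ~28.5 permil; a mid-range aerodynamic
#: weight of 0.5 is the default (28.5 * 0.5).
EPS_K_DEFAULT = 14.25

#: minimum |dT - dE| (permil) for a well-conditioned partition
CONDITIONING_THRESHOLD = 1.0


def calibrate_delta(raw_delta, standards, times=None, drift=None):
    """Map raw spectrometer deltas onto the VSMOW scale.

    An ordinary least-squares line measured -> true is fitted through the
    laboratory standards (at least two, typically light/middle/heavy) and
    applied to the raw values.  If ``drift`` is given as ``(drift_times,
    drift_measured)`` for a standard of constant composition sampled
    repeatedly, a time-linear instrument drift is removed first (relative to
    the drift trend's mean level, so the standards mapping is unaffected on
    average).

    Parameters
    ----------
    raw_delta : measured deltas, permil
    standards : sequence of (true, measured) pairs
    times, drift : optional drift correction inputs; ``times`` are the
        measurement times of ``raw_delta`` (any numeric or datetime64 scale
        shared with ``drift_times``).

    Returns
    -------
    Calibrated deltas, same shape as ``raw_delta``.
    """
    standards = np.asarray(standards, dtype=float)
    if standards.ndim != 2 or standards.shape[0] < 2:
        raise ValueError("need at least two (true, measured) standard pairs")
    true, measured = standards[:, 0], standards[:, 1]
    if np.ptp(measured) == 0:
        raise ValueError("standard measured values are identical; fit is singular")

    raw = np.asarray(raw_delta, dtype=float)
    if drift is not None:
        if times is None:
            raise ValueError("drift correction requires the sample times")
        drift_times, drift_measured = drift
        tx = _to_numeric_time(drift_times)
        ty = np.asarray(drift_measured, dtype=float)
        slope, intercept = np.polyfit(tx, ty, 1)
        t_raw = _to_numeric_time(times)
        trend = slope * t_raw + intercept
        raw = raw - (trend - ty.mean())

    # measured -> true line by least squares (exact for 2 points / collinear)
    a, b = np.polyfit(measured, true, 1)
    out = a * raw + b
    out = np.asarray(out)
    return out if out.ndim else float(out)


def _to_numeric_time(t):
    arr = np.asarray(t)
    if np.issubdtype(arr.dtype, np.datetime64):
        return arr.astype("datetime64[s]").astype(float)
    return arr.astype(float)


def delta_et_mass_balance(w_in, delta_in, w_out, delta_out):
    """Isotopic composition of the net vapor flux by chamber mass balance.

    dET = (w_out * d_out - w_in * d_in) / (w_out - w_in).

    Requires a net vapor source (w_out > w_in); otherwise the value is NaN
    and flagged.  Returns (delta_et, flag).
    """
    w_in = np.asarray(w_in, dtype=float)
    w_out = np.asarray(w_out, dtype=float)
    d_in = np.asarray(delta_in, dtype=float)
    d_out = np.asarray(delta_out, dtype=float)
    dw = w_out - w_in
    with np.errstate(divide="ignore", invalid="ignore"):
        det = np.where(dw > 0, (w_out * d_out - w_in * d_in) / dw, np.nan)
    flag = np.where(dw > 0, "ok", "no_net_source").astype(object)
    if det.ndim == 0:
        return float(det), str(flag)
    return det, flag


def alpha_equilibrium_18o(temp):
    """Equilibrium liquid-vapor fractionation factor for 18O.

    ln(alpha) = 1137/T^2 - 0.4156/T - 0.0020667 with T in kelvin
    (Majoube-1971 coefficients); alpha > 1 and decreases with temperature
    over the environmental range.  Valid for -10 to 60 degC.
    """
    t = np.asarray(temp, dtype=float)
    if np.any(t < -10) or np.any(t > 60):
        raise ValueError("temperature outside the supported -10..60 degC range")
    tk = t + 273.15
    ln_alpha = 1137.0 / tk**2 - 0.4156 / tk - 0.0020667
    alpha = np.exp(ln_alpha)
    alpha = np.asarray(alpha)
    return alpha if alpha.ndim else float(alpha)


@dataclass(frozen=True)
class CraigGordonParams:
    """Fractionation parameters of the Craig-Gordon evaporation model.

    ``alpha_eq`` is the temperature-dependent equilibrium factor (> 1),
    ``eps_k`` the kinetic (diffusive) enrichment in permil.  ``eps_eq`` is
    the equilibrium enrichment (alpha_eq - 1) * 1000, kept for reporting.
    """

    alpha_eq: float
    eps_k: float = EPS_K_DEFAULT
    formulation: str = "craig-gordon/majoube1971"

    @property
    def eps_eq(self) -> float:
        return (self.alpha_eq - 1.0) * 1000.0

    @classmethod
    def for_temperature(cls, temp_c, eps_k: float = EPS_K_DEFAULT):
        return cls(alpha_eq=alpha_equilibrium_18o(temp_c), eps_k=eps_k)


def craig_gordon_delta_e(delta_soil, delta_v_atm, h_norm, params: CraigGordonParams):
    """Isotopic composition of soil evaporation (Craig-Gordon model).

        dE = [ (1000 + d_soil)/alpha_eq - h * (1000 + d_atm) ]
             / [ (1 - h) * (1 + eps_k/1000) ]  -  1000

    with ``h`` the atmospheric humidity normalised to the temperature of the
    evaporating surface.  Undefined (NaN, flagged) when h >= 1, i.e. when
    there is no net evaporation.  Returns (delta_e, flag).
    """
    ds = np.asarray(delta_soil, dtype=float)
    da = np.asarray(delta_v_atm, dtype=float)
    h = np.asarray(h_norm, dtype=float)
    if np.any(h < 0):
        raise ValueError("normalized humidity must be non-negative")
    alpha = np.asarray(params.alpha_eq, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (1000.0 + ds) / alpha - h * (1000.0 + da)
        den = (1.0 - h) * (1.0 + params.eps_k / 1000.0)
        de = np.where(h < 1.0, num / den - 1000.0, np.nan)
    flag = np.where(h < 1.0, "ok", "no_net_evaporation").astype(object)
    if de.ndim == 0:
        return float(de), str(flag)
    return de, flag


def delta_t_steady_state(delta_source):
    """Isotopic composition of transpiration under isotopic steady state.

    At steady state the transpired vapor carries the (liquid) source-water
    signature unchanged, so dT = d_source.  Non-steady-state leaf-water
    enrichment is a deliberate extension point, not implemented.
    """
    out = np.asarray(delta_source, dtype=float)
    return out if out.ndim else float(out)


def partition_ft(
    delta_et,
    delta_e,
    delta_t,
    et,
    sd_delta: float = 0.0,
    et_sd=0.0,
    conditioning_threshold: float = CONDITIONING_THRESHOLD,
):
    """Partition ET into transpiration and evaporation via endmember mixing.

    ft_raw = (dET - dE) / (dT - dE); ft is ft_raw clamped to [0, 1] (the
    ``clamped`` column records when that happened), T = ft * ET and
    E = ET - T so that E + T = ET exactly.  Records with |dT - dE| below the
    conditioning threshold are flagged ``ill_conditioned`` and left NaN.

    Standard deviations are first-order propagated assuming the same
    independent uncertainty ``sd_delta`` on each of the three deltas.

    Returns a dict of arrays: ``ft_raw``, ``ft``, ``clamped``, ``t``, ``e``,
    ``ft_sd``, ``t_sd``, ``e_sd``, ``flag``.
    """
    det = np.asarray(delta_et, dtype=float)
    de = np.asarray(delta_e, dtype=float)
    dt_ = np.asarray(delta_t, dtype=float)
    et_arr = np.asarray(et, dtype=float)
    det, de, dt_, et_arr = np.broadcast_arrays(det, de, dt_, et_arr)

    denom = dt_ - de
    valid = np.abs(denom) >= conditioning_threshold
    with np.errstate(divide="ignore", invalid="ignore"):
        ft_raw = np.where(valid, (det - de) / denom, np.nan)
    ft = np.clip(ft_raw, 0.0, 1.0)
    clamped = valid & ((ft_raw < 0.0) | (ft_raw > 1.0))

    # d ft/d dET = 1/D ; d ft/d dT = -(dET-dE)/D^2 ; d ft/d dE = (dET-dT)/D^2
    with np.errstate(divide="ignore", invalid="ignore"):
        g_et = 1.0 / denom
        g_t = -(det - de) / denom**2
        g_e = (det - dt_) / denom**2
        ft_var = (sd_delta**2) * (g_et**2 + g_t**2 + g_e**2)
    ft_sd = np.where(valid, np.sqrt(ft_var), np.nan)

    t_flux = ft * et_arr
    e_flux = et_arr - t_flux
    et_sd_arr = np.broadcast_to(np.asarray(et_sd, dtype=float), et_arr.shape)
    t_sd = np.sqrt((et_arr * ft_sd) ** 2 + (ft * et_sd_arr) ** 2)
    e_sd = np.sqrt((et_arr * ft_sd) ** 2 + ((1.0 - ft) * et_sd_arr) ** 2)

    flag = np.where(valid, "ok", "ill_conditioned").astype(object)
    return {
        "ft_raw": ft_raw,
        "ft": np.where(valid, ft, np.nan),
        "clamped": clamped,
        "t": np.where(valid, t_flux, np.nan),
        "e": np.where(valid, e_flux, np.nan),
        "ft_sd": ft_sd,
        "t_sd": np.where(valid, t_sd, np.nan),
        "e_sd": np.where(valid, e_sd, np.nan),
        "flag": flag,
    }
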