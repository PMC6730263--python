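"""Chamber / eddy-covariance fusion and seasonal carbon-water budgets.

Campaign chamber measurements are validated against the continuous
eddy-covariance (EC) series by Spearman rank correlation on paired
half-hourly values.  When a campaign agrees well (r > 0.75) the additive
offset between daily sums (chamber minus EC) is retained; offsets are
nearest-neighbour interpolated over the season, applied to the EC daily
series, and the calibrated series summed per growth stage and season.
The same single EC series (measured over untreated, ambient grassland)
serves every treatment, each with its own chamber offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chamber import wue_eco
from .diurnal import MMOL_H2O_TO_KG, UMOL_CO2_TO_G_C

R_THRESHOLD = 0.75
PAIR_MAX_GAP_MIN = 15.0
MIN_PAIRS = 5
HALF_HOUR_S = 1800.0

FLUX_CONVERSION = {"nee": UMOL_CO2_TO_G_C, "et": MMOL_H2O_TO_KG}


@dataclass
class CampaignCalibration:
    """Spearman gate and daily-sum offset of one campaign/treatment/flux."""

    campaign_date: object
    treatment: str
    flux: str  # "nee" or "et"
    spearman_r: float
    n_pairs: int
    accepted: bool
    offset: float | None  # g C m-2 d-1 or kg H2O m-2 d-1; None if rejected


def ec_daily_sums(ec: pd.DataFrame) -> pd.DataFrame:
    """Daily NEE (g C m-2) and ET (kg H2O m-2) sums of the half-hourly EC
    series (rectangle rule at the 30-min cadence)."""
    df = ec.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date
    out = df.groupby("date").agg(
        nee=("nee", lambda v: v.sum() * HALF_HOUR_S * UMOL_CO2_TO_G_C),
        et=("et", lambda v: v.sum() * HALF_HOUR_S * MMOL_H2O_TO_KG),
        n=("nee", "size"),
    )
    return out.reset_index()


def campaign_correlation(
    ec: pd.DataFrame,
    chamber_fluxes: pd.DataFrame,
    flux: str = "nee",
    max_gap_min: float = PAIR_MAX_GAP_MIN,
    min_pairs: int = MIN_PAIRS,
):
    """Spearman rank correlation between EC and chamber half-hourly fluxes.

    Each chamber record is paired with the nearest EC timestamp within
    ``max_gap_min`` minutes.  Being rank-based, the statistic is invariant
    under strictly increasing transforms of either series.  Returns
    (r, n_pairs); r is NaN with fewer than ``min_pairs`` pairs.
    """
    ch = chamber_fluxes.sort_values("timestamp")
    ecs = ec.sort_values("timestamp")
    pairs = pd.merge_asof(
        ch[["timestamp", flux]].rename(columns={flux: "chamber"}),
        ecs[["timestamp", flux]].rename(columns={flux: "ec"}),
        on="timestamp",
        direction="nearest",
        tolerance=pd.Timedelta(minutes=max_gap_min),
    ).dropna()
    n = len(pairs)
    if n < min_pairs:
        return float("nan"), n
    r = stats.spearmanr(pairs["chamber"], pairs["ec"]).statistic
    return float(r), n


def campaign_offset(ec_daily, chamber_daily) -> float:
    """Additive calibration offset: mean(chamber daily sum - EC daily sum)
    over the campaign days."""
    ec_arr = np.asarray(ec_daily, dtype=float)
    ch_arr = np.asarray(chamber_daily, dtype=float)
    return float(np.mean(ch_arr - ec_arr))


def calibrate_campaigns(
    ec: pd.DataFrame,
    chamber_fluxes: pd.DataFrame,
    chamber_daily: pd.DataFrame,
    r_threshold: float = R_THRESHOLD,
    control: str = "CC",
) -> list[CampaignCalibration]:
    """Gate every campaign by the control-plot Spearman correlation and
    compute per-treatment daily-sum offsets for the accepted ones.

    Parameters
    ----------
    ec : half-hourly EC frame (``timestamp``, ``nee``, ``et``).
    chamber_fluxes : half-hourly chamber fluxes with ``treatment`` and
        ``dark`` columns (light records of the control treatment are used
        for the correlation gate).
    chamber_daily : chamber daily sums with columns ``date``, ``treatment``,
        ``nee_sum``, ``et_sum``.
    """
    ec = ec.copy()
    ec["timestamp"] = pd.to_datetime(ec["timestamp"])
    fluxes = chamber_fluxes.copy()
    fluxes["timestamp"] = pd.to_datetime(fluxes["timestamp"])
    fluxes["date"] = fluxes["timestamp"].dt.date
    daily = chamber_daily.copy()
    daily["date"] = pd.to_datetime(daily["date"]).dt.date
    ecd = ec_daily_sums(ec).set_index("date")

    col_map = {"nee": "nee_sum", "et": "et_sum"}
    calibrations: list[CampaignCalibration] = []
    for day, day_fluxes in fluxes.groupby("date"):
        cc_light = day_fluxes[
            (day_fluxes["treatment"] == control) & (~day_fluxes["dark"].astype(bool))
        ]
        # control plots are averaged per timestamp before ranking
        cc_mean = (
            cc_light.groupby("timestamp")[["nee", "et"]].mean().reset_index()
        )
        for flux in ("nee", "et"):
            r, n = campaign_correlation(ec, cc_mean, flux=flux)
            accepted = bool(np.isfinite(r) and r > r_threshold)
            for trt, sub in daily[daily["date"] == day].groupby("treatment"):
                offset = None
                if accepted and day in ecd.index:
                    offset = campaign_offset(
                        [ecd.loc[day, flux]], sub[col_map[flux]].to_numpy()
                    )
                calibrations.append(
                    CampaignCalibration(
                        campaign_date=day,
                        treatment=trt,
                        flux=flux,
                        spearman_r=r,
                        n_pairs=n,
                        accepted=accepted,
                        offset=offset,
                    )
                )
    return calibrations


def interpolate_offsets(campaign_dates, offsets, season_days) -> np.ndarray:
    """Nearest-neighbour interpolation of campaign offsets to season days.

    Each day receives the offset of the temporally nearest accepted
    campaign; exact ties go to the earlier campaign.  Idempotent on the
    campaign dates themselves.
    """
    cd = pd.to_datetime(pd.Index(campaign_dates)).sort_values()
    if len(cd) == 0:
        raise ValueError("no accepted campaigns: offsets cannot be interpolated")
    off = np.asarray(offsets, dtype=float)[np.argsort(pd.to_datetime(pd.Index(campaign_dates)))]
    days = pd.to_datetime(pd.Index(season_days))
    d_num = days.values.astype("datetime64[s]").astype(np.int64)
    c_num = cd.values.astype("datetime64[s]").astype(np.int64)
    idx = np.searchsorted(c_num, d_num)
    left = np.clip(idx - 1, 0, c_num.size - 1)
    right = np.clip(idx, 0, c_num.size - 1)
    d_left = np.abs(d_num - c_num[left])
    d_right = np.abs(d_num - c_num[right])
    nearest = np.where(d_left <= d_right, left, right)  # tie -> earlier
    return off[nearest]


@dataclass
class SeasonBudget:
    """Stage and season sums of calibrated NEE/ET for one treatment."""

    treatment: str
    stage_nee: list  # g C m-2 per growth stage
    stage_et: list  # kg H2O m-2 per growth stage
    season_nee: float
    season_et: float
    wue_eco_season: float
    pct_vs_control: dict  # per quantity, None for the control itself


def percent_vs_control(value, control_value) -> float:
    """Signed percent change of a quantity's magnitude relative to control
    (negative = reduction): 100 * (|x| - |x_c|) / |x_c|."""
    return 100.0 * (abs(value) - abs(control_value)) / abs(control_value)


def build_budget(
    ec_daily: pd.DataFrame,
    calibrations: list[CampaignCalibration],
    stage_breaks,
    season_start,
    season_end,
    control: str = "CC",
) -> dict[str, SeasonBudget]:
    """Apply interpolated offsets to the EC daily series and sum.

    ``ec_daily`` must carry columns ``date``, ``nee``, ``et``.  Missing days
    inside the season are linearly gap-filled on the calibrated daily sums.
    Stage sums split the season at ``stage_breaks`` (a break date starts the
    next stage).
    """
    days = pd.date_range(season_start, season_end, freq="D")
    ecd = ec_daily.copy()
    ecd["date"] = pd.to_datetime(ecd["date"])
    ecd = ecd.set_index("date").reindex(days)
    gap_filled = ecd["nee"].isna() | ecd["et"].isna()
    ecd[["nee", "et"]] = ecd[["nee", "et"]].interpolate(limit_direction="both")

    breaks = [pd.Timestamp(b) for b in stage_breaks]
    edges = [pd.Timestamp(season_start), *breaks, pd.Timestamp(season_end) + pd.Timedelta(days=1)]
    stage_idx = np.searchsorted(pd.DatetimeIndex(edges[1:-1]).values, days.values, side="right")

    treatments = sorted({c.treatment for c in calibrations})
    budgets: dict[str, SeasonBudget] = {}
    for trt in treatments:
        series = {}
        for flux in ("nee", "et"):
            accepted = [
                c
                for c in calibrations
                if c.treatment == trt and c.flux == flux and c.accepted and c.offset is not None
            ]
            if not accepted:
                raise ValueError(
                    f"no accepted campaign for treatment {trt!r} flux {flux!r}"
                )
            offs = interpolate_offsets(
                [c.campaign_date for c in accepted],
                [c.offset for c in accepted],
                days,
            )
            series[flux] = ecd[flux].to_numpy(float) + offs
        stage_nee = [float(series["nee"][stage_idx == k].sum()) for k in range(4)]
        stage_et = [float(series["et"][stage_idx == k].sum()) for k in range(4)]
        season_nee = float(series["nee"].sum())
        season_et = float(series["et"].sum())
        wue, _, _ = wue_eco(season_nee, season_et)
        budgets[trt] = SeasonBudget(
            treatment=trt,
            stage_nee=stage_nee,
            stage_et=stage_et,
            season_nee=season_nee,
            season_et=season_et,
            wue_eco_season=wue,
            pct_vs_control={},
        )
    if control in budgets:
        ref = budgets[control]
        for trt, b in budgets.items():
            if trt == control:
                b.pct_vs_control = {"nee": 0.0, "et": 0.0, "wue_eco": 0.0}
                continue
            b.pct_vs_control = {
                "nee": percent_vs_control(b.season_nee, ref.season_nee),
                "et": percent_vs_control(b.season_et, ref.season_et),
                "wue_eco": percent_vs_control(b.wue_eco_season, ref.wue_eco_season),
            }
    return budgets


def budget_table(budgets: dict[str, SeasonBudget]) -> pd.DataFrame:
    """Season summary, one row per treatment (NEE g C m-2, ET kg H2O m-2,
    WUE_eco g C per kg H2O, signed percent changes vs control)."""
    rows = []
    for trt in sorted(budgets):
        b = budgets[trt]
        rows.append(
            {
                "treatment": trt,
                "nee_season": b.season_nee,
                "et_season": b.season_et,
                "wue_eco": b.wue_eco_season,
                "pct_nee_vs_cc": b.pct_vs_control.get("nee"),
                "pct_et_vs_cc": b.pct_vs_control.get("et"),
                "pct_wue_vs_cc": b.pct_vs_control.get("wue_eco"),
                **{f"stage{k+1}_nee": b.stage_nee[k] for k in range(4)},
                **{f"stage{k+1}_et": b.stage_et[k] for k in range(4)},
            }
        )
    return pd.DataFrame(rows)
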