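"""Configuration of the synthetic grassland world and of the analysis defaults.

A :class:`TruthBundle` fully determines a synthetic growing season: the
calendar span and its four growth stages, per-treatment multipliers on the
component fluxes, the transpiration fraction trajectory, every noise standard
deviation, the eddy-covariance bias, and the rain-shelter exclusion fraction.
Identical bundles (including the seed) generate bit-identical tables.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: The four experimental treatments: control, drought (rain-out shelters),
#: nitrogen addition, and nitrogen + drought.
TREATMENTS = ("CC", "CD", "NC", "ND")


@dataclass(frozen=True)
class TreatmentEffect:
    """Multiplicative scalars applied to the control (CC) component fluxes.

    ``et`` scales both transpiration and soil evaporation, so the true
    transpiration fraction is treatment-invariant by construction.
    """

    gpp: float = 1.0
    reco: float = 1.0
    et: float = 1.0


def _default_effects() -> dict[str, TreatmentEffect]:
    # Chosen to emulate the seasonal contrast pattern of a fertilised /
    # sheltered temperate grassland: CC the strongest carbon sink, drought
    # cutting ET hardest in combination with nitrogen (ND).
    return {
        "CC": TreatmentEffect(1.00, 1.00, 1.000),
        "CD": TreatmentEffect(0.82, 1.07, 0.751),
        "NC": TreatmentEffect(0.76, 1.12, 0.873),
        "ND": TreatmentEffect(0.64, 1.01, 0.604),
    }


def _d(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


@dataclass
class TruthBundle:
    """Ground-truth description of one synthetic growing season."""

    seed: int = 1

    # --- calendar -----------------------------------------------------------
    season_start: dt.date = _d("2017-04-01")
    season_end: dt.date = _d("2017-09-30")
    #: three dates splitting the season into four growth stages
    #: (spring start, summer peak, summer dieback, autumn peak)
    stage_breaks: tuple[dt.date, dt.date, dt.date] = (
        _d("2017-06-01"),
        _d("2017-07-15"),
        _d("2017-08-20"),
    )

    # --- treatments ---------------------------------------------------------
    treatment_effects: dict[str, TreatmentEffect] = field(default_factory=_default_effects)

    # --- flux amplitudes (CC, stage-curve peak) ------------------------------
    gpp_max: float = 18.2  # umol CO2 m-2 s-1, midday uptake at peak stage
    reco_ref: float = 2.4  # umol CO2 m-2 s-1 at 15 degC
    q10: float = 2.0  # respiration temperature sensitivity
    t_max: float = 3.1  # mmol H2O m-2 s-1, midday transpiration at peak stage
    e_base: float = 0.85  # mmol H2O m-2 s-1, evaporation scale

    # --- noise (measurement layer; truth itself is noise-free) ---------------
    noise_sd_flux_co2: float = 0.5  # umol CO2 m-2 s-1, chamber NEE / Reco
    noise_sd_flux_h2o: float = 0.05  # mmol H2O m-2 s-1, chamber ET
    noise_sd_delta: float = 0.3  # permil, every sampled delta-18O
    ec_noise_sd_nee: float = 1.0  # umol CO2 m-2 s-1, half-hourly eddy NEE
    ec_noise_sd_et: float = 0.08  # mmol H2O m-2 s-1, half-hourly eddy ET

    # --- eddy-covariance bias (additive, expressed on daily sums) ------------
    ec_offset_nee: float = 0.6  # g C m-2 d-1 added to the eddy series
    ec_offset_et: float = 0.2  # kg H2O m-2 d-1 added to the eddy series

    # --- precipitation ------------------------------------------------------
    precip_total_mm: float = 446.6  # ambient April-September total
    precip_exclusion_frac: float = 0.367  # rain-out shelter exclusion

    # --- chamber / sampling design -------------------------------------------
    chamber_flow: float = 15.0  # L min-1 through the open chamber
    chamber_area_cm2: float = 962.0  # chamber base area
    co2_ambient: float = 410.0  # umol mol-1 at the chamber inlet
    n_plots: int = 3  # plots per treatment
    n_campaigns: int = 10  # chamber campaigns over the season
    sample_interval_min: int = 30  # within-campaign cadence

    # --- isotope world ------------------------------------------------------
    delta_source_mean: float = -8.0  # permil, xylem / source water
    delta_soil_mean: float = -3.0  # permil, evaporating-depth soil water
    delta_soil_seasonal: float = 2.0  # permil enrichment start -> end
    delta_vapor_in: float = -18.0  # permil, background vapor at the inlet
    eps_k: float = 14.25  # permil, kinetic fractionation (see isotopes)

    def __post_init__(self) -> None:
        if self.season_end < self.season_start + dt.timedelta(days=30):
            raise ValueError("season span must be at least 30 days")
        b = self.stage_breaks
        if not (self.season_start < b[0] < b[1] < b[2] < self.season_end):
            raise ValueError(
                "stage_breaks must be strictly increasing and inside the season span"
            )
        if not 0.0 <= self.precip_exclusion_frac <= 1.0:
            raise ValueError("precip_exclusion_frac must lie in [0, 1]")
        for name in TREATMENTS:
            if name not in self.treatment_effects:
                raise ValueError(f"treatment_effects missing entry for {name!r}")

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("season_start", "season_end"):
            out[key] = out[key].isoformat()
        out["stage_breaks"] = [d.isoformat() for d in self.stage_breaks]
        out["treatment_effects"] = {
            k: dataclasses.asdict(v) for k, v in self.treatment_effects.items()
        }
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "TruthBundle":
        kwargs = dict(data)
        for key in ("season_start", "season_end"):
            if key in kwargs and isinstance(kwargs[key], str):
                kwargs[key] = _d(kwargs[key])
        if "stage_breaks" in kwargs:
            kwargs["stage_breaks"] = tuple(
                _d(d) if isinstance(d, str) else d for d in kwargs["stage_breaks"]
            )
        if "treatment_effects" in kwargs:
            kwargs["treatment_effects"] = {
                k: v if isinstance(v, TreatmentEffect) else TreatmentEffect(**v)
                for k, v in kwargs["treatment_effects"].items()
            }
        return cls(**kwargs)


def load_config(path: str | Path) -> TruthBundle:
    """Read a YAML key/value file into a :class:`TruthBundle`.

    Keys mirror the dataclass fields; dates are ISO-8601 strings. Missing
    keys fall back to the defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return TruthBundle.from_dict(data)


def save_config(config: TruthBundle, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
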