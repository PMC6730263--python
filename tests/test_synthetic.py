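"""The synthetic world: determinism, truth shapes, and sampling round trips."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from conftest import zero_noise_bundle
from scipy import stats

from isoflux import (
    TruthBundle,
    chamber_flux,
    ec_daily_sums,
    generate_season,
    partition_nee,
    sample_chamber_campaigns,
    sample_ec_series,
    sheltered_precip,
)
from isoflux.pipeline import partition_campaign_records


class TestConfigValidation:
    def test_short_season_rejected(self):
        with pytest.raises(ValueError, match="30 days"):
            TruthBundle(
                season_start=dt.date(2017, 4, 1),
                season_end=dt.date(2017, 4, 20),
                stage_breaks=(dt.date(2017, 4, 5), dt.date(2017, 4, 10), dt.date(2017, 4, 15)),
            )

    def test_unordered_stage_breaks_rejected(self):
        with pytest.raises(ValueError, match="stage_breaks"):
            TruthBundle(
                stage_breaks=(dt.date(2017, 7, 15), dt.date(2017, 6, 1), dt.date(2017, 8, 20))
            )

    def test_yaml_round_trip(self, tmp_path):
        from isoflux import load_config, save_config

        cfg = TruthBundle(seed=42, gpp_max=15.0)
        save_config(cfg, tmp_path / "c.yaml")
        back = load_config(tmp_path / "c.yaml")
        assert back == cfg


class TestDeterminism:
    def test_identical_seed_identical_tables(self):
        cfg = TruthBundle(seed=123)
        s1, s2 = generate_season(cfg), generate_season(cfg)
        pd.testing.assert_frame_equal(s1.meteo, s2.meteo)
        c1, i1 = sample_chamber_campaigns(s1)
        c2, i2 = sample_chamber_campaigns(s2)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(i1, i2)
        pd.testing.assert_frame_equal(sample_ec_series(s1), sample_ec_series(s2))

    def test_different_seed_different_noise(self):
        c1, _ = sample_chamber_campaigns(generate_season(TruthBundle(seed=1)))
        c2, _ = sample_chamber_campaigns(generate_season(TruthBundle(seed=2)))
        assert not np.allclose(c1["co2_out"], c2["co2_out"])


class TestTruthShapes:
    def test_night_rule(self, quiet_season):
        meteo = quiet_season.meteo
        dark = meteo[meteo["ppfd"] == 0.0]["timestamp"]
        truth = quiet_season.truth_fluxes("CC", dark)
        assert np.all(truth["gpp"] == 0.0)
        assert np.all(truth["t"] == 0.0)
        assert np.all(truth["reco"] > 0.0)
        assert np.all(truth["e"] > 0.0)

    def test_ft_in_unit_interval_and_increasing(self, quiet_season):
        daily = quiet_season.truth_daily_sums("CC")
        assert daily["ft_day"].between(0, 1).all()
        # the transpired fraction rises as the canopy develops
        assert daily["ft_day"].iloc[-10:].mean() > daily["ft_day"].iloc[:10].mean()

    def test_ft_treatment_invariant(self, quiet_season):
        ts = quiet_season.meteo["timestamp"].iloc[500:540]
        ft_cc = quiet_season.true_ft(ts, "CC")
        ft_nd = quiet_season.true_ft(ts, "ND")
        assert np.allclose(ft_cc, ft_nd)

    def test_nee_identity(self, quiet_season):
        truth = quiet_season.truth_fluxes("CD", quiet_season.meteo["timestamp"].iloc[:200])
        assert np.allclose(truth["nee"], truth["gpp"] + truth["reco"])
        assert np.allclose(truth["et"], truth["t"] + truth["e"])


class TestPrecipitation:
    def test_exclusion_fraction_exact(self, quiet_season):
        met = quiet_season.meteo
        assert np.allclose(met["precip_sheltered"], 0.633 * met["precip"])

    def test_season_totals(self, quiet_season):
        met = quiet_season.meteo
        assert met["precip"].sum() == pytest.approx(446.6, rel=1e-9)
        assert met["precip_sheltered"].sum() == pytest.approx(282.7, abs=0.05)

    def test_sheltered_precip_helper(self):
        assert sheltered_precip(446.6, 0.367) == pytest.approx(282.7, abs=0.005)
        with pytest.raises(ValueError):
            sheltered_precip(100.0, 1.5)


class TestChamberSamplingRoundTrip:
    def test_zero_noise_identity(self, quiet_season):
        date = quiet_season.default_campaign_dates()[3]
        obs, _ = sample_chamber_campaigns(quiet_season, [date], n_plots=1)
        fluxes = chamber_flux(obs)
        for trt in ("CC", "ND"):
            sub = fluxes[(fluxes["treatment"] == trt) & (~fluxes["dark"])]
            truth = quiet_season.truth_fluxes(trt, sub["timestamp"])
            assert np.allclose(sub["nee"], truth["nee"], rtol=1e-9)
            assert np.allclose(sub["et"], truth["et"], rtol=1e-9)

    def test_zero_noise_dark_records_measure_reco(self, quiet_season):
        date = quiet_season.default_campaign_dates()[3]
        obs, _ = sample_chamber_campaigns(quiet_season, [date], n_plots=1)
        fluxes = partition_nee(chamber_flux(obs))
        light = fluxes[(fluxes["treatment"] == "CC") & (~fluxes["dark"])]
        truth = quiet_season.truth_fluxes("CC", light["timestamp"])
        assert np.allclose(light["reco"], truth["reco"], rtol=1e-9)
        assert np.allclose(light["gpp"], truth["gpp"], rtol=1e-9, atol=1e-12)

    def test_zero_noise_partition_recovers_true_ft(self, quiet_season):
        date = quiet_season.default_campaign_dates()[6]
        obs, iso = sample_chamber_campaigns(quiet_season, [date])
        part = partition_campaign_records(partition_nee(chamber_flux(obs)), iso)
        ok = part[part["partition_quality"] == "ok"]
        truth_ft = quiet_season.true_ft(ok["timestamp"])
        assert np.allclose(ok["ft"], truth_ft, atol=1e-10)

    def test_noise_sd_recovered_by_monte_carlo(self):
        cfg = zero_noise_bundle(noise_sd_flux_co2=0.5)
        season = generate_season(cfg)
        date = season.default_campaign_dates()[4]
        truth_cache = {}
        errs = []
        for rep in range(200):
            rng = np.random.default_rng([9, rep])
            obs, _ = sample_chamber_campaigns(season, [date], n_plots=1, rng=rng)
            obs = obs[(obs["treatment"] == "CC") & (~obs["dark"])]
            fx = chamber_flux(obs)
            key = "CC"
            if key not in truth_cache:
                truth_cache[key] = season.truth_fluxes("CC", fx["timestamp"])["nee"].to_numpy()
            errs.append(fx["nee"].to_numpy() - truth_cache[key])
        sd = np.std(np.concatenate(errs))
        assert sd == pytest.approx(0.5, rel=0.15)


class TestEcSeries:
    def test_no_bias_no_noise_matches_truth_daily(self, quiet_season):
        ec = sample_ec_series(quiet_season)
        ecd = ec_daily_sums(ec).set_index("date")
        truth = quiet_season.truth_daily_sums("CC").set_index("date")
        assert np.allclose(ecd["nee"], truth["nee_sum"], rtol=1e-9)
        assert np.allclose(ecd["et"], truth["et_sum"], rtol=1e-9)

    def test_known_bias_shifts_daily_sums(self):
        cfg = zero_noise_bundle(ec_offset_nee=0.6, ec_offset_et=0.2)
        season = generate_season(cfg)
        ecd = ec_daily_sums(sample_ec_series(season)).set_index("date")
        truth = season.truth_daily_sums("CC").set_index("date")
        assert np.allclose(ecd["nee"] - truth["nee_sum"], 0.6, atol=1e-9)
        assert np.allclose(ecd["et"] - truth["et_sum"], 0.2, atol=1e-9)

    def test_monotone_transform_preserves_ranks(self, quiet_season):
        ec = sample_ec_series(quiet_season)
        day = ec[pd.to_datetime(ec["timestamp"]).dt.date == dt.date(2017, 6, 15)]
        transformed = 3.0 * day["nee"] + 7.0
        r = stats.spearmanr(day["nee"], transformed).statistic
        assert r == 1.0
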