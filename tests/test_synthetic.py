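"""Generator contracts: determinism, degenerate-noise identities, ENSO
coupling signs, and injected-parameter recovery."""

import numpy as np
import pytest

import hatchclim as h
from hatchclim.synthetic import season_of


class TestMEI:
    def test_same_seed_gives_identical_series(self, default_config):
        assert h.gen_mei(default_config) == h.gen_mei(default_config)

    def test_zero_innovation_sd_gives_all_zero(self, default_config):
        mei = h.gen_mei(default_config.replace(enso_sd=0.0))
        assert all(mei[s] == 0.0 for s in mei.seasons)

    @pytest.mark.parametrize("phi", [1.0, -1.0, 1.3])
    def test_nonstationary_coefficient_rejected(self, default_config, phi):
        with pytest.raises(h.NonStationaryError):
            h.gen_mei(default_config.replace(enso_ar_coef=phi))

    def test_iid_case_matches_innovation_sd(self):
        # with no autocorrelation the index is i.i.d. N(0, enso_sd)
        cfg = h.GeneratorConfig(seed=7, enso_ar_coef=0.0, enso_sd=0.8,
                                n_seasons=10_000, start_year=0)
        mei = h.gen_mei(cfg)
        vals = np.array([mei[s] for s in cfg.seasons])
        assert np.std(vals, ddof=1) == pytest.approx(0.8, rel=0.05)
        assert np.mean(vals) == pytest.approx(0.0, abs=0.05)

    def test_ar1_marginal_sd_is_stationary(self):
        cfg = h.GeneratorConfig(seed=11, enso_ar_coef=0.5, enso_sd=1.0,
                                n_seasons=20_000, start_year=0)
        mei = h.gen_mei(cfg)
        vals = np.array([mei[s] for s in cfg.seasons])
        assert np.std(vals, ddof=1) == pytest.approx(1.0 / np.sqrt(0.75), rel=0.05)


class TestWeather:
    def test_no_noise_neutral_enso_reproduces_climatology(self, default_config):
        cfg = default_config.replace(enso_sd=0.0, precip_noise_sd=0.0,
                                     temp_noise_sd=0.0)
        weather = h.gen_weather(h.gen_mei(cfg), cfg)
        for year in (cfg.start_year, cfg.start_year + 2):
            for m in range(1, 13):
                assert weather.precip(year, m) == cfg.precip_monthly_means[m - 1]
                assert weather.temp(year, m) == cfg.temp_monthly_means[m - 1]

    def test_el_nino_season_is_drier_and_warmer(self, default_config):
        cfg = default_config.replace(n_seasons=2, precip_noise_sd=0.0,
                                     temp_noise_sd=0.0)
        y = cfg.start_year
        mei = h.MEISeries({y: 1.0, y + 1: -1.0})
        weather = h.gen_weather(mei, cfg)
        sep_oct = lambda season: weather.precip(season, 9) + weather.precip(season, 10)
        assert sep_oct(y) < sep_oct(y + 1)
        assert weather.temp(y, 10) > weather.temp(y + 1, 10)

    def test_rainy_season_mei_coupling_is_strongly_negative(self):
        cfg = h.GeneratorConfig(seed=5, n_seasons=1000, start_year=1000)
        mei = h.gen_mei(cfg)
        weather = h.gen_weather(mei, cfg)
        x = np.array([mei[s] for s in cfg.seasons])
        y = np.array([weather.precip(s, 9) + weather.precip(s, 10)
                      for s in cfg.seasons])
        r = np.corrcoef(x, y)[0, 1]
        assert r < -0.5

    def test_binned_mei_monotone_decrease_of_sep_oct_rain(self):
        cfg = h.GeneratorConfig(seed=6, n_seasons=4000, start_year=1000)
        mei = h.gen_mei(cfg)
        weather = h.gen_weather(mei, cfg)
        x = np.array([mei[s] for s in cfg.seasons])
        y = np.array([weather.precip(s, 9) + weather.precip(s, 10)
                      for s in cfg.seasons])
        edges = np.quantile(x, [0.0, 0.25, 0.5, 0.75, 1.0])
        means = [y[(x >= lo) & (x <= hi)].mean()
                 for lo, hi in zip(edges[:-1], edges[1:])]
        assert all(a > b for a, b in zip(means[:-1], means[1:]))

    def test_dry_season_stays_dry(self, default_config):
        weather = h.gen_weather(h.gen_mei(default_config), default_config)
        dry = [weather.precip(y, m)
               for y in range(default_config.start_year + 1,
                              default_config.start_year + 5)
               for m in (1, 2, 3)]
        wet = [weather.precip(y, m)
               for y in default_config.seasons for m in (9, 10)]
        assert np.mean(dry) < 30
        assert np.mean(wet) > 200

    def test_season_of_maps_climate_year(self):
        assert season_of(2004, 10) == 2004
        assert season_of(2005, 2) == 2004  # dry season follows its rainy season
        assert season_of(2005, 5) == 2005

    def test_determinism(self, default_config):
        mei = h.gen_mei(default_config)
        a = h.gen_weather(mei, default_config).to_frame()
        b = h.gen_weather(mei, default_config).to_frame()
        assert a.equals(b)


class TestNests:
    def test_counts_and_strata(self, default_config, default_records):
        cfg = default_config
        assert len(default_records) == cfg.n_seasons * 4 * cfg.nests_per_month
        # count identities are enforced by the record type itself
        for rec in default_records[:200]:
            assert rec.live_in_nest + rec.dead_in_nest <= rec.shells

    def test_determinism(self, default_config):
        weather = h.gen_weather(h.gen_mei(default_config), default_config)
        a = h.gen_nests(weather, default_config)
        b = h.gen_nests(weather, default_config)
        assert a == b

    def test_perfect_conditions_leave_no_failures(self, default_config,
                                                  intercept_fit):
        cfg = default_config.replace(obs_noise_sd=0.0, n_seasons=1,
                                     nests_per_month=5)
        weather = h.gen_weather(h.gen_mei(cfg), cfg)
        records = h.gen_nests(weather, cfg,
                              fits=(intercept_fit(1.0), intercept_fit(1.0)))
        for rec in records:
            assert rec.unhatched == 0
            assert rec.live_in_nest == 0 and rec.dead_in_nest == 0

    def test_zero_hatching_flags_emergence_as_undefined(self, default_config,
                                                        intercept_fit):
        cfg = default_config.replace(obs_noise_sd=0.0, n_seasons=1,
                                     nests_per_month=5)
        weather = h.gen_weather(h.gen_mei(cfg), cfg)
        records = h.gen_nests(weather, cfg,
                              fits=(intercept_fit(0.0), intercept_fit(1.0)))
        assert all(rec.shells == 0 for rec in records)
        with pytest.raises(h.UndefinedMetricError):
            h.emergence_rate(records[0])
        means = h.monthly_means(records)
        assert means["mean_r"].isna().all()
        assert (means["mean_h"] == 0).all()

    def test_realized_monthly_mean_matches_equation(self, reference_pair):
        # binomial mean oracle: mean realized H over many nests ~ expected H
        cfg = h.GeneratorConfig(seed=77, n_seasons=1, nests_per_month=2500,
                                obs_noise_sd=0.05)
        weather = h.gen_weather(h.gen_mei(cfg), cfg)
        records = h.gen_nests(weather, cfg, fits=reference_pair)
        means = h.monthly_means(records)
        for row in means.itertuples(index=False):
            expected = h.predict_response(
                reference_pair[0],
                h.build_predictors(weather, row.season_start_year, row.lay_month),
            )
            assert row.mean_h == pytest.approx(expected, abs=0.01)

    def test_missing_weather_names_the_month(self, default_config):
        cfg = default_config.replace(n_seasons=2)
        weather = h.gen_weather(h.gen_mei(cfg), cfg)
        df = weather.to_frame()
        df = df[~((df.year == cfg.start_year) & (df.month == 9))]
        broken = h.MonthlyClimateSeries(df)
        with pytest.raises(h.MissingCovariateError, match="Sep 2004"):
            h.gen_nests(broken, cfg)


class TestModelEnsemble:
    def test_zero_bias_zero_trend_zero_noise_is_climatology(self, default_config):
        cfg = default_config.replace(
            enso_sd=0.0, precip_noise_sd=0.0, temp_noise_sd=0.0,
            model_trend_temp=0.0, model_trend_precip=0.0,
            model_bias_temp=(0.0, 0.0), model_bias_precip=(1.0, 1.0),
        )
        models = h.gen_model_ensemble(cfg, n_models=3, years=range(2000, 2006))
        for series in models.values():
            for m in range(1, 13):
                assert series.precip(2003, m) == pytest.approx(
                    cfg.precip_monthly_means[m - 1])
                assert series.temp(2003, m) == pytest.approx(
                    cfg.temp_monthly_means[m - 1])

    def test_every_model_warms(self, default_config):
        models = h.gen_model_ensemble(default_config, n_models=5,
                                      years=range(2001, 2101))
        for series in models.values():
            early = np.mean([series.temp(y, m)
                             for y in range(2001, 2011) for m in range(1, 13)])
            late = np.mean([series.temp(y, m)
                            for y in range(2091, 2101) for m in range(1, 13)])
            assert late > early

    def test_majority_of_models_dry(self, default_config):
        cfg = default_config.replace(enso_sd=0.0, precip_noise_sd=0.0,
                                     temp_noise_sd=0.0)
        models = h.gen_model_ensemble(cfg, n_models=17, years=range(2001, 2101))
        drying = 0
        for series in models.values():
            early = np.mean([series.precip(y, 9) for y in range(2001, 2011)])
            late = np.mean([series.precip(y, 9) for y in range(2091, 2101)])
            drying += late < early
        assert drying == 13

    def test_reference_period_ratio_recovers_injected_bias(self, default_config):
        cfg = default_config.replace(
            enso_sd=0.0, precip_noise_sd=0.0, temp_noise_sd=0.0,
            model_trend_temp=0.0, model_trend_precip=0.0,
        )
        models = h.gen_model_ensemble(cfg, n_models=4, years=range(1990, 1996))
        for series in models.values():
            ratios = {m: series.precip(1992, m) / cfg.precip_monthly_means[m - 1]
                      for m in range(1, 13)}
            vals = np.array(list(ratios.values()))
            # one multiplicative bias per model, constant across months
            assert np.ptp(vals) == pytest.approx(0.0, abs=1e-12)
            lo, hi = cfg.model_bias_precip
            assert lo <= vals[0] <= hi
            offsets = {m: series.temp(1992, m) - cfg.temp_monthly_means[m - 1]
                       for m in range(1, 13)}
            ovals = np.array(list(offsets.values()))
            assert np.ptp(ovals) == pytest.approx(0.0, abs=1e-12)
            lo, hi = cfg.model_bias_temp
            assert lo <= ovals[0] <= hi

    def test_determinism_and_model_count(self, default_config):
        a = h.gen_model_ensemble(default_config, n_models=3, years=range(2000, 2004))
        b = h.gen_model_ensemble(default_config, n_models=3, years=range(2000, 2004))
        assert list(a) == list(b)
        for k in a:
            assert a[k].to_frame().equals(b[k].to_frame())
        with pytest.raises(ValueError):
            h.gen_model_ensemble(default_config, n_models=0, years=range(2000, 2004))


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            h.GeneratorConfig(n_seasons=0)
        with pytest.raises(ValueError):
            h.GeneratorConfig(enso_sd=-1.0)
        with pytest.raises(ValueError):
            h.GeneratorConfig(precip_monthly_means=(1.0,) * 11)
        with pytest.raises(ValueError):
            h.GeneratorConfig(precip_monthly_means=(-5.0,) + (10.0,) * 11)

    def test_config_file_round_trip(self, tmp_path, default_config):
        path = tmp_path / "gen.yaml"
        default_config.to_file(path)
        assert h.GeneratorConfig.from_file(path) == default_config
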