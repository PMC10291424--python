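"""Generators: determinism, planted structure, placement bias, closed forms."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from copial import (
    ConfigurationError,
    NicheParams,
    Period,
    PeriodTable,
    SyntheticConfig,
    gen_houses,
    gen_landscape,
    gen_occupation,
    gen_subregion_pops,
    gini,
    in_niche,
    sigma_for_gini,
)

ONE_PERIOD = PeriodTable((Period("P1", 600, 650),))


class TestLandscape:
    def test_zero_variance_is_exactly_the_mean(self):
        cfg = SyntheticConfig(
            n_cells=5, years=(600, 620), precip_cv=0.0, precip_ar1=0.0,
            fgdd_sd=0.0, fgdd_gradient=0.0, seed=1,
        )
        scape = gen_landscape(cfg, ONE_PERIOD)
        assert np.all(scape["precip_cm"] == cfg.precip_mean_cm)
        assert np.all(scape["fgdd"] == cfg.fgdd_mean)

    def test_record_count_is_cells_times_years(self):
        cfg = SyntheticConfig(n_cells=10, years=(600, 650), seed=1)
        assert len(gen_landscape(cfg, ONE_PERIOD)) == 510

    def test_lag1_autocorrelation_matches_configured_ar1(self):
        grid = PeriodTable((Period("P1", 0, 4999),))
        cfg = SyntheticConfig(
            n_cells=1, years=(0, 4999), precip_ar1=0.6, precip_cv=0.2,
            precip_spatial_corr=0.0, seed=2,
        )
        p = gen_landscape(cfg, grid).sort_values("year")["precip_cm"].to_numpy()
        x = p - p.mean()
        acf1 = np.dot(x[1:], x[:-1]) / np.dot(x, x)
        assert acf1 == pytest.approx(0.6, abs=0.05)

    def test_strict_positivity(self):
        cfg = SyntheticConfig(n_cells=30, years=(600, 700), fgdd_mean=300.0,
                              fgdd_gradient=0.0, fgdd_sd=400.0, seed=3)
        scape = gen_landscape(cfg, ONE_PERIOD)
        assert (scape["precip_cm"] > 0).all()
        assert (scape["fgdd"] > 0).all()

    @pytest.mark.parametrize(
        "field,value",
        [("precip_ar1", 1.0), ("precip_ar1", -0.1), ("precip_mean_cm", -3.0),
         ("precip_cv", -0.5), ("n_cells", 0)],
    )
    def test_invalid_config_names_the_field(self, field, value):
        cfg = SyntheticConfig(**{field: value})
        with pytest.raises(ConfigurationError, match=field):
            gen_landscape(cfg, ONE_PERIOD)

    def test_same_seed_byte_identical(self):
        cfg = SyntheticConfig(n_cells=8, years=(600, 640), seed=9)
        a = gen_landscape(cfg, ONE_PERIOD)
        b = gen_landscape(cfg, ONE_PERIOD)
        assert a.equals(b)


class TestOccupation:
    def _world(self, niche_preference, seed, precip=40.0, n_cells=20):
        grid = PeriodTable((Period("P1", 600, 799),))
        cfg = SyntheticConfig(
            n_cells=n_cells, years=(600, 799), precip_mean_cm=precip,
            precip_cv=0.3, fgdd_gradient=-15.0, fgdd_sd=0.0,
            n_settlements=200, niche_preference=niche_preference, seed=seed,
        )
        scape = gen_landscape(cfg, grid)
        return scape, gen_occupation(scape, cfg, grid), grid

    @staticmethod
    def _in_niche_at_founding(scape, ledger):
        flags = in_niche(scape["precip_cm"].to_numpy(), scape["fgdd"].to_numpy())
        lookup = {
            (c, y): f
            for c, y, f in zip(scape["cell_id"], scape["year"], flags)
        }
        return np.array(
            [lookup[(c, y)] for c, y in zip(ledger["cell_id"], ledger["start_year"])]
        )

    def test_full_preference_forces_in_niche_founding(self):
        # precip far above threshold: at least one in-niche cell every year
        scape, ledger, _ = self._world(1.0, seed=4, precip=60.0)
        assert self._in_niche_at_founding(scape, ledger).all()

    def test_zero_preference_matches_landscape_niche_fraction(self):
        # counting oracle: founding in-niche fraction ~ mean niche fraction
        scape, ledger, _ = self._world(0.0, seed=5)
        flags = in_niche(scape["precip_cm"].to_numpy(), scape["fgdd"].to_numpy())
        niche_frac = flags.mean()
        observed = self._in_niche_at_founding(scape, ledger).mean()
        # binomial error over 200 foundings
        assert observed == pytest.approx(niche_frac, abs=3 * 0.5 / math.sqrt(200))

    def test_partial_preference_lifts_in_niche_fraction(self):
        scape0, ledger0, _ = self._world(0.0, seed=6)
        scape1, ledger1, _ = self._world(0.9, seed=6)
        assert (
            self._in_niche_at_founding(scape1, ledger1).mean()
            > self._in_niche_at_founding(scape0, ledger0).mean()
        )

    def test_mean_span_approaches_configured_duration(self):
        grid = PeriodTable((Period("P1", 600, 2599),))
        cfg = SyntheticConfig(
            n_cells=5, years=(600, 2599), n_settlements=2000,
            occupation_duration_mean_yr=30.0, seed=8,
        )
        scape = gen_landscape(cfg, grid)
        ledger = gen_occupation(scape, cfg, grid)
        # ignore spans clipped by the horizon: founded early enough to finish
        free = ledger[ledger["start_year"] < 2200]
        spans = free["end_year"] - free["start_year"] + 1
        assert spans.mean() == pytest.approx(30.0, rel=0.10)

    def test_spans_are_valid_and_inside_years(self):
        scape, ledger, _ = self._world(0.5, seed=10)
        assert (ledger["end_year"] >= ledger["start_year"]).all()
        assert ledger["start_year"].min() >= 600
        assert ledger["end_year"].max() <= 799


class TestHouses:
    def test_planted_zero_gini_is_degenerate(self):
        cfg = SyntheticConfig(planted_gini_by_period={"P1": 0.0},
                              houses_per_period=100, seed=1)
        houses = gen_houses(cfg, ONE_PERIOD)
        assert houses["area_m2"].nunique() == 1
        assert gini(houses["area_m2"].to_numpy()) == pytest.approx(0.0, abs=1e-15)

    def test_sigma_closed_form_for_half(self):
        assert sigma_for_gini(0.5) == pytest.approx(
            math.sqrt(2) * stats.norm.ppf(0.75), abs=1e-12
        )

    @pytest.mark.parametrize("g", [0.1, 0.3, 0.5, 0.7])
    def test_sigma_closed_form_against_integration_oracle(self, g):
        # Gini = (1/mu) * int F(x)(1-F(x)) dx for a lognormal(0, sigma)
        sigma = sigma_for_gini(g)
        mu = math.exp(sigma**2 / 2)
        dist = stats.lognorm(s=sigma)
        val, _ = integrate.quad(
            lambda x: dist.cdf(x) * dist.sf(x), 0, np.inf, limit=200
        )
        assert val / mu == pytest.approx(g, abs=1e-8)

    def test_planted_gini_recovered_at_large_n(self):
        cfg = SyntheticConfig(planted_gini_by_period={"P1": 0.3},
                              houses_per_period=5000, seed=12)
        houses = gen_houses(cfg, ONE_PERIOD)
        assert gini(houses["area_m2"].to_numpy()) == pytest.approx(0.3, abs=0.01)

    def test_invalid_planted_gini_rejected(self):
        cfg = SyntheticConfig(planted_gini_by_period={"P1": 1.0})
        with pytest.raises(ConfigurationError):
            gen_houses(cfg, ONE_PERIOD)

    def test_houses_attach_to_settlements_active_in_period(self):
        grid = PeriodTable((Period("P1", 600, 650), Period("P2", 651, 700)))
        cfg = SyntheticConfig(n_cells=10, years=(600, 700), n_settlements=30,
                              houses_per_period=40, seed=13)
        scape = gen_landscape(cfg, grid)
        ledger = gen_occupation(scape, cfg, grid)
        houses = gen_houses(cfg, grid, ledger)
        active = {
            p.name: set(
                ledger.loc[
                    (ledger["start_year"] <= p.end_year)
                    & (ledger["end_year"] >= p.start_year),
                    "settlement_id",
                ]
            )
            for p in grid
        }
        for _, h in houses.iterrows():
            if active[h["period"]]:
                assert h["settlement_id"] in active[h["period"]]


class TestSubregionPops:
    # 40-year periods: midpoints 619.5 and 659.5, i.e. 40 years apart
    GRID = PeriodTable((Period("A", 600, 639), Period("B", 640, 679)))

    def test_flat_schedule_is_constant(self):
        cfg = SyntheticConfig(growth_schedule={"A": 0.0, "B": 0.0}, n_subregions=3)
        pops = gen_subregion_pops(cfg, self.GRID)
        wide = pops.pivot(index="subregion_id", columns="period", values="population")
        assert np.allclose(wide["A"], wide["B"])

    def test_compound_growth_closed_form(self):
        # midpoints 40 years apart; 1 %/yr compounds 1000 -> 1000*1.01^40
        cfg = SyntheticConfig(
            growth_schedule={"A": 0.0, "B": 1.0}, n_subregions=1,
            initial_population=1000.0,
        )
        pops = gen_subregion_pops(cfg, self.GRID).set_index("period")
        assert pops.loc["B", "population"] == pytest.approx(1488.8637, abs=1e-3)

    def test_unknown_period_in_schedule_rejected(self):
        cfg = SyntheticConfig(growth_schedule={"A": 0.0, "Z": 1.0})
        with pytest.raises(ConfigurationError):
            gen_subregion_pops(cfg, self.GRID)

    def test_planted_pulse_detected_by_churn_exactly_once(self):
        from copial import churn

        cfg = SyntheticConfig(
            growth_schedule={"A": 0.0, "B": 0.0},
            migration_pulses={("sub2", "B"): 2.0},
            n_subregions=6,
        )
        pops = gen_subregion_pops(cfg, self.GRID)
        results = churn(pops, self.GRID, threshold=0.7)
        assert len(results) == 1
        assert results[0].churn == 1
        exceed = [s for s, r in results[0].rates.items() if abs(r) >= 0.7]
        assert exceed == ["sub2"]

    def test_populations_nonnegative(self):
        cfg = SyntheticConfig(growth_schedule={"A": 0.0, "B": -5.0}, n_subregions=2)
        pops = gen_subregion_pops(cfg, self.GRID)
        assert (pops["population"] >= 0).all()


class TestDeterminism:
    def test_all_stages_reproduce_exactly(self, grid14, small_config):
        def build(cfg):
            scape = gen_landscape(cfg, grid14)
            ledger = gen_occupation(scape, cfg, grid14)
            houses = gen_houses(cfg, grid14, ledger)
            pops = gen_subregion_pops(cfg, grid14)
            return scape, ledger, houses, pops

        for a, b in zip(build(small_config), build(small_config)):
            assert a.equals(b)

    def test_different_seeds_differ(self, grid14, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        a = gen_landscape(small_config, grid14)
        b = gen_landscape(other, grid14)
        assert not a["precip_cm"].equals(b["precip_cm"])
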