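"""Generator contracts: unit tessellation, injected trends, designed factor
explanatory power, and exact land-use transition bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from vegeff import synth
from vegeff.synth import FactorSpec, ScenarioConfig, TrendSpec
from vegeff.types import ConfigError, InfeasibleSpecError


def small_config(**kw):
    defaults = dict(grid_rows=4, grid_cols=4, n_units=4, seed=0,
                    years=list(range(2000, 2011)))
    defaults.update(kw)
    return ScenarioConfig(**defaults)


class TestMakeUnits:
    def test_four_square_blocks(self):
        units = synth.make_units(small_config())
        assert sorted(units.unit_ids) == [1, 2, 3, 4]
        assert (units.areas == 4.0).all()
        # each unit is a 2x2 block
        for uid in units.unit_ids:
            rows, cols = np.nonzero(units.labels == uid)
            assert rows.max() - rows.min() == 1 and cols.max() - cols.min() == 1

    def test_single_cell_unit(self):
        units = synth.make_units(small_config(grid_rows=1, grid_cols=1, n_units=1))
        assert units.labels.tolist() == [[1]]
        assert units.areas[1] == 1.0

    def test_area_conservation(self):
        units = synth.make_units(small_config(grid_rows=6, grid_cols=6, n_units=4))
        assert units.areas.sum() == 36.0
        assert (units.labels > 0).all()

    def test_too_many_units_rejected(self):
        with pytest.raises(ConfigError):
            small_config(grid_rows=2, grid_cols=2, n_units=5)

    def test_subregion_labels_cover_all_units(self):
        cfg = small_config(grid_rows=6, grid_cols=6, n_units=9,
                           subregion_names=("NA", "OS", "FZ", "YM"))
        units = synth.make_units(cfg)
        assert set(units.subregion) == set(range(1, 10))
        assert set(units.subregion.values()) == {"NA", "OS", "FZ", "YM"}


class TestSimulateStacks:
    def test_noiseless_linear_series_recovers_slope_exactly(self):
        cfg = small_config(trend_spec=TrendSpec(unit_slopes=0.01), noise_sd=0.0)
        ndvi, npp = synth.simulate_stacks(cfg)
        t = (ndvi.years - ndvi.years[0]).astype(float)
        for px in [(0, 0), (2, 3)]:
            series = ndvi.data[:, px[0], px[1]]
            slope = np.polyfit(t, series, 1)[0]
            assert slope == pytest.approx(0.01, abs=1e-12)

    def test_break_step_shifts_mean_by_magnitude(self):
        cfg = small_config(noise_sd=0.0, break_year=2005, break_magnitude=4.0,
                           npp_scale=1.0, npp_base=100.0)
        _, npp = synth.simulate_stacks(cfg)
        means = npp.data.mean(axis=(1, 2))
        i = list(npp.years).index(2005)
        assert means[i] - means[i - 1] == pytest.approx(4.0, abs=1e-9)
        # elsewhere the series is flat (zero slope, zero noise)
        assert np.allclose(np.diff(means[:i]), 0.0)

    def test_same_config_same_seed_bit_identical(self):
        cfg = small_config(trend_spec=TrendSpec(0.002, 0.001), noise_sd=0.05)
        a = synth.simulate_stacks(cfg)
        b = synth.simulate_stacks(cfg)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)

    def test_value_ranges(self):
        cfg = small_config(noise_sd=0.5, trend_spec=TrendSpec(0.01))
        ndvi, npp = synth.simulate_stacks(cfg)
        assert ndvi.data.min() >= -1.0 and ndvi.data.max() <= 1.0
        assert npp.data.min() >= 0.0

    def test_per_unit_mean_slopes_recovered(self, rng):
        slopes = [0.004, 0.0, -0.002, 0.002]
        cfg = small_config(grid_rows=20, grid_cols=20,
                           trend_spec=TrendSpec(slopes, 0.0005), noise_sd=0.01,
                           years=list(range(2000, 2021)))
        units = synth.make_units(cfg)
        ndvi, _ = synth.simulate_stacks(cfg, units)
        t = (ndvi.years - ndvi.years[0]).astype(float)
        tc = t - t.mean()
        est = np.tensordot(tc, ndvi.data, axes=(0, 0)) / (tc**2).sum()
        for uid, s in zip(units.unit_ids, slopes):
            # 100 pixels per unit: mean slope within a few standard errors
            assert est[units.labels == uid].mean() == pytest.approx(s, abs=5e-4)


def _direct_q(y: np.ndarray, strata: np.ndarray) -> float:
    ssw = sum((strata == h).sum() * y[strata == h].var()
              for h in np.unique(strata))
    return 1.0 - ssw / (len(y) * y.var())


class TestSimulateFactor:
    def test_designed_zero_gives_near_zero_q(self, rng):
        cfg = small_config(grid_rows=25, grid_cols=20, n_units=500)
        y = pd.Series(rng.normal(0, 1, 500))
        part = synth.simulate_factor(cfg, y, FactorSpec("f", "climate", 0.0, 7))
        assert _direct_q(y.to_numpy(), part.strata.to_numpy()) < 0.05

    def test_designed_q_hit_within_tolerance(self, rng):
        cfg = small_config(grid_rows=25, grid_cols=20, n_units=500)
        y = pd.Series(rng.normal(0, 1, 500))
        part = synth.simulate_factor(cfg, y, FactorSpec("f", "climate", 0.95, 7))
        q = _direct_q(y.to_numpy(), part.strata.to_numpy())
        assert q == pytest.approx(0.95, abs=0.02)

    def test_more_groups_than_units_rejected(self, rng):
        cfg = small_config(grid_rows=5, grid_cols=1, n_units=5)
        y = pd.Series(rng.normal(0, 1, 5))
        with pytest.raises(InfeasibleSpecError):
            synth.simulate_factor(cfg, y, FactorSpec("f", "soil", 0.3, 7))

    def test_values_consistent_with_strata(self, rng):
        cfg = small_config(grid_rows=25, grid_cols=20, n_units=500)
        y = pd.Series(rng.normal(0, 1, 500))
        part = synth.simulate_factor(cfg, y, FactorSpec("f", "climate", 0.5, 7))
        # values are monotone in stratum: value ranges of strata do not overlap
        lo = part.values.groupby(part.strata).min()
        hi = part.values.groupby(part.strata).max()
        assert (lo.sort_index().to_numpy()[1:] > hi.sort_index().to_numpy()[:-1]).all()


class TestSimulateLanduse:
    def test_quarter_of_unit_converted_exactly(self):
        cfg = small_config(grid_rows=10, grid_cols=10, n_units=1,
                           transition_spec={(synth.CROPLAND, synth.GRASSLAND): 0.25})
        lu0, lu1, book = synth.simulate_landuse(cfg)
        converted = ((lu0 == synth.CROPLAND) & (lu1 == synth.GRASSLAND)).sum()
        assert converted == 25
        assert book.loc[0, "fraction"] == 0.25

    def test_zero_spec_identical_epochs(self):
        cfg = small_config(grid_rows=6, grid_cols=6, n_units=4,
                           transition_spec={(synth.CROPLAND, synth.GRASSLAND): 0.0})
        lu0, lu1, _ = synth.simulate_landuse(cfg)
        assert np.array_equal(lu0, lu1)

    def test_cross_tabulation_oracle_matches_bookkeeping(self):
        spec = {(synth.CROPLAND, synth.GRASSLAND): 0.3,
                (synth.UNUSED, synth.GRASSLAND): 0.17,
                (synth.FOREST, synth.FOREST): 0.2}
        cfg = small_config(grid_rows=10, grid_cols=10, n_units=4, transition_spec=spec)
        units = synth.make_units(cfg)
        lu0, lu1, book = synth.simulate_landuse(cfg, units)
        for row in book.itertuples():
            sel = units.labels == row.unit_id
            observed = int(((lu0 == row.from_class) & (lu1 == row.to_class) & sel).sum())
            assert observed == row.cells

    def test_fractions_summing_over_one_rejected(self):
        cfg = small_config(grid_rows=10, grid_cols=10, n_units=1,
                           transition_spec={(synth.CROPLAND, synth.GRASSLAND): 0.3,
                                            (synth.UNUSED, synth.GRASSLAND): 0.8})
        with pytest.raises(ConfigError):
            synth.simulate_landuse(cfg)


class TestAfforestation:
    def test_accumulated_intensity_spread_over_years(self):
        cfg = small_config(years=list(range(2000, 2021)))
        units = synth.make_units(cfg)
        table = synth.simulate_afforestation(
            cfg, units, pd.Series(19.0, index=units.unit_ids)
        )
        # 19% of a 4 km^2 unit = 0.76 km^2 over 2002..2020 (19 years)
        one = table[table.unit_id == 1]
        assert len(one) == 19
        assert one["afforested_area_km2"].sum() == pytest.approx(0.76)


def test_scenario_yaml_roundtrip(tmp_path):
    sc = synth.default_scenario(seed=7)
    d = synth.scenario_to_dict(sc)
    sc2 = synth.scenario_from_dict(d)
    assert np.array_equal(sc.years, sc2.years)
    assert sc2.seed == 7
    assert [f.name for f in sc2.factor_specs] == [f.name for f in sc.factor_specs]
    a = synth.simulate_stacks(sc)[0]
    b = synth.simulate_stacks(sc2)[0]
    assert np.array_equal(a.data, b.data)
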