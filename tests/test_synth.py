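"""Synthetic-scenario generator: determinism, linearity, noise contracts."""

import numpy as np
import pandas as pd
import pytest

from rfmscale import ScenarioConfig, generate_scenario
from rfmscale.synth import exponential_kernel_field
from conftest import tiny_config


def test_same_seed_is_bit_identical():
    a = generate_scenario(tiny_config(seed=11))
    b = generate_scenario(tiny_config(seed=11))
    pd.testing.assert_frame_equal(a.truth_fields.data, b.truth_fields.data)
    pd.testing.assert_frame_equal(a.model_fields.data, b.model_fields.data)
    pd.testing.assert_frame_equal(a.monitor_daily, b.monitor_daily)
    for sp in a.satellite:
        np.testing.assert_array_equal(a.satellite[sp].values, b.satellite[sp].values)
    np.testing.assert_array_equal(a.population.values, b.population.values)


def test_distinct_seeds_differ():
    a = generate_scenario(tiny_config(seed=11))
    b = generate_scenario(tiny_config(seed=12))
    assert not np.array_equal(a.population.values, b.population.values)


def test_unit_bias_zero_noise_model_equals_truth():
    cfg = tiny_config(
        seed=5,
        bias_factors={"pSO4": 1.0, "pNO3": 1.0, "pNH4": 1.0},
        model_noise_sd=0.0,
    )
    b = generate_scenario(cfg)
    pd.testing.assert_series_equal(
        b.model_fields.data["value"], b.truth_fields.data["value"], check_names=False
    )


def test_zero_noise_ratio_is_beta_everywhere(tiny_bundle):
    cfg = tiny_config(seed=5, model_noise_sd=0.0)
    b = generate_scenario(cfg)
    merged = b.model_fields.data.merge(
        b.truth_fields.data, on=["cell_id", "species", "sector"], suffixes=("_m", "_t")
    )
    merged = merged[merged["value_t"] > 0]
    ratio = merged["value_m"] / merged["value_t"]
    expected = merged["species"].map(cfg.bias_factors)
    assert np.allclose(ratio, expected, rtol=1e-12)


def test_sector_sum_linearity(tiny_bundle):
    for field in (tiny_bundle.truth_fields, tiny_bundle.model_fields):
        total = field.total().data.set_index(["cell_id", "species"])["value"]
        by_hand = (
            field.data.groupby(["cell_id", "species"])["value"].sum()
        )
        pd.testing.assert_series_equal(total.sort_index(), by_hand.sort_index(), check_names=False)


def test_single_sector_equals_total():
    cfg = tiny_config(
        seed=6,
        sectors=("onroad",),
        sector_species_weights={"onroad": {"pSO4": 1.0, "pNO3": 1.0, "pNH4": 1.0}},
    )
    b = generate_scenario(cfg)
    sector = b.truth_fields.data.set_index(["cell_id", "species"])["value"]
    total = b.truth_fields.total().data.set_index(["cell_id", "species"])["value"]
    pd.testing.assert_series_equal(sector.sort_index(), total.sort_index(), check_names=False)


def test_kernel_closed_form():
    xs = np.array([0.5, 10.5])
    ys = np.array([0.5])
    src = np.array([[0.5, 0.5, 2.0]])
    field = exponential_kernel_field(xs, ys, src, decay_km=5.0)
    assert field[0, 0] == pytest.approx(2.0)  # d = 0
    assert field[0, 1] == pytest.approx(2.0 * np.exp(-10.0 / 5.0))


def test_kernel_linear_in_strength():
    rng = np.random.default_rng(0)
    xs = np.arange(20) + 0.5
    ys = np.arange(20) + 0.5
    src = np.column_stack([rng.uniform(0, 20, 5), rng.uniform(0, 20, 5), rng.uniform(0.5, 2, 5)])
    one = exponential_kernel_field(xs, ys, src, 7.0)
    double = exponential_kernel_field(xs, ys, np.column_stack([src[:, :2], 2 * src[:, 2]]), 7.0)
    np.testing.assert_allclose(double, 2 * one, rtol=1e-12)


def test_kernel_matches_per_source_sum():
    rng = np.random.default_rng(1)
    xs = np.arange(15) + 0.5
    ys = np.arange(15) + 0.5
    src = np.column_stack([rng.uniform(0, 15, 4), rng.uniform(0, 15, 4), rng.uniform(0.5, 2, 4)])
    whole = exponential_kernel_field(xs, ys, src, 4.0)
    parts = sum(exponential_kernel_field(xs, ys, src[i : i + 1], 4.0) for i in range(4))
    np.testing.assert_allclose(whole, parts, rtol=1e-12)


class TestMonitors:
    def test_zero_day_noise_daily_equals_cell_truth(self):
        cfg = tiny_config(seed=8, monitor_noise_sd=0.0)
        b = generate_scenario(cfg)
        truth = b.truth_fields.total()
        mon = b.monitor_daily
        cell_of = b.grid.cell_index_of_points(
            mon.groupby("monitor_id")["x_km"].first().to_numpy(),
            mon.groupby("monitor_id")["y_km"].first().to_numpy(),
        )
        ids = [b.grid.cells[i].cell_id for i in cell_of]
        lookup = dict(zip(mon.groupby("monitor_id").groups.keys(), ids))
        for (mid, sp), g in mon.groupby(["monitor_id", "species"]):
            expected = truth.series(sp).loc[lookup[mid]]
            assert np.allclose(g["value_ugm3"], expected, rtol=1e-12)

    def test_monitor_count_respects_config(self, tiny_bundle):
        cfg = tiny_bundle.config
        counts = tiny_bundle.monitor_daily.groupby("species")["monitor_id"].nunique()
        assert (counts == cfg.n_monitors).all()

    def test_day_factor_mean_matches_lognormal_moment(self, tiny_bundle):
        # daily value / cell truth = exp(sd * z); its analytic mean is
        # exp(sd^2 / 2) with sd of the mean ~ sd(factors)/sqrt(365)
        sd = tiny_bundle.config.monitor_noise_sd
        mon = tiny_bundle.monitor_daily
        truth = tiny_bundle.truth_fields.total()
        g = mon[mon["species"] == "pSO4"].groupby("monitor_id")
        analytic_mean = np.exp(sd**2 / 2)
        analytic_var = (np.exp(sd**2) - 1) * np.exp(sd**2)
        se = np.sqrt(analytic_var / 365)
        # average over monitors to stabilise: mean of per-monitor factor means
        per_mon = []
        for mid, rows in g:
            x, y = rows["x_km"].iloc[0], rows["y_km"].iloc[0]
            idx = tiny_bundle.grid.cell_index_of_points(np.array([x]), np.array([y]))[0]
            base = truth.series("pSO4").loc[tiny_bundle.grid.cells[idx].cell_id]
            per_mon.append(rows["value_ugm3"].mean() / base)
        grand = np.mean(per_mon)
        assert abs(grand - analytic_mean) < 3 * se / np.sqrt(len(per_mon))

    def test_too_many_monitors_rejected(self):
        with pytest.raises(ValueError, match="monitors"):
            generate_scenario(tiny_config(seed=9, n_monitors=10_000_000))


class TestSatellite:
    def test_zero_error_equals_truth(self):
        cfg = tiny_config(seed=10, satellite_error_sd=0.0)
        b = generate_scenario(cfg)
        for sp in cfg.species:
            np.testing.assert_allclose(
                b.satellite[sp].values, b.truth_rasters[sp].values, rtol=1e-12
            )

    def test_log_error_sd_close_to_configured(self, tiny_bundle):
        cfg = tiny_bundle.config
        sp = "pNH4"
        ratio = tiny_bundle.satellite[sp].values / tiny_bundle.truth_rasters[sp].values
        # spatially correlated field: the *pointwise* log-sd is normalised
        # to the configured value by construction
        assert ratio.size >= 10_000
        assert np.log(ratio).std() == pytest.approx(cfg.satellite_error_sd, rel=0.10)

    def test_values_non_negative(self, tiny_bundle):
        for sp, raster in tiny_bundle.satellite.items():
            assert (raster.values >= 0).all()


def test_config_validation():
    with pytest.raises(ValueError, match="positive species weight"):
        tiny_config(sector_species_weights={"agriculture": {"pNH4": 0.0},
                                            "egu_point": {"pSO4": 1.0},
                                            "nonegu_point": {"pSO4": 1.0},
                                            "onroad": {"pNO3": 1.0}})
    with pytest.raises(ValueError, match="bias factor"):
        tiny_config(bias_factors={"pSO4": -1.0, "pNO3": 1.0, "pNH4": 1.0})
    with pytest.raises(ValueError, match="no emissions"):
        tiny_config(sector_species_weights={"agriculture": {"pNH4": 1.0},
                                            "egu_point": {"pSO4": 1.0},
                                            "nonegu_point": {"pSO4": 1.0},
                                            "onroad": {"pNH4": 1.0}})
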