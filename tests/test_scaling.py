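"""Scaling-factor computation and application under every scheme."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from rfmscale import (
    RegionSet,
    ScalingScheme,
    SpeciesField,
    apply_scaling_factors,
    compute_knn_scaling_factors,
    compute_scaling_factors,
    pairs_from_field,
    pairs_from_monitors,
)
from rfmscale.regions import Region
from rfmscale.scaling import MissingObservations, UndefinedScalingFactor


def monitor_frame(rows):
    """rows: (monitor_id, cell_id, species, O, x, y)"""
    return pd.DataFrame(
        rows, columns=["monitor_id", "cell_id", "species", "annual_mean", "x_km", "y_km"]
    )


def field_from_pairs(cell_values, species="pSO4"):
    return SpeciesField.from_arrays(list(cell_values), species, list(cell_values.values()))


class TestRatioOfMeans:
    def test_identity_when_obs_equal_pred(self):
        model = field_from_pairs({"a": 2.0, "b": 5.0})
        mon = monitor_frame([("m1", "a", "pSO4", 2.0, 0, 0), ("m2", "b", "pSO4", 5.0, 1, 1)])
        sfs = compute_scaling_factors(model, mon, ScalingScheme("nationwide", "monitor"))
        assert sfs.lookup("nation", "pSO4") == pytest.approx(1.0)

    def test_ratio_of_means_not_mean_of_ratios(self):
        # O = [2, 4], P = [1, 1]: SF = (6/2) / (2/2) = 3
        model = field_from_pairs({"a": 1.0, "b": 1.0})
        mon = monitor_frame([("m1", "a", "pSO4", 2.0, 0, 0), ("m2", "b", "pSO4", 4.0, 1, 1)])
        sfs = compute_scaling_factors(model, mon, ScalingScheme("nationwide", "monitor"))
        assert sfs.lookup("nation", "pSO4") == pytest.approx(3.0)
        assert sfs.table["n_pairs"].iloc[0] == 2

    def test_zero_prediction_sum_is_error(self):
        model = field_from_pairs({"a": 0.0})
        mon = monitor_frame([("m1", "a", "pSO4", 2.0, 0, 0)])
        with pytest.raises(UndefinedScalingFactor):
            compute_scaling_factors(model, mon, ScalingScheme("nationwide", "monitor"))

    def test_brute_force_oracle_random_pairs(self):
        rng = np.random.default_rng(5)
        cells = [f"c{i}" for i in range(40)]
        model = SpeciesField.from_arrays(cells, "pNO3", rng.uniform(0.5, 3, 40))
        rows = [
            (f"m{i}", cells[rng.integers(0, 40)], "pNO3", rng.uniform(0.5, 3), 0.0, 0.0)
            for i in range(25)
        ]
        mon = monitor_frame(rows)
        sfs = compute_scaling_factors(model, mon, ScalingScheme("nationwide", "monitor"))
        pred = model.series("pNO3")
        num = sum(r[3] for r in rows) / len(rows)
        den = sum(pred.loc[r[1]] for r in rows) / len(rows)
        assert sfs.lookup("nation", "pNO3") == pytest.approx(num / den, rel=1e-14)


class TestSchemeValidation:
    def test_knn_requires_monitor_source(self):
        with pytest.raises(ValueError, match="monitor"):
            ScalingScheme("knn_monitors", "satellite")

    def test_grid_cell_requires_satellite(self):
        with pytest.raises(ValueError, match="satellite"):
            ScalingScheme("grid_cell", "monitor")

    def test_relaxable_by_flag(self):
        ScalingScheme("grid_cell", "monitor", allow_any_source=True)


class TestStateScheme:
    def build(self):
        # two 10x10 states side by side; cells are 1 km so centroids are clear
        states = RegionSet(
            [Region("west", "state", box(0, 0, 10, 10)), Region("east", "state", box(10, 0, 20, 10))]
        )
        from rfmscale.grid import GridCell, GridSpec, VariableGrid

        spec = GridSpec(size_ladder_km=(10.0, 5.0, 1.0), domain_extent=(20.0, 10.0),
                        pop_threshold=1e9, density_threshold=1e9)
        cells = [
            GridCell("w1", (0, 0, 10, 10), 10.0, location_class="rural"),
            GridCell("e1", (10, 0, 20, 10), 10.0, location_class="rural"),
        ]
        return states, VariableGrid(cells, spec)

    def test_state_restriction_and_fallback(self):
        states, grid = self.build()
        model = SpeciesField(
            pd.DataFrame(
                dict(cell_id=["w1", "e1", "w1", "e1"],
                     species=["pSO4", "pSO4", "pNH4", "pNH4"],
                     sector="total",
                     value=[1.0, 2.0, 1.0, 2.0])
            )
        )
        mon = monitor_frame(
            [("m1", "w1", "pSO4", 3.0, 5, 5), ("m2", "e1", "pSO4", 4.0, 15, 5),
             ("m3", "w1", "pNH4", 5.0, 5, 5)]  # east has no pNH4 monitor
        )
        scheme = ScalingScheme("state", "monitor", fallback_map={"east": "west"})
        sfs = compute_scaling_factors(model, mon, scheme, regions=states, grid=grid)
        assert sfs.lookup("west", "pSO4") == pytest.approx(3.0)
        assert sfs.lookup("east", "pSO4") == pytest.approx(2.0)
        # donor state's SF is reused verbatim for the missing species
        assert sfs.lookup("east", "pNH4") == sfs.lookup("west", "pNH4") == pytest.approx(5.0)
        prov = sfs.table.set_index(["scope_id", "species"])["provenance"]
        assert prov.loc[("east", "pNH4")] == "fallback from west"

    def test_no_fallback_raises(self):
        states, grid = self.build()
        model = field_from_pairs({"w1": 1.0, "e1": 2.0}, species="pNH4")
        mon = monitor_frame([("m3", "w1", "pNH4", 5.0, 5, 5)])
        with pytest.raises(MissingObservations):
            compute_scaling_factors(
                model, mon, ScalingScheme("state", "monitor"), regions=states, grid=grid
            )

    def test_auto_fallback_picks_nearest(self):
        states, grid = self.build()
        model = field_from_pairs({"w1": 1.0, "e1": 2.0}, species="pNH4")
        mon = monitor_frame([("m3", "w1", "pNH4", 5.0, 5, 5)])
        sfs = compute_scaling_factors(
            model, mon, ScalingScheme("state", "monitor"), regions=states, grid=grid,
            auto_fallback=True,
        )
        assert sfs.lookup("east", "pNH4") == sfs.lookup("west", "pNH4")


class TestKnn:
    def test_uniform_neighborhood(self, tiny_bundle):
        # 5 monitors, all O = 2 with co-located P = 1 -> SF = 2 for any cell
        grid = tiny_bundle.grid
        cells = [c.cell_id for c in grid.cells[:5]]
        xy = [grid.cells[i].centroid for i in range(5)]
        model = SpeciesField.from_arrays(grid.cell_ids, "pSO4", np.ones(len(grid)))
        mon = monitor_frame(
            [(f"m{i}", cells[i], "pSO4", 2.0, xy[i][0], xy[i][1]) for i in range(5)]
        )
        sfs = compute_knn_scaling_factors(model, mon, grid, k=5)
        assert np.allclose(sfs.table["sf"], 2.0)

    def test_k1_monitor_in_cell(self, tiny_bundle):
        grid = tiny_bundle.grid
        rng = np.random.default_rng(0)
        model = SpeciesField.from_arrays(grid.cell_ids, "pSO4", rng.uniform(1, 2, len(grid)))
        cell = grid.cells[10]
        mon = monitor_frame([("m0", cell.cell_id, "pSO4", 3.0, *cell.centroid)])
        sfs = compute_knn_scaling_factors(model, mon, grid, k=1)
        expected = 3.0 / model.series("pSO4").loc[cell.cell_id]
        assert sfs.lookup(cell.cell_id, "pSO4") == pytest.approx(expected)

    def test_too_few_monitors(self, tiny_bundle):
        grid = tiny_bundle.grid
        model = SpeciesField.from_arrays(grid.cell_ids, "pSO4", np.ones(len(grid)))
        mon = monitor_frame([("m0", grid.cells[0].cell_id, "pSO4", 1.0, 1, 1)])
        with pytest.raises(ValueError, match="monitors"):
            compute_knn_scaling_factors(model, mon, grid, k=5)

    def test_tie_break_by_monitor_id(self):
        from rfmscale.grid import GridCell, GridSpec, VariableGrid

        spec = GridSpec(size_ladder_km=(2.0, 1.0), domain_extent=(2.0, 2.0),
                        pop_threshold=1e9, density_threshold=1e9)
        grid = VariableGrid([GridCell("c", (0, 0, 2, 2), 2.0, location_class="urban")], spec)
        model = SpeciesField.from_arrays(["c"], "pSO4", [1.0])
        # two monitors equidistant from the centroid (1,1); k=1 must pick 'a'
        mon = monitor_frame(
            [("b", "c", "pSO4", 9.0, 0.0, 1.0), ("a", "c", "pSO4", 5.0, 2.0, 1.0)]
        )
        sfs = compute_knn_scaling_factors(model, mon, grid, k=1)
        assert sfs.lookup("c", "pSO4") == pytest.approx(5.0)

    def test_matches_exhaustive_sort_oracle(self, tiny_bundle, tiny_monitors):
        grid = tiny_bundle.grid
        model = tiny_bundle.model_fields
        sfs = compute_knn_scaling_factors(model, tiny_monitors, grid, k=5)
        pred = model.total().data.set_index(["cell_id", "species"])["value"]
        rng = np.random.default_rng(9)
        for ci in rng.choice(len(grid), size=30, replace=False):
            cell = grid.cells[ci]
            cx, cy = cell.centroid
            for sp in ("pSO4", "pNH4"):
                g = tiny_monitors[tiny_monitors["species"] == sp]
                ranked = sorted(
                    ((m.x_km - cx) ** 2 + (m.y_km - cy) ** 2, m.monitor_id, m.annual_mean,
                     pred.loc[(m.cell_id, sp)])
                    for m in g.itertuples()
                )[:5]
                sf = sum(r[2] for r in ranked) / sum(r[3] for r in ranked)
                assert sfs.lookup(cell.cell_id, sp) == pytest.approx(sf, rel=1e-12)


class TestApply:
    def test_unit_sf_is_identity(self, tiny_bundle, tiny_monitors):
        model = tiny_bundle.model_fields
        sfs = compute_scaling_factors(model, tiny_monitors, ScalingScheme("nationwide", "monitor"))
        sfs.table["sf"] = 1.0
        out = apply_scaling_factors(model, sfs)
        pd.testing.assert_frame_equal(out.field.data, model.data)

    def test_simple_multiplication(self):
        model = field_from_pairs({"a": 2.0})
        mon = monitor_frame([("m1", "a", "pSO4", 3.0, 0, 0)])
        sfs = compute_scaling_factors(model, mon, ScalingScheme("nationwide", "monitor"))
        out = apply_scaling_factors(model, sfs)
        assert out.field.series("pSO4").loc["a"] == pytest.approx(3.0)  # SF = 1.5

    def test_sectors_share_cell_factor(self, tiny_bundle, tiny_satellite):
        model = tiny_bundle.model_fields
        sfs = compute_scaling_factors(model, tiny_satellite, ScalingScheme("grid_cell", "satellite"))
        out = apply_scaling_factors(model, sfs).field
        # scaled total equals sum of scaled sectors (linearity preserved)
        total = out.total().data.set_index(["cell_id", "species"])["value"]
        by_hand = out.data.groupby(["cell_id", "species"])["value"].sum()
        pd.testing.assert_series_equal(total.sort_index(), by_hand.sort_index(), check_names=False)

    def test_nationwide_scaling_zeroes_aggregate_bias(self, bundle, monitors):
        model = bundle.model_fields
        sfs = compute_scaling_factors(model, monitors, ScalingScheme("nationwide", "monitor"))
        scaled = apply_scaling_factors(model, sfs).field
        pairs = pairs_from_monitors(scaled, monitors)
        for sp, g in pairs.groupby("species"):
            nmb = 100 * (g["P"] - g["O"]).sum() / g["O"].sum()
            assert abs(nmb) < 1e-10

    def test_positivity(self, bundle, satellite):
        model = bundle.model_fields
        sfs = compute_scaling_factors(model, satellite, ScalingScheme("grid_cell", "satellite"))
        out = apply_scaling_factors(model, sfs).field
        assert (out.data["value"] >= 0).all()

    def test_city_cells_outside_flagged_unscaled(self, tiny_bundle, tiny_satellite):
        model = tiny_bundle.model_fields
        scheme = ScalingScheme("city_boundary", "satellite")
        sfs = compute_scaling_factors(
            model, tiny_satellite, scheme, regions=tiny_bundle.cities, grid=tiny_bundle.grid
        )
        out = apply_scaling_factors(model, sfs, grid=tiny_bundle.grid, regions=tiny_bundle.cities)
        unscaled = set(out.unscaled_cell_ids)
        assert unscaled  # some cells lie outside every city
        before = model.data.set_index(["cell_id", "species", "sector"])["value"]
        after = out.field.data.set_index(["cell_id", "species", "sector"])["value"]
        for cid in list(unscaled)[:20]:
            pd.testing.assert_series_equal(
                before.xs(cid, level="cell_id"), after.xs(cid, level="cell_id")
            )

    def test_uniform_sf_preserves_pearson_r2(self, bundle, monitors):
        model = bundle.model_fields
        sfs = compute_scaling_factors(model, monitors, ScalingScheme("nationwide", "monitor"))
        scaled = apply_scaling_factors(model, sfs).field
        a = pairs_from_monitors(model, monitors)
        b = pairs_from_monitors(scaled, monitors)
        for sp in a["species"].unique():
            ra = np.corrcoef(a[a.species == sp]["P"], a[a.species == sp]["O"])[0, 1] ** 2
            rb = np.corrcoef(b[b.species == sp]["P"], b[b.species == sp]["O"])[0, 1] ** 2
            assert abs(ra - rb) < 1e-12
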