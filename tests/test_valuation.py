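import itertools

import numpy as np
import pandas as pd
import pytest

from luces import (
    CropTable,
    LandUseMap,
    classify_levels,
    compute_esv,
    compute_uesv_grid,
    derive_unit_value,
    load_coefficients,
    load_crop_table,
)
from luces.exceptions import ArgumentError, FormatError
from luces.valuation import CATEGORIES, SERVICES, esv_by_category

from conftest import lum


def one_hectare(code):
    """A single-cell map whose cell covers exactly 1 hm²."""
    return LandUseMap(np.array([[code]], dtype=np.int16), cell_size=100.0)


class TestDeriveUnitValue:
    def test_single_crop_closed_form(self):
        ct = CropTable(
            pd.DataFrame(
                {"crop": ["x"], "sown_area_hm2": [123.0],
                 "yield_t_per_hm2": [1.0], "price_yuan_per_t": [700.0]}
            )
        )
        assert derive_unit_value(ct) == pytest.approx(100.0)

    def test_linear_in_prices(self):
        ct = load_crop_table()
        doubled = CropTable(ct.table.assign(price_yuan_per_t=2 * ct.table["price_yuan_per_t"]))
        assert derive_unit_value(doubled) == pytest.approx(2 * derive_unit_value(ct))

    def test_packaged_table_matches_row_by_row_oracle(self):
        # independent spreadsheet-style evaluation over the packaged rows
        rows = [
            (308968, 5.84, 2413),
            (236884, 5.57, 1771),
            (17000, 3.20, 2400),
            (5206, 2.64, 3529),
            (464, 1.44, 3488),
            (8127, 6.59, 2000),
        ]
        total = sum(m * q * p for m, q, p in rows)
        M = sum(m for m, _, _ in rows)
        expected = total / M / 7.0
        assert derive_unit_value(load_crop_table()) == pytest.approx(expected)

    def test_positive_values_enforced(self):
        with pytest.raises(ArgumentError):
            CropTable(
                pd.DataFrame(
                    {"crop": ["x"], "sown_area_hm2": [-1.0],
                     "yield_t_per_hm2": [1.0], "price_yuan_per_t": [1.0]}
                )
            )


class TestCoefficientTable:
    def test_packaged_cells(self):
        t = load_coefficients()
        assert t.values.loc["hydrology regulation", "water"] == 1766.01
        assert t.values.loc["water supply", "built"] == -268.66
        assert t.values.loc["food production", "built"] == 0.00
        assert t.values.loc["climate regulation", "woodland"] == 121.43
        assert t.values.loc["food production", "cultivated"] == 14.68

    def test_service_and_category_structure(self):
        t = load_coefficients()
        assert set(t.values.index) == set(SERVICES)
        assert set(t.category.values()) == set(CATEGORIES)
        assert len(t.services_in("regulating")) == 4

    def test_missing_cell_rejected(self, tmp_path):
        t = load_coefficients()
        df = t.values.reset_index()
        df.insert(1, "category", [t.category[s] for s in df["service"]])
        df.loc[0, "water"] = np.nan
        p = tmp_path / "c.csv"
        df.to_csv(p, index=False)
        with pytest.raises(FormatError):
            load_coefficients(p)

    def test_missing_service_rejected(self, tmp_path):
        t = load_coefficients()
        df = t.values.reset_index().iloc[1:]
        df.insert(1, "category", [t.category[s] for s in df["service"]])
        p = tmp_path / "c.csv"
        df.to_csv(p, index=False)
        with pytest.raises(FormatError):
            load_coefficients(p)


class TestComputeEsv:
    def test_all_nodata_map_is_zero(self):
        t = load_coefficients()
        esv = compute_esv(lum([[0, 0], [0, 0]]), t)
        assert (esv == 0).all()

    def test_one_hectare_water_hydrology(self):
        t = load_coefficients()
        esv = compute_esv(one_hectare(4), t, services=["hydrology regulation"])
        assert esv["hydrology regulation"] == pytest.approx(1766.01)

    def test_negative_disservice_retained(self):
        t = load_coefficients()
        esv = compute_esv(one_hectare(5), t, services=["water supply"])
        assert esv["water supply"] == pytest.approx(-268.66)

    def test_two_class_climate_regulation_sum(self):
        t = load_coefficients()
        m = LandUseMap(np.array([[1, 2]], dtype=np.int16), cell_size=100.0)
        esv = compute_esv(m, t, services=["climate regulation"])
        assert esv["climate regulation"] == pytest.approx(6.22 + 121.43)

    def test_linearity_over_disjoint_supports(self, map_pair_small):
        t0, _ = map_pair_small
        table = load_coefficients()
        left = t0.classes.copy()
        left[:, 12:] = 0
        right = t0.classes.copy()
        right[:, :12] = 0
        total = compute_esv(t0, table)
        parts = compute_esv(LandUseMap(left), table) + compute_esv(
            LandUseMap(right), table
        )
        np.testing.assert_allclose(total.to_numpy(), parts.to_numpy(), rtol=1e-12)

    def test_category_totals_sum_to_grand_total(self, map_pair_small):
        t0, _ = map_pair_small
        table = load_coefficients()
        esv = compute_esv(t0, table)
        cats = esv_by_category(esv, table)
        assert cats["total"] == pytest.approx(esv["total"])
        assert cats[list(CATEGORIES)].sum() == pytest.approx(esv["total"])


class TestUesvGrid:
    def test_uniform_map_has_constant_uesv(self):
        t = load_coefficients()
        m = LandUseMap(np.full((8, 8), 4, dtype=np.int16), cell_size=250.0)
        grid = compute_uesv_grid(m, t, grid_size=1000.0)
        u = grid.uesv
        assert np.allclose(u, u.flat[0])

    def test_edge_grid_same_composition_same_uesv(self):
        t = load_coefficients()
        # 6×6 water map, 4-cell grids: the right/bottom edge grids hold
        # fewer cells but identical composition → identical UESV
        m = LandUseMap(np.full((6, 6), 4, dtype=np.int16), cell_size=500.0)
        grid = compute_uesv_grid(m, t, grid_size=2000.0)
        assert grid.area_hm2[0, 0] != grid.area_hm2[0, 1]
        assert grid.uesv[0, 0] == pytest.approx(grid.uesv[0, 1])

    def test_hand_computed_toy(self):
        t = load_coefficients()
        # 2×2 grids of 2×2 cells, each cell 0.25 hm² (50 m)
        m = LandUseMap(
            np.array(
                [[1, 1, 2, 2], [1, 1, 2, 2], [4, 4, 5, 5], [4, 4, 5, 5]],
                dtype=np.int16,
            ),
            cell_size=50.0,
        )
        grid = compute_uesv_grid(m, t, grid_size=100.0)
        V = t.values
        for gi, gj, cls in [(0, 0, "cultivated"), (0, 1, "woodland"),
                            (1, 0, "water"), (1, 1, "built")]:
            expected = V[cls].sum()  # per-hm² column total
            assert grid.uesv[gi, gj] == pytest.approx(expected)

    def test_grid_totals_conserve_map_total(self, map_pair_small):
        t0, _ = map_pair_small
        table = load_coefficients()
        grid = compute_uesv_grid(t0, table, grid_size=120.0)
        total_map = compute_esv(t0, table)["total"]
        total_grid = np.nansum(grid.uesv * grid.area_hm2)
        assert total_grid == pytest.approx(total_map, rel=1e-6)

    def test_grid_smaller_than_cell_rejected(self, map_pair_small):
        with pytest.raises(ArgumentError):
            compute_uesv_grid(map_pair_small[0], load_coefficients(), grid_size=10.0)


def brute_force_best_gvf(values, k):
    """Exhaustive search over contiguous partitions of the sorted values."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    sdam = ((v - v.mean()) ** 2).sum()

    def sdcm(partition):
        return sum(((chunk - chunk.mean()) ** 2).sum() for chunk in partition)

    best = None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        chunks = [v[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
        s = sdcm(chunks)
        if best is None or s < best:
            best = s
    return 1 - best / sdam if sdam > 0 else 1.0


def gvf_of_labels(values, labels):
    v = np.asarray(values, dtype=float)
    sdam = ((v - v.mean()) ** 2).sum()
    s = sum(
        ((v[labels == l] - v[labels == l].mean()) ** 2).sum()
        for l in np.unique(labels)
    )
    return 1 - s / sdam if sdam > 0 else 1.0


class TestClassifyLevels:
    def test_five_distinct_values_get_five_levels(self):
        levels = classify_levels(np.array([3.0, 1.0, 5.0, 2.0, 4.0]), k=5)
        assert levels.tolist() == [3, 1, 5, 2, 4]

    def test_two_separated_clusters_split_at_gap(self):
        vals = np.array([1.0, 1.1, 0.9, 10.0, 10.2, 9.8])
        levels = classify_levels(vals, k=2)
        assert levels.tolist() == [1, 1, 1, 2, 2, 2]

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            vals = rng.random(rng.integers(6, 13))
            labels = classify_levels(vals, k=3)
            assert gvf_of_labels(vals, labels) == pytest.approx(
                brute_force_best_gvf(vals, 3), abs=1e-12
            )

    def test_levels_monotone_in_value(self):
        rng = np.random.default_rng(7)
        vals = rng.random(40)
        labels = classify_levels(vals, k=5)
        order = np.argsort(vals)
        assert (np.diff(labels[order]) >= 0).all()

    def test_nan_maps_to_level_zero(self):
        levels = classify_levels(np.array([1.0, np.nan, 2.0, 3.0]), k=3)
        assert levels[1] == 0 and set(levels[[0, 2, 3]]) == {1, 2, 3}

    def test_degenerate_values_collapse_with_warning(self):
        with pytest.warns(UserWarning, match="distinct"):
            levels = classify_levels(np.array([1.0, 1.0, 2.0]), k=5)
        assert levels.max() <= 2
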