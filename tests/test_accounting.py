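import numpy as np
import pandas as pd
import pytest

from transbound.accounting import (
    STOCK_CLASSES,
    cpi_adjust,
    cpi_table_from_frame,
    fill_prices,
    partition_by_stock_class,
    regional_rollup,
    revenue,
    revenue_table,
    stock_account_table,
    summary_report,
)
from transbound.trends import CatchSeries


FLAT_CPI = {y: 100.0 for y in range(2000, 2021)}


class TestCpiAdjust:
    def test_identity(self):
        assert cpi_adjust(100.0, 2010, 2010, {2010: 218.0}) == 100.0

    def test_ratio_arithmetic(self):
        cpi = {2010: 100.0, 2019: 120.0}
        assert cpi_adjust(100.0, 2010, 2019, cpi) == pytest.approx(120.0)

    def test_involution(self):
        cpi = {2010: 218.056, 2019: 255.657}
        v = cpi_adjust(cpi_adjust(123.45, 2010, 2019, cpi), 2019, 2010, cpi)
        assert v == pytest.approx(123.45, rel=1e-9)

    def test_missing_year_rejected(self):
        with pytest.raises(KeyError, match="2019"):
            cpi_adjust(1.0, 2010, 2019, {2010: 100.0})

    def test_annual_index_is_monthly_mean(self):
        df = pd.DataFrame(
            {"year": [2010] * 12, "month": range(1, 13), "cpi": range(100, 112)}
        )
        assert cpi_table_from_frame(df)[2010] == pytest.approx(105.5)


class TestRevenue:
    def test_constant_catch_and_price_closed_form(self):
        s = CatchSeries("S", "R", tuple(range(2005, 2015)), (10.0,) * 10)
        annual, mean = revenue(s, {y: 1000.0 for y in s.years}, FLAT_CPI)
        assert all(v == pytest.approx(10_000.0) for v in annual.values())
        assert mean == pytest.approx(10_000.0)

    def test_zero_catch_years_contribute_zero(self):
        s = CatchSeries("S", "R", (2005, 2006), (0.0, 10.0))
        annual, mean = revenue(s, {2005: 500.0, 2006: 1000.0}, FLAT_CPI)
        assert annual[2005] == 0.0
        assert mean == pytest.approx(10.0 * 1000.0 / 10)

    def test_cpi_standardization_applied(self):
        cpi = {2010: 100.0, 2019: 150.0}
        s = CatchSeries("S", "R", (2010,), (2.0,))
        annual, _ = revenue(s, {2010: 100.0}, cpi)
        assert annual[2010] == pytest.approx(300.0)

    def test_window_mean_divides_by_window_length(self):
        # only 2 of the 10 window years have data -> they still divide by 10
        s = CatchSeries("S", "R", (2005, 2006), (10.0, 10.0))
        _, mean = revenue(s, {2005: 100.0, 2006: 100.0}, FLAT_CPI)
        assert mean == pytest.approx(200.0)

    def test_currency_invariance(self):
        # summing in 2010 USD then adjusting == adjusting per-year then summing
        cpi = {2010: 100.0, 2019: 137.5}
        rng = np.random.default_rng(3)
        catches = rng.uniform(1, 100, 10)
        prices = {2005 + i: float(p) for i, p in enumerate(rng.uniform(100, 900, 10))}
        s = CatchSeries("S", "R", tuple(range(2005, 2015)), tuple(catches))
        annual, mean = revenue(s, prices, cpi)
        base_total = sum(c * prices[y] for y, c in zip(s.years, s.catch))
        assert sum(annual.values()) == pytest.approx(
            cpi_adjust(base_total, 2010, 2019, cpi), rel=1e-12
        )


class TestFillPrices:
    toy = pd.DataFrame(
        [
            {"species_id": "S1", "country_id": "C1", "year": 2005, "price": 100.0},
            {"species_id": "S1", "country_id": "C1", "year": 2010, "price": 200.0},
            {"species_id": "S1", "country_id": "C2", "year": 2007, "price": 300.0},
            {"species_id": "S2", "country_id": "C1", "year": 2007, "price": 50.0},
        ]
    )

    def test_exact_match(self):
        filled, rep = fill_prices(self.toy, [("S1", "C1", 2010)])
        assert filled.iloc[0]["price"] == 200.0
        assert filled.iloc[0]["fill_method"] == "exact"
        assert rep.n_exact == 1

    def test_nearest_year_within_pair(self):
        filled, rep = fill_prices(self.toy, [("S1", "C1", 2006)])
        assert filled.iloc[0]["price"] == 100.0  # 2005 closer than 2010
        assert filled.iloc[0]["fill_method"] == "nearest_year"
        # equidistant tie goes to the earlier year
        filled2, _ = fill_prices(self.toy, [("S1", "C1", 2007)])
        assert filled2.iloc[0]["price"] == 100.0

    def test_country_mean_fallback(self):
        # S1 has no C3 prices at all: mean across countries at nearest year
        filled, rep = fill_prices(self.toy, [("S1", "C3", 2007)])
        assert filled.iloc[0]["fill_method"] == "country_mean"
        assert filled.iloc[0]["price"] == pytest.approx(300.0)  # only C2 has 2007
        assert rep.n_country_mean == 1

    def test_unfillable_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            filled, rep = fill_prices(self.toy, [("S9", "C1", 2007)])
        assert filled.empty and rep.n_dropped == 1


def _toy_world_tables():
    """Three stocks: transboundary (A), excluded (B), plus a discrete species."""
    classification = pd.DataFrame(
        [
            {"species_id": "S1", "region_id": "A", "stock_label": "transboundary",
             "species_label": "transboundary"},
            {"species_id": "S1", "region_id": "B", "stock_label": "excluded_stock",
             "species_label": "transboundary"},
            {"species_id": "S2", "region_id": "A", "stock_label": "discrete_stock",
             "species_label": "discrete"},
        ]
    )
    catch = pd.DataFrame(
        [
            {"species_id": s, "region_id": r, "year": y, "tonnes": t}
            for (s, r, t) in (("S1", "A", 10.0), ("S1", "B", 4.0), ("S2", "A", 2.0))
            for y in range(2005, 2015)
        ]
    )
    prices = pd.DataFrame(
        [
            {"species_id": s, "country_id": c, "year": y, "price": p}
            for (s, c, p) in (("S1", "CA", 100.0), ("S1", "CB", 100.0), ("S2", "CA", 50.0))
            for y in range(2005, 2015)
        ]
    )
    return classification, catch, prices


class TestPartition:
    def test_class_totals_conserve_grand_total(self):
        classification, catch, prices = _toy_world_tables()
        rev, _ = revenue_table(
            catch, prices, FLAT_CPI, {"A": "CA", "B": "CB"}
        )
        table = stock_account_table(classification, catch, rev)
        totals = partition_by_stock_class(table)
        assert set(totals["stock_class"]) == set(STOCK_CLASSES)
        assert totals["mean_annual_catch"].sum() == pytest.approx(16.0, rel=1e-6)
        assert totals["mean_annual_revenue"].sum() == pytest.approx(
            (10 + 4) * 100.0 + 2 * 50.0, rel=1e-6
        )

    def test_excluded_region_catch_lands_in_excluded_row(self):
        classification, catch, prices = _toy_world_tables()
        rev, _ = revenue_table(catch, prices, FLAT_CPI, {"A": "CA", "B": "CB"})
        table = stock_account_table(classification, catch, rev)
        totals = partition_by_stock_class(table).set_index("stock_class")
        assert totals.loc["excluded_stock", "mean_annual_catch"] == pytest.approx(4.0)
        assert totals.loc["transboundary", "mean_annual_catch"] == pytest.approx(10.0)
        assert totals.loc["discrete_stock", "mean_annual_catch"] == pytest.approx(2.0)

    def test_discrete_only_world_has_zero_other_rows(self):
        cls = pd.DataFrame(
            [{"species_id": "S2", "region_id": "A", "stock_label": "discrete_stock",
              "species_label": "discrete"}]
        )
        catch = pd.DataFrame(
            [{"species_id": "S2", "region_id": "A", "year": 2010, "tonnes": 5.0}]
        )
        rev, _ = revenue_table(
            catch,
            pd.DataFrame([{"species_id": "S2", "country_id": "CA", "year": 2010,
                           "price": 10.0}]),
            FLAT_CPI, {"A": "CA"},
        )
        totals = partition_by_stock_class(
            stock_account_table(cls, catch, rev)
        ).set_index("stock_class")
        assert totals.loc["transboundary", "mean_annual_catch"] == 0.0
        assert totals.loc["excluded_stock", "mean_annual_revenue"] == 0.0
        assert (totals["mean_annual_catch"] >= 0).all()

    def test_unclassified_stock_rejected(self):
        classification, catch, prices = _toy_world_tables()
        rev, _ = revenue_table(catch, prices, FLAT_CPI, {"A": "CA", "B": "CB"})
        with pytest.raises(ValueError, match="unclassified"):
            stock_account_table(classification.iloc[:2], catch, rev)

    def test_brute_force_total_revenue(self):
        """Synthetic world totals equal an independent triple-loop sum."""
        from transbound.synth import WorldSpec, generate_world

        world = generate_world(WorldSpec(seed=5, n_species=5))
        cpi = cpi_table_from_frame(world.cpi)
        region_country = {r.region_id: r.grouping_country for r in world.regions}
        rev, _ = revenue_table(world.catch, world.prices, cpi, region_country)
        price_lookup = {
            (r.species_id, r.country_id, r.year): r.price
            for r in world.prices.itertuples(index=False)
        }
        factor = cpi[2019] / cpi[2010]
        expected = 0.0
        for row in world.catch.itertuples(index=False):
            p = price_lookup[(row.species_id, region_country[row.region_id], row.year)]
            expected += row.tonnes * p * factor
        assert rev["revenue"].sum() == pytest.approx(expected, rel=1e-9)


class TestRollup:
    meta = pd.DataFrame(
        {
            "grouping_country": {"A": "CA", "B": "CB", "C": "CC"},
            "un_subregion": {"A": "North", "B": "North", "C": "South"},
            "area_km2": {"A": 100.0, "B": 400.0, "C": 250.0},
        }
    ).rename_axis("region_id")

    def stock_table(self, scale=1.0):
        return pd.DataFrame(
            [
                {"species_id": "S1", "region_id": "A", "stock_label": "transboundary",
                 "species_label": "transboundary",
                 "mean_catch": 10.0 * scale, "mean_revenue": 1000.0 * scale},
                {"species_id": "S1", "region_id": "B", "stock_label": "transboundary",
                 "species_label": "transboundary",
                 "mean_catch": 30.0 * scale, "mean_revenue": 3000.0 * scale},
                {"species_id": "S2", "region_id": "C", "stock_label": "transboundary",
                 "species_label": "transboundary",
                 "mean_catch": 5.0 * scale, "mean_revenue": 500.0 * scale},
            ]
        )

    def test_per_km2_hand_computation(self):
        countries, subregions = regional_rollup(self.stock_table(), self.meta)
        c = countries.set_index("country_id")
        assert c.loc["CA", "catch_per_km2"] == pytest.approx(10.0 / 100.0)
        assert c.loc["CB", "revenue_per_km2"] == pytest.approx(3000.0 / 400.0)
        assert c.loc["CC", "catch_per_km2"] == pytest.approx(5.0 / 250.0)
        north = subregions.set_index("un_subregion").loc["North"]
        assert north["mean_revenue"] == pytest.approx((1000.0 + 3000.0) / 2)
        assert north["sd_revenue"] == pytest.approx(np.std([1000, 3000], ddof=1))
        assert north["area_km2"] == pytest.approx(500.0)

    def test_single_country_subregion_sd_flagged(self):
        _, subregions = regional_rollup(self.stock_table(), self.meta)
        south = subregions.set_index("un_subregion").loc["South"]
        assert south["sd_flag"] and south["sd_revenue"] == 0.0
        north = subregions.set_index("un_subregion").loc["North"]
        assert not north["sd_flag"]

    def test_doubling_revenue_doubles_subregion_mean(self):
        _, s1 = regional_rollup(self.stock_table(1.0), self.meta)
        _, s2 = regional_rollup(self.stock_table(2.0), self.meta)
        assert np.allclose(2 * s1["mean_revenue"], s2["mean_revenue"])
        assert np.allclose(2 * s1["mean_catch_per_km2"], s2["mean_catch_per_km2"])

    def test_area_counts_only_hosting_regions(self):
        # drop the stock in B: CB no longer hosts a transboundary stock
        table = self.stock_table().iloc[[0, 2]]
        countries, _ = regional_rollup(table, self.meta)
        assert "CB" not in set(countries["country_id"])

    def test_missing_subregion_label_rejected(self):
        meta = self.meta.copy()
        meta.loc["C", "un_subregion"] = ""
        with pytest.raises(ValueError, match="sub-region"):
            regional_rollup(self.stock_table(), meta)

    def test_summary_report_mentions_totals(self):
        classification, catch, prices = _toy_world_tables()
        rev, _ = revenue_table(catch, prices, FLAT_CPI, {"A": "CA", "B": "CB"})
        table = stock_account_table(classification, catch, rev)
        totals = partition_by_stock_class(table)
        meta = pd.DataFrame(
            {
                "grouping_country": {"A": "CA", "B": "CB"},
                "un_subregion": {"A": "North", "B": "North"},
                "area_km2": {"A": 10.0, "B": 10.0},
            }
        ).rename_axis("region_id")
        countries, _ = regional_rollup(table, meta)
        text = summary_report(totals, countries, 1, 1)
        assert "transboundary" in text and "Top 5 countries" in text
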